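# Methods

## Viscoplastic material model

The creep–recovery simulator uses the four-element Burgers model: a Maxwell
arm (spring `E1`, dashpot `η1`) in series with a Kelvin–Voigt arm (`E2` ∥
`η2`). It is the minimal linear model whose creep response separates into
the three experimentally distinguished parts — instantaneous elastic strain
`σ/E1`, delayed-recoverable viscoelastic strain `(σ/E2)(1 − e^{−tE2/η2})`,
and permanent flow `σt/η1` — and it has closed-form solutions in both
phases, which serve as exact oracles for the decomposition stage:

- loading (0 ≤ t ≤ t_load):
  `ε(t) = σ/E1 + σt/η1 + (σ/E2)(1 − e^{−tE2/η2})`
- recovery (t′ = t − t_load ≥ 0):
  `ε(t′) = σt_load/η1 + (σ/E2)(1 − e^{−t_load·E2/η2})·e^{−t′E2/η2}`

Setting `η1 = ∞` disables flow (viscoelastic solid; `elastic()` also sets
`E2 = ∞` for a pure spring), and `E2 = ∞` with finite `η1` gives a Maxwell
fluid. An optional `yield_stress` treats `η1` as infinite for stresses at or
below it, producing an elastic–plastic transition that the yield-bounding
stage can bracket. Degree of plasticity in closed form:
`DoP = 100 · (t_load/η1) / (1/E1 + t_load/η1 + (1/E2)(1 − e^{−t_load·E2/η2}))`.

The `LP/MP/HP_LIKE` presets share `E1 = 600 Pa` (a shear stiffness matching
hydrogels of Young's modulus ≈ 1.8 kPa at ν = 0.5), `E2 = 2000 Pa`,
`η2 = 10⁵ Pa·s`, and choose `η1` analytically so the closed-form degree of
plasticity at 100 Pa / 1 h equals 10, 20, or 30%. They are constructs that
reproduce that plasticity range at equal stiffness, not fits to any
measured material.

The standard protocol is 100 Pa held for 3600 s followed by 6400 s of
unloaded recovery, sampled at 1–4 s; the stress series for yield bounding
is 10/50/100/150 Pa.

## Creep–recovery decomposition conventions

Sampled traces cannot resolve a true strain discontinuity, so the elastic
recovery is measured as the strain drop from the last loaded sample to the
first sample more than `unload_window = 5 s` after unloading (configurable).
The permanent strain is the mean over the final `plateau_fraction = 10%` of
the recovery window; a linear fit over that window estimates residual drift
and warns if it exceeds 2% of the total strain (a fit, not endpoint
differencing, so measurement noise does not trip it). The viscoelastic part
is the remainder, clamped at zero with a warning if meaningfully negative.
Yield-stress output is deliberately a bracket (`below_lowest`, `between`,
`above_highest`), never an interpolated point estimate: with plasticity
already above tolerance at the lowest tested stress, only an upper bound is
defensible.

Indentation plasticity uses a single depth reference — the crossing of 25%
of the first cycle's peak force, linearly interpolated between samples —
because the contact point itself is unreliable on soft tissue. The synthetic
indentation generator shifts the second cycle's contact by the retained
depth and truncates at the same maximum depth, so the 25% crossing offset
equals the retained depth exactly and the second peak force drops by
`(1 − retained_fraction)^{3/2}` under the Hertz-like contact law used.

## Bead images and PIV

Bead image pairs are rendered as Gaussian spots (σ = 1 px default, ≥ 0.5 px)
at uniformly random sub-pixel positions; the deformed frame re-renders each
bead at `position + u(position)` (forward warping, so ground truth is exact,
with no image interpolation). A bead-free `exclusion_radius` emulates the
cell body the beads surround. Densities are stated per 100×100 px patch
(default 40 ≈ 16 beads per 64-px window). Fields are 2D on a single z-plane
by design.

The PIV stage cross-correlates zero-mean interrogation windows (64 px,
50% overlap default) via FFT, divides by the per-lag overlap count —
without this "unbiased" normalization the triangular envelope of
finite-window correlation biases every displacement a few percent toward
zero — and localizes the peak to sub-pixel precision with a three-point
log-Gaussian fit per axis, searching within ±window/4. Nodes whose
normalized correlation coefficient falls below 0.3 (empty or decorrelated
windows) are flagged invalid rather than raising. The normalized-median
outlier test (threshold 2.0, 0.1 µm noise floor) is available but off by
default, matching the literal pipeline.

Known limitations, reflected in the validation fixtures: a window estimates
a bead-weighted average displacement, so fields must be smooth at the window
scale for point-wise ground-truth comparisons to be meaningful; near a
dipole core the field reverses sign within one window and no single-window
estimate is well posed (in real data the cell body occupies that region).
Under the stated validity conditions (displacement ≤ window/4, ≥ 8 beads
per window, field scale ≳ window) recovery is better than 0.2 px RMSE, and
~0.1 px per vector for uniform motion at high bead density.

Drift correction registers each frame to the first by upsampled phase
correlation (sub-0.1 px) and removes the shift in Fourier space; the
reported registration shift is the negative of the applied drift.

## Averaged displacement maps

For each cell: valid vectors within `cutoff_radius = 20 µm` of the centroid
are translated so the centroid is at the origin, then positions *and*
vectors are rotated so the migration vector points along +x. Across cells,
vectors are summed per 10 µm × 10 µm bin and divided by the number of cells
— by N, not by per-bin vector counts, which is the stated normalization of
the procedure being reproduced. Bins near the cutoff therefore average in
zeros for cells that contributed no vector there; this bias is inherent to
that normalization and is documented rather than corrected. The migration
vector is the net centroid displacement over the analysis window
(configurable).

Coordinates: image origin top-left, x right (columns), y down (rows),
0-based; PIV nodes at window centres; physical quantities in µm.

## Strain and stress

Strains are central differences of (u, v) on the regular node grid
(one-sided at boundaries); `method="element"` instead evaluates
bilinear-element strains at element centres and averages them back to nodes.
Invalid displacement nodes propagate to invalid strain nodes. Plane strain
is assumed (ε_i3 = 0), so generalized Hooke's law reduces to
`σ_ij = 2µ ε_ij + λ ε_kk δ_ij` with `2µ = E/(1+ν)`,
`λ = νE/((1+ν)(1−2ν))`, `ε_kk = ε11 + ε22`; the out-of-plane normal stress
`σ33 = λ ε_kk` is nonzero and is included in the principal-stress
eigenproblem by default (toggle `include_sigma33`). Defaults `E = 2 kPa`,
`ν = 0.49`; ν = 0.5 is rejected (the λ term is singular). Because the real
matrix yields and flows, the linear-elastic estimate is an *upper bound* on
the stress actually sustained.

Near incompressibility makes point-wise stress exquisitely sensitive to
displacement noise through `λ ε_kk` (λ ≈ 33 kPa at ν = 0.49): a 0.05 px
node error contributes tens of Pa. End-to-end validation therefore compares
RMS principal-stress deviation over the analysis annulus against the
closed-form field (≤ 10% of the peak), on a dense-bead fixture whose decay
length (100 µm) is large compared with the 32-µm window.

## Tracks, motility, morphology, protrusions

Non-motile cells follow a per-axis Ornstein–Uhlenbeck jitter (stationary
s.d. 1.5 µm, relaxation 30 min), so their net displacement stays far below
threshold. Motile cells run at a constant speed drawn uniformly from
2–40 µm/h with slow angular diffusion of the 3D heading (persistence time
720 min), matching reported 3D invasion speeds; tracks are sampled every
5 min (configurable) and carry ground-truth labels. A cell is motile iff its
displacement from the first sample ever *strictly exceeds* 14 µm (one
average cell radius); proportions carry Wilson 95% intervals. "Maximum
speed" is the per-consecutive-step maximum, converted to µm/h — a sliding
window alternative was considered and rejected as less transparent; angular
diffusion biases per-step speed slightly below the nominal value (< 10%,
verified in tests).

Circularity uses pixel-count area and the length of the marching-squares
iso-0.5 contour after a 5-vertex circular moving average: the raw contour
polygon overestimates smooth perimeters by ~5% through pixel staircasing,
and the smoothing restores a rasterized disk to 1.00 ± 0.01 while moving a
square by < 1%. Masks must be single-component; exclusions (poorly
segmented cells, void artefacts) are explicit flags on the input tracks,
never silent.

Protrusion length series are fit to `A sin(2πt/T + φ) + c` by nonlinear
least squares, initialized from the dominant discrete-spectrum peak and the
corresponding quadrature amplitudes; the fit reports RMSE, recovers exact
sinusoids to machine precision, and a 6-h/5-min series with 10% noise to
within 5% in period. Protrusion length is tip-to-base-anchor distance
supplied with the series; automated tip detection is out of scope.

## Transport and optics

The partition coefficient is `K = C_sup / C_gel` with
`C_gel = (n_encapsulated − C_sup·V_sup)/V_gel` by mass balance; absorbance →
concentration conversion is a caller-supplied linear calibration (no
Beer–Lambert constants are hard-coded). `K < 0.05` is the (configurable)
convention for "tracer trapped ⇒ pores smaller than the tracer"; no numeric
threshold is canonical. Rayleigh resolution is `λ/(2·NA)`. Interpenetration
histograms pool pixel intensities (256 bins), smooth with a Gaussian of
1/64 of the intensity range, and count modes above 10% of the smoothed
maximum (boundary maxima included); the coefficient of variation quantifies
narrowness. A constant image is valid (CV 0, one mode).

## Determinism and problem sizes

All randomness flows through explicitly passed seeds
(`numpy.random.default_rng`); the pipeline fans one top-level seed into
per-stage children via `SeedSequence.spawn`, so stages re-run independently
yet reproducibly, and identical configs are bit-stable. Test and
acceptance workloads use 256–512 px images (≈ 50–200 PIV nodes), 150–400
tracks of 48–144 samples, and 2–4 s rheology sampling — sizes chosen so the
full suite validates every stage against its oracle in well under a minute
while keeping Monte-Carlo margins (seed-to-seed spread was checked across
8–20 seeds for the PIV and stress criteria).

## What the synthetic data does and does not show

The generators reproduce the *structure* of the real measurements — bead
constellations with a bead-free cell body, plasticity-graded rheology with
equal stiffness, motile/non-motile track mixtures, shapes of known
circularity — with exact ground truth, so passing tests demonstrate the
correctness of the quantification stack. They do not emulate photorealistic
microscopy (blur anisotropy, bleaching, out-of-focus light), 3D bead
volumes (fields are single-plane), cell-shaped exclusion zones, or
non-exponential real displacement decay; conclusions about algorithm
accuracy on real images carry the usual caveats. Experimentally derived
quantities (tissue stiffness, measured stress bounds around real cells)
cannot be reproduced without the raw data; the pipeline validates the
procedures, not those numbers.
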