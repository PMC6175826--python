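"""Matrix displacement mapping from tracer-bead images.

Bead image pairs are cross-correlated window by window (particle image
velocimetry with 64-px windows by default) to recover the matrix displacement
field around a cell; per-cell fields are then pooled into an averaged map:
vectors within a ~20 um cutoff of each cell centroid are translated to a
common origin, rotated so the cell's migration vector points along +x,
binned on a 10 um x 10 um grid, summed per bin, and divided by the number of
cells.

Coordinate convention: image origin top-left, x rightward (columns), y
downward (rows), 0-based pixels; PIV nodes sit at window centres; physical
outputs are in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.registration import phase_cross_correlation

__all__ = [
    "BeadImagePair", "DisplacementField", "AveragedMap",
    "correct_drift", "piv_displacement_field", "filter_vectors",
    "max_matrix_displacement", "average_displacement_map",
]

from .synth.beads import BeadImagePair  # canonical container for image pairs


@dataclass
class DisplacementField:
    """Gridded 2D displacement vectors in um.

    grid_x, grid_y : node positions (um), regular 2D grids.
    u, v           : displacement components (um).
    valid_mask     : per-node reliability flag.
    window, mesh_size : PIV window and node spacing (px) used.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid_mask: np.ndarray
    window: int = 64
    mesh_size: int = 32
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.grid_x, self.grid_y, self.u, self.v,
                                    self.valid_mask)}
        if len(shapes) != 1:
            raise ValueError("all field arrays must share a shape")
        if not np.all(np.isfinite(self.u[self.valid_mask])) or \
           not np.all(np.isfinite(self.v[self.valid_mask])):
            raise ValueError("non-finite displacement on valid nodes")

    def magnitudes(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class AveragedMap:
    """Multi-cell averaged displacement map on square bins.

    ``mean_u``/``mean_v`` are per-bin vector sums divided by the number of
    cells (the stated normalization — by N cells, not by per-bin counts).
    """

    bin_edges: np.ndarray  # um, shared by both axes
    mean_u: np.ndarray
    mean_v: np.ndarray
    n_cells: int
    cutoff_radius: float
    counts: np.ndarray | None = None  # vectors contributing per bin

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def correct_drift(stack: np.ndarray,
                  upsample_factor: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Register every frame of a stack to the first by rigid translation.

    Subpixel shifts are estimated by upsampled phase correlation and removed
    with a Fourier shift.  Returns (registered stack, per-frame shifts as
    (dy, dx) px).  Near-featureless frames get an identity shift and a
    warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of >= 2 same-shape frames")
    ref = stack[0]
    out = np.empty_like(stack)
    out[0] = ref
    shifts = np.zeros((stack.shape[0], 2))
    for i in range(1, stack.shape[0]):
        frame = stack[i]
        if frame.std() < 1e-12 or ref.std() < 1e-12:
            warnings.warn(f"frame {i} featureless; identity shift assumed",
                          stacklevel=2)
            out[i] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref, frame,
                                              upsample_factor=upsample_factor,
                                              normalization=None)
        shifts[i] = shift
        out[i] = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(frame),
                                                    shift)).real
    return out, shifts


def _gaussian_subpixel(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Three-point Gaussian peak interpolation along each axis."""
    py, px = peak
    offs = []
    for axis, p in ((0, py), (1, px)):
        if p == 0 or p == corr.shape[axis] - 1:
            offs.append(0.0)
            continue
        if axis == 0:
            cm, c0, cp = corr[p - 1, px], corr[p, px], corr[p + 1, px]
        else:
            cm, c0, cp = corr[py, p - 1], corr[py, p], corr[py, p + 1]
        cm, c0, cp = (max(c, 1e-12) for c in (cm, c0, cp))
        denom = np.log(cm) - 2 * np.log(c0) + np.log(cp)
        offs.append(0.0 if denom >= 0 else
                    0.5 * (np.log(cm) - np.log(cp)) / denom)
    return offs[0], offs[1]


def piv_displacement_field(
    pair: BeadImagePair,
    window: int = 64,
    overlap: float = 0.5,
    mesh_size: int | None = None,
    search: int | None = None,
    min_correlation: float = 0.3,
) -> DisplacementField:
    """Recover the displacement field of a bead image pair by windowed
    normalized cross-correlation with subpixel (3-point Gaussian) peaks.

    Nodes sit at window centres spaced ``mesh_size`` px (default
    window * (1 - overlap)).  The correlation peak is searched within
    +-``search`` px (default window/4, the classical validity limit).
    Nodes whose normalized correlation coefficient falls below
    ``min_correlation`` — empty or decorrelated windows — are flagged
    invalid rather than raising.
    """
    ref, dfm = pair.reference, pair.deformed
    h, w = ref.shape
    if window > min(h, w) // 2:
        raise ValueError("window must not exceed half the image extent")
    step = mesh_size if mesh_size is not None else max(int(round(window * (1 - overlap))), 1)
    search = search if search is not None else window // 4
    half = window // 2
    ys = np.arange(half, h - half + 1, step)
    xs = np.arange(half, w - half + 1, step)
    gx, gy = np.meshgrid(xs.astype(float), ys.astype(float))
    u = np.zeros_like(gx)
    v = np.zeros_like(gx)
    valid = np.zeros(gx.shape, dtype=bool)
    centre = window - 1  # zero-lag index of the full correlation
    # per-lag overlap count: dividing by it removes the triangular envelope
    # of finite-window correlation, which otherwise biases peaks toward zero
    ones = np.ones((window, window))
    overlap_count = fftconvolve(ones, ones, mode="full")

    for iy, yc in enumerate(ys):
        for ix, xc in enumerate(xs):
            rw = ref[yc - half:yc + half, xc - half:xc + half]
            dw = dfm[yc - half:yc + half, xc - half:xc + half]
            rstd, dstd = rw.std(), dw.std()
            if rstd < 1e-12 or dstd < 1e-12:
                continue  # empty window -> invalid node
            corr = fftconvolve(dw - dw.mean(), (rw - rw.mean())[::-1, ::-1],
                               mode="full") / overlap_count
            lo, hi = centre - search, centre + search + 1
            sub = corr[lo:hi, lo:hi]
            peak_flat = int(np.argmax(sub))
            py, px = np.unravel_index(peak_flat, sub.shape)
            coeff = sub[py, px] / (rstd * dstd)
            if coeff < min_correlation:
                continue
            oy, ox = _gaussian_subpixel(sub, (py, px))
            u[iy, ix] = (px - search + ox) * pair.pixel_size
            v[iy, ix] = (py - search + oy) * pair.pixel_size
            valid[iy, ix] = True

    return DisplacementField(
        grid_x=gx * pair.pixel_size, grid_y=gy * pair.pixel_size,
        u=u, v=v, valid_mask=valid, window=window, mesh_size=step,
        pixel_size=pair.pixel_size)


def filter_vectors(field: DisplacementField, threshold: float = 2.0,
                   eps: float = 0.1) -> DisplacementField:
    """Invalidate outlier vectors by the normalized median test.

    Each vector is compared with the median of its 8-neighbourhood: the
    residual |u - median| normalized by the median residual of the
    neighbours (+``eps`` um noise floor) must stay below ``threshold``.
    Gaps are not interpolated.  Off by default in the pipeline.
    """
    u, v, valid = field.u, field.v, field.valid_mask
    new_valid = valid.copy()
    ny, nx = u.shape
    for iy in range(ny):
        for ix in range(nx):
            if not valid[iy, ix]:
                continue
            ys = slice(max(iy - 1, 0), min(iy + 2, ny))
            xs = slice(max(ix - 1, 0), min(ix + 2, nx))
            nb_mask = valid[ys, xs].copy()
            nb_mask[min(iy, 1), min(ix, 1)] = False  # exclude centre
            if not nb_mask.any():
                warnings.warn(
                    f"node ({iy},{ix}) has no valid neighbours; left as-is",
                    stacklevel=2)
                continue
            norm = 0.0
            for comp in (u, v):
                nb = comp[ys, xs][nb_mask]
                med = np.median(nb)
                res_med = np.median(np.abs(nb - med))
                norm += ((comp[iy, ix] - med) / (res_med + eps)) ** 2
            if np.sqrt(norm) > threshold:
                new_valid[iy, ix] = False
    return replace(field, valid_mask=new_valid)


def max_matrix_displacement(field: DisplacementField,
                            cell_centroid: tuple[float, float],
                            cutoff_radius: float = 20.0) -> float:
    """Maximum displacement magnitude (um) among valid nodes within
    ``cutoff_radius`` um of the cell centroid."""
    r = np.hypot(field.grid_x - cell_centroid[0],
                 field.grid_y - cell_centroid[1])
    sel = (r <= cutoff_radius) & field.valid_mask
    if not sel.any():
        raise ValueError("no valid nodes within the cutoff radius")
    return float(field.magnitudes()[sel].max())


def average_displacement_map(
    entries: list[tuple[DisplacementField, tuple[float, float], tuple[float, float]]],
    cutoff_radius: float = 20.0,
    bin_size: float = 10.0,
) -> AveragedMap:
    """Build a multi-cell averaged displacement map.

    Each entry is (field, cell centroid um, migration vector um).  Per entry,
    valid vectors within ``cutoff_radius`` of the centroid are translated so
    the centroid sits at the origin, then positions *and* vectors are rotated
    so the migration vector points along +x.  Vectors are summed within each
    ``bin_size`` x ``bin_size`` um bin and divided by the number of cells.
    """
    if not entries:
        raise ValueError("no entries")
    n_bins = int(np.ceil(cutoff_radius / bin_size))
    edges = np.arange(-n_bins, n_bins + 1) * bin_size
    sum_u = np.zeros((len(edges) - 1, len(edges) - 1))
    sum_v = np.zeros_like(sum_u)
    counts = np.zeros_like(sum_u)
    for field, centroid, mig in entries:
        mnorm = float(np.hypot(*mig))
        if mnorm == 0:
            raise ValueError(
                f"entry with centroid {centroid} has a zero migration vector")
        ctheta, stheta = mig[0] / mnorm, mig[1] / mnorm
        # rotation by -theta aligns the migration vector with +x
        rot = np.array([[ctheta, stheta], [-stheta, ctheta]])
        px = field.grid_x - centroid[0]
        py = field.grid_y - centroid[1]
        sel = (np.hypot(px, py) <= cutoff_radius) & field.valid_mask
        pos = rot @ np.vstack([px[sel], py[sel]])
        vec = rot @ np.vstack([field.u[sel], field.v[sel]])
        hu, _, _ = np.histogram2d(pos[0], pos[1], bins=(edges, edges),
                                  weights=vec[0])
        hv, _, _ = np.histogram2d(pos[0], pos[1], bins=(edges, edges),
                                  weights=vec[1])
        hc, _, _ = np.histogram2d(pos[0], pos[1], bins=(edges, edges))
        sum_u += hu
        sum_v += hv
        counts += hc
    n = len(entries)
    return AveragedMap(bin_edges=edges, mean_u=sum_u / n, mean_v=sum_v / n,
                       n_cells=n, cutoff_radius=cutoff_radius, counts=counts)
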