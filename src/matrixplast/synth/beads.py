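"""Synthetic tracer-bead image pairs warped by prescribed displacement fields.

Emulates fluorescent microspheres embedded in a hydrogel around a cell: a
reference frame with beads rendered as Gaussian point-spread spots at random
subpixel positions, and a deformed frame in which each bead is re-rendered at
its forward-warped position (position + u(position)).  Forward warping per
bead keeps the ground-truth displacement exact — no image interpolation is
involved.  Fields are single-z-plane 2D by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FieldSpec", "BeadImagePair", "generate_bead_image_pair"]

_KINDS = ("uniform_translation", "linear_gradient",
          "contractile_dipole", "protrusive_dipole")


@dataclass(frozen=True)
class FieldSpec:
    """Analytic 2D displacement field, in micrometres.

    kinds
    -----
    uniform_translation : u = amplitude * direction everywhere.
    linear_gradient     : u = amplitude * ((p - center).direction / decay_length)
                          * direction (linear ramp along ``direction``).
    contractile_dipole  : u = -amplitude * exp(-r / decay_length) * r_hat
                          (vectors point toward ``center``).
    protrusive_dipole   : same magnitude, vectors point away from ``center``.
    """

    kind: str
    amplitude: float
    center: tuple[float, float] = (0.0, 0.0)
    decay_length: float = 10.0
    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.kind.endswith("dipole") or self.kind == "linear_gradient":
            if self.decay_length <= 0:
                raise ValueError("decay_length must be positive")
        n = float(np.hypot(*self.direction))
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("direction must be a unit vector")

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Displacement components (u, v) in um at positions (x, y) in um."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dx, dy = x - self.center[0], y - self.center[1]
        ex, ey = self.direction
        if self.kind == "uniform_translation":
            shape = np.broadcast(x, y).shape
            return (np.full(shape, self.amplitude * ex),
                    np.full(shape, self.amplitude * ey))
        if self.kind == "linear_gradient":
            s = (dx * ex + dy * ey) / self.decay_length
            return self.amplitude * s * ex, self.amplitude * s * ey
        r = np.hypot(dx, dy)
        with np.errstate(invalid="ignore", divide="ignore"):
            rx = np.where(r > 0, dx / r, 0.0)
            ry = np.where(r > 0, dy / r, 0.0)
        mag = self.amplitude * np.exp(-r / self.decay_length)
        sign = -1.0 if self.kind == "contractile_dipole" else 1.0
        return sign * mag * rx, sign * mag * ry


@dataclass
class BeadImagePair:
    """Reference/deformed bead frames plus the exact field on the PIV mesh."""

    reference: np.ndarray
    deformed: np.ndarray
    pixel_size: float  # um per px
    time_gap: float = 10.0  # min
    truth_x: np.ndarray = field(default=None)  # node positions, um
    truth_y: np.ndarray = field(default=None)
    truth_u: np.ndarray = field(default=None)  # displacements, um
    truth_v: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.reference.shape != self.deformed.shape:
            raise ValueError("frames must share a shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def _render(image: np.ndarray, xs: np.ndarray, ys: np.ndarray,
            amps: np.ndarray, sigma: float) -> None:
    """Accumulate Gaussian spots (subpixel centres, px units) into ``image``."""
    h, w = image.shape
    half = max(int(np.ceil(4 * sigma)), 2)
    for x0, y0, a in zip(xs, ys, amps):
        cx, cy = int(round(x0)), int(round(y0))
        x_lo, x_hi = max(cx - half, 0), min(cx + half + 1, w)
        y_lo, y_hi = max(cy - half, 0), min(cy + half + 1, h)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        gx = np.arange(x_lo, x_hi)
        gy = np.arange(y_lo, y_hi)
        g = np.exp(-((gy[:, None] - y0) ** 2 + (gx[None, :] - x0) ** 2)
                   / (2 * sigma ** 2))
        image[y_lo:y_hi, x_lo:x_hi] += a * g


def _piv_mesh(image_size: tuple[int, int], window: int,
              overlap: float) -> tuple[np.ndarray, np.ndarray]:
    """Node centres (px) of the default PIV mesh for a given window/overlap."""
    step = max(int(round(window * (1.0 - overlap))), 1)
    h, w = image_size
    ys = np.arange(window // 2, h - window // 2 + 1, step, dtype=float)
    xs = np.arange(window // 2, w - window // 2 + 1, step, dtype=float)
    return xs, ys


def generate_bead_image_pair(
    fieldspec: FieldSpec,
    image_size: int | tuple[int, int] = 256,
    pixel_size: float = 0.5,
    bead_density: float = 40.0,
    psf_sigma: float = 1.0,
    noise_sd: float = 0.005,
    seed: int | None = None,
    window: int = 64,
    overlap: float = 0.5,
    exclusion_radius: float = 0.0,
) -> BeadImagePair:
    """Render a reference/deformed bead image pair under a prescribed field.

    ``bead_density`` is beads per 100 x 100 px patch; ``psf_sigma`` the
    Gaussian spot width in px (>= 0.5 so spots stay resolvable);
    ``pixel_size`` converts the field (um) to pixels.  Ground truth is
    sampled on the mesh a (window, overlap) PIV pass will use.
    ``exclusion_radius`` (um) keeps a bead-free zone around the field centre,
    emulating the cell body the beads surround.
    """
    if bead_density <= 0:
        raise ValueError("bead_density must be positive")
    if psf_sigma < 0.5:
        raise ValueError("psf_sigma must be at least 0.5 px")
    if isinstance(image_size, int):
        image_size = (image_size, image_size)
    h, w = image_size
    rng = np.random.default_rng(seed)

    n_beads = rng.poisson(bead_density * h * w / 1e4)
    n_beads = max(int(n_beads), 1)
    bx = rng.uniform(0, w, n_beads)
    by = rng.uniform(0, h, n_beads)
    amps = rng.uniform(0.7, 1.0, n_beads)
    if exclusion_radius > 0:
        keep = np.hypot(bx * pixel_size - fieldspec.center[0],
                        by * pixel_size - fieldspec.center[1]) > exclusion_radius
        bx, by, amps = bx[keep], by[keep], amps[keep]

    u_um, v_um = fieldspec.evaluate(bx * pixel_size, by * pixel_size)
    u_px, v_px = u_um / pixel_size, v_um / pixel_size
    max_disp = float(np.hypot(u_px, v_px).max()) if n_beads else 0.0
    if max_disp > min(h, w) / 4:
        warnings.warn(
            f"max displacement {max_disp:.1f} px exceeds image_size/4; "
            "PIV windows may decorrelate", stacklevel=2)

    ref = np.zeros((h, w), dtype=float)
    dfm = np.zeros((h, w), dtype=float)
    _render(ref, bx, by, amps, psf_sigma)
    _render(dfm, bx + u_px, by + v_px, amps, psf_sigma)
    if noise_sd > 0:
        ref += rng.normal(0.0, noise_sd, ref.shape)
        dfm += rng.normal(0.0, noise_sd, dfm.shape)

    xs_px, ys_px = _piv_mesh((h, w), window, overlap)
    gx, gy = np.meshgrid(xs_px * pixel_size, ys_px * pixel_size)
    tu, tv = fieldspec.evaluate(gx, gy)
    return BeadImagePair(reference=ref, deformed=dfm, pixel_size=pixel_size,
                         truth_x=gx, truth_y=gy, truth_u=tu, truth_v=tv)
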