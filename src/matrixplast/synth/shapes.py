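"""Parametric binary cell-shape masks with analytic area and perimeter.

Fixtures for the circularity metric 4*pi*area/perimeter^2: shapes whose
analytic circularity is known exactly (disk: 1, square: pi/4) or to high
accuracy (ellipse via Ramanujan's perimeter approximation), so the raster
pipeline can be checked against closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import draw

from ..cells import CellMask

__all__ = ["ShapeTruth", "generate_shape_mask", "ellipse_perimeter"]


@dataclass(frozen=True)
class ShapeTruth:
    area: float       # px^2
    perimeter: float  # px

    @property
    def circularity(self) -> float:
        return 4.0 * math.pi * self.area / self.perimeter ** 2


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation (error < 1e-6 for aspect <= 4)."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def _star_vertices(r_outer: float, r_inner: float, n_points: int,
                   cx: float, cy: float) -> tuple[np.ndarray, np.ndarray]:
    angles = np.arange(2 * n_points) * math.pi / n_points - math.pi / 2
    radii = np.where(np.arange(2 * n_points) % 2 == 0, r_outer, r_inner)
    return cy + radii * np.sin(angles), cx + radii * np.cos(angles)


def generate_shape_mask(
    kind: str,
    size_px: float = 100.0,
    aspect: float = 1.0,
    resolution_px: int | None = None,
    pixel_size: float = 1.0,
) -> tuple[CellMask, ShapeTruth]:
    """Rasterize a parametric shape and return it with its analytic geometry.

    ``size_px`` is the characteristic half-size (disk/ellipse semi-major
    axis, rectangle half-length, star outer radius); ``aspect`` >= 1 the
    major:minor ratio (star: outer:inner radius ratio, default gives 0.5
    inner fraction).  The raster canvas defaults to a square comfortably
    containing the shape.
    """
    if aspect < 1.0:
        raise ValueError("aspect must be >= 1")
    if size_px <= 0 or size_px / aspect < 1.0:
        raise ValueError("degenerate (zero-area) shape")
    if resolution_px is None:
        resolution_px = int(2 * size_px + 20)
    c = resolution_px / 2.0
    if size_px >= c:
        raise ValueError("shape does not fit within the canvas")
    mask = np.zeros((resolution_px, resolution_px), dtype=bool)

    if kind == "disk":
        rr, cc = draw.disk((c, c), size_px, shape=mask.shape)
        mask[rr, cc] = True
        truth = ShapeTruth(area=math.pi * size_px ** 2,
                           perimeter=2 * math.pi * size_px)
    elif kind == "ellipse":
        a, b = size_px, size_px / aspect
        rr, cc = draw.ellipse(c, c, b, a, shape=mask.shape)
        mask[rr, cc] = True
        truth = ShapeTruth(area=math.pi * a * b, perimeter=ellipse_perimeter(a, b))
    elif kind == "rectangle":
        half_w, half_h = size_px, size_px / aspect
        r0, r1 = int(round(c - half_h)), int(round(c + half_h))
        c0, c1 = int(round(c - half_w)), int(round(c + half_w))
        mask[r0:r1, c0:c1] = True
        w, h = c1 - c0, r1 - r0  # use realized raster dims for the truth
        truth = ShapeTruth(area=float(w * h), perimeter=2.0 * (w + h))
    elif kind == "star":
        r_in = size_px * 0.5 / aspect
        ry, rx = _star_vertices(size_px, r_in, 5, c, c)
        rr, cc = draw.polygon(ry, rx, shape=mask.shape)
        mask[rr, cc] = True
        ys, xs = np.append(ry, ry[0]), np.append(rx, rx[0])
        perim = float(np.sum(np.hypot(np.diff(xs), np.diff(ys))))
        area = 0.5 * abs(float(np.sum(xs[:-1] * ys[1:] - xs[1:] * ys[:-1])))
        truth = ShapeTruth(area=area, perimeter=perim)
    else:
        raise ValueError(f"unknown shape kind {kind!r}")

    if not mask.any():
        raise ValueError("degenerate (zero-area) shape")
    return CellMask(mask=mask, pixel_size=pixel_size), truth
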