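"""Synthetic repeated-indentation force-depth cycles.

Emulates two successive indentations of a plastically deforming tissue plug:
the material permanently retains a fraction of the first indentation depth,
so the second cycle's force-depth curve is the first curve shifted right by
the retained depth and truncated at the same maximum depth — hence a lower
peak force on the second cycle, as observed on tumor tissue.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_indentation_cycles"]


def simulate_indentation_cycles(
    retained_fraction: float,
    peak_force: float = 1.0,
    depth_max: float = 0.8,
    n_points: int = 400,
    hertz_exponent: float = 1.5,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Two force-depth loading curves for successive indentation cycles.

    First cycle: Hertz-like contact, F(d) = peak_force * (d/depth_max)^1.5.
    Second cycle: contact starts only after the permanently retained depth
    retained_fraction * depth_max, then follows the same contact law up to
    depth_max, so the depth at any force fraction of the first peak is offset
    by exactly the retained depth, and the second peak force is
    peak_force * (1 - retained_fraction)^1.5 < peak_force.

    Returns ((depth1, force1), (depth2, force2)); depths in mm, forces in N.
    """
    if not 0.0 <= retained_fraction <= 1.0:
        raise ValueError("retained_fraction must be in [0, 1]")
    if peak_force <= 0 or depth_max <= 0:
        raise ValueError("peak_force and depth_max must be positive")
    d = np.linspace(0.0, depth_max, n_points)
    f1 = peak_force * (d / depth_max) ** hertz_exponent
    d0 = retained_fraction * depth_max
    contact = np.clip(d - d0, 0.0, None)
    f2 = peak_force * (contact / depth_max) ** hertz_exponent
    return (d, f1), (d.copy(), f2)
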