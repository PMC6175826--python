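"""Stiffness metrics and creep-recovery / indentation plasticity decomposition.

Oscillatory rheometry readings (storage modulus G', loss modulus G'') are
converted to the complex shear modulus G* = (G'^2 + G''^2)^(1/2) and to a
Young's modulus E = 2(1 + v) G* under an assumed Poisson ratio.  Creep-recovery
traces (constant shear stress followed by unloaded recovery) are decomposed
into elastic, viscoelastic, and plastic (permanent) strain components; the
degree of plasticity is the permanent fraction of the total creep strain,
in percent.  Indentation plasticity on tissue plugs is read out as the offset,
between successive indentation cycles, of the depth at which the force crosses
25% of the first cycle's peak force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModulusReading",
    "ElasticParams",
    "RheoTrace",
    "PlasticityResult",
    "IndentationResult",
    "YieldBound",
    "complex_modulus",
    "youngs_modulus",
    "loss_tangent",
    "decompose_creep_recovery",
    "estimate_yield_stress",
    "indentation_plasticity",
]


@dataclass(frozen=True)
class ModulusReading:
    """One oscillatory-rheometry operating point.

    Attributes
    ----------
    G_storage, G_loss : float
        Storage and loss moduli (Pa), both non-negative.
    frequency : float
        Angular frequency (rad/s).
    strain_amplitude : float
        Oscillation strain amplitude (fraction).
    """

    G_storage: float
    G_loss: float
    frequency: float = 1.0
    strain_amplitude: float = 0.01

    def __post_init__(self) -> None:
        if self.G_storage < 0 or self.G_loss < 0:
            raise ValueError("storage and loss moduli must be non-negative")


@dataclass(frozen=True)
class ElasticParams:
    """Isotropic linear-elastic parameters: Young's modulus E (Pa), Poisson v."""

    E: float
    v: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (-1.0 < self.v <= 0.5):
            raise ValueError("Poisson ratio must lie in (-1, 0.5]")

    @property
    def lame_lambda(self) -> float:
        if self.v >= 0.5:
            raise ValueError("lambda is singular at v = 0.5 (incompressible)")
        return self.v * self.E / ((1 + self.v) * (1 - 2 * self.v))

    @property
    def shear_modulus(self) -> float:
        return self.E / (2 * (1 + self.v))


@dataclass
class RheoTrace:
    """Strain response recorded under a creep-recovery stress protocol.

    ``time`` is strictly increasing (s); ``applied_stress`` is the piecewise
    constant shear stress (Pa); ``strain`` is dimensionless.  ``protocol``
    stores (creep stress Pa, load duration s, recovery duration s).
    """

    time: np.ndarray
    applied_stress: np.ndarray
    strain: np.ndarray
    protocol: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.applied_stress = np.asarray(self.applied_stress, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if not (self.time.shape == self.applied_stress.shape == self.strain.shape):
            raise ValueError("time, stress, and strain must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class PlasticityResult:
    """Elastic / viscoelastic / permanent partition of a creep-recovery response."""

    strain_total_end_load: float
    strain_elastic: float
    strain_viscoelastic: float
    strain_permanent: float
    degree_of_plasticity: float  # percent

    def __post_init__(self) -> None:
        if not (0.0 <= self.degree_of_plasticity <= 100.0 + 1e-9):
            raise ValueError("degree of plasticity must be within [0, 100] %")


@dataclass(frozen=True)
class IndentationResult:
    retained_depth: float  # mm, depth offset at 25% of initial peak force
    peak_force_ratio: float  # second peak / first peak

    def __post_init__(self) -> None:
        if self.retained_depth < -1e-9:
            raise ValueError("retained depth must be non-negative")
        if self.peak_force_ratio <= 0:
            raise ValueError("peak force ratio must be positive")


@dataclass(frozen=True)
class YieldBound:
    """Bracket on the elastic-plastic yield stress.

    ``relation`` is one of ``below_lowest`` (lowest tested stress already
    yields), ``between`` (bracketed by two tested stresses), or
    ``above_highest`` (no tested stress yields).  ``value`` is the upper bound
    of the bracket (for ``above_highest``, the highest tested stress, a lower
    bound).
    """

    value: float
    relation: str
    bracket: tuple[float | None, float | None] = field(default=(None, None))


def complex_modulus(reading: ModulusReading) -> float:
    """Complex shear modulus magnitude |G*| = sqrt(G'^2 + G''^2), in Pa."""
    return float(np.hypot(reading.G_storage, reading.G_loss))


def youngs_modulus(G_complex: float, v: float = 0.5) -> float:
    """Young's modulus E = 2 (1 + v) |G*| for an isotropic material.

    v = 0.5 (incompressible) is the conventional choice for hydrogels.
    """
    if G_complex < 0:
        raise ValueError("complex modulus must be non-negative")
    if not (-1.0 < v <= 0.5):
        raise ValueError("Poisson ratio must lie in (-1, 0.5]")
    return 2.0 * (1.0 + v) * G_complex


def loss_tangent(reading: ModulusReading) -> float:
    """Loss tangent tan(delta) = G''/G'; higher means more liquid-like."""
    if reading.G_storage <= 0:
        raise ValueError("loss tangent undefined for G' = 0")
    return reading.G_loss / reading.G_storage


def decompose_creep_recovery(
    trace: RheoTrace,
    unload_window: float = 5.0,
    plateau_fraction: float = 0.1,
) -> PlasticityResult:
    """Partition a creep-recovery strain trace into elastic, viscoelastic,
    and permanent components.

    The total strain is read at the last loaded sample.  The elastic part is
    the strain drop between that sample and the first sample more than
    ``unload_window`` seconds after unloading (a sampled trace cannot resolve
    a true discontinuity).  The permanent (plastic) part is the mean strain
    over the final ``plateau_fraction`` of the recovery phase; a residual
    slope there triggers a non-plateau warning.  The viscoelastic part is the
    remainder, clamped at zero with a warning if meaningfully negative.

    Returns degree_of_plasticity = 100 * permanent / total (percent).
    """
    if not 0.0 < plateau_fraction <= 1.0:
        raise ValueError("plateau_fraction must be in (0, 1]")
    creep_stress, load_duration, recovery_duration = trace.protocol
    t = trace.time
    loaded = trace.applied_stress > 0
    if not loaded.any() or loaded.all():
        raise ValueError("trace must contain both a load and a recovery phase")
    last_load_idx = int(np.nonzero(loaded)[0][-1])
    t_unload = t[last_load_idx]
    if t[-1] - t_unload < plateau_fraction * recovery_duration:
        raise ValueError("recovery phase shorter than the plateau window")

    strain_total = float(trace.strain[last_load_idx])

    after = np.nonzero(t > t_unload + unload_window)[0]
    if after.size == 0:
        raise ValueError("no samples beyond the unload window")
    strain_after_drop = float(trace.strain[after[0]])
    strain_elastic = strain_total - strain_after_drop

    plateau_start = t[-1] - plateau_fraction * (t[-1] - t_unload)
    in_plateau = t >= plateau_start
    plateau = trace.strain[in_plateau]
    strain_permanent = float(np.mean(plateau))
    # residual-slope check: fitted drift over the plateau window, relative to
    # total strain (a fit, not endpoints, so measurement noise does not trip it)
    if strain_total > 0 and plateau.size >= 3:
        slope = float(np.polyfit(t[in_plateau], plateau, 1)[0])
        drift = abs(slope) * (t[-1] - plateau_start)
        if drift > 0.02 * abs(strain_total):
            warnings.warn(
                "recovery has not plateaued (residual drift "
                f"{drift:.3g} vs total strain {strain_total:.3g})",
                stacklevel=2,
            )

    strain_visco = strain_total - strain_elastic - strain_permanent
    tol = 1e-6 * max(abs(strain_total), 1e-12)
    if strain_visco < -max(tol, 0.02 * abs(strain_total)):
        warnings.warn(
            f"negative viscoelastic component ({strain_visco:.3g}) clamped to 0",
            stacklevel=2,
        )
    strain_visco = max(strain_visco, 0.0)
    strain_elastic = max(strain_elastic, 0.0)
    strain_permanent_c = min(max(strain_permanent, 0.0), strain_total if strain_total > 0 else 0.0)

    dop = 100.0 * strain_permanent_c / strain_total if strain_total > 0 else 0.0
    return PlasticityResult(
        strain_total_end_load=strain_total,
        strain_elastic=strain_elastic,
        strain_viscoelastic=strain_visco,
        strain_permanent=strain_permanent_c,
        degree_of_plasticity=float(np.clip(dop, 0.0, 100.0)),
    )


def estimate_yield_stress(
    results: Sequence[tuple[float, PlasticityResult]],
    plasticity_tolerance: float = 1.0,
) -> YieldBound:
    """Bracket the elastic-plastic yield stress from a creep-stress series.

    The lowest applied stress whose degree of plasticity exceeds
    ``plasticity_tolerance`` (percent) defines the upper end of the bracket.
    If the lowest tested stress already yields, only an upper bound can be
    stated (relation ``below_lowest``); if none yields, only a lower bound
    (``above_highest``).
    """
    if len(results) == 0:
        raise ValueError("empty stress series")
    if len({s for s, _ in results}) < 2:
        raise ValueError("need at least two distinct stresses")
    ordered = sorted(results, key=lambda sr: sr[0])
    yielding = [s for s, r in ordered if r.degree_of_plasticity > plasticity_tolerance]
    if not yielding:
        return YieldBound(value=ordered[-1][0], relation="above_highest",
                          bracket=(ordered[-1][0], None))
    first_yield = yielding[0]
    stresses = [s for s, _ in ordered]
    idx = stresses.index(first_yield)
    if idx == 0:
        return YieldBound(value=first_yield, relation="below_lowest",
                          bracket=(None, first_yield))
    return YieldBound(value=first_yield, relation="between",
                      bracket=(stresses[idx - 1], first_yield))


def _crossing_depth(depth: np.ndarray, force: np.ndarray, level: float) -> float:
    """Depth at which the rising branch of a force-depth curve crosses ``level``
    (linear interpolation between samples)."""
    peak_idx = int(np.argmax(force))
    d, f = depth[: peak_idx + 1], force[: peak_idx + 1]
    above = np.nonzero(f >= level)[0]
    if above.size == 0:
        raise ValueError("curve never reaches the requested force level")
    i = int(above[0])
    if i == 0:
        return float(d[0])
    frac = (level - f[i - 1]) / (f[i] - f[i - 1])
    return float(d[i - 1] + frac * (d[i] - d[i - 1]))


def indentation_plasticity(
    first_curve: tuple[np.ndarray, np.ndarray],
    second_curve: tuple[np.ndarray, np.ndarray],
    force_fraction: float = 0.25,
) -> IndentationResult:
    """Retained indentation depth between successive indentation cycles.

    Because the true contact point is hard to locate on soft tissue, the only
    depth reference used is the crossing of ``force_fraction`` (default 25%)
    of the *first* cycle's peak force: the retained depth is the offset of the
    second cycle's crossing relative to the first's.  Also reports the ratio
    of peak forces (second / first).
    """
    d1, f1 = (np.asarray(a, dtype=float) for a in first_curve)
    d2, f2 = (np.asarray(a, dtype=float) for a in second_curve)
    peak1 = float(f1.max())
    peak2 = float(f2.max())
    if peak1 <= 0:
        raise ValueError("first curve has no positive peak force")
    level = force_fraction * peak1
    x1 = _crossing_depth(d1, f1, level)
    try:
        x2 = _crossing_depth(d2, f2, level)
    except ValueError as exc:
        raise ValueError(
            "second indentation never reaches "
            f"{100 * force_fraction:.0f}% of the first peak force "
            f"(peak ratio {peak2 / peak1:.3f}); retained depth undefined"
        ) from exc
    return IndentationResult(retained_depth=max(x2 - x1, 0.0),
                             peak_force_ratio=peak2 / peak1)
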