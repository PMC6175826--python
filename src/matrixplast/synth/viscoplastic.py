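"""Burgers-type viscoplastic creep-recovery simulator.

The four-element Burgers model (Maxwell arm in series with a Kelvin-Voigt
arm) is the minimal linear model whose creep-recovery response partitions
into an instantaneous elastic strain (spring E1), a recoverable viscoelastic
strain (Kelvin arm E2 || eta2), and a permanent flow strain (free dashpot
eta1).  Closed forms:

loading (0 <= t <= t_load, constant stress sigma):
    eps(t) = sigma/E1 + sigma*t/eta1 + (sigma/E2) * (1 - exp(-t*E2/eta2))
recovery (t' = t - t_load >= 0, stress 0):
    eps(t') = sigma*t_load/eta1
              + (sigma/E2) * (1 - exp(-t_load*E2/eta2)) * exp(-t'*E2/eta2)

Either dissipative arm may be disabled by an infinite parameter: eta1 = inf
removes permanent flow (viscoelastic solid), E2 = inf removes the Kelvin arm
(Maxwell fluid).  An optional yield threshold treats eta1 as infinite for
stresses at or below it, giving an elastic-plastic transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ..rheology import RheoTrace

__all__ = ["ViscoplasticParams", "simulate_creep_recovery", "burgers_strain",
           "closed_form_plasticity"]


@dataclass(frozen=True)
class ViscoplasticParams:
    """Burgers-model parameters.

    E1 : instantaneous spring modulus (Pa).
    eta1 : free-dashpot viscosity (Pa s); ``inf`` disables permanent flow.
    E2 : Kelvin spring modulus (Pa); ``inf`` disables the Kelvin arm.
    eta2 : Kelvin dashpot viscosity (Pa s).
    yield_stress : stress at or below which eta1 is treated as infinite (Pa).
    """

    E1: float
    eta1: float
    E2: float
    eta2: float
    yield_stress: float = 0.0

    def __post_init__(self) -> None:
        if not (self.E1 > 0 and self.E2 > 0):
            raise ValueError("spring moduli must be positive")
        if not (self.eta1 > 0 and self.eta2 > 0):
            raise ValueError("viscosities must be positive (may be inf)")
        if self.yield_stress < 0:
            raise ValueError("yield stress must be non-negative")

    @property
    def flows(self) -> bool:
        return math.isfinite(self.eta1)

    # -- convenience constructors -------------------------------------------

    @classmethod
    def elastic(cls, E: float) -> "ViscoplasticParams":
        """Ideal elastic solid: single spring, no flow, no Kelvin arm."""
        return cls(E1=E, eta1=math.inf, E2=math.inf, eta2=1.0)

    @classmethod
    def maxwell(cls, E: float, relaxation_time: float) -> "ViscoplasticParams":
        """Maxwell fluid: spring E in series with dashpot eta1 = E * tau."""
        return cls(E1=E, eta1=E * relaxation_time, E2=math.inf, eta2=1.0)

    @classmethod
    def kelvin_solid(cls, E1: float, E2: float, eta2: float) -> "ViscoplasticParams":
        """Standard linear (viscoelastic) solid: no permanent flow."""
        return cls(E1=E1, eta1=math.inf, E2=E2, eta2=eta2)

    @classmethod
    def ipn_like(cls, degree_of_plasticity: float,
                 E1: float = 600.0, E2: float = 2000.0,
                 eta2: float = 1.0e5) -> "ViscoplasticParams":
        """Burgers parameters whose closed-form degree of plasticity under a
        100 Pa / 1 h creep equals ``degree_of_plasticity`` percent.

        Shear moduli of order 600 Pa correspond to hydrogels of Young's
        modulus ~1.8 kPa at Poisson ratio 0.5.  eta1 is chosen analytically:
        with p = DoP/100,  t_load/eta1 = p/(1-p) * (1/E1 + 1/E2).
        """
        p = degree_of_plasticity / 100.0
        if not 0.0 < p < 1.0:
            raise ValueError("degree_of_plasticity must be in (0, 100)")
        t_load = 3600.0
        eta1 = t_load / (p / (1.0 - p) * (1.0 / E1 + 1.0 / E2))
        return cls(E1=E1, eta1=eta1, E2=E2, eta2=eta2)


# Presets emulating the low/medium/high-plasticity hydrogel formulations:
# equal instantaneous stiffness, degrees of plasticity 10/20/30% under the
# 100 Pa, 1 h creep protocol.
LP_LIKE = ViscoplasticParams.ipn_like(10.0)
MP_LIKE = ViscoplasticParams.ipn_like(20.0)
HP_LIKE = ViscoplasticParams.ipn_like(30.0)


def _effective(params: ViscoplasticParams, stress: float) -> ViscoplasticParams:
    if stress <= params.yield_stress and params.flows:
        return replace(params, eta1=math.inf)
    return params


def burgers_strain(params: ViscoplasticParams, stress: float,
                   t: np.ndarray, load_duration: float) -> np.ndarray:
    """Closed-form Burgers strain at times ``t`` for a creep-recovery protocol
    (constant ``stress`` for ``load_duration`` seconds, then unloaded)."""
    p = _effective(params, stress)
    t = np.asarray(t, dtype=float)
    eps = np.zeros_like(t)
    if stress == 0.0:
        return eps

    flow_rate = 0.0 if not p.flows else stress / p.eta1
    kelvin_amp = 0.0 if not math.isfinite(p.E2) else stress / p.E2
    tau2 = p.eta2 / p.E2 if math.isfinite(p.E2) else math.inf

    loading = t <= load_duration
    tl = t[loading]
    kel_l = kelvin_amp * (1.0 - np.exp(-tl / tau2)) if kelvin_amp else 0.0
    eps[loading] = stress / p.E1 + flow_rate * tl + kel_l

    tr = t[~loading] - load_duration
    kel_end = kelvin_amp * (1.0 - math.exp(-load_duration / tau2)) if kelvin_amp else 0.0
    kel_r = kel_end * np.exp(-tr / tau2) if kelvin_amp else 0.0
    eps[~loading] = flow_rate * load_duration + kel_r
    return eps


def closed_form_plasticity(params: ViscoplasticParams, stress: float,
                           load_duration: float) -> float:
    """Exact degree of plasticity (%) = permanent / end-of-load strain."""
    p = _effective(params, stress)
    if stress == 0.0:
        return 0.0
    flow = (stress / p.eta1) * load_duration if p.flows else 0.0
    kelvin = 0.0
    if math.isfinite(p.E2):
        kelvin = (stress / p.E2) * (1.0 - math.exp(-load_duration * p.E2 / p.eta2))
    total = stress / p.E1 + flow + kelvin
    return 100.0 * flow / total


def simulate_creep_recovery(
    params: ViscoplasticParams,
    stress: float,
    load_duration: float = 3600.0,
    recovery_duration: float = 6400.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> RheoTrace:
    """Simulate a creep-recovery test of a Burgers viscoplastic material.

    Constant shear ``stress`` (Pa) for ``load_duration`` s, then zero stress
    for ``recovery_duration`` s, sampled every ``dt`` s.  Additive Gaussian
    strain noise of standard deviation ``noise_sd`` is applied when positive,
    reproducibly from ``seed``.
    """
    if stress < 0:
        raise ValueError("stress must be non-negative")
    if load_duration <= 0 or recovery_duration <= 0 or dt <= 0:
        raise ValueError("durations and dt must be positive")
    t = np.arange(0.0, load_duration + recovery_duration + dt / 2, dt)
    strain = burgers_strain(params, stress, t, load_duration)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        strain = strain + rng.normal(0.0, noise_sd, size=strain.shape)
    applied = np.where(t <= load_duration, stress, 0.0)
    return RheoTrace(time=t, applied_stress=applied, strain=strain,
                     protocol=(stress, load_duration, recovery_duration))
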