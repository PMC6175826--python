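#!/usr/bin/env python
"""Simulate creep-recovery rheology for the reference material panel.

Generates the strain traces the downstream decomposition consumes: three
hydrogel-like viscoplastic formulations of increasing plasticity (LP/MP/HP-
like presets, equal instantaneous stiffness), a covalently cross-linked
elastic control, and a viscoelastic-fluid control, all under the standard
protocol (constant 100 Pa shear stress for 1 h, unloaded recovery for
6400 s).  The HP-like preset is additionally run over the 10/50/100/150 Pa
stress series used for yield-stress bounding.

Writes results/materials/*.csv (one trace per material/stress).
"""

from pathlib import Path

from matrixplast import io as mio
from matrixplast.synth import (HP_LIKE, LP_LIKE, MP_LIKE, ViscoplasticParams,
                               simulate_creep_recovery)

OUT = Path(__file__).resolve().parents[1] / "results" / "materials"
SEED = 0

MATERIALS = {
    "lp_like": LP_LIKE,
    "mp_like": MP_LIKE,
    "hp_like": HP_LIKE,
    "elastic_control": ViscoplasticParams.elastic(600.0),
    "fluid_control": ViscoplasticParams.maxwell(600.0, 10.0),
}


def main() -> None:
    for name, params in MATERIALS.items():
        trace = simulate_creep_recovery(params, 100.0, dt=2.0,
                                        noise_sd=1e-3, seed=SEED)
        mio.save_trace(trace, OUT / f"{name}_100Pa.csv")
        print(f"{name}: end-of-load strain {trace.strain[1800]:.4f}, "
              f"residual strain {trace.strain[-1]:.4f}")
    for i, stress in enumerate((10.0, 50.0, 100.0, 150.0)):
        trace = simulate_creep_recovery(HP_LIKE, stress, dt=2.0,
                                        noise_sd=1e-3, seed=SEED + 1 + i)
        mio.save_trace(trace, OUT / f"hp_like_{int(stress)}Pa.csv")
    print(f"wrote traces to {OUT}")


if __name__ == "__main__":
    main()
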