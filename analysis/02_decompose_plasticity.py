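#!/usr/bin/env python
"""Decompose the simulated creep-recovery traces into elastic, viscoelastic,
and plastic parts; bound the yield stress; quantify indentation plasticity.

Reads the traces written by 01_simulate_materials.py, reports each
material's degree of plasticity (the elastic control should sit at ~0%, the
fluid control near 100%, the hydrogel-like panel between 10 and 30%), brackets
the HP-like formulation's yield stress from the 10-150 Pa series (it flows at
every tested stress, so only "below 10 Pa" can be stated), and runs the
25%-of-peak-force analysis on synthetic repeat-indentation cycles.

Writes results/plasticity/decomposition.csv and summary.json.
"""

from pathlib import Path

import pandas as pd

from matrixplast import io as mio
from matrixplast.rheology import (decompose_creep_recovery,
                                  estimate_yield_stress,
                                  indentation_plasticity)
from matrixplast.synth import simulate_indentation_cycles

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "plasticity"


def main() -> None:
    rows = []
    for path in sorted((ROOT / "materials").glob("*_100Pa.csv")):
        trace = mio.load_trace(path)
        res = decompose_creep_recovery(trace)
        rows.append({"material": path.stem.replace("_100Pa", ""),
                     "strain_total": res.strain_total_end_load,
                     "strain_elastic": res.strain_elastic,
                     "strain_viscoelastic": res.strain_viscoelastic,
                     "strain_permanent": res.strain_permanent,
                     "degree_of_plasticity_pct": res.degree_of_plasticity})
        print(f"{rows[-1]['material']:>16}: "
              f"plasticity {res.degree_of_plasticity:5.1f}%")
    mio.save_table(pd.DataFrame(rows), OUT / "decomposition.csv")

    series = []
    for stress in (10.0, 50.0, 100.0, 150.0):
        trace = mio.load_trace(ROOT / "materials" / f"hp_like_{int(stress)}Pa.csv")
        series.append((stress, decompose_creep_recovery(trace)))
    bound = estimate_yield_stress(series, plasticity_tolerance=1.0)
    print(f"yield stress: {bound.relation} {bound.value:g} Pa")

    first, second = simulate_indentation_cycles(retained_fraction=0.3,
                                                depth_max=0.8)
    indent = indentation_plasticity(first, second)
    print(f"indentation: retained depth {indent.retained_depth:.3f} mm, "
          f"peak force ratio {indent.peak_force_ratio:.3f}")

    mio.save_json({"yield_bound_Pa": bound.value,
                   "yield_relation": bound.relation,
                   "indentation_retained_depth_mm": indent.retained_depth,
                   "indentation_peak_force_ratio": indent.peak_force_ratio},
                  OUT / "summary.json")


if __name__ == "__main__":
    main()
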