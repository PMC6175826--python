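#!/usr/bin/env python
"""Estimate the upper-bound stress field from the measured displacement map.

Loads the displacement field written by 03_map_displacements.py,
differentiates it into the small-strain tensor (plane strain: out-of-plane
strains assumed negligible), applies generalized Hooke's law with E = 2 kPa
and v = 0.49, and reports the field-wide maximum principal stress — an upper
bound on the stress the (actually yielding) matrix sustains, because the
linear-elastic assumption ignores plastic relaxation.

Writes results/stress/stress_field.csv and a principal-stress heat map PNG.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from matrixplast import io as mio
from matrixplast.rheology import ElasticParams
from matrixplast.stress import hooke_stress, principal_stress, strain_field

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "stress"


def main() -> None:
    field = mio.load_field(ROOT / "displacement" / "field.csv")
    params = ElasticParams(E=2000.0, v=0.49)
    strains = strain_field(field)
    stresses = hooke_stress(strains, params)
    pmax, upper = principal_stress(stresses)
    print(f"maximum principal stress (upper bound): {upper:.1f} Pa "
          f"(E = {params.E:g} Pa, v = {params.v}) ")

    df = pd.DataFrame({
        "x_um": field.grid_x.ravel(), "y_um": field.grid_y.ravel(),
        "sigma11_Pa": stresses.sigma11.ravel(),
        "sigma22_Pa": stresses.sigma22.ravel(),
        "sigma12_Pa": stresses.sigma12.ravel(),
        "sigma33_Pa": stresses.sigma33.ravel(),
        "principal_max_Pa": pmax.ravel(),
        "valid": stresses.valid_mask.ravel().astype(int)})
    mio.save_table(df, OUT / "stress_field.csv")

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(field.grid_x, field.grid_y,
                       np.where(stresses.valid_mask, pmax, np.nan),
                       shading="nearest", cmap="viridis")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title("maximum principal stress (Pa)")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(OUT / "principal_stress_heatmap.png", dpi=150)
    print(f"wrote outputs to {OUT}")


if __name__ == "__main__":
    main()
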