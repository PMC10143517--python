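#!/usr/bin/env python
"""Band-wise structure of the simulated population.

Computes (a) the per-band variance of reflectance across leaves, locating
the structurally driven green-band maximum, and (b) the Pearson
correlation between absorbance and reflectance at the blue/green/red
probe bands 435/550/674 nm, quantifying how far the two channels are
from perfect complementarity at each.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from leafspec import generate_dataset, band_correlation

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = generate_dataset()
    ds = study.dataset
    wl = ds.grid.wavelengths()
    R = ds.reflectance_matrix()
    A = ds.absorbance_matrix()

    var = R.var(axis=0)
    pd.DataFrame({"wavelength_nm": wl, "reflectance_variance": var}).to_csv(
        OUT / "reflectance_variance.csv", index=False, float_format="%.8g"
    )
    print(f"reflectance variance peaks at {wl[np.argmax(var)]} nm "
          f"(green-band structural effect)")

    rows = []
    for lam in (435, 550, 674):
        i = ds.grid.index_of(lam)
        r = band_correlation(A[:, i], R[:, i])
        rows.append({"wavelength_nm": lam, "pearson_r": r})
        print(f"  r(A, R) at {lam} nm = {r:+.3f}")
    pd.DataFrame(rows).to_csv(OUT / "band_correlations.csv", index=False,
                              float_format="%.6g")
    print("blue/red anticorrelation is strong; the green band is decoupled "
          "by leaf structure")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
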