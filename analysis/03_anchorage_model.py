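#!/usr/bin/env python
"""Fit the root-soil anchorage model S_p = K * tau * D^3 + c.

For each simulated experiment, regresses the measured anchorage moment on
tau*D^3 (soil shear strength times cubed cone diameter) and writes the
fitted slope K, intercept c, R^2 and n to results/anchorage_models.csv.
Also contrasts the 1 mm root-diameter classification with the finer 0.5 mm
one: the finer threshold admits long thin laterals and systematically
widens the estimated cone, overestimating tau*D^3.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from canolodge import biomech, io

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    rows = []
    for exp in ("exp1", "exp2", "exp3"):
        table = io.read_trait_table(OUT / f"trial_{exp}.csv")
        for threshold, col in ((1.0, "cone_D_m"), (0.5, "cone_D_05mm_m")):
            x = table["tau_N_m2"].to_numpy() * table[col].to_numpy() ** 3
            model = biomech.fit_anchorage_model(
                np.column_stack([x, table["S_p_Nm"].to_numpy()]))
            rows.append({"experiment": exp, "threshold_mm": threshold,
                         "K": model.K, "intercept_c": model.intercept_c,
                         "r_squared": model.r_squared, "n": model.n,
                         "mean_tauD3_Nm": float(np.mean(x))})
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "anchorage_models.csv", index=False)
    print(frame.round(4).to_string(index=False))
    one_mm = frame[frame.threshold_mm == 1.0]
    print(f"\n1 mm classification: K = {one_mm.K.mean():.3f}, "
          f"c = {one_mm.intercept_c.mean():.3f} "
          f"(R^2 = {one_mm.r_squared.mean():.3f}); the 0.5 mm classification "
          "inflates tau*D^3 by "
          f"{frame[frame.threshold_mm == 0.5].mean_tauD3_Nm.mean() / one_mm.mean_tauD3_Nm.mean():.2f}x")


if __name__ == "__main__":
    main()
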