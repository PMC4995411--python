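#!/usr/bin/env python
"""Calibrate the electrical predictors against the lodging indicators.

For each experiment, fits linear calibrations of S_p, S_s, SF_p and SF_s
on capacitance, resistance and impedance, ranks the predictors by R^2,
and writes results/calibrations_<exp>.csv plus a pooled Pearson
correlation map (results/correlation_map_exp1.csv).  The expected picture:
capacitance is the strongest and positive predictor of anchorage strength,
resistance and impedance are weaker and negative.
"""

from pathlib import Path

from canolodge import electro, io

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

RESPONSES = ("S_p", "S_s", "SF_p", "SF_s")


def main() -> None:
    for exp in ("exp1", "exp2", "exp3"):
        result = io.run_pipeline(io.RunConfig(
            out_dir=OUT / f"pipeline_{exp}", experiment=exp, seed=0,
            responses=RESPONSES))
        calib = result["calibrations"]
        calib.to_csv(OUT / f"calibrations_{exp}.csv", index=False)
        sp = calib[calib.response == "S_p"].sort_values("r_squared",
                                                        ascending=False)
        print(f"\n{exp}: predictors of S_p (descending R^2)")
        print(sp[["predictor", "slope", "r_squared", "p_value"]]
              .round(4).to_string(index=False))
        print(f"ranking for S_p: {result['ranking']['S_p']}")

    table = io.read_trait_table(OUT / "trial_exp1.csv")
    cols = ["capacitance_nF", "resistance_kOhm", "impedance_kOhm",
            "root_length_mm", "root_area_mm2", "root_volume_mm3",
            "root_dry_weight_g", "S_p_Nm", "S_s_Nm", "seed_yield_g"]
    r, p = electro.correlation_map(table, columns=cols)
    r.round(3).to_csv(OUT / "correlation_map_exp1.csv")
    print("\nexp1 correlations with S_p:")
    print(r["S_p_Nm"].drop("S_p_Nm").round(3).to_string())


if __name__ == "__main__":
    main()
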