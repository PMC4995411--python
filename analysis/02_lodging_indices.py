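#!/usr/bin/env python
"""Compute per-plant lodging indices and compare stem vs root failure risk.

Reads the simulated trait tables from 01, derives S_s, M_s, M_p, SF_s,
SF_p, SM and BS for every plant, and writes results/lodging_indices_<exp>.csv.
The headline comparison is the mean root safety factor SF_p against the
stem safety factor SF_s: a lower SF_p marks plants as more prone to
anchorage failure (root lodging) than stem buckling.
"""

from pathlib import Path

from canolodge import io

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    for exp in ("exp1", "exp2", "exp3"):
        table = io.read_trait_table(OUT / f"trial_{exp}.csv")
        indices = io.indices_table(table)
        path = OUT / f"lodging_indices_{exp}.csv"
        indices.to_csv(path, index=False)
        sf_p, sf_s = indices["SF_p"].mean(), indices["SF_s"].mean()
        verdict = ("root lodging more likely" if sf_p < sf_s
                   else "stem lodging more likely")
        print(f"{exp}: mean SF_p = {sf_p:.2f}, mean SF_s = {sf_s:.2f} "
              f"-> {verdict}  ({path.name})")


if __name__ == "__main__":
    main()
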