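# canolodge

Biomechanical lodging assessment for canola (*Brassica napus* L.): stem
and root safety factors, the root–soil anchorage model, and calibration
of non-invasive root electrical measurements against anchorage strength.

Lodging — the permanent displacement of a crop from vertical — costs
yield and quality. A plant fails either by stem buckling or by rotation
of its root–soil plate, and the balance between the two is captured by
safety factors: `SF_s = S_s / M_s` compares the stem's bending strength
(from a three-point bending test, `S_s = F_max·L/4`) with the stem's
self-weight moment `M_s = m_s·g·h_s·sin θ`, and `SF_p = S_p / M_p`
compares the measured anchorage moment with the whole-plant moment.
Anchorage itself follows the root–soil cone model `S_p = K·τ·D³ + c`
(soil shear strength τ, cone diameter D from diameter-classified root
segments). Because winching plants over is destructive, the package also
models root capacitance — each root segment an axially symmetric
cylindrical condenser, segments in parallel — and fits and ranks the
electrical predictors (C, R, Z at 1 kHz) of anchorage strength.

No plant-level data were published for the underlying field study, so
the package ships a synthetic-trial generator whose ground truth is the
study's printed effect sizes and fitted relationships (an irrigation
trial, a planting-date trial and a nitrogen trial, each 3 replications ×
8 plants per plot). Everything downstream — index computation, anchorage
fitting, calibration, ranking — is exercised and validated against it.

## Worked example

```python
import numpy as np
from canolodge import (default_config, simulate_trial, effect_estimate,
                       fit_anchorage_model, linear_calibration)

table = simulate_trial(default_config("exp1", seed=0))   # 96 plants

# irrigation effect on stem bending strength, pooled over varieties
print(round(effect_estimate(table, "irrigation", "S_s"), 1), "%")

# anchorage model: S_p on tau*D^3
pairs = np.column_stack([table["tauD3_Nm"], table["S_p_Nm"]])
m = fit_anchorage_model(pairs)
print(f"S_p = {m.K:.3f} tauD3 + {m.intercept_c:.3f}  (R2={m.r_squared:.2f})")

# capacitance as a non-invasive predictor of anchorage strength
fit = linear_calibration(table["capacitance_nF"], table["S_p_Nm"], "C")
print(f"C -> S_p: R2 = {fit.r_squared:.2f}")
```

prints

```
21.0 %
S_p = 0.526 tauD3 + 0.703  (R2=0.97)
C -> S_p: R2 = 0.88
```

— a single simulated cohort shows the subsurface-drip-irrigation effect
on stem strength near its configured +21.3 % (with sampling scatter), the
anchorage fit at slope 0.526 / intercept 0.703, and capacitance
explaining 88 % of the variance in anchorage strength.

The numbered scripts under `analysis/` run the full narrative: simulate
the three trials, derive per-plant lodging indices (root lodging comes
out more likely than stem lodging: mean SF_p < SF_s), fit the anchorage
model under both root-classification thresholds (1 mm predicts S_p far
better than 0.5 mm), calibrate and rank the electrical predictors
(capacitance first in all three experiments, R² = 0.88/0.70/0.56), and
recover all printed treatment effects by Monte Carlo. Outputs land in
`results/`. A thin CLI wraps the same library:

```sh
canolodge run --experiment exp1 --seed 1 --out-dir results/run1
```

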