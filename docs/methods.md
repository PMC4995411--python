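# Methods

## The problem

Canola (*Brassica napus* L.) lodges in two ways: the basal stem buckles
(stem lodging) or the root–soil anchorage fails and the plant rotates out
of the ground (root lodging). Which failure comes first is summarised by
safety factors — ratios of the strength of a support organ to the
gravitational self-weight moment it must bear at an inclination θ from
vertical. Measuring anchorage strength directly is destructive (the plant
is winched over with a prostrate tester), so the package also models a
non-invasive proxy: the electrical capacitance of the root system read
between a stem-base electrode and a soil electrode at 1 kHz, which tracks
absorbing root surface and, through root size, anchorage strength.

## Model and formulas

Per plant, with SI units at the module boundary (kg, m, N, N·m; stem
cross-section quantities in mm, mm³, N·mm⁻²):

* stem bending strength `S_s = F_max · L / 4` from a three-point bending
  test with span `L` (default 0.15 m);
* self-weight moments `M = m · g · h · sin θ` for the stem
  (`m_s`, `h_s`) and the whole plant (`m_p`, `h_p`), `g = 9.81 N·kg⁻¹`;
* safety factors `SF_s = S_s / M_s` and `SF_p = S_p / M_p`, with `S_p`
  the anchorage moment measured at the same θ (default 45°, the angle to
  which the anchorage test is driven);
* section modulus of the solid-oval basal section `SM = (π/32)·a²·b`
  (minor diameter `a` enters squared because bending is about the major
  axis; reduces to `πd³/32` for a circle) and bending stress
  `BS = 1000·S_s / SM`;
* anchorage model `S_p = K·τ·D³ + c`: soil shear strength τ (N·m⁻²)
  times the cubed root–soil cone diameter D (m) gives τD³ in N·m, so the
  slope K is dimensionless. The fit always includes the intercept `c`:
  a zero intercept would claim that a plant with no root plate has no
  anchorage, but the buried stem base itself anchors.

The root–soil cone diameter is estimated from diameter-classified root
segments: `D = 2 × max radial extent` over segments at or above a
classification threshold (1 mm default; 0.5 mm supported). Only roots
thicker than the threshold are lignified enough to move rigidly with the
cone, and the estimator is deliberately the simplest one consistent with a
circular plate centred on the stem. It is monotone non-increasing in the
threshold by construction; the finer 0.5 mm standard admits long thin
laterals and overestimates the cone, which is why the 1 mm classification
predicts `S_p` better in the analyses under `analysis/`.

Root capacitance uses the axially symmetric cylindrical-condenser model:
each segment contributes `2π·ε₀·ε_r·length / ln(radius_ratio)` and
segments add in parallel. The radius ratio is one effective value per
plant: for a thin epidermal dielectric of thickness t on roots of mean
diameter d̄ it is `1 + 2t/d̄`, which makes whole-plant capacitance
proportional to root surface area (the thin-film limit). Measured
readings are nF-scale rather than the µF-scale of the bare membrane
capacitance because only a small fraction of the root membrane is
polarised through the stem-to-soil current path at 1 kHz; a dimensionless
instrument-coupling factor (default 4·10⁻⁴) absorbs this.

Calibrations are simple OLS fits (slope, intercept, squared Pearson R²,
two-sided p for zero slope) with textbook prediction intervals
`ŷ ± t_{n−2}·s·√(1 + 1/n + (x₀−x̄)²/Sxx)`; predictors are ranked by
descending R², ties broken by ascending p then name. p-values are
reported per pair without multiple-testing correction, matching field
practice; a Benjamini–Hochberg helper is available for users who want it.

## The synthetic-trial generator

`canolodge.trials` emulates three factorial field experiments
(3 replications × 8 plants per plot):

* **exp1** — irrigation {CK, SDI} × variety {InVigorL140P, InVigor5440};
* **exp2** — planting date {Apr 27, May 8, May 22, Jun 3} × three varieties;
* **exp3** — nitrogen {0, 100, 200, 50+150 kg N ha⁻¹} × two varieties.

Treatment effects are multiplicative shifts of control-cell means. The
exp1 multipliers are the study's printed percentages (S_s +21.3 %,
S_p +14.0 %, M_p +8.1 %, M_s +7.6 %, root area +22.7 %, volume +30.9 %,
dry weight +30.1 %, capacitance +22.8 %, resistance −19.8 %, impedance
−20.1 %, seed yield +7.8 % under SDI; branch count +19.9 % for
InVigor5440). The planting-date and nitrogen level means are published
only as figures, so those ladders are *synthetic stand-ins*: monotone
sequences consistent with the reported directions (delayed planting
lowers S_p and C and raises R and Z; more N raises S_p, masses and C but
lowers BS and both safety factors, with the split application recovering
part of the safety factor; yield orders N200 > N100 > N50+150 > N0).

Structure of one plant draw, in order:

1. **Root segments.** A taproot, a geometric series of first-order
   laterals (count 1 + Poisson, redistributing a fixed length budget so
   branchiness does not add root mass), and 25 fine tertiary roots that
   sit below the 1 mm classification but straddle 0.5 mm. A shared
   lognormal *size latent* (σ = 0.14) scales all lengths; radial extents
   scale with the cube root of the latent — radial spread grows
   sublinearly with root mass — so the cone volume term D³ is *linear* in
   the same latent that drives surface area. That choice is what lets
   capacitance and anchorage share enough variance to support the
   configured calibration strength.
2. **Traits.** Length, area, volume, branch count aggregated from the
   segments by `canolodge.roots`; cone diameters at both thresholds.
3. **Anchorage.** `S_p = K·τ·D³ + c` (defaults K = 0.526, c = 0.703,
   τ ≈ 25 kPa) plus noise sized by the closed-form rule
   `σ² = K²·Var(x)·(1−R²)/R²` for the configured fit R² (default 0.97).
4. **Capacitance.** From the condenser model of the drawn segments, with
   measurement noise sized the same way against the configured C–S_p R²
   (0.88 / 0.70 / 0.56 for the three experiments).
5. **Resistance and impedance.** Noisy reciprocal-scaled functions of
   capacitance (the study treats R and Z empirically as negative
   correlates of root size; no circuit model is attempted).
6. **Stem.** Oval basal diameters scaled by the cube root of the
   configured S_s multiplier so SM and `S_s = BS·SM` stay mutually
   consistent; `F_max` back-computed from S_s.
7. **Yield.** Cell mean times `(S_p/μ_cell)^0.3`, coupling yield to
   anchorage within cells. The negative yield–SF_p association appears at
   plot/treatment level (the N response raises moments faster than
   strength), which is how the field data present it; per-plant pooled
   correlation is near zero because the within-cell coupling through S_p
   is positive.

**Moment-matched noise.** The two linkage noises (steps 3 and 4) are
drawn, then orthogonalised in sample against the signal columns and
rescaled to their nominal variance. Each simulated cohort therefore
*realises* the configured K, c and R² exactly (the same idea as
generating multivariate draws with empirical rather than population
moments). Treatment-effect traits keep plain mean-one lognormal noise
(CVs 4–14 % per source, compounding to roughly 10–20 % per trait), so
effect recovery is genuinely stochastic. If a cohort's intrinsic
geometric correlation ever fell below the target R² the matching would
add no noise and the cohort R² would fall short; with the default noise
budget the intrinsic correlation is ≈ 0.92 and this is a ≲1 % tail event.

Baseline means are desk-chosen to be agronomically plausible for canola
near maturity (plant height 1.1 m, whole-plant fresh mass 0.30 kg, basal
stem 10 × 12 mm, F_max ≈ 47 N, S_p ≈ 4 N·m, cone diameter ≈ 6.4 cm,
capacitance ≈ 4 nF, resistance ≈ 2 kΩ, yield ≈ 5 g per plant) and give
SF_p < SF_s — root lodging more likely than stem lodging, as observed in
the field. Problem sizes used throughout (96–288 plants per cohort, 200
Monte-Carlo replicates for recovery studies, 1000 draws for property and
coverage checks) are the package's default study conditions.

## What the generator does and does not emulate

It emulates: the factor structure and balance of the trials, the printed
effect sizes, the sign structure of the correlation map (C positive with
root size and S_p; R, Z negative), the anchorage fit, the
threshold-sensitivity of the cone estimate, and the predictor ordering
C > {R, Z} for S_p. It does **not** emulate: split-plot error structure
(plants are independent within cells; no plot random effects), weather or
phenology, spatial field layout, wind loading, within-plant correlation
between stem and root development beyond treatment level (the simulated
S_s–S_p per-plant correlation is weak), or measurement drift in the LCR
readings. Passing tests therefore show that the *estimators* recover
known ground truth under realistic noise — not that the field data would
reproduce them.

## Numerical choices and degenerate inputs

* g = 9.81 N·kg⁻¹; ε₀ = 8.854×10⁻¹² F·m⁻¹; θ ∈ [0°, 90°] enforced.
* A zero self-weight moment or section modulus raises a degenerate-input
  error rather than returning infinity.
* Constant predictors raise fit-degenerate errors; a constant *response*
  in the anchorage fit returns slope 0 with R² = 0.
* Constant columns in the correlation map are reported as missing (NaN),
  never zero.
* The zero-noise generator limit reproduces configured multipliers
  exactly for directly multiplied traits; capacitance tracks them to
  ~10⁻⁴ relative because the condenser log term is only asymptotically
  linear in the thin-film limit.
* Trait-table ingest converts cm/g field columns to SI and rejects rows
  violating physical invariants with row-numbered diagnostics.

## Known limitations

The cone-diameter estimator is definitional (twice the max supra-threshold
radial extent); alternative estimators (quantiles of extents, elliptical
plates) would change the τD³ scale and hence the fitted K. The τD³
x-axis units follow the convention τ in N·m⁻², D in m. Electrical R and Z
have no forward circuit model. The exp2/exp3 ladders are stand-ins, so
only their directions — not their magnitudes — should be read as
field-derived.
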