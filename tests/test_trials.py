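"""Synthetic-trial generator: determinism, structure, linkages, effects."""

import numpy as np
import pandas as pd
import pytest

from canolodge import electro, io, trials
from canolodge.errors import ConfigError, InvalidInputError


def test_deterministic_under_fixed_seed():
    a = trials.simulate_trial(trials.default_config("exp1", seed=5))
    b = trials.simulate_trial(trials.default_config("exp1", seed=5))
    pd.testing.assert_frame_equal(a, b)
    c = trials.simulate_trial(trials.default_config("exp1", seed=6))
    assert not a["S_p_Nm"].equals(c["S_p_Nm"])


@pytest.mark.parametrize("experiment, cells", [
    ("exp1", 2 * 2), ("exp2", 4 * 3), ("exp3", 4 * 2),
])
def test_row_count_and_domains(experiment, cells):
    table = trials.simulate_trial(trials.default_config(experiment, seed=2))
    assert len(table) == cells * 3 * 8
    numeric = table.select_dtypes("number")
    assert (numeric >= 0).all().all()
    assert (table["h_p_m"] <= table["height_H_m"]).all()
    assert (table["b_major_mm"] >= table["a_minor_mm"]).all()
    # S_s column consistent with the three-point bending force
    np.testing.assert_allclose(table["S_s_Nm"],
                               table["F_max_N"] * table["span_L_m"] / 4.0)


def test_zero_noise_limit_recovers_configured_multipliers():
    table = trials.simulate_trial(trials.default_config("exp1", seed=9).zero_noise())
    # direct multiplicative traits are exact; capacitance follows the
    # condenser geometry whose log term is linear to ~1e-4 here
    assert trials.effect_estimate(table, "irrigation", "S_s") == pytest.approx(21.3, abs=1e-9)
    assert trials.effect_estimate(table, "irrigation", "S_p") == pytest.approx(14.0, abs=1e-9)
    assert trials.effect_estimate(table, "irrigation", "volume_V") == pytest.approx(30.9, abs=1e-9)
    assert trials.effect_estimate(table, "irrigation", "surface_area_A") == pytest.approx(22.7, abs=1e-9)
    assert trials.effect_estimate(table, "irrigation", "capacitance_C") == pytest.approx(22.8, rel=1e-3)


def test_effect_estimate_on_constructed_table():
    table = pd.DataFrame({
        "treat": ["ctl"] * 4 + ["trt"] * 4,
        "y": [1.0, 1.0, 1.0, 1.0, 1.1, 1.1, 1.1, 1.1],
        "z": [2.0] * 8,
    })
    assert trials.effect_estimate(table, "treat", "y") == pytest.approx(10.0)
    assert trials.effect_estimate(table, "treat", "z") == pytest.approx(0.0)
    with pytest.raises(InvalidInputError):
        trials.effect_estimate(table, "missing", "y")
    with pytest.raises(InvalidInputError):
        trials.effect_estimate(table, "treat", "nope")


def test_effect_estimate_requires_named_levels_beyond_two():
    table = trials.simulate_trial(trials.default_config("exp2", seed=1))
    with pytest.raises(InvalidInputError):
        trials.effect_estimate(table, "planting_date", "S_p")
    eff = trials.effect_estimate(table, "planting_date", "S_p",
                                 treatment="Jun03", control="Apr27")
    assert eff < 0


def test_config_validation():
    with pytest.raises(ConfigError):
        trials.default_config("exp9")
    cfg = trials.default_config("exp1")
    with pytest.raises(ConfigError):
        trials.TrialConfig(experiment="exp1",
                           factors={"irrigation": ("CK", "Flood")},
                           multipliers=cfg.multipliers)


def test_capacitance_linked_to_root_surface_area(exp1_table):
    r = np.corrcoef(exp1_table["capacitance_nF"],
                    exp1_table["root_area_mm2"])[0, 1]
    assert r > 0.9


def test_anchorage_linkage_realises_configured_fit(exp1_table):
    from canolodge import biomech
    x = exp1_table["tauD3_Nm"].to_numpy()
    model = biomech.fit_anchorage_model(
        np.column_stack([x, exp1_table["S_p_Nm"].to_numpy()]))
    assert model.K == pytest.approx(0.526, abs=1e-9)
    assert model.intercept_c == pytest.approx(0.703, abs=1e-9)
    assert model.r_squared == pytest.approx(0.97, abs=1e-9)


def test_calibration_signs_match_field_pattern(exp1_table):
    sp = exp1_table["S_p_Nm"].to_numpy()
    fit_c = electro.linear_calibration(exp1_table["capacitance_nF"], sp, "C")
    fit_r = electro.linear_calibration(exp1_table["resistance_kOhm"], sp, "R")
    fit_z = electro.linear_calibration(exp1_table["impedance_kOhm"], sp, "Z")
    assert fit_c.slope > 0
    assert fit_r.slope < 0 and fit_z.slope < 0


def test_planting_date_delay_decreases_anchorage_and_capacitance():
    table = trials.simulate_trial(trials.default_config("exp2", seed=4))
    by_date = table.groupby("planting_date", sort=False)[
        ["S_p_Nm", "capacitance_nF"]].mean()
    assert list(by_date.index) == ["Apr27", "May08", "May22", "Jun03"]
    assert by_date["S_p_Nm"].is_monotonic_decreasing
    assert by_date["capacitance_nF"].is_monotonic_decreasing


def test_nitrogen_raises_moments_faster_than_strength():
    table = trials.simulate_trial(trials.default_config("exp3", seed=4))
    merged = table.merge(io.indices_table(table)[["plant_id", "SF_p", "M_p_Nm"]],
                         on="plant_id")
    rate_order = ["N0", "N100", "N200"]
    means = merged.groupby("nitrogen", sort=False)[
        ["S_p_Nm", "M_p_Nm", "SF_p"]].mean().loc[rate_order]
    assert means["S_p_Nm"].is_monotonic_increasing
    assert means["M_p_Nm"].is_monotonic_increasing
    assert means["SF_p"].is_monotonic_decreasing
    # split application restores part of the safety factor lost at N200
    sf = merged.groupby("nitrogen", sort=False)["SF_p"].mean()
    assert sf["N50+150"] > sf["N200"]


def test_seed_yield_coupled_to_anchorage_in_exp3():
    table = trials.simulate_trial(trials.default_config("exp3", seed=8))
    merged = table.merge(io.indices_table(table)[["plant_id", "SF_p"]],
                         on="plant_id")
    # per plant: yield rides on anchorage strength
    r_sp = np.corrcoef(merged["seed_yield_g"], merged["S_p_Nm"])[0, 1]
    assert r_sp > 0
    # at plot level (how yield is reported in the field) the N response
    # trades yield against the root safety factor
    plots = merged.groupby(["nitrogen", "variety", "rep"])[
        ["seed_yield_g", "SF_p"]].mean()
    r_sf = np.corrcoef(plots["seed_yield_g"], plots["SF_p"])[0, 1]
    assert r_sf < 0


def test_segment_table_feeds_reported_traits():
    cfg = trials.default_config("exp1", seed=3)
    table, segments = trials.simulate_trial(cfg, return_segments=True)
    from canolodge import roots
    agg = roots.aggregate_by_plant(segments).loc[table["plant_id"]]
    np.testing.assert_allclose(table["root_area_mm2"],
                               agg["surface_area_A"], rtol=1e-12)
    cones = roots.cone_diameter_by_plant(segments, 1.0).loc[table["plant_id"]]
    np.testing.assert_allclose(table["cone_D_m"], cones, rtol=1e-12)
    # the finer classification can only widen the estimated cone
    assert (table["cone_D_05mm_m"] >= table["cone_D_m"] - 1e-12).all()
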