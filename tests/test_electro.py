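"""Condenser model, linear calibration, prediction intervals, ranking,
correlation map -- each checked against an independent oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from canolodge import electro, roots
from canolodge.errors import FitDegenerateError, InvalidInputError


def test_segment_capacitance_constants():
    params = electro.CondenserParams(relative_permittivity=80.0,
                                     radius_ratio=math.e)
    # 2*pi*eps0*80*0.1 / ln(e) = 4.4506e-10 F
    c = electro.segment_capacitance(0.1, params)
    assert c == pytest.approx(2 * math.pi * 8.854e-12 * 80 * 0.1, rel=1e-12)
    assert c == pytest.approx(4.4506e-10, rel=1e-4)


def test_segment_capacitance_invalid():
    params = electro.CondenserParams(80.0, 2.0)
    with pytest.raises(InvalidInputError):
        electro.segment_capacitance(0.0, params)
    with pytest.raises(InvalidInputError):
        electro.CondenserParams(80.0, 1.0)


def _scan(lengths):
    return [roots.RootSegment(str(i), 1.0, L, 1.0, 1)
            for i, L in enumerate(lengths)]


@given(st.lists(st.floats(1, 500), min_size=1, max_size=10),
       st.lists(st.floats(1, 500), min_size=1, max_size=10))
def test_root_capacitance_parallel_additivity(la, lb):
    params = electro.CondenserParams(80.0, 1.5)
    ca = electro.root_system_capacitance(_scan(la), params)
    cb = electro.root_system_capacitance(_scan(lb), params)
    cab = electro.root_system_capacitance(_scan(la + lb), params)
    assert cab == pytest.approx(ca + cb, rel=1e-9)
    assert cab >= ca  # monotone under scan inclusion
    # linear in permittivity
    double_eps = electro.CondenserParams(160.0, 1.5)
    assert electro.root_system_capacitance(_scan(la), double_eps) == \
        pytest.approx(2 * ca, rel=1e-12)


def test_root_capacitance_tracks_surface_area(rng):
    # uniform diameters: C ~ total length ~ surface area
    params = electro.CondenserParams(80.0, 1.2)
    areas, caps = [], []
    for _ in range(50):
        lengths = rng.uniform(10, 400, rng.integers(2, 20))
        scan = _scan(lengths)
        areas.append(roots.aggregate_traits(scan).surface_area_A)
        caps.append(electro.root_system_capacitance(scan, params))
    r = np.corrcoef(areas, caps)[0, 1]
    assert r > 0.9


def test_linear_calibration_against_normal_equations(rng):
    x = np.array([1.0, 2.0, 3.5, 4.0, 5.5, 6.0, 7.2, 8.8, 9.1, 10.0])
    y = 0.7 * x + 1.3 + rng.normal(0, 0.4, 10)
    fit = electro.linear_calibration(x, y, "x")
    # closed-form normal equations, computed from definitions
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r2 = sxy**2 / (sxx * ((y - y.mean()) ** 2).sum())
    assert fit.slope == pytest.approx(slope, rel=1e-10)
    assert fit.intercept == pytest.approx(intercept, rel=1e-10)
    assert fit.r_squared == pytest.approx(r2, rel=1e-10)
    assert fit.n == 10


def test_linear_calibration_edge_cases(rng):
    x = np.arange(5.0)
    collinear = electro.linear_calibration(x, 2 * x + 1, "c")
    assert collinear.r_squared == pytest.approx(1.0)
    assert collinear.p_value < 1e-6
    noise = rng.normal(size=500)
    flat = electro.linear_calibration(np.arange(500.0), noise, "f")
    assert abs(flat.slope) < 0.01
    assert flat.r_squared < 0.02
    with pytest.raises(FitDegenerateError):
        electro.linear_calibration(np.ones(5), np.arange(5.0), "const")
    with pytest.raises(FitDegenerateError):
        electro.linear_calibration([1.0, 2.0], [1.0, 2.0], "short")


def test_prediction_interval_matches_statsmodels(rng):
    import statsmodels.api as sm

    x = rng.uniform(0, 10, 25)
    y = 1.5 + 0.8 * x + rng.normal(0, 0.5, 25)
    fit = electro.linear_calibration(x, y, "x")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    for x0 in (0.0, 4.2, x.mean(), 12.0):
        est, lo, hi = electro.predict_with_interval(fit, x0, 0.95)
        frame = res.get_prediction(np.array([[1.0, x0]])).summary_frame(alpha=0.05)
        assert est == pytest.approx(frame["mean"].iloc[0], rel=1e-9)
        assert lo == pytest.approx(frame["obs_ci_lower"].iloc[0], rel=1e-9)
        assert hi == pytest.approx(frame["obs_ci_upper"].iloc[0], rel=1e-9)


def test_prediction_interval_properties(rng):
    x = rng.uniform(0, 10, 30)
    y = 2.0 - 0.3 * x + rng.normal(0, 0.3, 30)
    fit = electro.linear_calibration(x, y, "x")
    widths = []
    for x0 in [x.mean() - 5, x.mean(), x.mean() + 5]:
        _, lo, hi = electro.predict_with_interval(fit, x0)
        widths.append(hi - lo)
    assert widths[1] == min(widths)  # narrowest at the training mean
    # noiseless training data: interval width collapses
    exact = electro.linear_calibration(x, 2 * x + 1, "e")
    _, lo, hi = electro.predict_with_interval(exact, 5.0)
    assert hi - lo == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(InvalidInputError):
        electro.predict_with_interval(fit, 1.0, level=1.5)


def _fit(name, r2, p):
    return electro.CalibrationFit(name, 1.0, 0.0, r2, p, 10)


def test_rank_predictors_order_and_ties():
    fits = [_fit("b", 0.56, 0.01), _fit("a", 0.88, 0.001), _fit("c", 0.30, 0.2)]
    ranked = electro.rank_predictors(fits)
    assert [f.predictor_name for f in ranked] == ["a", "b", "c"]
    # tie on R^2 broken by p, then name
    tied = [_fit("z", 0.5, 0.01), _fit("m", 0.5, 0.001), _fit("a", 0.5, 0.01)]
    assert [f.predictor_name for f in electro.rank_predictors(tied)] == ["m", "a", "z"]
    single = electro.rank_predictors([_fit("only", 0.4, 0.05)])
    assert single[0].predictor_name == "only"
    with pytest.raises(InvalidInputError):
        electro.rank_predictors([])


def test_correlation_map_against_definition():
    table = pd.DataFrame({
        "u": [1.0, 2.0, 3.0, 4.0, 5.0],
        "v": [2.1, 3.9, 6.2, 8.0, 9.8],
        "w": [5.0, 3.0, 4.0, 1.0, 2.0],
    })
    r, p = electro.correlation_map(table)
    assert np.allclose(r.values, r.values.T, equal_nan=True)
    assert np.allclose(np.diag(r), 1.0)

    def pearson(a, b):  # definition-level oracle
        a, b = np.asarray(a) - np.mean(a), np.asarray(b) - np.mean(b)
        return float((a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum()))

    for ci in table.columns:
        for cj in table.columns:
            assert r.loc[ci, cj] == pytest.approx(pearson(table[ci], table[cj]),
                                                  rel=1e-10)
    assert p.loc["u", "v"] < 0.01
    # a column against its own doubling correlates perfectly
    r2, _ = electro.correlation_map(table.assign(u2=2 * table["u"]))
    assert r2.loc["u", "u2"] == pytest.approx(1.0)


def test_correlation_map_constant_column_reported_missing():
    table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    r, p = electro.correlation_map(table)
    assert np.isnan(r.loc["a", "b"]) and np.isnan(r.loc["b", "b"])
    assert not np.isnan(r.loc["a", "a"])
    with pytest.raises(InvalidInputError):
        electro.correlation_map(table.iloc[:2])


def test_benjamini_hochberg_monotone():
    p = np.array([0.001, 0.01, 0.04, 0.5, np.nan])
    adj = electro.benjamini_hochberg(p)
    assert np.isnan(adj[-1])
    assert np.all(adj[:-1] >= p[:-1] - 1e-12)
    assert np.all(np.diff(adj[np.argsort(p[:-1])]) >= -1e-12)
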