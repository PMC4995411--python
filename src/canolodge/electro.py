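"""Root electrical measurements: condenser forward model and calibration.

An LCR meter connected between an electrode at the stem base and one in the
soil reads capacitance (C), resistance (R) and impedance (Z) at 1 kHz.
Each root segment behaves as an axially symmetric cylindrical condenser:
the root epidermal membrane is a dielectric separating the conductive soil
solution outside from the conductive root interior, so segment capacitance
follows the coaxial-capacitor law

    C = 2 pi eps0 eps_r * length / ln(r_outer / r_inner).

Segments conduct in parallel, hence whole-root capacitance is the sum over
segments and scales with the amount of absorbing root surface.  This is why
C is a positive, non-invasive correlate of root size and, through root
size, of root anchorage strength -- the calibration this module fits and
ranks against the alternative predictors R and Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitDegenerateError, InvalidInputError
from .roots import RootSegment, _as_frame

#: Vacuum permittivity, F m^-1.
EPSILON_0 = 8.854e-12

#: Measurement frequency of the LCR readings, kHz.
MEASUREMENT_FREQUENCY_KHZ = 1.0


@dataclass(frozen=True)
class ElectricalReading:
    """One plant's LCR readings at 1 kHz: C (nF), R (kOhm), Z (kOhm)."""

    capacitance_C: float
    resistance_R: float
    impedance_Z: float
    frequency: float = MEASUREMENT_FREQUENCY_KHZ

    def __post_init__(self) -> None:
        if min(self.capacitance_C, self.resistance_R, self.impedance_Z) < 0:
            raise InvalidInputError("C, R and Z must be >= 0")
        if self.frequency != MEASUREMENT_FREQUENCY_KHZ:
            raise InvalidInputError("readings are defined at 1 kHz")


@dataclass(frozen=True)
class CondenserParams:
    """Effective cylindrical-condenser parameters for one plant.

    ``radius_ratio`` is the outer/inner conductor radius ratio of the
    equivalent coaxial capacitor (one effective value per plant; the
    electrode geometry is not resolved per segment).  For a thin epidermal
    membrane of thickness t on a root of diameter d the ratio is
    1 + 2 t / d, making the segment capacitance proportional to the
    segment's lateral surface area.
    """

    relative_permittivity: float
    radius_ratio: float

    def __post_init__(self) -> None:
        if self.relative_permittivity <= 0:
            raise InvalidInputError("relative permittivity must be > 0")
        if self.radius_ratio <= 1.0:
            raise InvalidInputError("radius_ratio must exceed 1")


@dataclass(frozen=True)
class CalibrationFit:
    """A simple linear calibration y = slope * x + intercept.

    Stores the design moments (x mean, centred sum of squares) and the
    residual variance needed to build prediction intervals for new plants.
    """

    predictor_name: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    x_mean: float = field(default=float("nan"), repr=False)
    x_ss: float = field(default=float("nan"), repr=False)  # sum((x - mean)^2)
    residual_var: float = field(default=float("nan"), repr=False)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InvalidInputError("calibration requires n >= 3")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise InvalidInputError(f"r_squared outside [0, 1]: {self.r_squared}")


def segment_capacitance(length: float, params: CondenserParams) -> float:
    """Capacitance (F) of one root segment as a cylindrical condenser."""
    if length <= 0:
        raise InvalidInputError("segment length must be > 0")
    return (2.0 * math.pi * EPSILON_0 * params.relative_permittivity * length
            / math.log(params.radius_ratio))


def root_system_capacitance(
    segments: Union[pd.DataFrame, Iterable[RootSegment]],
    params: CondenserParams,
) -> float:
    """Whole-root capacitance (nF): parallel sum of segment condensers.

    Proportional to total root length at fixed params; with the thin-film
    radius ratio (1 + 2t/d evaluated at the root system's mean diameter)
    it tracks root surface area.  Empty scans give 0.
    """
    df = _as_frame(segments)
    if len(df) == 0:
        return 0.0
    total_length_m = float(df["length_mm"].sum()) / 1000.0
    return segment_capacitance(total_length_m, params) * 1e9


def linear_calibration(x, y, predictor_name: str = "x") -> CalibrationFit:
    """OLS calibration of y on x with slope p-value (two-sided, zero slope).

    R^2 is the squared Pearson correlation, identical to the OLS coefficient
    of determination for a single predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise FitDegenerateError("calibration requires at least 3 points")
    if np.ptp(x) == 0:
        raise FitDegenerateError(f"{predictor_name}: constant predictor")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = n - 2
    return CalibrationFit(
        predictor_name=predictor_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
        x_mean=float(x.mean()),
        x_ss=float(((x - x.mean()) ** 2).sum()),
        residual_var=float((resid**2).sum() / dof) if dof > 0 else 0.0,
    )


def predict_with_interval(fit: CalibrationFit, x0: float, level: float = 0.95):
    """Point prediction and prediction interval for a new observation at x0.

    Uses the standard OLS prediction interval
    yhat +- t_{n-2, (1+level)/2} * s * sqrt(1 + 1/n + (x0 - xbar)^2 / Sxx),
    which is narrowest at the training mean and widens away from it.
    """
    if not 0.0 < level < 1.0:
        raise InvalidInputError("level must be in (0, 1)")
    if not np.isfinite(fit.residual_var) or not np.isfinite(fit.x_ss):
        raise InvalidInputError("fit does not carry design moments")
    yhat = fit.slope * x0 + fit.intercept
    se = math.sqrt(fit.residual_var
                   * (1.0 + 1.0 / fit.n + (x0 - fit.x_mean) ** 2 / fit.x_ss))
    tcrit = stats.t.ppf(0.5 + level / 2.0, fit.n - 2)
    return yhat, yhat - tcrit * se, yhat + tcrit * se


def rank_predictors(fits: Sequence[CalibrationFit]):
    """Sort calibrations by descending R^2; ties by ascending p, then name."""
    if len(fits) == 0:
        raise InvalidInputError("need at least one fit to rank")
    return sorted(fits, key=lambda f: (-f.r_squared, f.p_value, f.predictor_name))


def correlation_map(
    table: pd.DataFrame, columns: Optional[Sequence[str]] = None
):
    """Pairwise Pearson correlations with p-values over numeric columns.

    Returns ``(r, p)`` DataFrames, both symmetric with unit / zero diagonal.
    Constant columns have undefined correlations and are reported as NaN
    (missing), never coerced to zero.
    """
    num = table[list(columns)] if columns is not None else table.select_dtypes("number")
    if len(num) < 3:
        raise InvalidInputError("correlation map requires at least 3 rows")
    cols = list(num.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    values = num.to_numpy(dtype=float)
    constant = np.ptp(values, axis=0) == 0
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
            else:
                rij, pij = stats.pearsonr(values[:, i], values[:, j])
                r[i, j] = r[j, i] = rij
                p[i, j] = p[j, i] = pij
    for i in range(k):
        if constant[i]:
            r[i, i] = np.nan
            p[i, i] = np.nan
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional multiple-testing aid)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    mask = np.isfinite(p)
    out = np.full_like(p, np.nan)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
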