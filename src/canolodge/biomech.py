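"""Per-plant biomechanical lodging indices and the root-soil anchorage model.

A plant lodges either by buckling of the basal stem (stem lodging) or by
rotation of the root-soil plate (root lodging).  Both failure modes are
summarised by a *safety factor*: the ratio of the strength of the support
organ (stem bending strength ``S_s`` or root anchorage strength ``S_p``) to
the gravitational self-weight moment (``M_s`` or ``M_p``) it must bear when
the plant is displaced by an angle theta from vertical.  A safety factor
below one means the organ fails under the plant's own weight.

Anchorage strength can also be predicted from soil mechanics: the root-soil
plate behaves as a cone of diameter ``D`` shearing through soil of shear
strength ``tau``, giving ``S_p = K * tau * D**3 + c`` with a dimensionless
slope ``K`` and an intercept ``c`` contributed by the stem base.

All functions take and return SI units (kg, m, N, N*m) except for the
cross-section quantities, which use the conventional mm / mm^3 / N*mm^-2.
Unit conversion is the job of :mod:`canolodge.io`; nothing here converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, FitDegenerateError, InvalidInputError

#: Acceleration due to gravity, N kg^-1.
GRAVITY = 9.81

#: Default span between the fulcra of the three-point bending test, m.
DEFAULT_SPAN_L = 0.15

#: Default inclination of the anchorage (prostrate-tester) test, degrees.
DEFAULT_THETA_DEG = 45.0


@dataclass(frozen=True)
class PlantSpecimen:
    """One plant's measured geometry, masses, mechanical and electrical data.

    Heights and masses are SI (m, kg); basal cross-section diameters are mm;
    ``frew``/``dryw`` are basal-stem fresh/dry weight per unit length in
    g cm^-1 and are carried through unchanged.
    """

    plant_id: str
    height_H: float
    h_s: float
    h_p: float
    m_s: float
    m_p: float
    a_minor: float
    b_major: float
    F_max: float
    S_p_measured: float
    span_L: float = DEFAULT_SPAN_L
    theta_deg: float = DEFAULT_THETA_DEG
    frew: float = float("nan")
    dryw: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("height_H", "h_s", "h_p", "m_s", "m_p", "a_minor",
                     "b_major", "F_max", "S_p_measured", "span_L"):
            if getattr(self, name) < 0:
                raise InvalidInputError(
                    f"{self.plant_id}: {name} must be >= 0, got {getattr(self, name)}")
        if self.b_major < self.a_minor:
            raise InvalidInputError(
                f"{self.plant_id}: b_major ({self.b_major}) < a_minor ({self.a_minor})")
        if not 0.0 <= self.theta_deg <= 90.0:
            raise InvalidInputError(
                f"{self.plant_id}: theta_deg must be in [0, 90], got {self.theta_deg}")
        if self.h_p > self.height_H:
            raise InvalidInputError(
                f"{self.plant_id}: h_p ({self.h_p}) exceeds plant height ({self.height_H})")


@dataclass(frozen=True)
class LodgingIndices:
    """Derived per-plant lodging indices (all non-negative).

    S_s, M_s, M_p in N*m; SF_s, SF_p dimensionless; SM in mm^3; BS in N mm^-2.
    """

    S_s: float
    M_s: float
    M_p: float
    SF_s: float
    SF_p: float
    SM: float
    BS: float


@dataclass(frozen=True)
class AnchorageModel:
    """Fitted S_p = K * (tau * D^3) + c relationship.

    ``K`` is the dimensionless slope linking soil shear strength and cone
    diameter to anchorage strength; ``intercept_c`` (N*m) is the anchoring
    contribution of the stem base in the absence of a root plate.
    """

    K: float
    intercept_c: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError(f"anchorage model needs n >= 2, got {self.n}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise InvalidInputError(f"r_squared outside [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class SoilMechanics:
    """Soil shear strength tau (N m^-2) and root-soil cone diameter D (m)."""

    tau: float
    cone_D: float

    def __post_init__(self) -> None:
        if self.tau < 0 or self.cone_D < 0:
            raise InvalidInputError("tau and cone_D must be >= 0")


def stem_bending_strength(F_max, span_L=DEFAULT_SPAN_L):
    """Stem bending strength S_s = F_max * L / 4 (N*m).

    ``F_max`` is the peak force (N) from a three-point bending test of the
    basal stem across a span ``span_L`` (m); for a centre point load the
    maximum bending moment is F*L/4.
    """
    F_max = np.asarray(F_max, dtype=float)
    if np.any(F_max < 0):
        raise InvalidInputError("F_max must be >= 0")
    if np.any(np.asarray(span_L, dtype=float) <= 0):
        raise InvalidInputError("span_L must be > 0")
    return F_max * span_L / 4.0


def self_weight_moment(mass, h_cg, theta_deg=DEFAULT_THETA_DEG):
    """Gravitational moment M = m * g * h_cg * sin(theta) (N*m).

    ``mass`` (kg) acting at centre-of-gravity height ``h_cg`` (m) on a plant
    inclined ``theta_deg`` degrees from vertical; the lever arm of the weight
    about the stem base is h_cg * sin(theta).
    """
    mass = np.asarray(mass, dtype=float)
    h_cg = np.asarray(h_cg, dtype=float)
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(mass < 0) or np.any(h_cg < 0):
        raise InvalidInputError("mass and h_cg must be >= 0")
    if np.any(theta < 0) or np.any(theta > 90):
        raise InvalidInputError("theta_deg must be in [0, 90]")
    return mass * GRAVITY * h_cg * np.sin(np.deg2rad(theta))


def safety_factor(strength, moment):
    """Safety factor = strength / moment (dimensionless).

    The number of times a support organ can bear the self-weight moment of
    the material it supports; values below one predict failure.
    """
    strength = np.asarray(strength, dtype=float)
    moment = np.asarray(moment, dtype=float)
    if np.any(strength < 0):
        raise InvalidInputError("strength must be >= 0")
    if np.any(moment <= 0):
        raise DegenerateInputError(
            "self-weight moment is zero (or negative): safety factor undefined")
    return strength / moment


def section_modulus(a_minor, b_major):
    """Section modulus SM = (pi/32) * a^2 * b of a solid oval section (mm^3).

    ``a_minor`` and ``b_major`` are the outer diameters of the minor and
    major axes of the oval basal cross-section (mm).  Bending is about the
    major axis (the plane in which the stem is bent in the three-point
    test), so the minor diameter enters squared; for a circle (a == b) the
    expression reduces to pi d^3 / 32.
    """
    a = np.asarray(a_minor, dtype=float)
    b = np.asarray(b_major, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise InvalidInputError("diameters must be > 0")
    if np.any(b < a):
        raise InvalidInputError("b_major must be >= a_minor")
    return math.pi / 32.0 * a**2 * b


def bending_stress(S_s, SM):
    """Bending stress BS = bending moment / section modulus (N mm^-2).

    ``S_s`` is in N*m and is converted to N*mm before dividing by SM (mm^3).
    """
    S_s = np.asarray(S_s, dtype=float)
    SM = np.asarray(SM, dtype=float)
    if np.any(S_s < 0):
        raise InvalidInputError("S_s must be >= 0")
    if np.any(SM <= 0):
        raise DegenerateInputError("section modulus is zero: bending stress undefined")
    return S_s * 1000.0 / SM


def anchorage_predict(tau, D, model: AnchorageModel):
    """Predict anchorage strength S_p = K * tau * D^3 + c (N*m).

    ``tau`` is soil shear strength (N m^-2), ``D`` the root-soil cone
    diameter (m); the product tau*D^3 is therefore in N*m and ``K`` is
    dimensionless.
    """
    tau = np.asarray(tau, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(tau < 0) or np.any(D < 0):
        raise InvalidInputError("tau and D must be >= 0")
    return model.K * tau * D**3 + model.intercept_c


def fit_anchorage_model(pairs) -> AnchorageModel:
    """Ordinary least squares fit of S_p on tau*D^3, with intercept.

    ``pairs`` is a sequence of (tau*D^3, S_p) tuples, both in N*m.  The fit
    always includes an intercept: a zero intercept would imply no anchoring
    force in the absence of a root plate, whereas the stem base itself
    anchors.  R^2 is the squared Pearson correlation (identical to the OLS
    coefficient of determination for a simple linear regression).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise FitDegenerateError("need at least 2 (tau*D^3, S_p) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise FitDegenerateError("tau*D^3 values are constant: slope undefined")
    if np.ptp(y) == 0:
        # constant response: zero slope, no explained variance
        return AnchorageModel(K=0.0, intercept_c=float(y[0]), r_squared=0.0,
                              n=len(x))
    res = stats.linregress(x, y)
    return AnchorageModel(K=float(res.slope), intercept_c=float(res.intercept),
                          r_squared=float(res.rvalue**2), n=len(x))


def lodging_indices(spec: PlantSpecimen) -> LodgingIndices:
    """Compute all seven lodging indices for one plant.

    SF_s compares the stem bending strength with the stem self-weight
    moment; SF_p compares the *measured* anchorage moment with the
    whole-plant self-weight moment, both evaluated at the specimen's
    inclination angle.
    """
    try:
        S_s = float(stem_bending_strength(spec.F_max, spec.span_L))
        M_s = float(self_weight_moment(spec.m_s, spec.h_s, spec.theta_deg))
        M_p = float(self_weight_moment(spec.m_p, spec.h_p, spec.theta_deg))
        SM = float(section_modulus(spec.a_minor, spec.b_major))
        BS = float(bending_stress(S_s, SM))
        SF_s = float(safety_factor(S_s, M_s))
        SF_p = float(safety_factor(spec.S_p_measured, M_p))
    except (InvalidInputError, DegenerateInputError) as exc:
        raise type(exc)(f"plant {spec.plant_id}: {exc}") from exc
    return LodgingIndices(S_s=S_s, M_s=M_s, M_p=M_p, SF_s=SF_s, SF_p=SF_p,
                          SM=SM, BS=BS)
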