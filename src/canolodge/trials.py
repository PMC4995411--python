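"""Synthetic factorial field trials for the lodging-assessment pipeline.

No raw plant-level data accompany the field study this package analyses, so
every pipeline stage is exercised on synthetic cohorts whose ground truth is
the set of printed treatment effects and fitted relationships:

* three experiments -- an irrigation trial (2 irrigation regimes x 2
  varieties), a planting-date trial (4 dates x 3 varieties) and a nitrogen
  trial (4 N managements x 2 varieties), each with 3 replications and 8
  plants per plot;
* per-trait treatment effects entered as multiplicative shifts of the
  control mean (the irrigation-trial defaults are the printed percentages,
  e.g. 1.213 for stem bending strength and 1.228 for root capacitance under
  subsurface drip irrigation; the date/N ladders are monotone synthetic
  stand-ins consistent with the reported directions);
* the structural linkages that make the cohort more than independent
  columns: root segments are drawn first and aggregated to morphological
  traits, capacitance follows from the cylindrical-condenser model of the
  root system, resistance and impedance are noisy decreasing functions of
  capacitance, anchorage strength follows S_p = K*tau*D^3 + c from the
  simulated root-soil cone, and stem strength follows from the section
  modulus through a material bending stress.

Noise is multiplicative lognormal per trait (traits are positive and
right-skewed).  The two published *levels* -- the anchorage fit
(K = 0.526, c = 0.703, R^2 = 0.97) and the capacitance-anchorage
calibration (R^2 = 0.88 in the strongest experiment) -- are enforced by a
closed-form variance-matching rule with empirically moment-matched noise
(the noise vector is orthogonalised in sample and scaled to its nominal
variance), so each simulated cohort realises the configured fit exactly
rather than approximately.  Everything else is plain Monte Carlo.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import roots
from .electro import EPSILON_0
from .errors import ConfigError, InvalidInputError

__all__ = [
    "Linkage", "TrialConfig", "default_config", "simulate_trial",
    "simulate_root_segments", "effect_estimate", "TRAIT_COLUMNS",
    "EXPERIMENTS",
]

EXPERIMENTS = ("exp1", "exp2", "exp3")

#: Friendly trait names -> trial-table column names.
TRAIT_COLUMNS: Dict[str, str] = {
    "S_s": "S_s_Nm",
    "S_p": "S_p_Nm",
    "capacitance_C": "capacitance_nF",
    "resistance_R": "resistance_kOhm",
    "impedance_Z": "impedance_kOhm",
    "surface_area_A": "root_area_mm2",
    "root_area": "root_area_mm2",
    "volume_V": "root_volume_mm3",
    "root_volume": "root_volume_mm3",
    "total_length_L": "root_length_mm",
    "dry_weight": "root_dry_weight_g",
    "seed_yield": "seed_yield_g",
    "branch_count": "branch_count",
    "cone_D": "cone_D_m",
    "tauD3": "tauD3_Nm",
}


@dataclass(frozen=True)
class Linkage:
    """Parameters tying the simulated traits together.

    ``K``/``intercept_c`` define the anchorage model S_p = K*tau*D^3 + c
    (tau*D^3 in N*m, D in metres); ``target_r2_tauD3`` is the coefficient of
    determination of that fit in the cohort and ``target_r2_C_Sp`` the one
    of the capacitance->anchorage calibration.  The condenser constants
    (relative permittivity, epidermal membrane thickness, instrument
    coupling) set the nF scale of the capacitance readings: only a small
    fraction of the membrane capacitance is polarised through the
    stem-to-soil current path at 1 kHz, which the dimensionless coupling
    factor absorbs.
    """

    K: float = 0.526
    intercept_c: float = 0.703  # N*m
    target_r2_tauD3: float = 0.97
    target_r2_C_Sp: float = 0.88
    tau_mean: float = 25000.0  # soil shear strength, N m^-2
    relative_permittivity: float = 80.0
    membrane_thickness_mm: float = 1.0e-3  # ~1 um effective dielectric film
    instrument_coupling: float = 4.0e-4  # polarised fraction at 1 kHz


#: Baseline (control-cell) trait means; units in the comments.
_BASELINE: Dict[str, float] = {
    "height_H": 1.10,     # m
    "h_s": 0.45,          # m
    "h_p": 0.55,          # m
    "m_s": 0.12,          # kg, stem fresh mass excl. basal 10 cm
    "m_p": 0.30,          # kg, whole plant fresh mass
    "a_minor": 10.0,      # mm
    "b_major": 12.0,      # mm
    "BS": 15.0,           # N mm^-2, material bending stress
    "S_p": 4.0,           # N*m, mean anchorage strength
    "dry_weight": 2.0,    # g, root dry weight per plant
    "frew": 2.5,          # g cm^-1
    "dryw": 0.55,         # g cm^-1
    "resistance": 2.0,    # kOhm
    "impedance": 2.6,     # kOhm
    "seed_yield": 5.0,    # g per plant
    "branches": 7.0,      # mean first-order lateral count
}

#: Lognormal sigma per noise source (roughly the coefficient of variation).
#: The shared size latent carries most of the root-system variation; the
#: independent components are kept small so that the geometric chain
#: root area -> capacitance and cone diameter -> anchorage stays tight
#: enough to support the configured calibration R^2.
_NOISE: Dict[str, float] = {
    "size": 0.14,          # shared root-system size latent
    "extent": 0.005,       # plant-level radial-extent factor
    "extent_jitter": 0.004,  # per-segment radial-extent jitter
    "root_diam": 0.012,    # plant-level root diameter factor
    "seg_len": 0.012,      # per-plant aggregation jitter on lengths
    "fine_diam": 0.10,     # per-segment fine-root diameter spread
    "fine_len": 0.08,
    "tau": 0.01,
    "stem_diam": 0.06,
    "bs": 0.10,
    "mass": 0.10,
    "height": 0.05,
    "hcg": 0.04,
    "frew": 0.10,
    "dry_weight": 0.12,
    "resistance": 0.10,
    "impedance": 0.10,
    "seed_yield": 0.07,
}

#: Root-system template (control cell): taproot + geometric lateral series
#: + fine tertiary roots.  Diameters mm, lengths mm, radial extents cm.
_TEMPLATE = {
    "tap_diam": 7.0, "tap_len": 220.0, "tap_extent": 1.0,
    "lat_diam0": 2.4, "lat_diam_decay": 0.85,
    "lat_len_total": 900.0, "lat_len_decay": 0.9,
    "lat_extent0": 3.2, "lat_extent_decay": 0.92,
    "n_fine": 25, "fine_diam": 0.50, "fine_len": 110.0,
    "fine_extent_lo": 2.0, "fine_extent_hi": 8.0,
}

#: Exponent coupling per-plant seed yield to anchorage strength within a cell.
_YIELD_SP_EXPONENT = 0.3

# ---------------------------------------------------------------------------
# Default treatment-effect multipliers.  The irrigation-trial (exp1) numbers
# are the printed percentages; the planting-date and nitrogen ladders are
# monotone synthetic stand-ins consistent with the reported directions.
# Omitted traits default to 1.0; the first level of each factor is the
# control and carries no entry.
# ---------------------------------------------------------------------------

_VARIETY_5440 = {  # larger root system, stronger anchorage, higher yield
    "root_area": 1.10, "root_volume": 1.13, "capacitance": 1.10,
    "dry_weight": 1.08, "S_p": 1.08, "S_s": 1.05, "branches": 1.199,
    "resistance": 0.92, "impedance": 0.92, "seed_yield": 1.03,
    "m_p": 1.04, "m_s": 1.04, "frew": 1.03, "dryw": 1.03,
}

_DEFAULT_MULTIPLIERS = {
    "exp1": {
        "irrigation": {
            "CK": {},
            "SDI": {
                "S_s": 1.213, "S_p": 1.140, "m_p": 1.081, "m_s": 1.076,
                "root_area": 1.227, "root_volume": 1.309, "dry_weight": 1.301,
                "capacitance": 1.228, "resistance": 0.802, "impedance": 0.799,
                "seed_yield": 1.078, "frew": 1.05, "dryw": 1.05,
            },
        },
        "variety": {"InVigorL140P": {}, "InVigor5440": _VARIETY_5440},
    },
    "exp2": {
        "planting_date": {
            "Apr27": {},
            "May08": {"S_p": 0.92, "S_s": 0.94, "capacitance": 0.93,
                      "root_area": 0.93, "root_volume": 0.91,
                      "resistance": 1.09, "impedance": 1.09,
                      "seed_yield": 0.94, "m_p": 0.95, "m_s": 0.95,
                      "height_H": 0.97, "dry_weight": 0.92},
            "May22": {"S_p": 0.85, "S_s": 0.88, "capacitance": 0.86,
                      "root_area": 0.86, "root_volume": 0.82,
                      "resistance": 1.18, "impedance": 1.18,
                      "seed_yield": 0.88, "m_p": 0.90, "m_s": 0.90,
                      "height_H": 0.94, "dry_weight": 0.85},
            "Jun03": {"S_p": 0.78, "S_s": 0.83, "capacitance": 0.79,
                      "root_area": 0.79, "root_volume": 0.74,
                      "resistance": 1.28, "impedance": 1.28,
                      "seed_yield": 0.81, "m_p": 0.86, "m_s": 0.86,
                      "height_H": 0.91, "dry_weight": 0.78},
        },
        "variety": {
            "InVigorL140P": {},
            "InVigor5440": _VARIETY_5440,
            "InVigorL150": {"root_area": 1.04, "root_volume": 1.05,
                            "capacitance": 1.04, "S_p": 1.03, "S_s": 1.02,
                            "resistance": 0.97, "impedance": 0.97,
                            "seed_yield": 1.02},
        },
    },
    "exp3": {
        "nitrogen": {
            "N0": {},
            "N100": {"S_p": 1.10, "m_p": 1.20, "m_s": 1.18, "BS": 0.93,
                     "S_s": 1.06, "height_H": 1.08, "capacitance": 1.12,
                     "root_area": 1.12, "root_volume": 1.16,
                     "resistance": 0.90, "impedance": 0.90,
                     "seed_yield": 1.12, "frew": 1.10, "dry_weight": 1.10},
            "N200": {"S_p": 1.18, "m_p": 1.40, "m_s": 1.35, "BS": 0.86,
                     "S_s": 1.12, "height_H": 1.15, "capacitance": 1.22,
                     "root_area": 1.22, "root_volume": 1.30,
                     "resistance": 0.82, "impedance": 0.82,
                     "seed_yield": 1.20, "frew": 1.20, "dry_weight": 1.20},
            "N50+150": {"S_p": 1.14, "m_p": 1.30, "m_s": 1.26, "BS": 0.90,
                        "S_s": 1.09, "height_H": 1.12, "capacitance": 1.16,
                        "root_area": 1.16, "root_volume": 1.22,
                        "resistance": 0.87, "impedance": 0.87,
                        "seed_yield": 1.08, "frew": 1.15, "dry_weight": 1.15},
        },
        "variety": {"InVigorL140P": {}, "InVigor5440": _VARIETY_5440},
    },
}

_DEFAULT_R2_C_SP = {"exp1": 0.88, "exp2": 0.70, "exp3": 0.56}


@dataclass(frozen=True)
class TrialConfig:
    """Factor structure, effect sizes, noise and linkage of one experiment."""

    experiment: str
    factors: Dict[str, tuple]
    multipliers: Dict[str, Dict[str, Dict[str, float]]]
    replications: int = 3
    plants_per_plot: int = 8
    baseline: Dict[str, float] = field(default_factory=lambda: dict(_BASELINE))
    noise_cv: Dict[str, float] = field(default_factory=lambda: dict(_NOISE))
    noise_scale: float = 1.0
    linkage: Linkage = field(default_factory=Linkage)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replications < 1 or self.plants_per_plot < 1:
            raise ConfigError("replications and plants_per_plot must be >= 1")
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be >= 0")
        for factor, levels in self.factors.items():
            if factor not in self.multipliers:
                raise ConfigError(f"no multipliers for factor {factor!r}")
            for level in levels:
                if level not in self.multipliers[factor]:
                    raise ConfigError(
                        f"unknown level {level!r} for factor {factor!r}")
            for level, table in self.multipliers[factor].items():
                for trait, mult in table.items():
                    if mult <= 0:
                        raise ConfigError(
                            f"multiplier {factor}/{level}/{trait} must be > 0")

    def multiplier(self, trait: str, levels: Dict[str, str]) -> float:
        """Product of per-factor multipliers for one treatment cell."""
        m = 1.0
        for factor, level in levels.items():
            m *= self.multipliers[factor][level].get(trait, 1.0)
        return m

    def zero_noise(self) -> "TrialConfig":
        """Copy of this config with all stochastic variation removed."""
        return replace(self, noise_scale=0.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["factors"] = {k: list(v) for k, v in self.factors.items()}
        return d


def default_config(experiment: str, seed: int = 0, **overrides) -> TrialConfig:
    """Default configuration for one of the three emulated experiments."""
    if experiment not in EXPERIMENTS:
        raise ConfigError(f"unknown experiment {experiment!r}; "
                          f"expected one of {EXPERIMENTS}")
    factors = {f: tuple(levels) for f, levels
               in _DEFAULT_MULTIPLIERS[experiment].items()}
    linkage = overrides.pop(
        "linkage", Linkage(target_r2_C_Sp=_DEFAULT_R2_C_SP[experiment]))
    return TrialConfig(experiment=experiment, factors=factors,
                       multipliers=_DEFAULT_MULTIPLIERS[experiment],
                       linkage=linkage, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# noise helpers
# ---------------------------------------------------------------------------

def _lognoise(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise (exactly 1 when sigma == 0)."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.standard_normal(size) * sigma - sigma**2 / 2.0)


def _matched_noise(rng: np.random.Generator, n: int, variance: float,
                   orthogonal_to) -> np.ndarray:
    """Noise with *empirically* matched moments.

    Returns a vector of exact sample variance ``variance`` (ddof = 0) that is
    exactly orthogonal, in sample, to the supplied columns and to the
    intercept.  Adding such noise to a signal dilutes the signal's sample
    correlation with any of the supplied columns by a known factor, which is
    what lets a closed-form variance-matching rule hit a configured R^2
    exactly rather than on average.
    """
    if variance <= 0:
        return np.zeros(n)
    e = rng.standard_normal(n)
    X = np.column_stack([np.ones(n)] + [np.asarray(c, dtype=float)
                                        for c in orthogonal_to])
    beta, *_ = np.linalg.lstsq(X, e, rcond=None)
    e = e - X @ beta
    sd = e.std()
    if sd == 0:
        return np.zeros(n)
    return e * (np.sqrt(variance) / sd)


# ---------------------------------------------------------------------------
# root-system construction
# ---------------------------------------------------------------------------

def _root_scales(config: TrialConfig, levels: Dict[str, str]):
    """Cell-level diameter/length/extent scale factors for the root system.

    The configured surface-area and volume multipliers pin down a unique
    uniform diameter scale s_d = mult_V / mult_A and length scale
    s_L = mult_A^2 / mult_V (area ~ d*l, volume ~ d^2*l).  The radial-extent
    scale is solved from the configured anchorage multiplier through
    S_p = K*tau*D^3 + c, correcting for the third moment of the mean-one
    lognormal plant factors so that the cell *mean* of S_p lands on target.
    """
    mult_A = config.multiplier("root_area", levels)
    mult_V = config.multiplier("root_volume", levels)
    s_d = mult_V / mult_A
    s_L = mult_A**2 / mult_V

    link = config.linkage
    ns = config.noise_scale
    cv = config.noise_cv
    # radial extents scale with the cube root of the size latent, so D^3 is
    # linear in the latent (E[U] = 1) and only the extent noises enter cubed
    sig2 = (cv["extent"] * ns) ** 2 + (cv["extent_jitter"] * ns) ** 2
    m3 = np.exp(3.0 * sig2)  # E[(mean-one lognormal)^3]
    mu_sp = config.baseline["S_p"] * config.multiplier("S_p", levels)
    if mu_sp <= link.intercept_c:
        raise ConfigError("configured mean S_p does not exceed the anchorage "
                          "intercept; no positive cone diameter solves it")
    D_base = 2.0 * _TEMPLATE["lat_extent0"] / 100.0  # m
    s_r3 = (mu_sp - link.intercept_c) / (link.K * link.tau_mean
                                         * D_base**3 * m3)
    return s_d, s_L, float(np.cbrt(s_r3))


def simulate_root_segments(config: TrialConfig, plant_ids, cells,
                           rng: np.random.Generator):
    """Draw the long-format root-segment table for a cohort.

    Each plant gets a taproot, a geometric series of first-order laterals
    whose count follows the cell's branch multiplier, and a population of
    fine tertiary roots (below the 1 mm classification threshold).  A shared
    plant-level size factor scales lengths and radial extents, tying root
    morphology, capacitance and anchorage together.  Returns the segment
    table plus the per-plant size and extent factors (used downstream).
    """
    ns = config.noise_scale
    cv = config.noise_cv
    n = len(plant_ids)
    t = _TEMPLATE

    size = _lognoise(rng, cv["size"] * ns, n)          # shared latent
    diam_f = _lognoise(rng, cv["root_diam"] * ns, n)
    # radial spread grows sublinearly with root mass: extent ~ size^(1/3),
    # which makes the cone volume term D^3 linear in the shared latent
    extent_f = np.cbrt(size) * _lognoise(rng, cv["extent"] * ns, n)
    len_jit = _lognoise(rng, cv["seg_len"] * ns, n)

    scale_d = np.empty(n)
    scale_L = np.empty(n)
    scale_r = np.empty(n)
    n_lat = np.empty(n, dtype=int)
    for i, levels in enumerate(cells):
        s_d, s_L, s_r = _root_scales(config, levels)
        scale_d[i], scale_L[i], scale_r[i] = s_d, s_L, s_r
        lat_mean = (config.baseline["branches"] - 1.0) \
            * config.multiplier("branches", levels)
        n_lat[i] = 1 + (rng.poisson(lat_mean) if ns > 0
                        else int(round(lat_mean)))

    pid_out, diam_out, len_out, ext_out, ord_out = [], [], [], [], []
    for i in range(n):
        pid = plant_ids[i]
        k = np.arange(n_lat[i])
        # lateral lengths: geometric profile normalised to a fixed total so
        # the branch count redistributes rather than adds root material
        w = t["lat_len_decay"] ** k
        lat_len = (t["lat_len_total"] * w / w.sum()
                   * scale_L[i] * size[i] * len_jit[i])
        # diameter profile stretched over the count, largest first
        decay_exp = k * (7.0 / max(n_lat[i], 1))
        lat_diam = t["lat_diam0"] * t["lat_diam_decay"] ** decay_exp \
            * scale_d[i] * diam_f[i]
        lat_ext = (t["lat_extent0"] * t["lat_extent_decay"] ** k
                   * scale_r[i] * extent_f[i]
                   * _lognoise(rng, cv["extent_jitter"] * ns, n_lat[i]))
        nf = t["n_fine"]
        fine_diam = t["fine_diam"] * scale_d[i] * diam_f[i] \
            * _lognoise(rng, cv["fine_diam"] * ns, nf)
        fine_len = t["fine_len"] * scale_L[i] * size[i] \
            * _lognoise(rng, cv["fine_len"] * ns, nf)
        if ns > 0:
            fine_ext = rng.uniform(t["fine_extent_lo"], t["fine_extent_hi"], nf)
        else:
            fine_ext = np.full(nf, 0.5 * (t["fine_extent_lo"]
                                          + t["fine_extent_hi"]))
        fine_ext = fine_ext * scale_r[i] * extent_f[i]

        diam = np.concatenate(([t["tap_diam"] * scale_d[i] * diam_f[i]],
                               lat_diam, fine_diam))
        length = np.concatenate(([t["tap_len"] * scale_L[i] * size[i]
                                  * len_jit[i]], lat_len, fine_len))
        extent = np.concatenate(([t["tap_extent"] * scale_r[i] * extent_f[i]],
                                 lat_ext, fine_ext))
        order = np.concatenate(([0], np.ones(n_lat[i], dtype=int),
                                np.full(nf, 2, dtype=int)))
        pid_out.extend([pid] * len(diam))
        diam_out.append(diam)
        len_out.append(length)
        ext_out.append(extent)
        ord_out.append(order)
    out = pd.DataFrame({
        "plant_id": pid_out,
        "diameter_mm": np.concatenate(diam_out),
        "length_mm": np.concatenate(len_out),
        "radial_extent_cm": np.concatenate(ext_out),
        "branch_order": np.concatenate(ord_out),
    })
    out.insert(1, "segment_id",
               out["plant_id"] + "-s" + out.groupby("plant_id").cumcount().astype(str))
    return out


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def simulate_trial(config: TrialConfig, return_segments: bool = False):
    """Simulate one experiment; returns the plant-level trial table.

    The table has one row per plant (levels x replications x plants per
    plot) with factor labels, stem geometry and masses, mechanical test
    results, soil mechanics, root traits, electrical readings and a
    per-plant seed-yield proxy.  Identical config (including seed) gives an
    identical table.  With ``return_segments=True`` the long-format
    root-segment table is returned as well.
    """
    rng = np.random.default_rng(config.seed)
    ns = config.noise_scale
    cv = config.noise_cv
    base = config.baseline
    link = config.linkage

    factor_names = list(config.factors)
    level_grid = [{}]
    for f in factor_names:
        level_grid = [dict(g, **{f: lv}) for g in level_grid
                      for lv in config.factors[f]]
    cells, reps, plants, ids = [], [], [], []
    for g in level_grid:
        for r in range(1, config.replications + 1):
            for p in range(1, config.plants_per_plot + 1):
                cells.append(g)
                reps.append(r)
                plants.append(p)
                ids.append("_".join([config.experiment]
                                    + [g[f] for f in factor_names]
                                    + [f"r{r}", f"p{p}"]))
    n = len(ids)

    def cell_mult(trait):
        return np.array([config.multiplier(trait, g) for g in cells])

    # (1) root segments -> morphological traits and cone diameter
    segments = simulate_root_segments(config, ids, cells, rng)
    agg = roots.aggregate_by_plant(segments).loc[ids]
    cone_1mm = roots.cone_diameter_by_plant(segments, 1.0).loc[ids].to_numpy()
    cone_half = roots.cone_diameter_by_plant(segments, 0.5).loc[ids].to_numpy()
    area = agg["surface_area_A"].to_numpy()
    volume = agg["volume_V"].to_numpy()
    length_mm = agg["total_length_L"].to_numpy()

    # (4, computed early so the electrical linkage can see it)
    # anchorage strength from the root-soil cone: S_p = K*tau*D^3 + c
    tau = link.tau_mean * _lognoise(rng, cv["tau"] * ns, n)
    x = tau * cone_1mm**3
    if ns > 0 and np.ptp(x) > 0:
        r2 = link.target_r2_tauD3
        var_eps = link.K**2 * x.var() * (1.0 - r2) / r2
        eps = _matched_noise(rng, n, var_eps, [x])
    else:
        eps = np.zeros(n)
    S_p = link.K * x + link.intercept_c + eps

    # (2) capacitance from the condenser model of the drawn root system;
    # measurement noise sized so the pooled C-S_p calibration hits target R^2
    mean_diam_mm = area / (np.pi * length_mm)
    radius_ratio = 1.0 + 2.0 * link.membrane_thickness_mm / mean_diam_mm
    c_phys = (2.0 * np.pi * EPSILON_0 * link.relative_permittivity
              * (length_mm / 1000.0) / np.log(radius_ratio)) * 1e9  # nF
    c_phys = c_phys * link.instrument_coupling
    # residual (non-geometric) treatment effect on the reading
    c0 = c_phys * cell_mult("capacitance") / cell_mult("root_area")
    if ns > 0 and np.ptp(S_p) > 0:
        rho0 = np.corrcoef(c0, S_p)[0, 1] ** 2
        var_e = c0.var() * max(rho0 / link.target_r2_C_Sp - 1.0, 0.0)
        capacitance = c0 + _matched_noise(rng, n, var_e, [c0, S_p])
    else:
        capacitance = c0
    capacitance = np.maximum(capacitance, 1e-3)

    # (3) resistance and impedance: noisy reciprocal-scaled functions of C
    ln_c = np.log(capacitance)
    cell_key = ["|".join(g[f] for f in factor_names) for g in cells]
    ln_c_centred = ln_c - pd.Series(ln_c).groupby(cell_key).transform("mean").to_numpy()
    resistance = (base["resistance"] * cell_mult("resistance")
                  * np.exp(-ln_c_centred)
                  * _lognoise(rng, cv["resistance"] * ns, n))
    impedance = (base["impedance"] * cell_mult("impedance")
                 * np.exp(-ln_c_centred)
                 * _lognoise(rng, cv["impedance"] * ns, n))

    # (5) stem: section modulus from oval diameters, strength from a
    # material bending stress; the configured S_s multiplier enters through
    # the diameter scale (cube root) so SM and S_s stay consistent
    s_stem = np.cbrt(cell_mult("S_s") / cell_mult("BS"))
    a_minor = base["a_minor"] * s_stem * _lognoise(rng, cv["stem_diam"] * ns, n)
    b_major = base["b_major"] * s_stem * _lognoise(rng, cv["stem_diam"] * ns, n)
    b_major = np.maximum(b_major, a_minor)  # oval convention: b >= a
    SM = np.pi / 32.0 * a_minor**2 * b_major
    BS = base["BS"] * cell_mult("BS") * _lognoise(rng, cv["bs"] * ns, n)
    S_s = BS * SM / 1000.0
    F_max = 4.0 * S_s / 0.15

    # masses, heights, carried traits
    m_s = base["m_s"] * cell_mult("m_s") * _lognoise(rng, cv["mass"] * ns, n)
    m_p = base["m_p"] * cell_mult("m_p") * _lognoise(rng, cv["mass"] * ns, n)
    height = base["height_H"] * cell_mult("height_H") \
        * _lognoise(rng, cv["height"] * ns, n)
    h_s = base["h_s"] * cell_mult("height_H") * _lognoise(rng, cv["hcg"] * ns, n)
    h_p = base["h_p"] * cell_mult("height_H") * _lognoise(rng, cv["hcg"] * ns, n)
    h_p = np.minimum(h_p, height)
    frew = base["frew"] * cell_mult("frew") * _lognoise(rng, cv["frew"] * ns, n)
    dryw = base["dryw"] * cell_mult("dryw") * _lognoise(rng, cv["frew"] * ns, n)
    dry_weight = base["dry_weight"] * cell_mult("dry_weight") \
        * _lognoise(rng, cv["dry_weight"] * ns, n)

    # seed yield: positively coupled to anchorage within each cell
    mu_sp_cell = base["S_p"] * cell_mult("S_p")
    seed_yield = (base["seed_yield"] * cell_mult("seed_yield")
                  * (S_p / mu_sp_cell) ** _YIELD_SP_EXPONENT
                  * _lognoise(rng, cv["seed_yield"] * ns, n))

    table = pd.DataFrame({
        "plant_id": ids,
        "experiment": config.experiment,
        **{f: [g[f] for g in cells] for f in factor_names},
        "rep": reps,
        "plant": plants,
        "height_H_m": height,
        "h_s_m": h_s,
        "h_p_m": h_p,
        "m_s_kg": m_s,
        "m_p_kg": m_p,
        "a_minor_mm": a_minor,
        "b_major_mm": b_major,
        "F_max_N": F_max,
        "span_L_m": 0.15,
        "theta_deg": 45.0,
        "S_s_Nm": S_s,
        "S_p_Nm": S_p,
        "tau_N_m2": tau,
        "cone_D_m": cone_1mm,
        "cone_D_05mm_m": cone_half,
        "tauD3_Nm": x,
        "root_length_mm": length_mm,
        "root_area_mm2": area,
        "root_volume_mm3": volume,
        "branch_count": agg["branch_count"].to_numpy(),
        "root_dry_weight_g": dry_weight,
        "capacitance_nF": capacitance,
        "resistance_kOhm": resistance,
        "impedance_kOhm": impedance,
        "frew_g_cm": frew,
        "dryw_g_cm": dryw,
        "seed_yield_g": seed_yield,
    })
    table.attrs["config"] = config.to_dict()
    table.attrs["seed"] = config.seed
    if return_segments:
        return table, segments
    return table


def effect_estimate(table: pd.DataFrame, factor: str, trait: str,
                    treatment: Optional[str] = None,
                    control: Optional[str] = None) -> float:
    """Percent difference of a trait between two factor levels.

    100 * (mean_treatment - mean_control) / mean_control, pooled over all
    other factors.  For a two-level factor the levels are inferred (first
    level observed = control); otherwise name them explicitly.  ``trait``
    may be a friendly name (``"capacitance_C"``) or a column of the table.
    """
    if factor not in table.columns:
        raise InvalidInputError(f"factor {factor!r} not in table")
    col = TRAIT_COLUMNS.get(trait, trait)
    if col not in table.columns:
        raise InvalidInputError(f"trait {trait!r} (column {col!r}) not in table")
    levels = list(dict.fromkeys(table[factor]))
    if control is None:
        control = levels[0]
    if treatment is None:
        others = [lv for lv in levels if lv != control]
        if len(others) != 1:
            raise InvalidInputError(
                f"factor {factor!r} has levels {levels}; name the treatment level")
        treatment = others[0]
    for lv in (control, treatment):
        if lv not in levels:
            raise InvalidInputError(f"level {lv!r} not present for {factor!r}")
    mean_c = table.loc[table[factor] == control, col].mean()
    mean_t = table.loc[table[factor] == treatment, col].mean()
    if mean_c == 0:
        raise InvalidInputError("control mean is zero; percent change undefined")
    return float(100.0 * (mean_t - mean_c) / mean_c)
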