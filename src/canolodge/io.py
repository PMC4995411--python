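"""Trait-table I/O, validation, and the end-to-end pipeline.

CSV conventions: comma-separated, UTF-8, mandatory header, '.' decimal,
units encoded in column names (``F_max_N``, ``h_p_m``, ``capacitance_nF``).
Field sheets recorded in cm/g (``h_p_cm``, ``m_p_g``) are converted to SI
on ingest; the computational core never converts units.

The pipeline chains the full workflow: simulate (or load) a plant-level
trait table, compute the per-plant lodging indices, fit the root-soil
anchorage model S_p ~ K*(tau*D^3) + c, calibrate the electrical predictors
against the lodging indicators, rank them, and write a report bundle
(indices CSV, calibration CSV, anchorage-model JSON, predictor ranking and
a plain-text report carrying the seed and a config digest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__, biomech, electro, trials
from .errors import ConfigError, InvalidInputError

log = logging.getLogger("canolodge")

#: columns that must be present (after unit normalisation) and non-negative
REQUIRED_COLUMNS = (
    "plant_id", "height_H_m", "h_s_m", "h_p_m", "m_s_kg", "m_p_kg",
    "a_minor_mm", "b_major_mm", "F_max_N", "S_p_Nm",
)

#: accepted field-sheet columns -> (canonical SI column, factor)
UNIT_CONVERSIONS = {
    "height_H_cm": ("height_H_m", 0.01),
    "h_s_cm": ("h_s_m", 0.01),
    "h_p_cm": ("h_p_m", 0.01),
    "m_s_g": ("m_s_kg", 0.001),
    "m_p_g": ("m_p_kg", 0.001),
    "span_L_cm": ("span_L_m", 0.01),
    "cone_D_cm": ("cone_D_m", 0.01),
}

DEFAULT_PREDICTORS = ("capacitance_C", "resistance_R", "impedance_Z")
DEFAULT_RESPONSES = ("S_p", "S_s", "SF_p", "SF_s")


def read_trait_table(path) -> pd.DataFrame:
    """Read and validate a plant-level trait table.

    cm/g columns are converted to SI; rows violating the physical
    invariants (negative masses or forces, b_major < a_minor, h_p > H,
    non-numeric cells) are rejected and reported row by row through the
    package logger.  The number of rejected rows is stored in
    ``table.attrs["n_rejected"]``.
    """
    df = pd.read_csv(path)
    for src, (dst, factor) in UNIT_CONVERSIONS.items():
        if src in df.columns:
            if dst in df.columns:
                raise InvalidInputError(
                    f"{path}: both {src!r} and {dst!r} present; ambiguous units")
            df[dst] = pd.to_numeric(df[src], errors="coerce") * factor
            df = df.drop(columns=[src])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing mandatory columns {missing}")

    numeric_cols = set(REQUIRED_COLUMNS[1:]) | {
        "span_L_m", "theta_deg", "S_s_Nm", "tau_N_m2", "cone_D_m",
        "cone_D_05mm_m", "tauD3_Nm", "root_length_mm", "root_area_mm2",
        "root_volume_mm3", "branch_count", "root_dry_weight_g",
        "capacitance_nF", "resistance_kOhm", "impedance_kOhm",
        "frew_g_cm", "dryw_g_cm", "seed_yield_g",
    }
    for c in df.columns:
        if c in numeric_cols:
            df[c] = pd.to_numeric(df[c], errors="coerce")

    bad = pd.Series(False, index=df.index)
    reasons: Dict[int, str] = {}

    def flag(mask, reason):
        for idx in df.index[mask & ~bad]:
            reasons[idx] = reason
        bad.loc[mask] = True

    check_nonneg = [c for c in REQUIRED_COLUMNS[1:] if c in df.columns]
    flag(df[check_nonneg].isna().any(axis=1), "non-numeric or missing value")
    for c in check_nonneg:
        flag(df[c] < 0, f"negative {c}")
    if {"a_minor_mm", "b_major_mm"} <= set(df.columns):
        flag(df["b_major_mm"] < df["a_minor_mm"], "b_major < a_minor")
    if {"h_p_m", "height_H_m"} <= set(df.columns):
        flag(df["h_p_m"] > df["height_H_m"], "h_p exceeds plant height")
    for c in ("root_length_mm", "root_area_mm2", "root_volume_mm3",
              "capacitance_nF", "resistance_kOhm", "impedance_kOhm",
              "cone_D_m", "tau_N_m2"):
        if c in df.columns:
            flag(df[c] < 0, f"negative {c}")

    for idx, why in sorted(reasons.items()):
        log.warning("%s: row %d rejected (%s)", path, idx + 2, why)  # 1-based + header
    out = df.loc[~bad].reset_index(drop=True)
    out.attrs["n_rejected"] = int(bad.sum())
    return out


def write_trait_table(table: pd.DataFrame, path, metadata: Optional[dict] = None) -> Path:
    """Write a trial table as CSV plus a JSON run-metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    meta = {"rows": len(table), "canolodge_version": __version__}
    meta.update(table.attrs or {})
    if metadata:
        meta.update(metadata)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, default=str))
    return path


def indices_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-plant lodging indices for a whole trait table (vectorised).

    Applies the same formulas as :func:`canolodge.biomech.lodging_indices`
    column-wise: S_s, M_s, M_p, SF_s, SF_p, SM and BS for every plant.
    """
    theta = table.get("theta_deg", pd.Series(biomech.DEFAULT_THETA_DEG,
                                             index=table.index))
    span = table.get("span_L_m", pd.Series(biomech.DEFAULT_SPAN_L,
                                           index=table.index))
    S_s = biomech.stem_bending_strength(table["F_max_N"], span)
    M_s = biomech.self_weight_moment(table["m_s_kg"], table["h_s_m"], theta)
    M_p = biomech.self_weight_moment(table["m_p_kg"], table["h_p_m"], theta)
    SM = biomech.section_modulus(table["a_minor_mm"], table["b_major_mm"])
    out = pd.DataFrame({
        "plant_id": table["plant_id"],
        "S_s_Nm": S_s,
        "M_s_Nm": M_s,
        "M_p_Nm": M_p,
        "SF_s": biomech.safety_factor(S_s, M_s),
        "SF_p": biomech.safety_factor(table["S_p_Nm"], M_p),
        "SM_mm3": SM,
        "BS_N_mm2": biomech.bending_stress(S_s, SM),
    })
    return out


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    experiment: str = "exp1"
    input_table: Optional[Path] = None  # if None, simulate
    seed: int = 0
    cone_threshold_mm: float = 1.0
    predictors: Sequence[str] = DEFAULT_PREDICTORS
    responses: Sequence[str] = DEFAULT_RESPONSES

    def __post_init__(self) -> None:
        if self.cone_threshold_mm <= 0:
            raise ConfigError("cone_threshold_mm must be > 0")
        if self.input_table is not None and not Path(self.input_table).exists():
            raise ConfigError(f"input table not found: {self.input_table}")


def _column_for(table: pd.DataFrame, name: str) -> pd.Series:
    col = trials.TRAIT_COLUMNS.get(name, name)
    alias = {"SF_p": "SF_p", "SF_s": "SF_s"}
    col = alias.get(name, col)
    if col not in table.columns:
        raise ConfigError(f"unknown predictor/response {name!r} "
                          f"(no column {col!r})")
    return table[col]


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> indices -> anchorage fit -> calibrate -> rank -> report.

    Returns a dict with the in-memory results and the paths written.  Any
    stage failure raises; the CLI maps stages to exit codes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_table is None:
        log.info("simulating %s (seed %d)", config.experiment, config.seed)
        trial_cfg = trials.default_config(config.experiment, seed=config.seed)
        table = trials.simulate_trial(trial_cfg)
        cfg_echo = trial_cfg.to_dict()
    else:
        log.info("reading %s", config.input_table)
        table = read_trait_table(config.input_table)
        cfg_echo = {"input_table": str(config.input_table)}
    table_path = write_trait_table(table, out / "trait_table.csv",
                                   {"seed": config.seed})

    log.info("computing lodging indices for %d plants", len(table))
    indices = indices_table(table)
    merged = table.merge(indices.drop(columns=["S_s_Nm"], errors="ignore"),
                         on="plant_id")
    indices.to_csv(out / "lodging_indices.csv", index=False)

    # anchorage model: S_p on tau*D^3
    anchorage = None
    if {"tau_N_m2", "cone_D_m"} <= set(table.columns):
        x = table["tau_N_m2"].to_numpy() * table["cone_D_m"].to_numpy() ** 3
        anchorage = biomech.fit_anchorage_model(
            np.column_stack([x, table["S_p_Nm"].to_numpy()]))
        (out / "anchorage_model.json").write_text(json.dumps(
            dataclasses.asdict(anchorage), indent=2))
        log.info("anchorage fit: K=%.3f c=%.3f R2=%.3f",
                 anchorage.K, anchorage.intercept_c, anchorage.r_squared)

    # electrical -> mechanical calibrations
    fits = []
    rows = []
    for response in config.responses:
        y = _column_for(merged, response).to_numpy(dtype=float)
        per_response = []
        for pred in config.predictors:
            xcol = _column_for(merged, pred).to_numpy(dtype=float)
            fit = electro.linear_calibration(xcol, y, predictor_name=pred)
            per_response.append(fit)
            rows.append({"predictor": pred, "response": response,
                         "slope": fit.slope, "intercept": fit.intercept,
                         "r_squared": fit.r_squared, "p_value": fit.p_value,
                         "n": fit.n})
        fits.append((response, electro.rank_predictors(per_response)))
    calib = pd.DataFrame(rows)
    calib.to_csv(out / "calibrations.csv", index=False)

    ranking = {resp: [f.predictor_name for f in ranked]
               for resp, ranked in fits}
    (out / "predictor_ranking.json").write_text(json.dumps(ranking, indent=2))

    digest = hashlib.sha256(
        json.dumps(cfg_echo, sort_keys=True, default=str).encode()).hexdigest()[:16]
    report = [
        f"canolodge {__version__} pipeline report",
        f"experiment: {config.experiment}",
        f"seed: {config.seed}",
        f"config digest: {digest}",
        f"plants: {len(table)} (rejected on ingest: "
        f"{table.attrs.get('n_rejected', 0)})",
        "",
    ]
    if anchorage is not None:
        report.append(
            f"anchorage model: S_p = {anchorage.K:.3f} * tauD3 "
            f"+ {anchorage.intercept_c:.3f}  (R2 = {anchorage.r_squared:.3f}, "
            f"n = {anchorage.n})")
    for resp, ranked in fits:
        top = ranked[0]
        report.append(
            f"best predictor of {resp}: {top.predictor_name} "
            f"(R2 = {top.r_squared:.3f}, p = {top.p_value:.2e})")
    (out / "report.txt").write_text("\n".join(report) + "\n")

    return {"table": table, "table_path": table_path, "indices": indices,
            "anchorage": anchorage, "calibrations": calib,
            "ranking": ranking, "report_path": out / "report.txt",
            "config_digest": digest}
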