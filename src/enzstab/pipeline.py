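"""End-to-end stability analysis: measurement table → thermodynamic table.

Glue between the study-design, deactivation and reporting layers.  The
input is a measurement table in the schema the synthetic generator emits
(batch, temperature_K, vial_id, month, activity_UL); the output bundles
per-temperature isotherm fits, the Arrhenius fit across them, and the
thermodynamic record per temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design
from .constants import LITERATURE, PhysicalConstants
from .deactivation import (
    ArrheniusFit,
    IsothermFit,
    KdUnitMode,
    ThermoRecord,
    arrhenius_fit,
    fit_kd,
    thermo_table,
)

__all__ = ["StabilityResult", "monthly_summary", "fit_stability_study", "thermo_frame"]

log = logging.getLogger(__name__)


@dataclass
class StabilityResult:
    isotherms: list[IsothermFit]
    arrhenius: ArrheniusFit | None
    thermo: list[ThermoRecord]
    summary: pd.DataFrame          # per (temperature, month) stratified mean ± CI


def monthly_summary(df: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Stratified mean ± CI half-width per (temperature, month).

    Batches are the strata; stratum sizes are the vial counts present in
    the table (the generator emits the whole population, so the sample is
    exhaustive and the fpc zeroes the CI — subsampled tables get honest
    half-widths).
    """
    rows = []
    for (T, month), grp in df.groupby(["temperature_K", "month"]):
        strata = [g["activity_UL"].to_numpy() for _, g in grp.groupby("batch")]
        sizes = [len(s) for s in strata]
        est = design.stratified_mean_ci(strata, sizes, confidence)
        rows.append((T, month, est.mean, est.ci_halfwidth, sum(sizes)))
    return pd.DataFrame(rows, columns=["temperature_K", "month", "mean_activity_UL",
                                       "ci_halfwidth_UL", "n"])


def fit_stability_study(
    df: pd.DataFrame,
    initial_activity: float,
    apply_stop_rule: bool = True,
    stop_threshold: float = 25.0,
    confidence: float = 0.95,
    constants: PhysicalConstants = LITERATURE,
    kd_unit_mode: KdUnitMode = "paper-months",
    through_origin: bool = False,
) -> StabilityResult:
    """Fit the full accelerated-stability model to a measurement table.

    Per temperature, the sampling stop rule is evaluated on the stratified
    mean relative-activity trace (sampling would have ceased once ~75% of
    the activity was lost), the retained vial-level records are fitted for
    k_d, and the positive-k_d isotherms feed the Arrhenius regression.
    Vials whose measured activity is non-positive (noise-truncated) are
    excluded from the log fit.
    """
    summary = monthly_summary(df, confidence)
    isotherms: list[IsothermFit] = []
    for T, sub in df.groupby("temperature_K"):
        sum_T = summary[summary["temperature_K"] == T].sort_values("month")
        months = sum_T["month"].tolist()
        if apply_stop_rule:
            rel = (100.0 * sum_T["mean_activity_UL"] / initial_activity).tolist()
            kept = design.apply_stop_rule(rel, months, threshold=stop_threshold)
        else:
            kept = months
        data = sub[sub["month"].isin(kept) & (sub["activity_UL"] > 0)]
        n_dropped = int((sub["month"].isin(kept) & (sub["activity_UL"] <= 0)).sum())
        if n_dropped:
            log.info("%.2f K: dropped %d non-positive activities from the log fit",
                     T, n_dropped)
        iso = fit_kd(data["month"].to_numpy(), data["activity_UL"].to_numpy(),
                     initial_activity, through_origin=through_origin, temperature=float(T))
        isotherms.append(iso)

    positive = [i for i in isotherms if i.k_d > 0]
    arr = arrhenius_fit(positive, constants) if len(positive) >= 3 else None
    if arr is None:
        log.warning("fewer than 3 positive-k_d isotherms: no Arrhenius fit")
    thermo = thermo_table(positive, arr, constants, kd_unit_mode)
    return StabilityResult(isotherms=isotherms, arrhenius=arr,
                           thermo=thermo, summary=summary)


def thermo_frame(result: StabilityResult) -> pd.DataFrame:
    """Thermodynamic table as a DataFrame in the report column schema."""
    iso_by_T = {i.temperature: i for i in result.isotherms}
    rows = []
    for rec in result.thermo:
        iso = iso_by_T.get(rec.temperature)
        rows.append({
            "temperature_K": rec.temperature,
            "kd_per_month": rec.k_d,
            "t_half_months": rec.t_half,
            "dH_kJ_mol": rec.dH,
            "dG_kJ_mol": rec.dG,
            "dS_J_mol_K": rec.dS,
            "r_squared": iso.r_squared if iso else np.nan,
            "n_points": iso.n_points if iso else 0,
        })
    return pd.DataFrame(rows)
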