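"""Descriptive layer: county rates, cross-phenotype correlation, decile
profiles of putative predictors, and the patient-level comorbidity odds
ratio."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import IncidencePanel, PatientTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "RateTable",
    "DecileProfile",
    "county_rates",
    "rate_correlation",
    "decile_profile",
    "comorbidity_or",
]


@dataclass
class RateTable:
    """Per-(county, disease, gender) incidence proportions plus summaries.

    ``rates`` has columns county_id, disease, gender, rate (a proportion;
    multiply by 100 for percent).  ``summary`` holds unweighted mean /
    median / max over counties per disease x gender cell.
    """

    rates: pd.DataFrame
    summary: pd.DataFrame


@dataclass
class DecileProfile:
    """Mean outcome rate within predictor deciles.

    ``bins``: bin index 1..10, predictor range, mean outcome rate, county
    count; counts partition the counties.
    """

    predictor: str
    bins: pd.DataFrame
    merged_bins: bool = False


def county_rates(panel: IncidencePanel) -> RateTable:
    """Exact y/N proportions; zero-offset rows are excluded with a warning."""
    df = panel.data.copy()
    zero = df["N"] <= 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero-offset row(s) from rates",
                      stacklevel=2)
        df = df.loc[~zero]
    df["rate"] = df["y"] / df["N"]
    summary = (
        df.groupby(["disease", "gender"], sort=True)["rate"]
        .agg(mean="mean", median="median", max="max", n_counties="size")
        .reset_index()
    )
    return RateTable(rates=df[["county_id", "disease", "gender", "rate"]],
                     summary=summary)


def rate_correlation(rates_a, rates_b) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValidationError("need two equal-length vectors with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def decile_profile(predictor, outcome, name: str = "predictor",
                   county_ids=None) -> DecileProfile:
    """Rank counties by a predictor and average the outcome within deciles.

    Counties are ranked by predictor value (ties broken by stable county-id
    order) and split into 10 equal-count bins at the empirical decile
    cut-points.  If massive ties would leave a bin without its own
    predictor range, adjacent bins are merged and the profile flagged.
    """
    x = np.asarray(predictor, dtype=float)
    yv = np.asarray(outcome, dtype=float)
    if len(x) != len(yv):
        raise ValidationError("predictor and outcome lengths differ")
    n = len(x)
    if n < 10:
        raise ValidationError("need at least 10 counties for a decile profile")
    ids = np.asarray(county_ids) if county_ids is not None else np.arange(n)
    order = np.lexsort((ids, x))  # stable: predictor, then county id
    edges = np.linspace(0, n, 11).round().astype(int)

    rows = []
    merged = False
    start = 0
    for i in range(10):
        stop = edges[i + 1]
        if stop <= start:
            merged = True
            continue
        sel = order[start:stop]
        rows.append({
            "bin": i + 1,
            "pred_min": x[sel].min(),
            "pred_max": x[sel].max(),
            "mean_outcome": yv[sel].mean(),
            "n_counties": len(sel),
        })
        start = stop
    if merged:
        logger.warning("decile_profile(%s): empty bins merged", name)
    bins = pd.DataFrame(rows)
    assert int(bins["n_counties"].sum()) == n
    return DecileProfile(predictor=name, bins=bins, merged_bins=merged)


def comorbidity_or(
    patients: PatientTable,
    exposure_flag: str = "flag_ConGen",
    outcome_flag: str = "flag_ASD",
    stratum: dict | None = None,
    ci_method: str = "normal",
    alpha: float = 0.05,
) -> dict:
    """Cross-product odds ratio with Fisher's exact two-sided p-value.

    ``stratum`` filters rows first (e.g. ``{"gender": "M"}``).  The CI is a
    normal approximation on the log odds ratio by default;
    ``ci_method="exact"`` gives the conditional-ML interval.  Returns a dict
    with the 2x2 table, odds_ratio, p_value, ci and the method used.
    """
    df = patients.data
    for col, val in (stratum or {}).items():
        df = df[df[col] == val]
    e = df[exposure_flag].to_numpy(bool)
    o = df[outcome_flag].to_numpy(bool)
    a = int(np.sum(e & o))
    b = int(np.sum(e & ~o))
    c = int(np.sum(~e & o))
    d = int(np.sum(~e & ~o))
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("empty margin in 2x2 table; odds ratio undefined")

    continuity_note = None
    if (table == 0).any():
        continuity_note = "zero cell: odds ratio computed with 0.5 continuity correction"
        at, bt, ct, dt = (v + 0.5 for v in (a, b, c, d))
    else:
        at, bt, ct, dt = a, b, c, d
    or_hat = (at * dt) / (bt * ct)
    _, p = stats.fisher_exact(table, alternative="two-sided")

    z = stats.norm.ppf(1 - alpha / 2)
    if ci_method == "normal":
        se = np.sqrt(1 / at + 1 / bt + 1 / ct + 1 / dt)
        ci = (float(np.exp(np.log(or_hat) - z * se)),
              float(np.exp(np.log(or_hat) + z * se)))
    elif ci_method == "exact":
        res = stats.contingency.odds_ratio(table, kind="conditional")
        ci_obj = res.confidence_interval(confidence_level=1 - alpha)
        ci = (float(ci_obj.low), float(ci_obj.high))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return {
        "table": table,
        "odds_ratio": float(or_hat),
        "p_value": float(p),
        "ci": ci,
        "ci_method": ci_method,
        "continuity_note": continuity_note,
    }
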