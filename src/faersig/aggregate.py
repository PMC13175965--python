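"""Cumulative signal metrics, death proportions, and cross-drug overlap.

The cumulative metrics C-ROR025, C-IC025 and C-EBGM05 sum a term's
lower-bound statistic over exactly the drugs flagged positive by the
corresponding method — drugs with a negative signal contribute nothing.
They rank terms by total signal intensity across the drug class.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from faersig.cleaning import CaseData
from faersig.meddra import Hierarchy, roll_up

__all__ = [
    "METRICS",
    "CumulativeSignal",
    "OverlapSummary",
    "cumulative_metric",
    "death_proportion",
    "overlap_analysis",
    "share_of_total",
]

#: metric name -> (lower-bound column, positivity flag column)
METRICS = {
    "C-ROR025": ("ror_lo", "ror_pos"),
    "C-IC025": ("ic_lo", "bcpnn_pos"),
    "C-EBGM05": ("ebgm_lo", "mgps_pos"),
}


@dataclass(frozen=True)
class CumulativeSignal:
    term: str
    level: str
    metric_name: str
    value: float
    n_drugs_positive: int


@dataclass
class OverlapSummary:
    """Strong-signal PT sets per drug and their overlap structure."""

    per_drug: dict[str, set[str]]
    shared: set[str]  # strong in >= 2 drugs
    unique: dict[str, set[str]]  # strong in exactly this one drug
    total_distinct: int


def cumulative_metric(
    results: pd.DataFrame, metric: str, level: str | None = None
) -> pd.DataFrame:
    """Per-term cumulative lower-bound sums over positive-flagged drugs.

    Returns a DataFrame (term, level, metric, value, n_drugs_positive)
    ranked by descending value (ties broken by term name); terms with no
    positive drug are excluded.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {list(METRICS)}")
    col, flag = METRICS[metric]
    sub = results
    if level is not None:
        sub = sub[sub["level"] == level]
    pos = sub[sub[flag].astype(bool)]
    grouped = pos.groupby("term").agg(
        value=(col, "sum"), n_drugs_positive=(col, "size")
    )
    out = grouped.reset_index()
    out["level"] = level if level is not None else (
        sub["level"].iloc[0] if len(sub) else ""
    )
    out["metric"] = metric
    out = out.sort_values(
        ["value", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out[["term", "level", "metric", "value", "n_drugs_positive"]]


def death_proportion(
    data: CaseData,
    hierarchy: Hierarchy | None = None,
    level: str = "SOC",
    scope: str = "narrow",
) -> tuple[pd.DataFrame, float]:
    """Per-term and overall fractions of reports with a death (DE) outcome.

    A report counts toward a term's denominator if any of its PTs map there;
    its numerator contribution is 1 if DE appears among its outcome codes.
    Terms with zero mapped reports are never emitted.  Returns (per-term
    frame with columns term, n_reports, n_deaths, death_fraction; overall
    fraction over all reports in ``data``).
    """
    deaths = set(
        data.outcomes.loc[
            data.outcomes["outc_cod"].astype("string").str.strip().str.upper() == "DE",
            "primaryid",
        ].astype(str)
    )
    if hierarchy is None or level == "PT":
        terms = (
            data.reactions[["primaryid", "pt"]]
            .astype(str)
            .drop_duplicates()
            .rename(columns={"pt": "term"})
        )
    else:
        terms = roll_up(data.reactions, hierarchy, level=level, scope=scope)
    terms = terms.assign(death=terms["primaryid"].astype(str).isin(deaths))
    per_term = (
        terms.groupby("term")
        .agg(n_reports=("primaryid", "nunique"), n_deaths=("death", "sum"))
        .reset_index()
    )
    per_term["death_fraction"] = per_term["n_deaths"] / per_term["n_reports"]
    per_term = per_term.sort_values(
        ["death_fraction", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    overall = len(deaths & set(data.cases["primaryid"].astype(str))) / data.n_cases
    return per_term, overall


def overlap_analysis(
    results: pd.DataFrame, band_threshold: str = "strong"
) -> OverlapSummary:
    """Cross-drug overlap of strong (by default) PT-level signals.

    ``shared`` collects terms strong in at least two drugs; ``unique`` the
    terms strong in exactly one.
    """
    order = ["weak", "moderate", "strong"]
    if band_threshold not in order:
        raise ValueError(f"band_threshold must be one of {order}")
    keep_bands = set(order[order.index(band_threshold):])
    strong = results[results["band"].isin(keep_bands)]
    per_drug = {
        drug: set(grp["term"]) for drug, grp in strong.groupby("drug")
    }
    all_terms = set().union(*per_drug.values()) if per_drug else set()
    counts = {t: sum(t in s for s in per_drug.values()) for t in all_terms}
    shared = {t for t, k in counts.items() if k >= 2}
    unique = {
        drug: {t for t in terms if counts[t] == 1} for drug, terms in per_drug.items()
    }
    return OverlapSummary(
        per_drug=per_drug,
        shared=shared,
        unique=unique,
        total_distinct=len(all_terms),
    )


def share_of_total(component_value: float, total_value: float) -> float:
    """Percentage 100 * component / total, rounded half-up to 2 decimals."""
    if not total_value > 0:
        raise ValueError("total_value must be positive")
    pct = Decimal(100) * Decimal(str(component_value)) / Decimal(str(total_value))
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def ratio(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Plain ratio rounded half-up, e.g. adverse events per case."""
    if not denominator > 0:
        raise ValueError("denominator must be positive")
    q = Decimal(str(numerator)) / Decimal(str(denominator))
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))
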