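"""Reporting-characteristics summaries: demographics, onset, outcomes.

Time to onset is the day difference between the event onset date and the
start of therapy with the annotated primary-suspect drug, computed only when
both dates are day-precise, and binned into 30-day "months".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from faersig.aggregate import share_of_total
from faersig.cleaning import CaseData
from faersig.io import date_to_timestamp

__all__ = [
    "time_to_onset",
    "demographic_summary",
    "load_country_continent",
    "default_country_continent",
]

#: outcome codes marking a serious case (death included)
SERIOUS_OUTCOMES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


def load_country_continent(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["country"], df["continent"]))


def default_country_continent() -> dict[str, str]:
    return load_country_continent(
        Path(__file__).parent / "data" / "country_continent.tsv"
    )


def time_to_onset(
    data: CaseData, within_days: int = 90, synonyms: dict[str, str] | None = None
) -> dict:
    """Per-report onset intervals for the annotated primary-suspect drug.

    The therapy start is the earliest day-precise start date among the PS
    rows of the annotated drug; the event date comes from the case record.
    Intervals are computable only when both dates are day-precise and the
    event does not precede the start (negative differences are dropped and
    counted).

    Returns a dict with ``records`` (drug, primaryid, onset_days,
    onset_month_bin), ``median_days`` per drug, ``fraction_within`` (onset
    < ``within_days`` among computable records), ``n_computable`` and
    ``n_negative_dropped``.
    """
    if data.annotations is None:
        raise ValueError("time_to_onset requires primary-suspect annotations")
    drugs = data.drugs.copy()
    role = drugs["role_cod"].astype("string").str.strip().str.upper()
    name = drugs["drugname"].astype("string").str.strip().str.upper()
    ps = drugs[role == "PS"].copy()
    ps["start"] = date_to_timestamp(ps["therapy_start"], "day")
    ps["drugname_uc"] = name[ps.index]

    ann = data.annotations.astype({"primaryid": str}).copy()
    ps = ps.astype({"primaryid": str}).merge(ann, on="primaryid")
    if synonyms is None:
        from faersig.cleaning import default_ici_synonyms

        synonyms = default_ici_synonyms()
    # a multi-target case joins every annotated drug to every PS row of the
    # case; restrict each annotation to PS rows whose name maps to that drug
    canon = ps["drugname_uc"].map({k.upper(): v for k, v in synonyms.items()})
    ps = ps[canon.isna() | (canon == ps["drug"])]

    starts = (
        ps.groupby(["primaryid", "drug"])["start"].min().rename("therapy_start")
    ).reset_index()

    cases = data.cases.astype({"primaryid": str})[["primaryid", "event_dt"]].copy()
    cases["event"] = date_to_timestamp(cases["event_dt"], "day")
    rec = starts.merge(cases[["primaryid", "event"]], on="primaryid")
    rec = rec[rec["therapy_start"].notna() & rec["event"].notna()]
    delta = (rec["event"] - rec["therapy_start"]).dt.days
    n_negative = int((delta < 0).sum())
    rec = rec[delta >= 0].copy()
    rec["onset_days"] = delta[delta >= 0].astype(int)
    rec["onset_month_bin"] = rec["onset_days"] // 30
    records = rec[["drug", "primaryid", "onset_days", "onset_month_bin"]].reset_index(
        drop=True
    )
    medians = records.groupby("drug")["onset_days"].median()
    frac = (
        float((records["onset_days"] < within_days).mean()) if len(records) else np.nan
    )
    return {
        "records": records,
        "median_days": medians,
        "fraction_within": frac,
        "within_days": within_days,
        "n_computable": int(len(records)),
        "n_negative_dropped": n_negative,
    }


def _partition_summary(labels: pd.Series, total: int) -> pd.DataFrame:
    counts = labels.value_counts(dropna=False)
    df = counts.rename_axis("category").rename("count").reset_index()
    df["category"] = df["category"].astype(str)
    df["percent"] = [share_of_total(int(k), total) for k in df["count"]]
    return df.sort_values("count", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def demographic_summary(
    data: CaseData, country_continent: dict[str, str] | None = None
) -> dict[str, pd.DataFrame]:
    """Counts and percentages by sex, age band, year, continent, occupation,
    outcome and report type.

    Every dimension except ``outcome`` is an exhaustive partition of the
    cases (missing values form their own ``missing`` category), so its
    percentages sum to 100 up to rounding.  ``outcome`` rows are the
    non-exclusive shares of each outcome code plus ``serious`` (any outcome
    code present) and are not a partition.
    """
    cases = data.cases
    n = len(cases)
    if n == 0:
        raise ValueError("no cases to summarise")
    if country_continent is None:
        country_continent = default_country_continent()

    sex = cases["sex"].astype("string").str.strip().str.upper()
    sex = sex.where(sex.isin(["M", "F"]), pd.NA).fillna("missing")

    age = pd.to_numeric(cases["age_years"], errors="coerce")
    age_band = pd.Series(
        np.where(age.isna(), "missing", np.where(age > 65, ">65", "<=65")),
        index=cases.index,
    )

    year = cases["fda_dt"].astype("string").str.slice(0, 4).fillna("missing")

    country = cases["reporter_country"].astype("string").str.strip().str.upper()
    continent = country.map(country_continent).fillna("missing").astype(str)

    occ = (
        cases["occp_cod"].astype("string").str.strip().str.upper().fillna("missing")
    )
    rept = (
        cases["rept_cod"].astype("string").str.strip().str.upper().fillna("missing")
    )

    out = {
        "sex": _partition_summary(sex, n),
        "age_band": _partition_summary(age_band, n),
        "year": _partition_summary(year, n),
        "continent": _partition_summary(continent, n),
        "occupation": _partition_summary(occ, n),
        "report_type": _partition_summary(rept, n),
    }

    oc = data.outcomes.copy()
    oc["outc_cod"] = oc["outc_cod"].astype("string").str.strip().str.upper()
    oc["primaryid"] = oc["primaryid"].astype(str)
    rows = []
    for code in sorted(SERIOUS_OUTCOMES):
        k = oc.loc[oc["outc_cod"] == code, "primaryid"].nunique()
        rows.append({"category": code, "count": int(k), "percent": share_of_total(k, n)})
    n_serious = oc.loc[oc["outc_cod"].isin(SERIOUS_OUTCOMES), "primaryid"].nunique()
    rows.append(
        {
            "category": "serious",
            "count": int(n_serious),
            "percent": share_of_total(n_serious, n),
        }
    )
    out["outcome"] = pd.DataFrame(rows)
    return out
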