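"""Case-level cleaning: deduplication, reporter filtering, suspect selection.

Spontaneous reports arrive in versions: the same CASEID may appear in several
quarters under different PRIMARYIDs as the case is amended.  The cleaning
convention is to keep, per CASEID, the version with the latest report date
(FDA_DT) and, among ties, the largest PRIMARYID; cases on the FDA deletion
lists are removed entirely.  Reports filed by non-health-professionals
(consumers, lawyers, unknown occupation) are then excluded, and finally the
analysis set is restricted to reports naming one of the target drugs as the
primary suspect (role code PS).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from faersig.io import RawRecordSet, age_to_years

__all__ = [
    "CaseData",
    "DEFAULT_EXCLUDED_OCCUPATIONS",
    "PROFESSIONAL_OCCUPATIONS",
    "deduplicate",
    "filter_reporters",
    "select_primary_suspect",
    "load_synonyms",
    "default_ici_synonyms",
]

#: reporter occupation codes retained by default (health professionals)
PROFESSIONAL_OCCUPATIONS = frozenset({"MD", "PH", "OT", "HP"})
#: codes excluded by default: consumers, lawyers (missing is always excluded
#: unless ``excluded_codes`` is empty)
DEFAULT_EXCLUDED_OCCUPATIONS = frozenset({"CN", "LW"})


@dataclass
class CaseData:
    """Deduplicated case reports plus their child rows.

    ``cases`` has one row per surviving case: primaryid, caseid, fda_dt,
    event_dt, sex, age_years, occp_cod, reporter_country, rept_cod.
    ``drugs``/``reactions``/``outcomes`` carry the child rows of surviving
    primaryids only.  ``annotations`` (primaryid, drug) is set by
    :func:`select_primary_suspect` and may assign one report to several
    canonical target drugs.
    """

    cases: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    annotations: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def subset(self, primaryids: pd.Series | pd.Index) -> "CaseData":
        keep = set(primaryids.astype(str))
        sel = lambda df: df[df["primaryid"].astype(str).isin(keep)].reset_index(drop=True)
        ann = None if self.annotations is None else sel(self.annotations)
        return CaseData(
            cases=sel(self.cases),
            drugs=sel(self.drugs),
            reactions=sel(self.reactions),
            outcomes=sel(self.outcomes),
            annotations=ann,
            meta=dict(self.meta),
        )


def _primaryid_sort_key(pid: pd.Series) -> pd.Series:
    # numeric ids compare numerically and above any non-numeric id;
    # non-numeric ids fall back to lexicographic order among themselves
    return pd.to_numeric(pid, errors="coerce").fillna(-1.0)


def deduplicate(records: RawRecordSet, deletions: set[str] | None = None) -> CaseData:
    """Collapse versioned reports to one per CASEID and attach child rows.

    Survivor choice per CASEID: maximum FDA_DT; ties broken by maximum
    PRIMARYID (numeric when parseable, else lexicographic).  CASEIDs present
    in ``deletions`` are removed outright.  Idempotent: re-running on its own
    output changes nothing.
    """
    demo = records.demo
    if demo.empty:
        raise ValueError("demo table is empty; nothing to deduplicate")
    deletions = deletions or set()

    d = demo.copy()
    d["_fda"] = pd.to_numeric(d["fda_dt"], errors="coerce")
    d["_pidnum"] = _primaryid_sort_key(d["primaryid"].astype(str))
    d["_pid"] = d["primaryid"].astype(str)
    d = d.sort_values(
        ["caseid", "_fda", "_pidnum", "_pid"], kind="mergesort"
    )
    survivors = d.groupby("caseid", sort=False).tail(1)
    survivors = survivors[~survivors["caseid"].astype(str).isin(deletions)]
    survivors = survivors.drop(columns=["_fda", "_pidnum", "_pid"]).reset_index(drop=True)

    cases = pd.DataFrame(
        {
            "primaryid": survivors["primaryid"].astype(str),
            "caseid": survivors["caseid"].astype(str),
            "fda_dt": survivors["fda_dt"],
            "event_dt": survivors.get("event_dt"),
            "sex": survivors.get("sex"),
            "age_years": age_to_years(
                survivors.get("age"), survivors.get("age_cod")
            ).to_numpy(),
            "occp_cod": survivors.get("occp_cod"),
            "reporter_country": survivors.get("reporter_country"),
            "rept_cod": survivors.get("rept_cod"),
        }
    )
    keep = set(cases["primaryid"])
    attach = lambda df: df[df["primaryid"].astype(str).isin(keep)].reset_index(drop=True)

    drugs = attach(records.drug).copy()
    # carry therapy start dates onto drug rows when a THER table is present
    if not records.ther.empty:
        ther = records.ther.copy()
        ther["dsg_drug_seq"] = ther["dsg_drug_seq"].astype(str)
        drugs["drug_seq"] = drugs["drug_seq"].astype(str)
        drugs = drugs.merge(
            ther.rename(columns={"dsg_drug_seq": "drug_seq", "start_dt": "therapy_start"})[
                ["primaryid", "drug_seq", "therapy_start"]
            ],
            on=["primaryid", "drug_seq"],
            how="left",
        )
    elif "therapy_start" not in drugs.columns:
        drugs["therapy_start"] = pd.NA

    return CaseData(
        cases=cases,
        drugs=drugs,
        reactions=attach(records.reac),
        outcomes=attach(records.outc),
        meta={"n_deleted": len(deletions & set(demo["caseid"].astype(str)))},
    )


def filter_reporters(
    data: CaseData,
    excluded_codes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_OCCUPATIONS,
) -> CaseData:
    """Drop reports filed by excluded reporter occupations.

    With the default exclusion set, consumer (CN) and lawyer (LW) reports and
    reports with a missing/unknown occupation are removed, leaving the
    health-professional codes MD, PH, OT and HP.  An empty exclusion set is
    the identity (nothing, not even missing, is dropped).
    """
    occ = data.cases["occp_cod"].astype("string").str.strip().str.upper()
    if not excluded_codes:
        return data
    keep = occ.notna() & (occ != "") & ~occ.isin({c.upper() for c in excluded_codes})
    out = data.subset(data.cases.loc[keep, "primaryid"])
    out.meta["n_reporter_excluded"] = int((~keep).sum())
    return out


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Load a drug-name synonym table (TSV: variant <tab> canonical)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header and [h.strip().lower() for h in header[:2]] != ["variant", "canonical"]:
            # header-less file: first line is data
            mapping[header[0].strip().upper()] = header[1].strip()
        for row in reader:
            if len(row) >= 2 and row[0].strip():
                mapping[row[0].strip().upper()] = row[1].strip()
    return mapping


def default_ici_synonyms() -> dict[str, str]:
    """The bundled synonym table for the eight immune checkpoint inhibitors."""
    return load_synonyms(Path(__file__).parent / "data" / "ici_synonyms.tsv")


def select_primary_suspect(
    data: CaseData, target_drugs: dict[str, str]
) -> CaseData:
    """Keep reports with a primary-suspect (PS) drug matching a target.

    Matching is exact on upper-cased, whitespace-trimmed names against the
    ``variant -> canonical`` mapping.  A report whose PS rows match several
    canonical drugs is kept once but annotated with each (it contributes one
    case to each matched drug's analysis).
    """
    if not target_drugs:
        raise ValueError("target_drugs mapping is empty")
    mapping = {k.strip().upper(): v for k, v in target_drugs.items()}
    drugs = data.drugs
    role = drugs["role_cod"].astype("string").str.strip().str.upper()
    name = drugs["drugname"].astype("string").str.strip().str.upper()
    hit = drugs.loc[(role == "PS") & name.isin(mapping), ["primaryid"]].copy()
    hit["drug"] = name[hit.index].map(mapping)
    annotations = (
        hit.astype({"primaryid": str})
        .drop_duplicates()
        .sort_values(["primaryid", "drug"])
        .reset_index(drop=True)
    )
    out = data.subset(annotations["primaryid"])
    out.annotations = annotations
    out.meta["n_target_cases"] = out.n_cases
    return out
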