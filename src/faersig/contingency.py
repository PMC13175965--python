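"""2x2 contingency tables of (drug, term) pairs against the background.

For a target drug D and a term T at some level, with N cleaned background
reports:

    a = reports with D and T        b = reports with D, without T
    c = reports with T, without D   d = reports with neither

and the expected count under independence E = (a+b)(a+c)/N.  Counting is at
the report level throughout (a report contributes 0 or 1 to each cell), and
the background is the full cleaned professional-reporter database, including
the other target drugs' reports.
"""

from __future__ import annotations

import pandas as pd

from faersig.cleaning import CaseData
from faersig.meddra import Hierarchy, roll_up

__all__ = ["build_tables"]


def build_tables(
    background: CaseData,
    annotations: pd.DataFrame | None = None,
    hierarchy: Hierarchy | None = None,
    level: str = "PT",
    scope: str = "narrow",
    min_a: int = 1,
    smq_include: set[str] | None = None,
) -> pd.DataFrame:
    """Build all (drug, term) 2x2 tables with a >= ``min_a``.

    Parameters
    ----------
    background
        The post-deduplication, post-reporter-filter case set; its reactions
        define the term marginals and its size is N.
    annotations
        (primaryid, drug) target-drug annotations (defaults to
        ``background.annotations``); a report annotated to several drugs
        counts once in each drug's margin.
    hierarchy, level, scope
        Passed to :func:`faersig.meddra.roll_up`.

    Returns a long-format DataFrame with columns drug, level, term,
    a, b, c, d, n, e.
    """
    if annotations is None:
        annotations = background.annotations
    if annotations is None or annotations.empty:
        raise ValueError("no target-drug annotations supplied")
    if hierarchy is None and level != "PT":
        raise ValueError("a hierarchy is required for SMQ/SOC roll-up")
    if hierarchy is None:
        terms = (
            background.reactions[["primaryid", "pt"]]
            .astype(str)
            .drop_duplicates()
            .rename(columns={"pt": "term"})
        )
    else:
        terms = roll_up(
            background.reactions, hierarchy, level=level, scope=scope,
            smq_include=smq_include,
        )

    n_total = background.n_cases
    ann = annotations[["primaryid", "drug"]].astype(str).drop_duplicates()
    drug_margin = ann.groupby("drug")["primaryid"].nunique()
    term_margin = terms.groupby("term")["primaryid"].nunique()

    joint = (
        ann.merge(terms, on="primaryid")
        .groupby(["drug", "term"])["primaryid"]
        .nunique()
        .rename("a")
        .reset_index()
    )
    joint = joint[joint["a"] >= min_a]
    out = joint.assign(
        level=level,
        n_drug=joint["drug"].map(drug_margin),
        n_term=joint["term"].map(term_margin),
    )
    out["b"] = out["n_drug"] - out["a"]
    out["c"] = out["n_term"] - out["a"]
    out["d"] = n_total - out["n_drug"] - out["c"]
    out["n"] = n_total
    out["e"] = out["n_drug"] * out["n_term"] / n_total
    if (out[["a", "b", "c", "d"]] < 0).any().any():
        raise AssertionError("negative contingency cell: inconsistent marginals")
    return (
        out[["drug", "level", "term", "a", "b", "c", "d", "n", "e"]]
        .sort_values(["drug", "term"])
        .reset_index(drop=True)
    )
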