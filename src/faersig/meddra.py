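"""MedDRA-style hierarchy loading and multi-level event roll-up.

MedDRA itself is licensed, so the hierarchy is supplied as two plain TSV
extracts: a PT -> primary SOC table and an SMQ membership table with a
narrow/broad scope flag per (SMQ, PT) pair.  Events are counted at the
report level: a report contributes at most once to any term at any level,
however many of its PTs map there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["Hierarchy", "load_hierarchy", "roll_up", "fixture_hierarchy_paths"]

LEVELS = ("PT", "SMQ", "SOC")
SCOPES = ("narrow", "broad")


@dataclass
class Hierarchy:
    """PT->SOC primary assignment plus SMQ memberships with scope flags."""

    pt_to_soc: pd.Series  # index: pt, value: soc
    smq_members: pd.DataFrame  # columns: smq, pt, scope
    version_label: str = ""

    @property
    def pts(self) -> set[str]:
        return set(self.pt_to_soc.index)

    @property
    def socs(self) -> set[str]:
        return set(self.pt_to_soc.unique())

    @property
    def smqs(self) -> set[str]:
        return set(self.smq_members["smq"].unique())


def fixture_hierarchy_paths() -> tuple[Path, Path]:
    """Paths of the bundled synthetic test hierarchy (37 PTs, 6 SOCs, 7 SMQs)."""
    d = Path(__file__).parent / "data"
    return d / "fixture_pt_soc.tsv", d / "fixture_smq.tsv"


def load_hierarchy(
    pt_soc_path: str | Path,
    smq_path: str | Path | None = None,
    version_label: str = "",
) -> Hierarchy:
    """Load the two TSV extracts and check referential integrity.

    Raises on a PT mapped to two SOCs, on an SMQ scope flag outside
    {narrow, broad}, and on SMQ members missing from the PT->SOC table.
    """
    pt_soc = pd.read_csv(pt_soc_path, sep="\t", dtype=str).dropna()
    dup = pt_soc[pt_soc.duplicated("pt", keep=False)].drop_duplicates()
    if dup["pt"].nunique() != len(dup):
        offenders = sorted(dup[dup.duplicated("pt", keep=False)]["pt"].unique())
        raise ValueError(f"PT(s) mapped to more than one primary SOC: {offenders}")
    pt_to_soc = pt_soc.drop_duplicates().set_index("pt")["soc"]

    if smq_path is None:
        smq = pd.DataFrame(columns=["smq", "pt", "scope"])
    else:
        try:
            smq = pd.read_csv(smq_path, sep="\t", dtype=str).dropna()
        except pd.errors.EmptyDataError:
            smq = pd.DataFrame(columns=["smq", "pt", "scope"])
    if len(smq):
        bad_scope = sorted(set(smq["scope"]) - set(SCOPES))
        if bad_scope:
            raise ValueError(f"unknown SMQ scope flag(s): {bad_scope}")
        missing = sorted(set(smq["pt"]) - set(pt_to_soc.index))
        if missing:
            raise ValueError(
                f"SMQ member PT(s) absent from the PT->SOC table: {missing}"
            )
    return Hierarchy(
        pt_to_soc=pt_to_soc,
        smq_members=smq.reset_index(drop=True),
        version_label=version_label,
    )


def roll_up(
    reactions: pd.DataFrame,
    hierarchy: Hierarchy,
    level: str = "PT",
    scope: str = "narrow",
    on_missing: str = "drop",
    smq_include: set[str] | None = None,
) -> pd.DataFrame:
    """Map (primaryid, pt) reaction rows to (primaryid, term) at a level.

    Parameters
    ----------
    reactions
        DataFrame with columns ``primaryid`` and ``pt`` (one row per reported
        reaction; duplicates are harmless).
    level
        ``PT`` (identity), ``SMQ`` (union of memberships of the report's PTs
        at the requested scope) or ``SOC`` (primary SOC of each PT).
    scope
        ``narrow`` (default) or ``narrow+broad``; only meaningful at SMQ level.
    on_missing
        ``drop`` (default): PTs absent from the hierarchy are ignored (their
        count is reported in the frame's ``attrs['n_unmapped_pts']``);
        ``error``: raise listing the offenders.
    smq_include
        Optional allow-list restricting which SMQs are emitted.

    Returns a deduplicated (primaryid, term) DataFrame — each report counts
    at most once per term.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    if scope not in ("narrow", "narrow+broad"):
        raise ValueError(f"scope must be 'narrow' or 'narrow+broad', got {scope!r}")
    rx = reactions[["primaryid", "pt"]].astype(str).drop_duplicates()
    unmapped = sorted(set(rx["pt"]) - hierarchy.pts)
    if unmapped and on_missing == "error":
        raise ValueError(f"PT(s) absent from hierarchy: {unmapped}")
    n_unmapped = int(rx["pt"].isin(unmapped).sum())
    rx = rx[~rx["pt"].isin(unmapped)]

    if level == "PT":
        out = rx.rename(columns={"pt": "term"})
    elif level == "SOC":
        out = rx.assign(term=rx["pt"].map(hierarchy.pt_to_soc))[["primaryid", "term"]]
    else:  # SMQ
        members = hierarchy.smq_members
        if scope == "narrow":
            members = members[members["scope"] == "narrow"]
        if smq_include is not None:
            members = members[members["smq"].isin(smq_include)]
        out = rx.merge(members[["pt", "smq"]], on="pt", how="inner").rename(
            columns={"smq": "term"}
        )[["primaryid", "term"]]
    out = out.drop_duplicates().reset_index(drop=True)
    out.attrs["n_unmapped_pts"] = n_unmapped
    return out
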