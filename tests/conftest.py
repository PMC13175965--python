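"""Shared fixtures: hand-built record sets and a reusable synthetic run."""

from __future__ import annotations

import pandas as pd
import pytest

from faersig.cleaning import (
    CaseData,
    deduplicate,
    default_ici_synonyms,
    filter_reporters,
    select_primary_suspect,
)
from faersig.io import RawRecordSet
from faersig.meddra import fixture_hierarchy_paths, load_hierarchy
from faersig.synthetic import SyntheticConfig, generate


def make_recordset(
    demo_rows: list[dict],
    drug_rows: list[dict] | None = None,
    reac_rows: list[dict] | None = None,
    outc_rows: list[dict] | None = None,
    ther_rows: list[dict] | None = None,
) -> RawRecordSet:
    """Build a RawRecordSet from row dicts, filling absent fields with NA."""
    from faersig.io import TABLE_SCHEMAS

    def frame(rows, name):
        cols = TABLE_SCHEMAS[name]["mandatory"] + TABLE_SCHEMAS[name]["optional"]
        df = pd.DataFrame(rows or [], columns=cols, dtype=object)
        return df.where(pd.notna(df), pd.NA)

    return RawRecordSet(
        demo=frame(demo_rows, "demo"),
        drug=frame(drug_rows, "drug"),
        reac=frame(reac_rows, "reac"),
        outc=frame(outc_rows, "outc"),
        ther=frame(ther_rows, "ther"),
    )


def make_case_data(
    cases: list[dict],
    reactions: list[dict],
    outcomes: list[dict] | None = None,
    drugs: list[dict] | None = None,
    annotations: list[dict] | None = None,
) -> CaseData:
    """Build a CaseData directly (already-deduplicated fixtures)."""
    case_cols = [
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "sex",
        "age_years",
        "occp_cod",
        "reporter_country",
        "rept_cod",
    ]
    cd = CaseData(
        cases=pd.DataFrame(cases, columns=case_cols, dtype=object),
        drugs=pd.DataFrame(
            drugs or [],
            columns=["primaryid", "drug_seq", "role_cod", "drugname", "therapy_start"],
            dtype=object,
        ),
        reactions=pd.DataFrame(reactions, columns=["primaryid", "pt"], dtype=object),
        outcomes=pd.DataFrame(
            outcomes or [], columns=["primaryid", "outc_cod"], dtype=object
        ),
    )
    if annotations is not None:
        cd.annotations = pd.DataFrame(annotations, columns=["primaryid", "drug"])
    return cd


@pytest.fixture(scope="session")
def hierarchy():
    return load_hierarchy(*fixture_hierarchy_paths(), version_label="fixture")


@pytest.fixture(scope="session")
def synthetic_run():
    """One moderate synthetic extract shared across tests (fixed seed)."""
    cfg = SyntheticConfig(n_cases=4000, seed=123, duplicate_rate=0.2)
    records, truth = generate(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def cleaned_run(synthetic_run):
    """The shared extract taken through dedup -> reporter filter -> PS select."""
    _, records, truth = synthetic_run
    deduped = deduplicate(records)
    background = filter_reporters(deduped)
    annotated = select_primary_suspect(background, default_ici_synonyms())
    return background, annotated, truth
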