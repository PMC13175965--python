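"""Deduplication, reporter filtering and primary-suspect selection."""

import pandas as pd
import pytest

from faersig.cleaning import (
    deduplicate,
    filter_reporters,
    select_primary_suspect,
)
from faersig.synthetic import SyntheticConfig, generate

from conftest import make_recordset


def _demo(pid, caseid, fda, occ="MD"):
    return {
        "primaryid": pid,
        "caseid": caseid,
        "fda_dt": fda,
        "occp_cod": occ,
        "sex": "M",
        "reporter_country": "US",
        "rept_cod": "EXP",
    }


def brute_force_survivors(demo: pd.DataFrame, deletions: set[str]) -> set[str]:
    """Independent group-by -> argmax oracle for the survivor set."""

    def key(row):
        pid = str(row["primaryid"])
        numeric = pid.isdigit()
        return (
            int(row["fda_dt"]),
            1 if numeric else 0,
            int(pid) if numeric else 0,
            pid,
        )

    survivors = set()
    for caseid, grp in demo.groupby("caseid"):
        if str(caseid) in deletions:
            continue
        best = max(grp.to_dict("records"), key=key)
        survivors.add(str(best["primaryid"]))
    return survivors


def test_max_primaryid_breaks_fda_dt_ties():
    rs = make_recordset(
        [
            _demo("X1", "X", "20200101"),
            _demo("X2", "X", "20200301"),
            _demo("X9", "X", "20200301"),
        ],
        reac_rows=[{"primaryid": p, "pt": "Colitis"} for p in ("X1", "X2", "X9")],
    )
    out = deduplicate(rs)
    assert out.cases["primaryid"].tolist() == ["X9"]


def test_single_record_is_its_own_survivor():
    rs = make_recordset([_demo("100", "1", "20200101")])
    out = deduplicate(rs)
    assert out.cases["primaryid"].tolist() == ["100"]


def test_deletion_list_removes_case_entirely():
    rs = make_recordset([_demo("100", "1", "20200101"), _demo("200", "2", "20200101")])
    out = deduplicate(rs, deletions={"1"})
    assert out.cases["caseid"].tolist() == ["2"]
    assert out.meta["n_deleted"] == 1


def test_dedup_matches_brute_force_oracle_on_synthetic_duplicates():
    records, truth = generate(
        SyntheticConfig(n_cases=1000, seed=21, duplicate_rate=0.3)
    )
    deletions = set(truth.cases["caseid"].iloc[:17])
    expected = brute_force_survivors(records.demo, deletions)
    got = set(deduplicate(records, deletions).cases["primaryid"])
    assert got == expected
    # survivor count identity: distinct caseids minus deleted ones present
    n_distinct = records.demo["caseid"].nunique()
    assert len(got) == n_distinct - len(deletions)


def test_dedup_is_idempotent():
    records, _ = generate(SyntheticConfig(n_cases=400, seed=31, duplicate_rate=0.4))
    once = deduplicate(records)
    again_input = make_recordset([])
    again_input.demo = records.demo[
        records.demo["primaryid"].isin(set(once.cases["primaryid"]))
    ].reset_index(drop=True)
    again_input.drug, again_input.reac, again_input.outc, again_input.ther = (
        records.drug,
        records.reac,
        records.outc,
        records.ther,
    )
    twice = deduplicate(again_input)
    assert set(twice.cases["primaryid"]) == set(once.cases["primaryid"])


def test_reporter_filter_defaults_keep_health_professionals():
    rs = make_recordset(
        [
            _demo("1", "1", "20200101", "MD"),
            _demo("2", "2", "20200101", "CN"),
            _demo("3", "3", "20200101", "LW"),
            _demo("4", "4", "20200101", "PH"),
            _demo("5", "5", "20200101", None),
        ]
    )
    out = filter_reporters(deduplicate(rs))
    assert sorted(out.cases["occp_cod"]) == ["MD", "PH"]
    # empty exclusion set is the identity
    assert filter_reporters(deduplicate(rs), set()).n_cases == 5
    # everything excluded -> empty result
    all_cn = make_recordset([_demo("1", "1", "20200101", "CN")])
    assert filter_reporters(deduplicate(all_cn)).n_cases == 0


def test_filter_and_dedup_commute_when_versions_share_occupation():
    records, _ = generate(
        SyntheticConfig(n_cases=500, seed=41, duplicate_rate=0.3)
    )
    # force every version of a case to the final version's occupation
    demo = records.demo.copy()
    final_occ = demo.sort_values("primaryid").groupby("caseid")["occp_cod"].last()
    demo["occp_cod"] = demo["caseid"].map(final_occ)
    records.demo = demo
    a = filter_reporters(deduplicate(records))
    demo_kept = demo[
        demo["occp_cod"].astype("string").str.upper().isin(["MD", "PH", "OT", "HP"])
    ]
    records2 = make_recordset([])
    records2.demo, records2.drug, records2.reac, records2.outc, records2.ther = (
        demo_kept.reset_index(drop=True),
        records.drug,
        records.reac,
        records.outc,
        records.ther,
    )
    b = deduplicate(records2)
    assert set(a.cases["primaryid"]) == set(b.cases["primaryid"])


def test_primary_suspect_selection_and_annotation():
    rs = make_recordset(
        [_demo("1", "1", "20200101"), _demo("2", "2", "20200101"), _demo("3", "3", "20200101")],
        drug_rows=[
            {"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": " OPDIVO "},
            {"primaryid": "2", "drug_seq": "1", "role_cod": "C", "drugname": "NIVOLUMAB"},
            {"primaryid": "3", "drug_seq": "1", "role_cod": "PS", "drugname": "NIVOLUMAB"},
            {"primaryid": "3", "drug_seq": "2", "role_cod": "PS", "drugname": "YERVOY"},
        ],
    )
    data = deduplicate(rs)
    out = select_primary_suspect(
        data, {"OPDIVO": "nivolumab", "NIVOLUMAB": "nivolumab", "YERVOY": "ipilimumab"}
    )
    # report 2 (concomitant only) is dropped; report 3 counts for both drugs
    assert set(out.cases["primaryid"]) == {"1", "3"}
    ann = out.annotations.groupby("drug")["primaryid"].apply(set)
    assert ann["nivolumab"] == {"1", "3"}
    assert ann["ipilimumab"] == {"3"}
    with pytest.raises(ValueError):
        select_primary_suspect(data, {})
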