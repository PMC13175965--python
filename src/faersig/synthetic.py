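"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of a FAERS extract at desk scale: multi-version cases
(same CASEID, earlier FDA_DTs, distinct PRIMARYIDs) for the deduplicator to
collapse, professional and non-professional reporter occupations, one
primary-suspect drug per case drawn from a configurable marginal over target
and background drugs, PT-coded events whose per-drug reporting rates are
tilted by a planted relative-reporting-rate (rr) matrix, death outcomes with
PT-dependent probabilities, therapy-start and event-onset dates with
exponential onset times, and realistic missingness in age/sex/dates.

The planted rr acts as a multiplicative tilt on the PT sampling weights and
is renormalised per drug, so the realised report-level relative reporting
rate approximates (not equals) the configured rr; recovery tests therefore
assert detection and ordering properties rather than exact rr equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from faersig.io import RawRecordSet, write_tables
from faersig.meddra import Hierarchy, fixture_hierarchy_paths, load_hierarchy

__all__ = [
    "TARGET_DRUGS",
    "SyntheticConfig",
    "SyntheticTruth",
    "synthetic_hierarchy",
    "generate",
    "evaluate_recovery",
]

#: the eight target immunotherapy drugs, with their default share of target
#: cases patterned on the reported per-drug distribution (three drugs carry
#: ~80% of cases)
TARGET_DRUGS = {
    "nivolumab": 0.30,
    "pembrolizumab": 0.28,
    "atezolizumab": 0.22,
    "ipilimumab": 0.06,
    "avelumab": 0.05,
    "durvalumab": 0.04,
    "cemiplimab": 0.04,
    "tremelimumab": 0.01,
}

#: PTs with an elevated fatality probability in the default configuration
_HIGH_FATALITY_PTS = {
    "Myocarditis",
    "Immune-mediated myocarditis",
    "Cardiac failure",
    "Myocardial infarction",
    "Pneumonitis",
    "Interstitial lung disease",
    "Immune-mediated lung disease",
    "Hepatic failure",
    "Guillain-Barre syndrome",
}

_COUNTRIES = ["JP", "US", "CA", "DE", "FR", "GB", "IT", "CN", "KR", "BR", "AU", "ZA"]
_COUNTRY_W = [0.28, 0.27, 0.03, 0.09, 0.08, 0.07, 0.05, 0.04, 0.04, 0.03, 0.015, 0.005]


def synthetic_hierarchy(
    n_pts: int = 200, n_socs: int = 10, n_smqs: int = 20, seed: int = 0
) -> Hierarchy:
    """A programmatic hierarchy for large-vocabulary simulations.

    PTs ``PT_0001..`` are assigned round-robin to SOCs ``SOC_01..``; each SMQ
    gets a random disjoint block of PTs split 2:1 into narrow and broad
    scope.
    """
    rng = np.random.default_rng(seed)
    pts = [f"PT_{i + 1:04d}" for i in range(n_pts)]
    socs = [f"SOC_{i + 1:02d}" for i in range(n_socs)]
    pt_to_soc = pd.Series([socs[i % n_socs] for i in range(n_pts)], index=pts)
    perm = rng.permutation(n_pts)
    block = max(3, n_pts // max(n_smqs, 1))
    rows = []
    for s in range(n_smqs):
        members = perm[s * block : (s + 1) * block]
        for j, m in enumerate(members):
            rows.append(
                {
                    "smq": f"SMQ_{s + 1:02d}",
                    "pt": pts[m],
                    "scope": "narrow" if j % 3 != 2 else "broad",
                }
            )
    return Hierarchy(
        pt_to_soc=pt_to_soc,
        smq_members=pd.DataFrame(rows, columns=["smq", "pt", "scope"]),
        version_label="synthetic",
    )


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic extract.

    Defaults emulate the reporting characteristics of the real database at
    desk scale: ~15% of raw records are superseded duplicate versions, half
    of the reports come from non-professionals (consumers, lawyers, unknown),
    sex splits M/F/missing at 0.53/0.34/0.13, a quarter of ages are missing
    with the known ages centred so that ~57% exceed 65 years, onset medians
    span 28-50 days across target drugs, and event/therapy dates are missing
    often enough that onset is computable for roughly 40% of reports.
    """

    n_cases: int = 10_000
    seed: int = 0
    hierarchy: Hierarchy | None = None  # default: the bundled fixture
    target_shares: dict[str, float] = field(
        default_factory=lambda: dict(TARGET_DRUGS)
    )
    target_fraction: float = 0.20  # share of cases with a target PS drug
    n_background_drugs: int = 50
    baseline_p: dict[str, float] | None = None  # default: power-law over vocab
    rr: dict[tuple[str, str], float] = field(default_factory=dict)
    duplicate_rate: float = 0.15
    nonprofessional_fraction: float = 0.50
    death_probability: dict[str, float] | None = None
    base_death_probability: float = 0.15
    high_death_probability: float = 0.45
    serious_nonfatal_probability: float = 0.885
    onset_median_days: dict[str, float] | None = None  # default: 28-50 d span
    missing_age: float = 0.25
    missing_sex: float = 0.13
    missing_event_dt: float = 0.45
    missing_therapy_start: float = 0.35
    year_range: tuple[int, int] = (2011, 2024)

    def resolved_hierarchy(self) -> Hierarchy:
        if self.hierarchy is not None:
            return self.hierarchy
        return load_hierarchy(*fixture_hierarchy_paths(), version_label="fixture")

    def validate(self) -> None:
        probs = [
            self.target_fraction,
            self.duplicate_rate,
            self.nonprofessional_fraction,
            self.base_death_probability,
            self.high_death_probability,
            self.serious_nonfatal_probability,
            self.missing_age,
            self.missing_sex,
            self.missing_event_dt,
            self.missing_therapy_start,
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probability parameters must lie in [0, 1]")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if any(r < 0 for r in self.rr.values()):
            raise ValueError("relative reporting rates must be >= 0")
        if abs(sum(self.target_shares.values()) - 1.0) > 1e-9:
            raise ValueError("target_shares must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated extract."""

    rr: dict[tuple[str, str], float]
    lineage: dict[str, list[tuple[str, str]]]  # caseid -> [(primaryid, fda_dt)]
    cases: pd.DataFrame  # caseid, primaryid, drug, death
    target_drugs: list[str]
    vocabulary: list[str]


def _default_baseline(pts: list[str]) -> np.ndarray:
    # power-law frequencies: a few common events, a long rare tail
    ranks = np.arange(1, len(pts) + 1, dtype=float)
    w = ranks**-0.8
    return w / w.sum()


def _yyyymmdd(days: np.ndarray) -> np.ndarray:
    dt = np.datetime64("1970-01-01") + days.astype("timedelta64[D]")
    return np.char.replace(np.datetime_as_string(dt, unit="D"), "-", "")


def generate(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[RawRecordSet, SyntheticTruth]:
    """Generate one synthetic extract; optionally serialise it to disk.

    Identical config + seed gives identical output.  Returns the in-memory
    :class:`RawRecordSet` (the same object the reader would produce from the
    written files) and the :class:`SyntheticTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    hier = config.resolved_hierarchy()
    pts = list(hier.pt_to_soc.index)
    v = len(pts)
    n = config.n_cases

    targets = list(config.target_shares)
    background = [f"backgrounddrug{i + 1:03d}" for i in range(config.n_background_drugs)]
    drugs_all = targets + background
    p_target = np.array([config.target_shares[t] for t in targets]) * config.target_fraction
    p_bg = np.full(len(background), (1.0 - config.target_fraction) / max(len(background), 1))
    p_drug = np.concatenate([p_target, p_bg])
    p_drug = p_drug / p_drug.sum()

    baseline = (
        np.array([config.baseline_p.get(pt, 0.0) for pt in pts])
        if config.baseline_p is not None
        else _default_baseline(pts)
    )
    if baseline.sum() <= 0:
        raise ValueError("baseline event probabilities are all zero")

    if config.death_probability is not None:
        death_p = np.array([config.death_probability.get(pt, 0.0) for pt in pts])
    else:
        death_p = np.where(
            np.isin(pts, list(_HIGH_FATALITY_PTS)),
            config.high_death_probability,
            config.base_death_probability,
        )

    onset_cfg = config.onset_median_days or {}
    onset_medians = np.array(
        [
            onset_cfg.get(d, 28.0 + 22.0 * i / max(len(targets) - 1, 1))
            if d in targets
            else onset_cfg.get(d, 40.0)
            for i, d in enumerate(drugs_all)
        ]
    )

    # --- per-case draws -----------------------------------------------------
    drug_idx = rng.choice(len(drugs_all), size=n, p=p_drug)
    n_pts_case = np.minimum(1 + rng.poisson(1.0, size=n), min(10, v))

    rr_mat = np.ones((len(drugs_all), v))
    for (drg, pt), r in config.rr.items():
        if drg not in drugs_all or pt not in pts:
            raise ValueError(f"rr entry ({drg!r}, {pt!r}) outside drug/PT vocabulary")
        rr_mat[drugs_all.index(drg), pts.index(pt)] = r

    case_pts: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    order = np.arange(n)
    for di in np.unique(drug_idx):
        rows = order[drug_idx == di]
        w = baseline * rr_mat[di]
        logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
        gumbel = rng.gumbel(size=(len(rows), v))
        keys = logw[None, :] + gumbel
        kmax = int(n_pts_case[rows].max())
        top = np.argpartition(-keys, kth=kmax - 1 if kmax < v else v - 1, axis=1)[
            :, :kmax
        ]
        for j, row in enumerate(rows):
            case_pts[row] = np.sort(top[j, : n_pts_case[row]])

    # outcomes: death governed by the most lethal drawn PT
    p_death_case = np.array([death_p[ix].max() for ix in case_pts])
    death = rng.random(n) < p_death_case
    serious_alive = rng.random(n) < config.serious_nonfatal_probability
    nonfatal_codes = rng.choice(
        ["HO", "OT", "LT", "DS", "RI", "CA"],
        size=n,
        p=[0.60, 0.25, 0.05, 0.05, 0.03, 0.02],
    )

    # demographics
    sex = rng.choice(["M", "F"], size=n, p=[0.53 / 0.87, 0.34 / 0.87])
    sex = np.where(rng.random(n) < config.missing_sex, "", sex)
    age = np.clip(np.round(rng.normal(67.0, 12.0, size=n)), 18, 95).astype(int)
    age_missing = rng.random(n) < config.missing_age
    occ_prof = rng.choice(["MD", "PH", "OT", "HP"], size=n, p=[0.585, 0.26, 0.15, 0.005])
    occ_non = rng.choice(["CN", "LW", ""], size=n, p=[0.70, 0.10, 0.20])
    occ = np.where(rng.random(n) < config.nonprofessional_fraction, occ_non, occ_prof)
    country = rng.choice(_COUNTRIES, size=n, p=np.array(_COUNTRY_W) / sum(_COUNTRY_W))
    rept = rng.choice(["EXP", "PER", "DIR"], size=n, p=[0.90, 0.08, 0.02])

    # dates (epoch days)
    y0, y1 = config.year_range
    d0 = (np.datetime64(f"{y0}-01-01") - np.datetime64("1970-01-01")).astype(int)
    d1 = (np.datetime64(f"{y1}-12-31") - np.datetime64("1970-01-01")).astype(int)
    fda = rng.integers(d0, d1 + 1, size=n)
    start = fda - rng.integers(180, 731, size=n)
    onset_scale = onset_medians[drug_idx] / np.log(2.0)
    onset = rng.exponential(onset_scale)
    onset = np.minimum(np.floor(onset), (fda - start) - 1).astype(int)
    event = start + onset
    start_missing = rng.random(n) < config.missing_therapy_start
    event_missing = rng.random(n) < config.missing_event_dt
    # a sliver of month-precision event dates
    event_month_prec = (~event_missing) & (rng.random(n) < 0.05)

    caseid_num = 10_000_000 + np.arange(n)
    n_extra = np.where(rng.random(n) < config.duplicate_rate, rng.integers(1, 4, size=n), 0)
    primaryid_num = caseid_num * 100 + n_extra  # final version

    caseid = caseid_num.astype(str)
    primaryid = primaryid_num.astype(str)
    fda_s = _yyyymmdd(fda)
    event_full = _yyyymmdd(event)
    event_s = np.array(
        [s[:6] if m else s for s, m in zip(event_full, event_month_prec)]
    )
    event_s = np.where(event_missing, "", event_s)
    start_s = np.where(start_missing, "", _yyyymmdd(start))

    demo_rows = {
        "primaryid": primaryid,
        "caseid": caseid,
        "fda_dt": fda_s,
        "event_dt": event_s,
        "age": np.where(age_missing, "", age.astype(str)),
        "age_cod": np.where(age_missing, "", np.where(rng.random(n) < 0.9, "YR", "")),
        "sex": sex,
        "occp_cod": occ,
        "reporter_country": country,
        "rept_cod": rept,
    }
    demo = pd.DataFrame(demo_rows)

    # earlier versions of duplicated cases: same caseid, smaller primaryid,
    # strictly earlier fda_dt, occupation occasionally differing
    dup_case = np.repeat(np.arange(n), n_extra)
    if len(dup_case):
        version = np.concatenate([np.arange(k) for k in n_extra[n_extra > 0]])
        back = rng.integers(30, 400, size=len(dup_case))
        # strictly earlier and strictly ordered: subtract (n_extra - version)*step
        steps = (n_extra[dup_case] - version) * back
        dup_fda = fda[dup_case] - steps
        dup_occ = occ[dup_case].copy()
        resample = rng.random(len(dup_case)) < 0.3
        dup_occ[resample] = rng.choice(
            ["MD", "PH", "OT", "CN", "LW", ""], size=int(resample.sum())
        )
        dup_demo = pd.DataFrame(
            {
                "primaryid": (caseid_num[dup_case] * 100 + version).astype(str),
                "caseid": caseid[dup_case],
                "fda_dt": _yyyymmdd(dup_fda),
                "event_dt": event_s[dup_case],
                "age": demo["age"].to_numpy()[dup_case],
                "age_cod": demo["age_cod"].to_numpy()[dup_case],
                "sex": sex[dup_case],
                "occp_cod": dup_occ,
                "reporter_country": country[dup_case],
                "rept_cod": rept[dup_case],
            }
        )
        demo = pd.concat([demo, dup_demo], ignore_index=True)
        all_case_idx = np.concatenate([np.arange(n), dup_case])
        all_pids = np.concatenate(
            [primaryid, (caseid_num[dup_case] * 100 + version).astype(str)]
        )
    else:
        all_case_idx = np.arange(n)
        all_pids = primaryid

    demo = demo.sort_values("primaryid", kind="mergesort").reset_index(drop=True)

    # child tables for every version
    drug_tbl = pd.DataFrame(
        {
            "primaryid": all_pids,
            "drug_seq": "1",
            "role_cod": "PS",
            "drugname": np.array([drugs_all[i].upper() for i in drug_idx])[all_case_idx],
        }
    ).sort_values("primaryid", kind="mergesort").reset_index(drop=True)

    reac_pid = np.repeat(all_pids, n_pts_case[all_case_idx])
    reac_pt = np.concatenate([[pts[j] for j in case_pts[i]] for i in all_case_idx])
    reac_tbl = (
        pd.DataFrame({"primaryid": reac_pid, "pt": reac_pt})
        .sort_values(["primaryid", "pt"], kind="mergesort")
        .reset_index(drop=True)
    )

    outc_code = np.where(death, "DE", np.where(serious_alive, nonfatal_codes, ""))
    has_outc = outc_code[all_case_idx] != ""
    outc_tbl = (
        pd.DataFrame(
            {
                "primaryid": all_pids[has_outc],
                "outc_cod": outc_code[all_case_idx][has_outc],
            }
        )
        .sort_values("primaryid", kind="mergesort")
        .reset_index(drop=True)
    )

    has_start = start_s[all_case_idx] != ""
    ther_tbl = (
        pd.DataFrame(
            {
                "primaryid": all_pids[has_start],
                "dsg_drug_seq": "1",
                "start_dt": start_s[all_case_idx][has_start],
            }
        )
        .sort_values("primaryid", kind="mergesort")
        .reset_index(drop=True)
    )

    def _na(df: pd.DataFrame) -> pd.DataFrame:
        df = df.astype(object)
        return df.where(df != "", pd.NA)

    records = RawRecordSet(
        demo=_na(demo),
        drug=_na(drug_tbl),
        reac=_na(reac_tbl),
        outc=_na(outc_tbl),
        ther=_na(ther_tbl),
        load_report={
            t: {"data_lines": k, "parsed": k, "dropped": 0}
            for t, k in {
                "demo": len(demo),
                "drug": len(drug_tbl),
                "reac": len(reac_tbl),
                "outc": len(outc_tbl),
                "ther": len(ther_tbl),
            }.items()
        },
    )

    lineage: dict[str, list[tuple[str, str]]] = {}
    if len(dup_case):
        dup_pid = (caseid_num[dup_case] * 100 + version).astype(str)
        dup_fda_s = _yyyymmdd(dup_fda)
        for i, ci in enumerate(dup_case):
            lineage.setdefault(caseid[ci], [(primaryid[ci], fda_s[ci])]).append(
                (dup_pid[i], dup_fda_s[i])
            )

    truth = SyntheticTruth(
        rr=dict(config.rr),
        lineage=lineage,
        cases=pd.DataFrame(
            {
                "caseid": caseid,
                "primaryid": primaryid,
                "drug": [drugs_all[i] for i in drug_idx],
                "death": death,
            }
        ),
        target_drugs=targets,
        vocabulary=pts,
    )

    if out_dir is not None:
        write_tables(records, out_dir, format="csv")
    return records, truth


def recovery_benchmark_config(
    n_cases: int = 50_000,
    seed: int = 0,
    n_planted: int = 20,
    rr_value: float = 10.0,
    hierarchy: Hierarchy | None = None,
) -> SyntheticConfig:
    """The standard planted-signal recovery scenario.

    Twenty (by default) (drug, PT) pairs carry a planted relative reporting
    rate of 10, assigned round-robin across the eight target drugs with
    uniform target shares (so each drug has enough reports for detection to
    be a property of the method, not of the drug's market share) and placed
    on mid-frequency PTs with baseline probability closest to 0.005.
    """
    h = hierarchy or synthetic_hierarchy(n_pts=640, n_socs=12, n_smqs=30, seed=1)
    pts = list(h.pt_to_soc.index)
    baseline = _default_baseline(pts)
    chosen = np.argsort(np.abs(baseline - 0.005), kind="stable")[:n_planted]
    targets = list(TARGET_DRUGS)
    rr = {
        (targets[i % len(targets)], pts[int(j)]): rr_value
        for i, j in enumerate(sorted(chosen))
    }
    return SyntheticConfig(
        n_cases=n_cases,
        seed=seed,
        hierarchy=h,
        target_shares={t: 1.0 / len(targets) for t in targets},
        rr=rr,
    )


def evaluate_recovery(
    results: pd.DataFrame,
    truth: SyntheticTruth,
    rr_threshold: float = 2.0,
    methods: tuple[str, ...] = ("ROR", "MHRA", "BCPNN", "MGPS"),
) -> pd.DataFrame:
    """Sensitivity / specificity / false-discovery proportion per method.

    True positives are (target drug, PT) pairs whose planted rr is at least
    ``rr_threshold``; the evaluation universe is all target-drug x vocabulary
    pairs, with pairs absent from ``results`` counted as negative calls.
    """
    from faersig.dispro import METHOD_FLAGS

    res = results[results["level"] == "PT"] if "level" in results else results
    unknown = set(res["term"]) - set(truth.vocabulary)
    if unknown:
        raise ValueError(f"result terms outside the truth vocabulary: {sorted(unknown)[:5]}")
    truth_pos = {
        (d, p) for (d, p), r in truth.rr.items() if r >= rr_threshold and d in truth.target_drugs
    }
    universe = {(d, p) for d in truth.target_drugs for p in truth.vocabulary}
    rows = []
    for m in methods:
        flag = METHOD_FLAGS[m]
        called = {
            (r.drug, r.term)
            for r in res.itertuples()
            if getattr(r, flag) and r.drug in truth.target_drugs
        }
        tp = len(called & truth_pos)
        fp = len(called - truth_pos)
        tn = len(universe - truth_pos - called)
        fn = len(truth_pos - called)
        rows.append(
            {
                "method": m,
                "sensitivity": tp / max(tp + fn, 1),
                "specificity": tn / max(tn + fp, 1),
                "fdp": fp / max(tp + fp, 1),
                "n_called": tp + fp,
            }
        )
    return pd.DataFrame(rows).set_index("method")
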