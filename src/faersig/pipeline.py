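"""End-to-end orchestration: simulate/ingest -> clean -> signal -> aggregate.

``run_pipeline`` executes the staged workflow and writes a JSON manifest —
the canonical provenance artifact — recording per-stage record counts,
timings, output files and the configuration echo, so that the cleaning
funnel is auditable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from faersig.aggregate import cumulative_metric, death_proportion, overlap_analysis
from faersig.characteristics import demographic_summary, time_to_onset
from faersig.cleaning import (
    DEFAULT_EXCLUDED_OCCUPATIONS,
    deduplicate,
    default_ici_synonyms,
    filter_reporters,
    load_synonyms,
    select_primary_suspect,
)
from faersig.contingency import build_tables
from faersig.dispro import ScreeningCriteria, compare_methods, score_tables, screen_signals
from faersig.io import read_deletion_list, read_quarter, write_tables
from faersig.meddra import fixture_hierarchy_paths, load_hierarchy
from faersig.synthetic import SyntheticConfig, generate

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("faersig")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_paths`` (table name -> file path) and
    ``synthetic`` (a :class:`SyntheticConfig` or its field dict) must be set.
    """

    out_dir: str | Path = "faersig_out"
    seed: int = 0
    input_paths: dict[str, str] | None = None
    synthetic: SyntheticConfig | dict | None = None
    deletion_lists: list[str] = field(default_factory=list)
    synonyms_path: str | None = None  # default: bundled target-drug table
    pt_soc_path: str | None = None  # default: bundled fixture hierarchy
    smq_path: str | None = None
    excluded_occupations: list[str] | None = None
    levels: list[str] = field(default_factory=lambda: ["SOC", "SMQ", "PT"])
    scope: str = "narrow"
    criteria: dict = field(default_factory=dict)
    fit_prior: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_paths is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of input_paths and synthetic must be configured"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _stage(manifest: dict, name: str, t0: float, **counts) -> None:
    manifest["stages"].append(
        {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **counts}
    )
    log.info("stage %s: %s", name, counts)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and write) the manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from faersig import __version__ as pkg_version

    manifest: dict = {
        "version": pkg_version,
        "stages": [],
        "outputs": [],
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
            if k != "synthetic"
        },
    }

    # --- ingest -------------------------------------------------------------
    t0 = time.perf_counter()
    if config.synthetic is not None:
        syn = config.synthetic
        if isinstance(syn, dict):
            syn = SyntheticConfig(**syn)
        records, truth = generate(syn, out_dir=out / "synthetic")
        manifest["config"]["synthetic"] = {
            k: v for k, v in vars(syn).items() if k not in ("hierarchy", "rr")
        }
    else:
        records, truth = read_quarter(config.input_paths), None
    manifest["load_report"] = records.load_report
    _stage(
        manifest,
        "ingest",
        t0,
        demo_rows=len(records.demo),
        reac_rows=len(records.reac),
    )

    # --- clean --------------------------------------------------------------
    t0 = time.perf_counter()
    deletions: set[str] = set()
    for p in config.deletion_lists:
        deletions |= read_deletion_list(p)
    deduped = deduplicate(records, deletions)
    filtered = filter_reporters(
        deduped,
        set(config.excluded_occupations)
        if config.excluded_occupations is not None
        else DEFAULT_EXCLUDED_OCCUPATIONS,
    )
    synonyms = (
        load_synonyms(config.synonyms_path)
        if config.synonyms_path
        else default_ici_synonyms()
    )
    analysis = select_primary_suspect(filtered, synonyms)
    _stage(
        manifest,
        "clean",
        t0,
        raw_demo_rows=len(records.demo),
        deduplicated=deduped.n_cases,
        deleted=deduped.meta.get("n_deleted", 0),
        professional=filtered.n_cases,
        reporter_excluded=filtered.meta.get("n_reporter_excluded", 0),
        target_cases=analysis.n_cases,
    )

    # --- signal -------------------------------------------------------------
    t0 = time.perf_counter()
    if config.pt_soc_path:
        hierarchy = load_hierarchy(config.pt_soc_path, config.smq_path)
    elif config.synthetic is not None and getattr(syn, "hierarchy", None) is not None:
        hierarchy = syn.hierarchy
    else:
        hierarchy = load_hierarchy(*fixture_hierarchy_paths())
    criteria = ScreeningCriteria(**config.criteria)
    all_results = []
    for level in config.levels:
        tables = build_tables(
            filtered,
            annotations=analysis.annotations,
            hierarchy=hierarchy,
            level=level,
            scope=config.scope,
        )
        scored = score_tables(tables, fit_prior=config.fit_prior)
        screened = screen_signals(scored, criteria)
        all_results.append(screened)
    results = pd.concat(all_results, ignore_index=True)
    manifest["outputs"] += write_tables(results, out / "signals.csv")
    _stage(
        manifest,
        "signal",
        t0,
        tables=len(results),
        positives_bcpnn=int(results["bcpnn_pos"].sum()),
    )

    # --- aggregate ----------------------------------------------------------
    t0 = time.perf_counter()
    for metric, level in (
        ("C-ROR025", "SOC"),
        ("C-IC025", "SOC"),
        ("C-EBGM05", "SMQ"),
        ("C-IC025", "PT"),
    ):
        if level in config.levels:
            ranked = cumulative_metric(results, metric, level)
            fp = out / f"cumulative_{metric.replace('-', '').lower()}_{level.lower()}.csv"
            manifest["outputs"] += write_tables(ranked, fp)
    if "SOC" in config.levels:
        per_term, overall = death_proportion(analysis, hierarchy, level="SOC")
        manifest["outputs"] += write_tables(per_term, out / "death_by_soc.csv")
        manifest["death_proportion_overall"] = overall
    if "PT" in config.levels:
        ov = overlap_analysis(results[results["level"] == "PT"])
        (out / "overlap.json").write_text(
            json.dumps(
                {
                    "per_drug": {k: sorted(v) for k, v in ov.per_drug.items()},
                    "shared": sorted(ov.shared),
                    "unique": {k: sorted(v) for k, v in ov.unique.items()},
                    "total_distinct": ov.total_distinct,
                },
                indent=2,
            )
        )
        manifest["outputs"].append(str(out / "overlap.json"))
    _stage(manifest, "aggregate", t0)

    # --- describe -----------------------------------------------------------
    t0 = time.perf_counter()
    summaries = demographic_summary(analysis)
    for dim, df in summaries.items():
        manifest["outputs"] += write_tables(df, out / f"characteristics_{dim}.csv")
    onset = time_to_onset(analysis, synonyms=synonyms)
    manifest["onset"] = {
        "n_computable": onset["n_computable"],
        "fraction_within_90d": onset["fraction_within"],
        "median_days_per_drug": {
            k: float(v) for k, v in onset["median_days"].items()
        },
    }
    manifest["method_comparison"] = {
        "counts": compare_methods(results)["counts"].to_dict(),
    }
    _stage(manifest, "describe", t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    manifest["outputs"].append(str(manifest_path))
    return manifest
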