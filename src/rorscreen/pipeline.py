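"""End-to-end orchestration: ingest → dedup → link → window → screen → write.

:func:`run_screen` executes the full analysis in a fixed stage order and
records per-stage record counts in a run summary, so that every count a
report quotes (total co-occurrences per drug, distinct PTs, per-class n)
can be traced to an ingestion stage.  Any stage failure is surfaced as a
:class:`StageError` naming the stage, which the command-line layer turns
into a non-zero exit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from rorscreen import jader_io
from rorscreen.disproportionality import (
    extract_cooccurrences,
    screen,
    signals_frame,
)
from rorscreen.event_dictionary import (
    EventDictionary,
    load_default_dictionary,
    load_dictionary,
)
from rorscreen.jader_io import (
    CaseDatabase,
    DEFAULT_DIALECT,
    Involvement,
    TableDialect,
    deduplicate,
    filter_window,
    link_tables,
    parse_table,
)
from rorscreen.synthetic_data import SimulationConfig, simulate_database

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "StageError",
    "exclude_sparse_drugs",
    "run_screen",
    "run_simulate",
    "parse_quarter",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def parse_quarter(text: str) -> tuple[int, int]:
    """Parse a quarter written as ``2014Q3`` into ``(2014, 3)``."""
    try:
        year_s, quarter_s = text.upper().split("Q")
        year, quarter = int(year_s), int(quarter_s)
    except ValueError as exc:
        raise ValueError(f"quarter must look like 2014Q3, got {text!r}") from exc
    if not 1 <= quarter <= 4:
        raise ValueError(f"quarter must be in 1..4, got {text!r}")
    return year, quarter


@dataclass
class RunConfig:
    """Configuration of one screening run.

    ``window_start``/``window_end`` are inclusive ``(year, quarter)``
    bounds; leave both ``None`` to analyse all quarters.  ``dictionary``
    is either the string ``"default"`` (packaged infection classes) or a
    path to a YAML class→PT-list file.  ``min_drug_reports`` excludes
    target drugs with too few suspected-case reports from the screen
    (sparse products yield unstable RORs); ``min_count`` only flags
    low-count pairs as ineligible without removing them.
    """

    demo_path: str | Path
    drug_path: str | Path
    reac_path: str | Path
    target_drugs: Sequence[str]
    window_start: tuple[int, int] | None = None
    window_end: tuple[int, int] | None = None
    dictionary: str | Path = "default"
    min_drug_reports: int = 10
    correction: str = "haldane_if_zero"
    min_count: int = 1
    unit: str = "cooccurrence"
    output_path: str | Path = "signals.csv"
    log_level: str = "INFO"
    dialect: TableDialect = field(default_factory=lambda: DEFAULT_DIALECT)

    def __post_init__(self) -> None:
        if not self.target_drugs:
            raise ValueError("target_drugs must be non-empty")
        if self.min_drug_reports < 0:
            raise ValueError("min_drug_reports must be >= 0")
        if (self.window_start is None) != (self.window_end is None):
            raise ValueError("window_start and window_end must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        for key in ("window_start", "window_end"):
            if isinstance(data.get(key), str):
                data[key] = parse_quarter(data[key])
            elif isinstance(data.get(key), (list, tuple)):
                data[key] = tuple(int(v) for v in data[key])
        return cls(**data)

    def load_event_dictionary(self) -> EventDictionary:
        if self.dictionary == "default":
            return load_default_dictionary()
        return load_dictionary(self.dictionary)


def exclude_sparse_drugs(
    cases: CaseDatabase,
    target_drugs: Sequence[str],
    min_drug_reports: int,
) -> tuple[list[str], list[tuple[str, int]]]:
    """Drop target drugs with too few suspected-case reports.

    A drug is retained iff the number of distinct cases reporting it as a
    suspected medicine is at least ``min_drug_reports``.  The exclusion
    report lists each dropped drug with its count, so sparse products are
    excluded transparently rather than silently.
    """
    if min_drug_reports < 0:
        raise ValueError("min_drug_reports must be >= 0")
    suspected = cases.drug[cases.drug["involvement"] == Involvement.SUSPECTED.value]
    counts = (
        suspected.drop_duplicates(["case_id", "drug_name"])["drug_name"]
        .value_counts()
        .to_dict()
    )
    retained, excluded = [], []
    for drug in target_drugs:
        count = int(counts.get(drug, 0))
        if count >= min_drug_reports:
            retained.append(drug)
        else:
            excluded.append((drug, count))
            logger.info(
                "exclude_sparse_drugs: %r excluded (%d suspected reports < %d)",
                drug, count, min_drug_reports,
            )
    return retained, excluded


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 — re-raised with stage context
            raise StageError(name, str(exc)) from exc
    return wrap


def run_screen(config: RunConfig) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Run the full screen and write the signals CSV.

    Stage order: parse → deduplicate → link → filter_window →
    exclude_sparse_drugs → extract_cooccurrences → screen → write.

    Returns
    -------
    (signals, summary)
        ``signals`` is the written results table (one row per drug ×
        event-class pair); ``summary`` records per-stage input/output
        counts and the full configuration.
    """
    summary: dict[str, Any] = {"config": _config_dict(config), "stages": {}}
    stages = summary["stages"]

    run = _stage("parse")
    demo = run(parse_table, config.demo_path, "demo", config.dialect)
    drug = run(parse_table, config.drug_path, "drug", config.dialect)
    reac = run(parse_table, config.reac_path, "reac", config.dialect)
    stages["parse"] = {"demo_rows": len(demo), "drug_rows": len(drug), "reac_rows": len(reac)}

    demo_dedup = _stage("deduplicate")(deduplicate, demo)
    stages["deduplicate"] = {
        "rows_in": len(demo), "rows_out": len(demo_dedup),
        "duplicates_removed": len(demo) - len(demo_dedup),
    }

    cases = _stage("link")(link_tables, demo_dedup, drug, reac)
    stages["link"] = {
        "cases": len(cases),
        "drug_rows": len(cases.drug),
        "reac_rows": len(cases.reac),
        "orphan_drug_rows": cases.orphan_drug_count,
        "orphan_reac_rows": cases.orphan_reac_count,
    }

    if config.window_start is not None and config.window_end is not None:
        cases = _stage("filter_window")(
            filter_window, cases, tuple(config.window_start), tuple(config.window_end)
        )
    stages["filter_window"] = {"cases": len(cases)}

    retained, excluded = _stage("exclude_sparse_drugs")(
        exclude_sparse_drugs, cases, list(config.target_drugs), config.min_drug_reports
    )
    stages["exclude_sparse_drugs"] = {
        "retained": retained,
        "excluded": [{"drug": d, "suspected_reports": c} for d, c in excluded],
    }

    dictionary = _stage("load_dictionary")(config.load_event_dictionary)
    units = _stage("extract_cooccurrences")(extract_cooccurrences, cases, dictionary)
    per_drug: dict[str, Any] = {}
    for drug_name in retained:
        drug_units = units[units["drug_name"] == drug_name]
        by_class = (
            drug_units["event_class"].value_counts().to_dict()
            if not drug_units.empty else {}
        )
        per_drug[drug_name] = {
            "cooccurrences": len(drug_units),
            "distinct_preferred_terms": int(drug_units["preferred_term"].nunique()),
            "per_class_n": {str(k): int(v) for k, v in by_class.items()},
        }
    stages["extract_cooccurrences"] = {"units": len(units), "per_drug": per_drug}

    if units.empty:
        logger.warning("run_screen: no co-occurrence units — writing empty signals table")
    results = _stage("screen")(
        screen, units, dictionary, retained,
        correction=config.correction, min_count=config.min_count, unit=config.unit,
    )
    signals = signals_frame(results)
    stages["screen"] = {
        "pairs": len(signals),
        "signals": int(signals["signal"].sum()) if not signals.empty else 0,
    }

    out_path = Path(config.output_path)
    _stage("write")(signals.to_csv, out_path, index=False)
    summary["output_path"] = str(out_path)
    return signals, summary


def run_simulate(
    sim_config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate a synthetic database and write it with its ground truth.

    Writes demo.csv / drug.csv / reac.csv plus a ``ground_truth.json``
    sidecar recording the seed and the injected odds multipliers, so a
    downstream screen can be checked against what was planted.
    """
    demo, drug, reac = simulate_database(sim_config)
    out_dir = Path(out_dir)
    demo_p, drug_p, reac_p = jader_io.write_tables((demo, drug, reac), out_dir)
    truth: dict[str, Any] = {
        "seed": sim_config.seed,
        "n_cases": sim_config.n_cases,
        "odds_multipliers": [
            {"drug": d, "preferred_term": pt, "theta": theta}
            for (d, pt), theta in sim_config.odds_multipliers.items()
        ],
    }
    truth_p = out_dir / "ground_truth.json"
    truth_p.write_text(json.dumps(truth, indent=2) + "\n", encoding="utf-8")
    return {"demo": demo_p, "drug": drug_p, "reac": reac_p, "ground_truth": truth_p}


def _config_dict(config: RunConfig) -> dict[str, Any]:
    data = dataclasses.asdict(config)
    data["dialect"] = {
        "sep": config.dialect.sep,
        "encoding": config.dialect.encoding,
    }
    for key in ("demo_path", "drug_path", "reac_path", "output_path", "dictionary"):
        data[key] = str(data[key])
    data["target_drugs"] = list(config.target_drugs)
    data["involvement_values"] = sorted(
        {v.value for v in config.dialect.involvement_map.values()}
    )
    return data
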