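"""Ingestion, deduplication, and linkage of JADER-style report tables.

The JADER public release (and FAERS-style databases generally) ships as
linked flat tables keyed by a case identifier: DEMO (one row per submitted
case report), DRUG (one row per reported medication), and REAC (one row per
reported adverse event, coded as a MedDRA Preferred Term).  Because the
same case can be reported from several sources and resubmitted in later
quarters, DEMO contains duplicate case identifiers that must be collapsed
before any counting.

This module reads the three tables into pandas DataFrames with canonical
column names, removes duplicate case submissions (keeping the latest
report version), and links the tables into a :class:`CaseDatabase` — the
case-level container the downstream screening operates on.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Involvement",
    "DemoRecord",
    "DrugRecord",
    "ReacRecord",
    "CaseReport",
    "CaseDatabase",
    "TableDialect",
    "SchemaError",
    "parse_table",
    "deduplicate",
    "link_tables",
    "filter_window",
    "write_tables",
    "DEMO_COLUMNS",
    "DRUG_COLUMNS",
    "REAC_COLUMNS",
]


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


class Involvement(str, enum.Enum):
    """Reporter-assigned causal role of a drug within a case report.

    JADER classifies each medication on a report as suspected medicine,
    concomitant medicine, or interaction.  Only suspected medicines enter
    the disproportionality counts; restricting to them limits the masking
    of one drug's signal by co-reported products.
    """

    SUSPECTED = "suspected"
    CONCOMITANT = "concomitant"
    INTERACTION = "interaction"


#: Canonical column order for each table kind.
DEMO_COLUMNS = (
    "case_id",
    "report_version",
    "sex",
    "age_band",
    "weight_band",
    "height_band",
    "report_year",
    "report_quarter",
)
DRUG_COLUMNS = ("case_id", "drug_name", "involvement")
REAC_COLUMNS = ("case_id", "preferred_term", "outcome")

_COLUMNS = {"demo": DEMO_COLUMNS, "drug": DRUG_COLUMNS, "reac": REAC_COLUMNS}

#: Involvement strings accepted out of the box (case-insensitive).  Real
#: releases use Japanese category labels; map them via
#: ``TableDialect.involvement_map``.
_DEFAULT_INVOLVEMENT_MAP = {
    "suspected": Involvement.SUSPECTED,
    "suspected medicine": Involvement.SUSPECTED,
    "concomitant": Involvement.CONCOMITANT,
    "concomitant medicine": Involvement.CONCOMITANT,
    "interaction": Involvement.INTERACTION,
}


@dataclass(frozen=True)
class TableDialect:
    """File-format and header configuration for the three input tables.

    Parameters
    ----------
    sep, encoding
        CSV delimiter and text encoding.  The default is comma-separated
        UTF-8; real JADER releases use a Japanese legacy encoding, which
        can be selected here (e.g. ``encoding="cp932"``).
    column_maps
        Per-table mapping from canonical column name to the header actually
        present in the file, e.g. ``{"demo": {"case_id": "識別番号"}}``.
        Unmapped canonical names are looked up verbatim.
    involvement_map
        Mapping from the involvement strings found in the DRUG table
        (matched case-insensitively after trimming) to
        :class:`Involvement` categories.
    """

    sep: str = ","
    encoding: str = "utf-8"
    column_maps: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    involvement_map: Mapping[str, Involvement] = field(
        default_factory=lambda: dict(_DEFAULT_INVOLVEMENT_MAP)
    )

    def source_column(self, table_kind: str, canonical: str) -> str:
        return self.column_maps.get(table_kind, {}).get(canonical, canonical)


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class DemoRecord:
    """One row of the DEMO table: a submitted case report's demographics.

    Age, weight, and height are released as categorical bands (decades,
    kg-ranges, cm-ranges) and are treated as opaque strings throughout —
    they are never parsed back into numbers.
    """

    case_id: str
    report_version: int
    sex: str
    age_band: str
    weight_band: str
    height_band: str
    report_quarter: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.report_version < 0:
            raise ValueError("report_version must be non-negative")
        year, quarter = self.report_quarter
        if not 1 <= quarter <= 4:
            raise ValueError(f"quarter must be in 1..4, got {quarter}")


@dataclass(frozen=True)
class DrugRecord:
    """One row of the DRUG table: a medication reported on a case."""

    case_id: str
    drug_name: str
    involvement: Involvement

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        object.__setattr__(self, "involvement", Involvement(self.involvement))


@dataclass(frozen=True)
class ReacRecord:
    """One row of the REAC table: an adverse event coded as a MedDRA PT."""

    case_id: str
    preferred_term: str
    outcome: str | None = None

    def __post_init__(self) -> None:
        pt = " ".join(self.preferred_term.split())
        if not pt:
            raise ValueError("preferred_term must be non-empty")
        object.__setattr__(self, "preferred_term", pt)


@dataclass(frozen=True)
class CaseReport:
    """A deduplicated case with its demographics, drugs, and events."""

    case_id: str
    demographics: DemoRecord
    drugs: tuple[DrugRecord, ...]
    events: tuple[ReacRecord, ...]

    def __post_init__(self) -> None:
        for rec in (self.demographics, *self.drugs, *self.events):
            if rec.case_id != self.case_id:
                raise ValueError(
                    f"member record case_id {rec.case_id!r} != {self.case_id!r}"
                )


def _read_csv(path: str | Path, table_kind: str, dialect: TableDialect) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table_kind} table not found: {path}")
    raw = pd.read_csv(
        path, sep=dialect.sep, encoding=dialect.encoding, dtype=str, keep_default_na=False
    )
    rename = {}
    for canonical in _COLUMNS[table_kind]:
        source = dialect.source_column(table_kind, canonical)
        if source not in raw.columns:
            raise SchemaError(
                f"{table_kind} table {path} is missing column {source!r}"
                f" (canonical {canonical!r})"
            )
        rename[source] = canonical
    return raw.rename(columns=rename)[list(_COLUMNS[table_kind])]


def parse_table(
    path: str | Path,
    table_kind: str,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> pd.DataFrame:
    """Read one of the three tables into a canonical-column DataFrame.

    Rows with an empty case identifier are dropped (their count is logged).
    DRUG rows whose involvement string is not recognised by the dialect's
    involvement map are dropped with a warning; recognised strings are
    normalised to the canonical ``suspected`` / ``concomitant`` /
    ``interaction`` values.

    Parameters
    ----------
    path
        CSV file to read.
    table_kind
        One of ``"demo"``, ``"drug"``, ``"reac"``.
    dialect
        Separator, encoding, header aliases, and involvement-label mapping.

    Returns
    -------
    pandas.DataFrame
        One row per retained data row, columns as in :data:`DEMO_COLUMNS`,
        :data:`DRUG_COLUMNS`, or :data:`REAC_COLUMNS`.
    """
    if table_kind not in _COLUMNS:
        raise ValueError(f"unknown table_kind {table_kind!r}")
    df = _read_csv(path, table_kind, dialect)
    df["case_id"] = df["case_id"].str.strip()
    blank = df["case_id"] == ""
    if blank.any():
        logger.info(
            "%s table %s: dropped %d row(s) with empty case_id",
            table_kind, path, int(blank.sum()),
        )
        df = df[~blank]

    if table_kind == "demo":
        df = df.assign(
            report_version=pd.to_numeric(df["report_version"]).astype(int),
            report_year=pd.to_numeric(df["report_year"]).astype(int),
            report_quarter=pd.to_numeric(df["report_quarter"]).astype(int),
        )
        bad_q = ~df["report_quarter"].between(1, 4)
        if bad_q.any():
            raise SchemaError(
                f"demo table {path}: report_quarter outside 1..4 in "
                f"{int(bad_q.sum())} row(s)"
            )
    elif table_kind == "drug":
        inv_map = {k.casefold(): Involvement(v).value for k, v in dialect.involvement_map.items()}
        normalized = df["involvement"].str.strip().str.casefold().map(inv_map)
        unmapped = normalized.isna()
        if unmapped.any():
            for value in df.loc[unmapped, "involvement"].unique():
                logger.warning(
                    "drug table %s: unmappable involvement %r — row(s) dropped",
                    path, value,
                )
            df, normalized = df[~unmapped], normalized[~unmapped]
        df = df.assign(drug_name=df["drug_name"].str.strip(), involvement=normalized)
    else:  # reac
        df = df.assign(
            preferred_term=df["preferred_term"].str.split().str.join(" "),
            outcome=df["outcome"].replace("", None),
        )
        empty_pt = df["preferred_term"] == ""
        if empty_pt.any():
            logger.info(
                "reac table %s: dropped %d row(s) with empty preferred_term",
                path, int(empty_pt.sum()),
            )
            df = df[~empty_pt]

    return df.reset_index(drop=True)


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Collapse resubmitted case reports to one DEMO row per case.

    The same case arrives repeatedly (different sources, later quarterly
    resubmissions); among rows sharing a ``case_id`` the one with the
    highest ``report_version`` is kept, ties broken by last occurrence in
    file order.  Output is sorted by ``case_id`` so the result is
    deterministic regardless of input ordering.
    """
    if demo.empty:
        return demo.reset_index(drop=True)
    kept = (
        demo.assign(_order=range(len(demo)))
        .sort_values(["case_id", "report_version", "_order"], kind="stable")
        .groupby("case_id", sort=True)
        .tail(1)
        .drop(columns="_order")
    )
    n_removed = len(demo) - len(kept)
    if n_removed:
        logger.info("deduplicate: removed %d duplicate DEMO row(s)", n_removed)
    return kept.sort_values("case_id", kind="stable").reset_index(drop=True)


class CaseDatabase:
    """Linked, deduplicated case-level view of the three tables.

    Holds the DEMO spine plus the DRUG and REAC rows restricted to linked
    cases, with within-case exact-duplicate rows collapsed.  Iterating
    yields :class:`CaseReport` objects; the underlying frames remain
    available (``.demo``, ``.drug``, ``.reac``) for vectorised operations.
    """

    def __init__(
        self,
        demo: pd.DataFrame,
        drug: pd.DataFrame,
        reac: pd.DataFrame,
        orphan_drug_count: int = 0,
        orphan_reac_count: int = 0,
    ) -> None:
        self.demo = demo.reset_index(drop=True)
        self.drug = drug.reset_index(drop=True)
        self.reac = reac.reset_index(drop=True)
        self.orphan_drug_count = orphan_drug_count
        self.orphan_reac_count = orphan_reac_count

    def __len__(self) -> int:
        return len(self.demo)

    @property
    def case_ids(self) -> list[str]:
        return self.demo["case_id"].tolist()

    def __iter__(self) -> Iterator[CaseReport]:
        drugs_by_case = {cid: grp for cid, grp in self.drug.groupby("case_id", sort=False)}
        reacs_by_case = {cid: grp for cid, grp in self.reac.groupby("case_id", sort=False)}
        for row in self.demo.itertuples(index=False):
            demo_rec = DemoRecord(
                case_id=row.case_id,
                report_version=int(row.report_version),
                sex=row.sex,
                age_band=row.age_band,
                weight_band=row.weight_band,
                height_band=row.height_band,
                report_quarter=(int(row.report_year), int(row.report_quarter)),
            )
            dgrp = drugs_by_case.get(row.case_id)
            rgrp = reacs_by_case.get(row.case_id)
            drugs = tuple(
                DrugRecord(r.case_id, r.drug_name, Involvement(r.involvement))
                for r in dgrp.itertuples(index=False)
            ) if dgrp is not None else ()
            events = tuple(
                ReacRecord(r.case_id, r.preferred_term, r.outcome)
                for r in rgrp.itertuples(index=False)
            ) if rgrp is not None else ()
            yield CaseReport(row.case_id, demo_rec, drugs, events)

    def case(self, case_id: str) -> CaseReport:
        for report in self:
            if report.case_id == case_id:
                return report
        raise KeyError(case_id)


def link_tables(
    demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame
) -> CaseDatabase:
    """Link DRUG and REAC rows to the deduplicated DEMO spine by case id.

    Every DEMO row becomes a case; DRUG/REAC rows whose case id has no
    DEMO row are orphans — they are dropped and counted (DEMO is the
    linkage spine, so a case without demographics does not exist for the
    analysis).  Cases with zero drugs or zero events are retained; they
    simply contribute no co-occurrence units downstream.  Within a case,
    exact-duplicate drug rows (same name and involvement) and event rows
    (same preferred term) are collapsed to one.
    """
    if demo["case_id"].duplicated().any():
        raise ValueError("demo must be deduplicated before linking")
    known = set(demo["case_id"])

    drug_linked = drug[drug["case_id"].isin(known)]
    reac_linked = reac[reac["case_id"].isin(known)]
    orphan_drug = len(drug) - len(drug_linked)
    orphan_reac = len(reac) - len(reac_linked)
    if orphan_drug or orphan_reac:
        logger.info(
            "link_tables: dropped %d orphan drug row(s) and %d orphan reac row(s)",
            orphan_drug, orphan_reac,
        )

    drug_linked = drug_linked.drop_duplicates(["case_id", "drug_name", "involvement"])
    reac_linked = reac_linked.drop_duplicates(["case_id", "preferred_term"])

    return CaseDatabase(
        demo.sort_values("case_id", kind="stable"),
        drug_linked,
        reac_linked,
        orphan_drug_count=orphan_drug,
        orphan_reac_count=orphan_reac,
    )


def filter_window(
    cases: CaseDatabase,
    start: tuple[int, int],
    end: tuple[int, int],
) -> CaseDatabase:
    """Restrict to cases reported in the closed quarter window [start, end].

    ``start`` and ``end`` are ``(year, quarter)`` pairs compared
    lexicographically; a case at exactly the start or end quarter is kept.
    """
    if start > end:
        raise ValueError(f"window start {start} is after end {end}")
    yq = list(zip(cases.demo["report_year"], cases.demo["report_quarter"]))
    keep = pd.Series([start <= q <= end for q in yq], index=cases.demo.index)
    demo = cases.demo[keep]
    kept_ids = set(demo["case_id"])
    return CaseDatabase(
        demo,
        cases.drug[cases.drug["case_id"].isin(kept_ids)],
        cases.reac[cases.reac["case_id"].isin(kept_ids)],
        orphan_drug_count=cases.orphan_drug_count,
        orphan_reac_count=cases.orphan_reac_count,
    )


def write_tables(
    db: CaseDatabase | tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
    out_dir: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> tuple[Path, Path, Path]:
    """Write the three tables back to CSV (demo.csv, drug.csv, reac.csv).

    The output uses canonical headers and round-trips through
    :func:`parse_table` / :func:`link_tables`.
    """
    if isinstance(db, CaseDatabase):
        frames = (db.demo, db.drug, db.reac)
    else:
        frames = db
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame, name in zip(frames, ("demo", "drug", "reac")):
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, sep=dialect.sep, encoding=dialect.encoding)
        paths.append(path)
    return tuple(paths)
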