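"""Reporting-odds-ratio disproportionality analysis.

The reporting odds ratio (ROR) compares how often an event of interest is
reported with a target drug against how often the same event is reported
with every other drug in the database.  From the 2×2 table

    =============  ============  ============
                   target event  other events
    target drug         a             b
    other drugs         c             d
    =============  ============  ============

ROR = (a/b) / (c/d) = ad/bc, with the Wald 95% confidence interval
exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d)), z = 1.96.  A drug–event pair
is a *signal* when the lower CI bound exceeds 1.  The ROR measures
disproportionate reporting, not clinical risk: spontaneous databases have
no denominator population.

The counting unit filling the cells is the distinct
(case, suspected drug, Preferred Term) co-occurrence; only drugs recorded
as *suspected* contribute, which limits masking by co-reported products.
A case-level unit (one count per case × drug × event class) is available
behind the ``unit`` option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from rorscreen.event_dictionary import EventDictionary
from rorscreen.jader_io import CaseDatabase, Involvement

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "extract_cooccurrences",
    "build_contingency",
    "compute_ror",
    "screen",
    "signals_frame",
    "event_class_share",
    "Z_95",
]

#: Standard-normal quantile used for the 95% Wald interval.
Z_95 = 1.96

#: Columns of the co-occurrence unit frame.
UNIT_COLUMNS = ("case_id", "drug_name", "preferred_term", "event_class")


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of one drug × event-class 2×2 table.

    ``a``: target drug & target event class; ``b``: target drug & other
    events; ``c``: other drugs & target class; ``d``: other drugs & other
    events.  Cells may be half-integers after a continuity correction.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative: {getattr(self, name)}")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def corrected(self, delta: float = 0.5) -> "ContingencyTable":
        """Return the table with ``delta`` added to every cell."""
        return ContingencyTable(self.a + delta, self.b + delta, self.c + delta, self.d + delta)


@dataclass(frozen=True)
class SignalResult:
    """ROR estimate and signal flag for one drug / event-class pair.

    ``n`` is the raw report count in cell *a* (before any continuity
    correction); ``ror``/``ci_low``/``ci_high`` are ``None`` when the
    estimate is undefined (a zero cell under ``correction="none"``).
    ``signal`` is true exactly when the lower CI bound is defined and
    exceeds 1.  ``eligible`` marks pairs meeting the configured minimum
    report count.
    """

    drug_name: str | None
    event_class: str | None
    n: int
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    corrected: bool
    signal: bool
    table: ContingencyTable | None = None
    eligible: bool = True


def extract_cooccurrences(
    cases: CaseDatabase, dictionary: EventDictionary
) -> pd.DataFrame:
    """Enumerate distinct (case, suspected drug, PT) co-occurrence units.

    Each unit carries the event class assigned by the dictionary (or
    ``None`` for unlisted PTs).  Concomitant and interaction drug records
    contribute nothing.

    Returns
    -------
    pandas.DataFrame
        Columns ``case_id, drug_name, preferred_term, event_class``; one
        row per distinct triple.
    """
    suspected = cases.drug.loc[
        cases.drug["involvement"] == Involvement.SUSPECTED.value,
        ["case_id", "drug_name"],
    ]
    units = suspected.merge(
        cases.reac[["case_id", "preferred_term"]], on="case_id", how="inner"
    ).drop_duplicates(["case_id", "drug_name", "preferred_term"])
    lookup = dictionary.lookup_table()
    normalized = units["preferred_term"].str.split().str.join(" ").str.casefold()
    units = units.assign(event_class=normalized.map(lookup))
    units["event_class"] = units["event_class"].astype(object).where(
        units["event_class"].notna(), None
    )
    return units.reset_index(drop=True)[list(UNIT_COLUMNS)]


def build_contingency(
    units: pd.DataFrame, drug_name: str, event_class: str
) -> ContingencyTable:
    """Count the 2×2 cells for one drug / event-class pair.

    The four cells partition the co-occurrence units, so
    ``a + b + c + d`` equals the number of units.
    """
    if units.empty:
        raise ValueError("co-occurrence units are empty")
    is_drug = (units["drug_name"] == drug_name).to_numpy()
    is_class = (units["event_class"] == event_class).to_numpy()
    a = int((is_drug & is_class).sum())
    b = int((is_drug & ~is_class).sum())
    c = int((~is_drug & is_class).sum())
    d = int((~is_drug & ~is_class).sum())
    return ContingencyTable(a, b, c, d)


def compute_ror(
    table: ContingencyTable,
    z: float = Z_95,
    correction: str = "haldane_if_zero",
    drug_name: str | None = None,
    event_class: str | None = None,
) -> SignalResult:
    """ROR point estimate, Wald CI, and signal flag for one 2×2 table.

    Parameters
    ----------
    table
        Non-negative cell counts.
    z
        Normal quantile for the CI (1.96 for 95% coverage).
    correction
        ``"haldane_if_zero"`` (default): when any cell is 0, add 0.5 to
        every cell (Haldane–Anscombe) and flag the result as corrected so
        sparse pairs stay reportable but marked.  ``"none"``: a zero cell
        leaves ROR and CI undefined and the pair cannot be a signal.
    """
    if correction not in ("none", "haldane_if_zero"):
        raise ValueError(f"unknown correction policy {correction!r}")
    n = int(table.a)
    corrected = False
    work = table
    if work.has_zero_cell:
        if correction == "none":
            return SignalResult(
                drug_name, event_class, n,
                ror=None, ci_low=None, ci_high=None,
                corrected=False, signal=False, table=table,
            )
        work = table.corrected(0.5)
        corrected = True
    ror = (work.a * work.d) / (work.b * work.c)
    se = math.sqrt(1 / work.a + 1 / work.b + 1 / work.c + 1 / work.d)
    log_ror = math.log(ror)
    ci_low = math.exp(log_ror - z * se)
    ci_high = math.exp(log_ror + z * se)
    return SignalResult(
        drug_name, event_class, n,
        ror=ror, ci_low=ci_low, ci_high=ci_high,
        corrected=corrected, signal=ci_low > 1, table=table,
    )


def _collapse_to_case_units(units: pd.DataFrame) -> pd.DataFrame:
    # Case-level alternative unit: one count per (case, drug, event class);
    # unlisted PTs keep their own term as the event key.
    key = units["event_class"].astype(object).where(
        units["event_class"].notna(), units["preferred_term"]
    )
    collapsed = units.assign(_event_key=key).drop_duplicates(
        ["case_id", "drug_name", "_event_key"]
    )
    return collapsed.drop(columns="_event_key").reset_index(drop=True)


def screen(
    cases: CaseDatabase | pd.DataFrame,
    dictionary: EventDictionary,
    drugs: Sequence[str],
    *,
    z: float = Z_95,
    correction: str = "haldane_if_zero",
    min_count: int = 1,
    unit: str = "cooccurrence",
) -> list[SignalResult]:
    """Screen every (target drug, event class) pair for a signal.

    Parameters
    ----------
    cases
        A linked :class:`~rorscreen.jader_io.CaseDatabase`, or a
        precomputed co-occurrence frame from
        :func:`extract_cooccurrences`.
    dictionary
        Event classes to screen.
    drugs
        Target drug names; each is compared against all other drugs in the
        database.
    min_count
        Pairs with fewer than this many reports in cell *a* are still
        emitted but flagged ineligible.
    unit
        ``"cooccurrence"`` (distinct case × drug × PT triples, default) or
        ``"case"`` (one count per case × drug × event class).

    Returns
    -------
    list of :class:`SignalResult`
        One result per pair, ordered by drug (input order) then by
        descending report count.
    """
    if unit not in ("cooccurrence", "case"):
        raise ValueError(f"unknown counting unit {unit!r}")
    if isinstance(cases, CaseDatabase):
        units = extract_cooccurrences(cases, dictionary)
    else:
        units = cases
    if unit == "case" and not units.empty:
        units = _collapse_to_case_units(units)

    results: list[SignalResult] = []
    if units.empty:
        logger.warning("screen: no co-occurrence units — emitting no results")
        return results

    known_drugs = set(units["drug_name"])
    for drug in drugs:
        if drug not in known_drugs:
            logger.warning("screen: drug %r has no suspected co-occurrences", drug)
        drug_results = []
        for class_name in dictionary.class_names:
            table = build_contingency(units, drug, class_name)
            result = compute_ror(
                table, z=z, correction=correction,
                drug_name=drug, event_class=class_name,
            )
            if result.n < min_count:
                result = replace(result, eligible=False)
            drug_results.append(result)
        drug_results.sort(key=lambda r: (-r.n, r.event_class))
        results.extend(drug_results)
    return results


def signals_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Tabulate screen results (one row per drug / event-class pair)."""
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "drug": r.drug_name,
                "event_class": r.event_class,
                "a": None if t is None else t.a,
                "b": None if t is None else t.b,
                "c": None if t is None else t.c,
                "d": None if t is None else t.d,
                "n": r.n,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "corrected": r.corrected,
                "signal": r.signal,
                "eligible": r.eligible,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "event_class", "a", "b", "c", "d", "n",
            "ror", "ci_low", "ci_high", "corrected", "signal", "eligible",
        ],
    )


def event_class_share(n_class: int, n_total: int) -> float:
    """Percentage share of an event class among all co-occurrences.

    Returns ``100 * n_class / n_total`` rounded half-up to one decimal
    (the rounding convention of published report tables, where e.g.
    657/2771 prints as 23.7).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_class <= n_total:
        raise ValueError("n_class must lie in [0, n_total]")
    share = (Decimal(n_class) * 100) / Decimal(n_total)
    return float(share.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
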