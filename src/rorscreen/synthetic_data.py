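"""Seeded generator of JADER-schema databases with known ground truth.

The generator emits the three linked tables (DEMO, DRUG, REAC) for a
configurable number of cases.  Each case carries one or more suspected
drugs drawn from a weighted catalog; each adverse event (a MedDRA PT)
occurs independently with a baseline per-case probability, except that a
drug g carrying an odds multiplier θ for PT e changes the occurrence
probability on cases with g to p' = θp / (1 − p + θp) — i.e. the odds of
the event are multiplied by θ.  Because the reporting odds ratio is an
odds ratio over reported co-occurrences, an injected θ on a rare event is
(approximately) the quantity the screen should recover, which is what
makes the generator a ground-truthed test bed for the whole pipeline.

Duplicate case submissions (same case id, higher report version),
concomitant drug records, and uniformly spread reporting quarters are
included so that deduplication, the suspected-only filter, and the
analysis window all operate on non-trivial input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rorscreen.jader_io import DEMO_COLUMNS, DRUG_COLUMNS, REAC_COLUMNS, Involvement

__all__ = [
    "SimulationConfig",
    "SyntheticFixture",
    "simulate_database",
    "make_paper_like_fixture",
]

_SEXES = ("male", "female", "unknown")
_SEX_P = (0.42, 0.48, 0.10)
_AGE_BANDS = ("20s", "30s", "40s", "50s", "60s", "70s", "80s")
_AGE_P = (0.08, 0.13, 0.17, 0.2, 0.22, 0.14, 0.06)
_WEIGHT_BANDS = ("40-49kg", "50-59kg", "60-69kg", "70-79kg", "80kg+")
_WEIGHT_P = (0.15, 0.3, 0.3, 0.17, 0.08)
_HEIGHT_BANDS = ("140-149cm", "150-159cm", "160-169cm", "170-179cm", "180cm+")
_HEIGHT_P = (0.08, 0.3, 0.34, 0.23, 0.05)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic database.

    Parameters
    ----------
    n_cases
        Number of distinct cases (duplicates add DEMO rows on top).
    drug_catalog
        ``(drug_name, prevalence_weight)`` pairs; weights are normalised.
    n_drugs_per_case
        Either a fixed integer or a ``{count: probability}`` distribution
        over the number of suspected drugs per case (drawn without
        replacement from the catalog).
    baseline_event_probs
        Per-case occurrence probability for each MedDRA PT, absent any
        multiplier.
    odds_multipliers
        ``(drug_name, preferred_term) -> θ``; carrying the drug multiplies
        the event's occurrence odds by θ.  Multipliers from several
        carried drugs on the same PT compound multiplicatively.
    duplicate_rate
        Probability that a case is re-submitted: its rows are emitted
        twice, with report versions 1 and 2.
    concomitant_rate
        Probability that a case carries one additional concomitant
        (non-suspected) drug drawn from the catalog.
    window
        Inclusive ``((year, quarter), (year, quarter))`` range over which
        reporting quarters are assigned uniformly.
    seed
        Seed for the single random generator; identical configs produce
        byte-identical output tables.
    """

    n_cases: int
    drug_catalog: Sequence[tuple[str, float]]
    baseline_event_probs: Mapping[str, float]
    n_drugs_per_case: int | Mapping[int, float] = 1
    odds_multipliers: Mapping[tuple[str, str], float] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    concomitant_rate: float = 0.0
    window: tuple[tuple[int, int], tuple[int, int]] = ((2014, 3), (2018, 4))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not self.drug_catalog:
            raise ValueError("drug_catalog must be non-empty")
        weights = [w for _, w in self.drug_catalog]
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ValueError("prevalence weights must be non-negative with positive sum")
        names = [d for d, _ in self.drug_catalog]
        if len(set(names)) != len(names):
            raise ValueError("drug_catalog names must be unique")
        for pt, p in self.baseline_event_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"baseline probability for {pt!r} outside [0, 1]: {p}")
        for (drug, pt), theta in self.odds_multipliers.items():
            if theta <= 0:
                raise ValueError(f"odds multiplier for ({drug!r}, {pt!r}) must be > 0")
            if drug not in names:
                raise ValueError(f"multiplier names unknown drug {drug!r}")
            if pt not in self.baseline_event_probs:
                raise ValueError(f"multiplier names unknown preferred term {pt!r}")
        for name, rate in (("duplicate_rate", self.duplicate_rate),
                           ("concomitant_rate", self.concomitant_rate)):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} outside [0, 1]: {rate}")
        if isinstance(self.n_drugs_per_case, int):
            if not 1 <= self.n_drugs_per_case <= len(names):
                raise ValueError("n_drugs_per_case outside 1..catalog size")
        else:
            ks = list(self.n_drugs_per_case)
            ps = [self.n_drugs_per_case[k] for k in ks]
            if any(k < 1 or k > len(names) for k in ks):
                raise ValueError("drugs-per-case counts outside 1..catalog size")
            if any(p < 0 for p in ps) or abs(sum(ps) - 1) > 1e-9:
                raise ValueError("drugs-per-case probabilities must sum to 1")
        start, end = self.window
        if start > end:
            raise ValueError(f"window start {start} after end {end}")
        for _, q in (start, end):
            if not 1 <= q <= 4:
                raise ValueError("window quarters must be in 1..4")


def _quarter_range(start: tuple[int, int], end: tuple[int, int]) -> list[tuple[int, int]]:
    quarters = []
    year, quarter = start
    while (year, quarter) <= end:
        quarters.append((year, quarter))
        quarter += 1
        if quarter == 5:
            year, quarter = year + 1, 1
    return quarters


def simulate_database(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic database as (demo, drug, reac) DataFrames.

    The frames use the canonical column layout of
    :mod:`rorscreen.jader_io` and can be written with
    :func:`~rorscreen.jader_io.write_tables` or fed straight into
    :func:`~rorscreen.jader_io.deduplicate` /
    :func:`~rorscreen.jader_io.link_tables`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    names = np.array([d for d, _ in config.drug_catalog], dtype=object)
    weights = np.array([w for _, w in config.drug_catalog], dtype=float)
    weights = weights / weights.sum()
    n_drugs = len(names)

    case_ids = np.array([f"C{i:07d}" for i in range(n)], dtype=object)

    # Suspected drugs per case: weighted sampling without replacement via
    # Gumbel-perturbed log-weights (top-k per row).
    if isinstance(config.n_drugs_per_case, int):
        k = np.full(n, config.n_drugs_per_case)
    else:
        ks = np.array(sorted(config.n_drugs_per_case))
        ps = np.array([config.n_drugs_per_case[int(x)] for x in ks], dtype=float)
        k = rng.choice(ks, size=n, p=ps / ps.sum())
    with np.errstate(divide="ignore"):
        log_w = np.log(weights)
    scores = log_w[None, :] + rng.gumbel(size=(n, n_drugs))
    ranks = np.argsort(np.argsort(-scores, axis=1, kind="stable"), axis=1)
    has_drug = ranks < k[:, None]

    # Event occurrence probabilities: baseline, with odds multiplied per
    # carried drug (compounding across drugs).
    pts = list(config.baseline_event_probs)
    pt_index = {pt: j for j, pt in enumerate(pts)}
    drug_index = {name: j for j, name in enumerate(names)}
    probs = np.tile(
        np.array([config.baseline_event_probs[pt] for pt in pts], dtype=float), (n, 1)
    )
    for (drug, pt), theta in config.odds_multipliers.items():
        mask = has_drug[:, drug_index[drug]]
        p = probs[mask, pt_index[pt]]
        probs[mask, pt_index[pt]] = theta * p / (1 - p + theta * p)
    occurs = rng.random((n, len(pts))) < probs

    # Demographics and reporting quarter.
    sex = rng.choice(_SEXES, size=n, p=_SEX_P)
    age = rng.choice(_AGE_BANDS, size=n, p=_AGE_P)
    weight = rng.choice(_WEIGHT_BANDS, size=n, p=_WEIGHT_P)
    height = rng.choice(_HEIGHT_BANDS, size=n, p=_HEIGHT_P)
    quarters = _quarter_range(*config.window)
    q_idx = rng.integers(len(quarters), size=n)
    years = np.array([quarters[i][0] for i in q_idx])
    qtrs = np.array([quarters[i][1] for i in q_idx])

    conc_mask = rng.random(n) < config.concomitant_rate
    conc_drug = rng.choice(n_drugs, size=n, p=weights)
    dup_mask = rng.random(n) < config.duplicate_rate

    demo = pd.DataFrame(
        {
            "case_id": case_ids,
            "report_version": np.ones(n, dtype=int),
            "sex": sex,
            "age_band": age,
            "weight_band": weight,
            "height_band": height,
            "report_year": years,
            "report_quarter": qtrs,
        },
        columns=list(DEMO_COLUMNS),
    )

    sus_case, sus_drug = np.nonzero(has_drug)
    drug_rows = pd.DataFrame(
        {
            "case_id": case_ids[sus_case],
            "drug_name": names[sus_drug],
            "involvement": Involvement.SUSPECTED.value,
        },
        columns=list(DRUG_COLUMNS),
    )
    if conc_mask.any():
        conc_rows = pd.DataFrame(
            {
                "case_id": case_ids[conc_mask],
                "drug_name": names[conc_drug[conc_mask]],
                "involvement": Involvement.CONCOMITANT.value,
            },
            columns=list(DRUG_COLUMNS),
        )
        drug_rows = pd.concat([drug_rows, conc_rows], ignore_index=True)

    ev_case, ev_pt = np.nonzero(occurs)
    reac_rows = pd.DataFrame(
        {
            "case_id": case_ids[ev_case],
            "preferred_term": np.array(pts, dtype=object)[ev_pt],
            "outcome": "unknown",
        },
        columns=list(REAC_COLUMNS),
    )

    # Re-submitted cases: identical rows emitted again with version 2.
    if dup_mask.any():
        dup_ids = set(case_ids[dup_mask])
        demo_dup = demo[dup_mask].assign(report_version=2)
        demo = pd.concat([demo, demo_dup], ignore_index=True)
        drug_rows = pd.concat(
            [drug_rows, drug_rows[drug_rows["case_id"].isin(dup_ids)]],
            ignore_index=True,
        )
        reac_rows = pd.concat(
            [reac_rows, reac_rows[reac_rows["case_id"].isin(dup_ids)]],
            ignore_index=True,
        )

    return demo, drug_rows.reset_index(drop=True), reac_rows.reset_index(drop=True)


@dataclass(frozen=True)
class SyntheticFixture:
    """A generated database bundled with its generating configuration."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    config: SimulationConfig
    target_drugs: tuple[str, ...]
    class_multipliers: Mapping[tuple[str, str], float]


#: Injected class-level odds multipliers of the demonstration fixture.
#: For the first target drug, tuberculosis carries by far the largest
#: multiplier, echoing the rank order seen in real anti-TNF surveillance.
_FIXTURE_CLASS_THETA = {
    ("IFX originator", "Tuberculosis"): 25.0,
    ("IFX originator", "Pneumonia"): 3.6,
    ("IFX originator", "Infection"): 3.5,
    ("IFX originator", "Sepsis"): 2.4,
    ("IFX originator", "Interstitial lung disease"): 2.3,
    ("IFX biosimilar 1", "Pneumonia"): 4.7,
    ("IFX biosimilar 1", "Sepsis"): 4.1,
    ("IFX biosimilar 1", "Tuberculosis"): 8.9,
    ("IFX biosimilar 1", "Interstitial lung disease"): 2.2,
    ("IFX biosimilar 1", "Infection"): 1.5,
}

_FIXTURE_CLASS_PTS = {
    "Pneumonia": {"Pneumonia": 0.010, "Pneumocystis jirovecii pneumonia": 0.003},
    "Interstitial lung disease": {"Interstitial lung disease": 0.008},
    "Tuberculosis": {"Tuberculosis": 0.003, "Pulmonary tuberculosis": 0.002},
    "Infection": {"Infection": 0.006, "Urinary tract infection": 0.004},
    "Sepsis": {"Sepsis": 0.004, "Septic shock": 0.002},
}

_FIXTURE_BACKGROUND_PTS = {
    "Drug ineffective": 0.08,
    "Rash": 0.06,
    "Hepatic function abnormal": 0.05,
    "Nausea": 0.05,
    "Pyrexia": 0.05,
    "Headache": 0.04,
}


def make_paper_like_fixture(n_cases: int = 2000, seed: int = 20140703) -> SyntheticFixture:
    """A small fixed fixture shaped like a biologic-surveillance screen.

    Two target biologics (an originator and its biosimilar) sit in a
    catalog with three background immunosuppressants; events cover the
    five default infection classes plus common background PTs.  Injected
    class-level odds multipliers give the first drug its strongest
    association with tuberculosis.  Fully reproducible from the fixed
    seed; the ground-truth multipliers travel with the returned object.
    """
    baseline: dict[str, float] = {}
    multipliers: dict[tuple[str, str], float] = {}
    for class_name, pt_probs in _FIXTURE_CLASS_PTS.items():
        for pt, p in pt_probs.items():
            baseline[pt] = p
            for (drug, cls), theta in _FIXTURE_CLASS_THETA.items():
                if cls == class_name:
                    multipliers[(drug, pt)] = theta
    baseline.update(_FIXTURE_BACKGROUND_PTS)

    config = SimulationConfig(
        n_cases=n_cases,
        drug_catalog=(
            ("IFX originator", 0.22),
            ("IFX biosimilar 1", 0.10),
            ("methotrexate", 0.30),
            ("prednisolone", 0.23),
            ("adalimumab", 0.15),
        ),
        baseline_event_probs=baseline,
        n_drugs_per_case={1: 0.8, 2: 0.15, 3: 0.05},
        odds_multipliers=multipliers,
        duplicate_rate=0.05,
        concomitant_rate=0.20,
        seed=seed,
    )
    demo, drug, reac = simulate_database(config)
    return SyntheticFixture(
        demo=demo,
        drug=drug,
        reac=reac,
        config=config,
        target_drugs=("IFX originator", "IFX biosimilar 1"),
        class_multipliers=dict(_FIXTURE_CLASS_THETA),
    )
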