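"""Co-occurrence extraction, 2×2 tables, ROR estimation, screening."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from rorscreen import (
    ContingencyTable,
    build_contingency,
    compute_ror,
    event_class_share,
    extract_cooccurrences,
    link_tables,
    load_dictionary,
    screen,
    signals_frame,
)
from conftest import demo_frame, drug_frame, reac_frame

SMALL_DICT = load_dictionary({"P class": ["PT P"], "Q class": ["PT Q"]})


def small_db(drug_rows, reac_rows):
    case_ids = sorted({r[0] for r in drug_rows} | {r[0] for r in reac_rows})
    return link_tables(
        demo_frame([(cid, 1, 2016, 2) for cid in case_ids]),
        drug_frame(drug_rows),
        reac_frame(reac_rows),
    )


class TestExtractCooccurrences:
    def test_one_drug_two_events_gives_two_units(self):
        db = small_db(
            [("A", "X", "suspected")],
            [("A", "PT P"), ("A", "PT Q")],
        )
        units = extract_cooccurrences(db, SMALL_DICT)
        assert len(units) == 2
        assert set(units["event_class"]) == {"P class", "Q class"}

    def test_concomitant_only_case_gives_no_units(self):
        db = small_db([("A", "X", "concomitant")], [("A", "PT P")])
        assert len(extract_cooccurrences(db, SMALL_DICT)) == 0

    def test_two_suspected_drugs_one_event_gives_two_units(self):
        db = small_db(
            [("A", "X", "suspected"), ("A", "Y", "suspected")],
            [("A", "PT P")],
        )
        units = extract_cooccurrences(db, SMALL_DICT)
        assert len(units) == 2
        assert set(units["drug_name"]) == {"X", "Y"}

    def test_unlisted_term_gets_no_class(self):
        db = small_db([("A", "X", "suspected")], [("A", "Something else")])
        units = extract_cooccurrences(db, SMALL_DICT)
        assert units["event_class"].tolist() == [None]


# Six hand-written co-occurrence units over distinct (case, drug, PT) triples.
SIX_UNITS = pd.DataFrame(
    {
        "case_id": ["1", "2", "3", "4", "5", "6"],
        "drug_name": ["X", "X", "X", "Y", "Y", "Y"],
        "preferred_term": ["PT P", "PT P", "PT Q", "PT P", "PT Q", "PT Q"],
        "event_class": ["P class", "P class", "Q class", "P class", "Q class", "Q class"],
    }
)


class TestBuildContingency:
    def test_hand_counted_cells(self):
        table = build_contingency(SIX_UNITS, "X", "P class")
        assert (table.a, table.b, table.c, table.d) == (2, 1, 1, 2)

    def test_absent_class_gives_empty_event_column(self):
        table = build_contingency(SIX_UNITS, "X", "Z class")
        assert table.a == 0 and table.c == 0
        assert table.total == len(SIX_UNITS)

    def test_single_drug_database_has_empty_comparator(self):
        units = SIX_UNITS[SIX_UNITS["drug_name"] == "X"]
        table = build_contingency(units, "X", "P class")
        assert table.c == 0 and table.d == 0
        result = compute_ror(table, correction="none")
        assert result.ror is None and not result.signal

    def test_cells_partition_the_units(self):
        for drug in ("X", "Y"):
            for cls in ("P class", "Q class"):
                assert build_contingency(SIX_UNITS, drug, cls).total == 6


class TestComputeRor:
    def test_symmetric_table_is_exactly_null(self):
        result = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert result.ror == 1.0
        assert not result.signal
        assert result.ci_low < 1 < result.ci_high

    def test_frozen_wald_example(self):
        # Independently derived: ROR = 20*900/(80*100) = 2.25,
        # CI = exp(ln 2.25 ± 1.96 * sqrt(1/20 + 1/80 + 1/100 + 1/900)).
        result = compute_ror(ContingencyTable(20, 80, 100, 900))
        assert result.ror == pytest.approx(2.25, rel=1e-12)
        assert result.ci_low == pytest.approx(1.3220127820138894, rel=1e-12)
        assert result.ci_high == pytest.approx(3.8293880882815947, rel=1e-12)
        assert result.signal and not result.corrected

    def test_matches_statsmodels_odds_ratio_routine(self):
        """Cross-check point estimate and CI against an independent
        odds-ratio implementation (which uses the exact normal quantile,
        hence the loose tolerance on the bounds)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            ours = compute_ror(ContingencyTable(a, b, c, d))
            ref = Table2x2(np.array([[a, b], [c, d]]))
            lo, hi = ref.oddsratio_confint()
            assert ours.ror == pytest.approx(ref.oddsratio, rel=1e-12)
            assert ours.ci_low == pytest.approx(lo, rel=1e-4)
            assert ours.ci_high == pytest.approx(hi, rel=1e-4)

    def test_zero_cell_without_correction_is_undefined(self):
        result = compute_ror(ContingencyTable(0, 10, 10, 100), correction="none")
        assert result.ror is None and result.ci_low is None
        assert not result.signal
        assert result.n == 0

    def test_zero_cell_haldane_correction_flags_and_defines(self):
        result = compute_ror(ContingencyTable(0, 10, 10, 100))
        assert result.corrected
        expected = (0.5 * 100.5) / (10.5 * 10.5)
        assert result.ror == pytest.approx(expected, rel=1e-12)
        assert result.n == 0  # raw count, not the corrected cell

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ContingencyTable(-1, 2, 3, 4)

    def test_unknown_correction_policy_rejected(self):
        with pytest.raises(ValueError, match="correction"):
            compute_ror(ContingencyTable(1, 1, 1, 1), correction="yates")

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
    )
    def test_swapping_drug_rows_inverts_the_ror(self, a, b, c, d):
        forward = compute_ror(ContingencyTable(a, b, c, d))
        backward = compute_ror(ContingencyTable(c, d, a, b))
        assert forward.ror * backward.ror == pytest.approx(1.0, rel=1e-12)
        assert forward.ci_low * backward.ci_high == pytest.approx(1.0, rel=1e-12)

    def test_strictly_increasing_in_target_cell(self):
        rors = [
            compute_ror(ContingencyTable(a, 50, 30, 700)).ror for a in range(1, 40, 3)
        ]
        assert all(x < y for x, y in zip(rors, rors[1:]))


class TestScreen:
    def test_pair_cardinality(self, paper_like_db, default_dictionary, paper_like):
        results = screen(paper_like_db, default_dictionary, list(paper_like.target_drugs))
        assert len(results) == 10  # 2 drugs x 5 classes

    def test_results_ordered_by_drug_then_descending_count(
        self, paper_like_db, default_dictionary, paper_like
    ):
        results = screen(paper_like_db, default_dictionary, list(paper_like.target_drugs))
        drugs_seen = [r.drug_name for r in results]
        assert drugs_seen == sorted(
            drugs_seen, key=lambda d: list(paper_like.target_drugs).index(d)
        )
        for drug in paper_like.target_drugs:
            counts = [r.n for r in results if r.drug_name == drug]
            assert counts == sorted(counts, reverse=True)

    def test_min_count_flags_ineligible_but_emits(self):
        results = screen(SIX_UNITS, SMALL_DICT, ["X"], min_count=2)
        by_class = {r.event_class: r for r in results}
        assert by_class["P class"].eligible          # n = 2
        assert not by_class["Q class"].eligible      # n = 1
        assert len(results) == 2

    def test_unknown_drug_warns_and_yields_empty_cells(self, caplog):
        results = screen(SIX_UNITS, SMALL_DICT, ["nonexistent"])
        assert "nonexistent" in caplog.text
        assert all(r.n == 0 for r in results)

    def test_empty_units_yield_no_results(self, caplog):
        empty = SIX_UNITS.iloc[0:0]
        assert screen(empty, SMALL_DICT, ["X"]) == []
        assert "no co-occurrence units" in caplog.text

    def test_case_unit_counts_each_class_once_per_case(self):
        dictionary = load_dictionary({"P class": ["PT P", "PT P2"]})
        db = small_db(
            [("A", "X", "suspected"), ("B", "Y", "suspected")],
            [("A", "PT P"), ("A", "PT P2"), ("B", "PT P")],
        )
        cooc = screen(db, dictionary, ["X"], unit="cooccurrence")[0]
        case_level = screen(db, dictionary, ["X"], unit="case")[0]
        assert cooc.n == 2
        assert case_level.n == 1

    def test_screen_matches_bruteforce_over_raw_tables(
        self, paper_like_db, default_dictionary, paper_like
    ):
        """Every screened ROR equals a brute-force recomputation that
        iterates over the raw linked tables with python sets only."""
        suspected = {
            (r.case_id, r.drug_name)
            for r in paper_like_db.drug.itertuples()
            if r.involvement == "suspected"
        }
        events = {
            (r.case_id, r.preferred_term) for r in paper_like_db.reac.itertuples()
        }
        triples = {
            (cid, drug, pt)
            for (cid, drug) in suspected
            for (cid2, pt) in events
            if cid2 == cid
        }
        pt_class = {}
        for definition in default_dictionary:
            for pt in definition.preferred_terms:
                pt_class[pt.casefold()] = definition.class_name

        results = screen(paper_like_db, default_dictionary, list(paper_like.target_drugs))
        for result in results:
            a = b = c = d = 0
            for (_, drug, pt) in triples:
                in_class = pt_class.get(pt.casefold()) == result.event_class
                if drug == result.drug_name:
                    a, b = (a + 1, b) if in_class else (a, b + 1)
                else:
                    c, d = (c + 1, d) if in_class else (c, d + 1)
            assert (result.table.a, result.table.b, result.table.c, result.table.d) == (a, b, c, d)
            expected_ror = (a * d) / (b * c)
            assert result.ror == pytest.approx(expected_ror, rel=1e-12)


class TestEventClassShare:
    @pytest.mark.parametrize(
        "n_class,n_total,expected",
        [(657, 2771, 23.7), (88, 402, 21.9), (0, 100, 0.0), (5, 400, 1.3)],
    )
    def test_rounded_half_up_to_one_decimal(self, n_class, n_total, expected):
        assert event_class_share(n_class, n_total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            event_class_share(0, 0)

    def test_class_count_must_not_exceed_total(self):
        with pytest.raises(ValueError):
            event_class_share(5, 4)


def test_signals_frame_columns(paper_like_db, default_dictionary, paper_like):
    frame = signals_frame(
        screen(paper_like_db, default_dictionary, list(paper_like.target_drugs))
    )
    assert list(frame.columns) == [
        "drug", "event_class", "a", "b", "c", "d", "n",
        "ror", "ci_low", "ci_high", "corrected", "signal", "eligible",
    ]
    assert (frame["a"] + frame["b"] + frame["c"] + frame["d"]).nunique() == 1
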