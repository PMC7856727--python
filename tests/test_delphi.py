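"""Consensus engine: quantile arithmetic, classification rule, round flow."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hkpim import (
    Category,
    DelphiConfig,
    Origin,
    PIMStatement,
    RatingMatrix,
    Status,
    assemble_final_list,
    classify_statement,
    compute_consensus,
    load_rating_matrix,
    run_round,
    write_rating_matrix,
)
from hkpim.synthetic_data import enumerate_rating_vectors


def make_matrix(vectors: dict[str, list[int]]) -> RatingMatrix:
    n = max(len(v) for v in vectors.values())
    experts = [f"E{i+1}" for i in range(n)]
    cells = {sid: {experts[i]: r for i, r in enumerate(v)}
             for sid, v in vectors.items()}
    return RatingMatrix(list(vectors), experts, cells)


class TestComputeConsensus:
    def test_constant_vector(self):
        res = compute_consensus([5] * 8)
        assert (res.median, res.q1, res.q3) == (5.0, 5.0, 5.0)
        assert res.iqr_width == 0.0
        assert res.classification is Status.INCLUDED

    def test_eight_rater_quarter_step_quartiles(self):
        # strong-consensus panel: the quartiles land on the 0.25 grid
        res = compute_consensus([4, 4, 5, 5, 5, 5, 5, 5])
        assert (res.median, res.q1, res.q3) == (5.0, 4.75, 5.0)
        assert res.classification is Status.INCLUDED

    def test_seven_rater_wide_spread_is_questionable(self):
        res = compute_consensus([1, 2, 3, 4, 4, 5, 5])
        assert (res.median, res.q1, res.q3) == (4.0, 2.5, 4.5)
        assert res.iqr_width == 2.0
        assert res.classification is Status.QUESTIONABLE

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            compute_consensus([])

    def test_out_of_scale_rating_rejected(self):
        with pytest.raises(ValueError):
            compute_consensus([1, 2, 6])

    @pytest.mark.parametrize("n", range(1, 10))
    def test_linear_matches_numpy_exhaustively(self, n):
        """Exact-rational quartiles equal numpy's linear interpolation for
        every integer multiset of size 1..9."""
        for vec in enumerate_rating_vectors(n):
            res = compute_consensus(list(vec))
            med, q1, q3 = np.percentile(vec, [50, 25, 75])
            assert res.median == pytest.approx(med)
            assert res.q1 == pytest.approx(q1)
            assert res.q3 == pytest.approx(q3)

    @pytest.mark.parametrize("n", range(1, 10))
    def test_nearest_rank_matches_numpy_inverted_cdf(self, n):
        cfg = DelphiConfig(quantile_method="nearest_rank")
        for vec in enumerate_rating_vectors(n):
            res = compute_consensus(list(vec), cfg)
            med, q1, q3 = np.percentile(vec, [50, 25, 75],
                                        method="inverted_cdf")
            assert (res.median, res.q1, res.q3) == (med, q1, q3)

    @pytest.mark.parametrize("vec,expected", [
        ([1, 2, 3, 4, 5], (3.0, 2.0, 4.0)),
        ([1, 2, 3, 4], (2.5, 1.5, 3.5)),
        ([1, 1, 2, 5, 5, 5], (3.5, 1.0, 5.0)),
    ])
    def test_tukey_hinges_known_values(self, vec, expected):
        cfg = DelphiConfig(quantile_method="tukey_hinges")
        res = compute_consensus(vec, cfg)
        assert (res.median, res.q1, res.q3) == expected

    @given(st.lists(st.integers(1, 5), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_adding_top_rating_never_lowers_median(self, vec):
        before = compute_consensus(vec).median
        after = compute_consensus(vec + [5]).median
        assert after >= before


class TestClassifyStatement:
    @pytest.mark.parametrize("median,width,expected", [
        (3.0, 1.0, Status.QUESTIONABLE),   # undecided zone
        (2.0, 1.0, Status.EXCLUDED),
        (4.0, 2.0, Status.QUESTIONABLE),   # consensus too wide
        (3.5, 1.5, Status.INCLUDED),       # both thresholds inclusive
        (5.0, 0.0, Status.INCLUDED),
        (2.75, 2.0, Status.EXCLUDED),      # exclusion beats wide IQR
        (3.25, 0.0, Status.QUESTIONABLE),
        (1.0, 4.0, Status.EXCLUDED),
    ])
    def test_rule(self, median, width, expected):
        assert classify_statement(median, width) is expected

    def test_total_exclusive_exhaustive_on_quarter_grid(self):
        """Every (median, width) on the 0.25 grid maps to exactly one class."""
        for m4 in range(4, 21):       # medians 1.00 .. 5.00
            for w4 in range(0, 17):   # widths  0.00 .. 4.00
                cls = classify_statement(m4 / 4, w4 / 4)
                med = Fraction(m4, 4)
                width = Fraction(w4, 4)
                if med < 3:
                    assert cls is Status.EXCLUDED
                elif med >= Fraction(7, 2) and width <= Fraction(3, 2):
                    assert cls is Status.INCLUDED
                else:
                    assert cls is Status.QUESTIONABLE

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_statement(0.5, 1.0)
        with pytest.raises(ValueError):
            classify_statement(4.0, 5.0)

    def test_constant_vectors_partition_by_value(self):
        for c in range(1, 6):
            cls = compute_consensus([c] * 8).classification
            if c in (4, 5):
                assert cls is Status.INCLUDED
            elif c in (1, 2):
                assert cls is Status.EXCLUDED
            else:
                assert cls is Status.QUESTIONABLE


class TestRunRound:
    def test_constant_vector_partition(self):
        rm = make_matrix({"A": [5] * 8, "B": [1] * 8, "C": [3] * 8})
        rr = run_round(["A", "B", "C"], rm, 1)
        assert rr.included == ["A"]
        assert rr.excluded == ["B"]
        assert rr.questionable == ["C"]
        assert rr.sizes()["candidates"] == 3

    def test_missing_candidate_rejected(self):
        rm = make_matrix({"A": [5] * 8})
        with pytest.raises(KeyError):
            run_round(["A", "Z"], rm, 1)

    def test_empty_candidate_list(self):
        rm = make_matrix({"A": [5] * 8})
        rr = run_round([], rm, 1)
        assert rr.sizes() == {"candidates": 0, "included": 0,
                              "excluded": 0, "questionable": 0}

    def test_deterministic(self):
        rm = make_matrix({"A": [1, 3, 5, 5, 4, 4, 2, 3], "B": [2, 2, 3, 4]})
        r1 = run_round(["A", "B"], rm, 1)
        r2 = run_round(["A", "B"], rm, 1)
        assert r1.included == r2.included
        assert r1.results == r2.results

    def test_dropout_uses_remaining_raters_only(self):
        # one blank cell: the statement is summarised over 7 ratings
        rm = make_matrix({"A": [1, 2, 3, 4, 4, 5, 5]})
        rm.experts.append("E8")  # expert present in the panel, no rating
        res = run_round(["A"], rm, 2).results["A"]
        assert (res.median, res.q1, res.q3) == (4.0, 2.5, 4.5)


class TestRatingMatrixIO:
    def test_roundtrip_with_missing_cells(self, tmp_path):
        rm = make_matrix({"A": [5, 4, 3], "B": [1, 2]})
        path = tmp_path / "ratings.csv"
        write_rating_matrix(rm, path)
        back = load_rating_matrix(path)
        assert back.vector("A") == [3, 4, 5]
        assert back.vector("B") == [1, 2]

    def test_bad_rating_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("statement_id,E1\nA,7\n", encoding="utf-8")
        with pytest.raises(ValueError, match="outside 1..5"):
            load_rating_matrix(path)


def _meta(sid, category=Category.INDEPENDENT):
    return PIMStatement(
        statement_id=sid, category=category, class_name="c",
        medication_name="m", atc_code_printed="N05BA01",
        atc_code_curated="N05BA01",
        condition_id="" if category is Category.INDEPENDENT else "falls",
        median=4, iqr_low=4, iqr_high=4, status=Status.INCLUDED,
        origin=Origin.PRELIMINARY, decided_round=1)


class TestAssembleFinalList:
    def _rounds(self):
        rm1 = make_matrix({"A": [5] * 8, "B": [3] * 8, "C": [1] * 8})
        r1 = run_round(["A", "B", "C"], rm1, 1)
        rm2 = make_matrix({"B": [4] * 7, "D": [3] * 7})
        r2 = run_round(["B", "D"], rm2, 2)
        return r1, r2

    def test_final_is_union_of_round_inclusions(self):
        r1, r2 = self._rounds()
        meta = {sid: _meta(sid) for sid in "ABCD"}
        final = assemble_final_list(r1, r2, meta)
        included = {s.statement_id for s in final.included()}
        assert included == {"A", "B"}
        assert final.get("B").decided_round == 2
        assert final.get("D").status is Status.QUESTIONABLE
        assert final.get("C").status is Status.EXCLUDED

    def test_conservation(self):
        r1, r2 = self._rounds()
        final = assemble_final_list(r1, r2, {sid: _meta(sid) for sid in "ABCD"})
        assert sorted(s.statement_id for s in final) == list("ABCD")

    def test_round1_inclusion_cannot_be_rerated(self):
        r1, r2 = self._rounds()
        rm2 = make_matrix({"A": [4] * 7})
        bad_r2 = run_round(["A"], rm2, 2)
        with pytest.raises(ValueError, match="overlap"):
            assemble_final_list(r1, bad_r2, {sid: _meta(sid) for sid in "AD"})

    def test_round2_with_zero_inclusions(self):
        rm1 = make_matrix({"A": [5] * 8, "B": [3] * 8})
        r1 = run_round(["A", "B"], rm1, 1)
        r2 = run_round(["B"], make_matrix({"B": [3] * 7}), 2)
        final = assemble_final_list(r1, r2, {sid: _meta(sid) for sid in "AB"})
        assert {s.statement_id for s in final.included()} == {"A"}

    def test_empty_round2(self):
        rm1 = make_matrix({"A": [5] * 8})
        r1 = run_round(["A"], rm1, 1)
        r2 = run_round([], rm1, 2)
        final = assemble_final_list(r1, r2, {"A": _meta("A")})
        assert {s.statement_id for s in final.included()} == {"A"}
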