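import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gnmscaffold.structure_io import DimerModel
from gnmscaffold.interface_targets import TargetSet
from gnmscaffold.scaffold_predictor import PredictionResult
from gnmscaffold.decoy_evaluation import (
    EvaluationRecord,
    aggregate,
    classify,
    combined_standing,
    evaluate_chain,
    evaluate_chain_lenient,
    rank_decoys,
    read_labels,
    sequence_length_ratio,
    standing_of,
)

from conftest import straight_chain


def _pred(predicted):
    return PredictionResult(
        predicted=set(predicted), mode_count=1, iterations=[(1, 0.0)],
        strategy="combined", terminated_by="fixed",
    )


def _targets(contacts, n):
    return TargetSet(set(contacts), set(), n)


class TestEvaluateChain:
    def test_perfect_prediction(self):
        rec = evaluate_chain(_pred(range(5)), _targets(range(5), 20))
        assert (rec.tp_ratio, rec.fp_ratio) == (1.0, 0.0)
        assert rec.quadrant == "good"
        assert rec.standing == 0.0

    def test_complement_prediction(self):
        rec = evaluate_chain(_pred(range(5, 20)), _targets(range(5), 20))
        assert (rec.tp_ratio, rec.fp_ratio) == (0.0, 1.0)
        assert rec.quadrant == "very_bad"
        assert rec.standing == pytest.approx(math.sqrt(2))

    def test_half_half_boundary(self):
        # tp = fp = 0.5: not good, not very bad, not above the diagonal
        rec = evaluate_chain(_pred([0, 1, 2, 3, 4, 10, 11, 12, 13, 14]),
                             _targets(range(10), 20))
        assert rec.tp_ratio == 0.5 and rec.fp_ratio == 0.5
        assert rec.quadrant == "unsatisfying"
        assert rec.standing == pytest.approx(math.sqrt(0.5))

    def test_degenerate_targets_rejected(self):
        with pytest.raises(ValueError, match="zero targets"):
            evaluate_chain(_pred([1]), _targets([], 10))
        with pytest.raises(ValueError, match="all residues"):
            evaluate_chain(_pred([1]), _targets(range(10), 10))

    def test_lenient_handles_degenerate_targets(self):
        rec = evaluate_chain_lenient(_pred([1, 2]), _targets([], 10))
        assert (rec.tp_ratio, rec.fp_ratio) == (0.0, 0.2)
        rec = evaluate_chain_lenient(_pred(range(10)), _targets(range(10), 10))
        assert (rec.tp_ratio, rec.fp_ratio) == (1.0, 0.0)


class TestQuadrantAlgebra:
    def test_partition_exhaustive_exclusive(self):
        grid = np.linspace(0, 1, 101)
        for tp in grid:
            for fp in grid:
                q = classify(tp, fp)
                members = [
                    tp > 0.5 and fp <= 0.5,
                    fp > 0.5 and tp <= 0.5,
                    q == "satisfying",
                    q == "unsatisfying",
                ]
                assert q in ("good", "very_bad", "satisfying", "unsatisfying")
                if q == "good":
                    assert members[0]
                elif q == "very_bad":
                    assert members[1]
                elif q == "satisfying":
                    assert tp > fp and not members[0] and not members[1]
                else:
                    assert tp <= fp or members[1]

    @settings(derandomize=True, max_examples=200)
    @given(
        tp=st.floats(0, 1), fp=st.floats(0, 1),
        dtp=st.floats(0, 1), dfp=st.floats(0, 1),
    )
    def test_standing_bounds_and_monotone_property(self, tp, fp, dtp, dfp):
        s = standing_of(tp, fp)
        assert 0.0 <= s <= math.sqrt(2) + 1e-12
        assert classify(tp, fp) in ("good", "very_bad", "satisfying", "unsatisfying")
        # more true positives never hurt; more false positives never help
        assert standing_of(min(1.0, tp + dtp), fp) <= s + 1e-12
        assert standing_of(tp, min(1.0, fp + dfp)) >= s - 1e-12

    def test_standing_monotonicity(self):
        grid = np.linspace(0, 1, 21)
        for fp in grid:
            standings = [standing_of(tp, fp) for tp in grid]
            assert all(b <= a + 1e-12 for a, b in zip(standings, standings[1:]))
        for tp in grid:
            standings = [standing_of(tp, fp) for fp in grid]
            assert all(b >= a - 1e-12 for a, b in zip(standings, standings[1:]))


class TestAggregate:
    def test_single_record(self):
        rec = EvaluationRecord(0.6, 0.4, "good", standing_of(0.6, 0.4))
        summary = aggregate([rec])
        assert summary.tp_mean_pct == pytest.approx(60.0)
        assert summary.fp_mean_pct == pytest.approx(40.0)
        assert summary.good_pct == 100.0 and summary.very_bad_pct == 0.0

    def test_two_opposite_records(self):
        recs = [
            EvaluationRecord(1.0, 0.0, classify(1, 0), standing_of(1, 0)),
            EvaluationRecord(0.0, 1.0, classify(0, 1), standing_of(0, 1)),
        ]
        summary = aggregate(recs)
        assert summary.tp_mean_pct == summary.fp_mean_pct == 50.0
        assert summary.good_pct == summary.very_bad_pct == 50.0

    def test_matches_naive_resummation(self):
        rng = np.random.default_rng(8)
        recs = [
            EvaluationRecord(tp, fp, classify(tp, fp), standing_of(tp, fp))
            for tp, fp in rng.uniform(size=(100, 2))
        ]
        summary = aggregate(recs)
        assert summary.tp_mean_pct == pytest.approx(
            100 * sum(r.tp_ratio for r in recs) / 100
        )
        assert summary.good_pct == pytest.approx(
            100 * len([r for r in recs if r.quadrant == "good"]) / 100
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


def _evals(standings):
    return {
        did: {"a": EvaluationRecord(0.5, 0.5, "unsatisfying", st)}
        for did, st in standings.items()
    }


class TestRankDecoys:
    def test_near_native_all_best(self):
        evals = _evals({"n1": 0.1, "n2": 0.2, "d1": 0.9, "d2": 0.8})
        ranking = rank_decoys(evals, {"n1", "n2"}, chain_select="a")
        assert ranking.best_rank == 1
        assert ranking.coverage == 2
        assert ranking.decoy_ids[:2] == ["n1", "n2"]

    def test_near_native_all_worst(self):
        evals = _evals({"n1": 0.9, "n2": 1.0, "d1": 0.1, "d2": 0.2, "d3": 0.3})
        ranking = rank_decoys(evals, {"n1", "n2"}, chain_select="a")
        assert ranking.best_rank == 5 - 2 + 1
        assert ranking.coverage == 0

    def test_matches_sort_oracle_and_permutation(self):
        rng = np.random.default_rng(21)
        standings = {f"d{i:02d}": float(rng.uniform()) for i in range(20)}
        near = {f"d{i:02d}" for i in rng.choice(20, 5, replace=False)}
        ranking = rank_decoys(_evals(standings), near, chain_select="a")
        expected_order = [d for _, d in sorted((s, d) for d, s in standings.items())]
        assert ranking.decoy_ids == expected_order
        assert sorted(ranking.decoy_ids) == sorted(standings)
        expected_best = min(expected_order.index(d) for d in near) + 1
        assert ranking.best_rank == expected_best
        assert ranking.coverage == len(set(expected_order[:5]) & near)

    def test_min_chain_selection(self):
        evals = {
            "x": {
                "a": EvaluationRecord(0, 0, "unsatisfying", 1.0),
                "b": EvaluationRecord(0, 0, "unsatisfying", 0.2),
            },
            "y": {
                "a": EvaluationRecord(0, 0, "unsatisfying", 0.5),
                "b": EvaluationRecord(0, 0, "unsatisfying", 0.6),
            },
        }
        ranking = rank_decoys(evals, {"x"}, chain_select="min")
        assert ranking.decoy_ids == ["x", "y"]

    def test_errors(self):
        evals = _evals({"a": 0.1, "b": 0.2})
        with pytest.raises(ValueError, match="labels without decoys"):
            rank_decoys(evals, {"zz"})
        with pytest.raises(ValueError, match="at least 2"):
            rank_decoys(_evals({"a": 0.1}), {"a"})
        with pytest.raises(ValueError, match="chain_select"):
            rank_decoys(evals, {"a"}, chain_select="c")


class TestCombinedStanding:
    @pytest.mark.parametrize(
        "ranks,expected",
        [((1, 1), 0.0), ((1, 2), 1.0), ((3, 4), math.sqrt(13))],
    )
    def test_values(self, ranks, expected):
        assert combined_standing(*ranks) == pytest.approx(expected)

    def test_rank_below_one_rejected(self):
        with pytest.raises(ValueError):
            combined_standing(0, 5)


class TestSequenceLengthRatio:
    def _dimer(self, n_a, n_b):
        return DimerModel(straight_chain(n_a, "A"), straight_chain(n_b, "B"))

    def test_high_ratio(self):
        lr = sequence_length_ratio(self._dimer(400, 100))
        assert lr.ratio == pytest.approx(4.0) and lr.high_ratio

    def test_low_ratio(self):
        lr = sequence_length_ratio(self._dimer(100, 90))
        assert lr.ratio == pytest.approx(100 / 90) and not lr.high_ratio

    def test_short_chain_exclusion(self):
        lr = sequence_length_ratio(self._dimer(200, 79))
        assert lr.ratio == pytest.approx(200 / 79) and not lr.high_ratio


class TestReadLabels:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "labels.txt"
        path.write_text("# comment\nd0 native\nd1 near_native\nd2 far\nd3 neutral\n")
        assert read_labels(path) == {
            "d0": "native", "d1": "near_native", "d2": "far", "d3": "neutral"
        }

    def test_errors(self, tmp_path):
        path = tmp_path / "labels.txt"
        path.write_text("d0 native\nd0 far\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_labels(path)
        path.write_text("d0 sort_of_native\n")
        with pytest.raises(ValueError, match="unknown label"):
            read_labels(path)
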