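"""Graded metrics, inferred estimators and run-level evaluation."""

import itertools
import math

import numpy as np
import pytest

from meshir import (Qrels, RankedList, SampledQrels, average_precision,
                    evaluate_run, inf_ap, inf_ndcg, ndcg_at_k,
                    parse_qrels, parse_sampled_qrels, precision_at_k,
                    write_qrels, write_sampled_qrels)
from _reference import (ref_average_precision, ref_inf_ap, ref_ndcg_at_k,
                        ref_precision_at_k)


def ranked(qid, docs):
    return RankedList(qid=qid, entries=[
        (d, float(len(docs) - i), i + 1) for i, d in enumerate(docs)])


def qrels_for(qid, grade_of):
    return Qrels(grades={(qid, d): g for d, g in grade_of.items()})


class TestPrecisionAtK:
    GRADES = dict(zip("abcdefghij", [2, 1, 0, 2, 0, 0, 1, 0, 0, 0]))

    def test_partial_counts_grade_one(self):
        rl = ranked("q", list("abcdefghij"))
        assert precision_at_k(rl, qrels_for("q", self.GRADES), 10, 1) == 0.4

    def test_strict_counts_only_grade_two(self):
        rl = ranked("q", list("abcdefghij"))
        assert precision_at_k(rl, qrels_for("q", self.GRADES), 10, 2) == 0.2

    def test_short_list_padded_with_nonrelevant(self):
        rl = ranked("q", ["a", "b", "c"])
        q = qrels_for("q", {"a": 2, "b": 2, "c": 2})
        assert precision_at_k(rl, q, 10, 2) == pytest.approx(0.3)


class TestNDCG:
    def test_hand_worked_example(self):
        # ranks [1,2,0], graded multiset {2,1}:
        # DCG = 1 + 2/log2(3), iDCG = 2 + 1/log2(3)
        rl = ranked("q", ["a", "b", "c"])
        q = qrels_for("q", {"a": 1, "b": 2, "c": 0})
        expected = (1 + 2 / math.log2(3)) / (2 + 1 / math.log2(3))
        got = ndcg_at_k(rl, q, 10)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.85972, abs=5e-6)

    def test_ideal_ordering_scores_one(self):
        rl = ranked("q", ["a", "b", "c"])
        assert ndcg_at_k(rl, qrels_for("q", {"a": 2, "b": 1}), 10) == 1.0

    def test_no_relevant_docs_scores_zero(self):
        rl = ranked("q", ["a", "b"])
        assert ndcg_at_k(rl, qrels_for("q", {"a": 0}), 10) == 0.0

    def test_exponential_gain_flag(self):
        rl = ranked("q", ["a", "b"])
        q = qrels_for("q", {"a": 1, "b": 2})
        lin = ndcg_at_k(rl, q, 10, gain="linear")
        exp = ndcg_at_k(rl, q, 10, gain="exponential")
        assert lin != exp  # grade 2 weighs relatively more with 2^g - 1


class TestAveragePrecision:
    def test_hand_worked_example(self):
        rl = ranked("q", ["a", "x", "b", "y"])
        q = qrels_for("q", {"a": 1, "b": 2, "x": 0, "y": 0})
        assert average_precision(rl, q) == pytest.approx((1 + 2 / 3) / 2)

    def test_perfect_ranking_scores_one(self):
        rl = ranked("q", ["a", "b", "c"])
        assert average_precision(rl, qrels_for("q", {"a": 1, "b": 2})) == 1.0

    def test_no_relevant_scores_zero(self):
        rl = ranked("q", ["a"])
        assert average_precision(rl, qrels_for("q", {"a": 0})) == 0.0

    def test_min_grade_two_binarization(self):
        rl = ranked("q", ["a", "b"])
        q = qrels_for("q", {"a": 1, "b": 2})
        assert average_precision(rl, q, min_grade=2) == pytest.approx(0.5)


def random_instance(rng, n_docs=30):
    docs = [f"d{i}" for i in range(n_docs)]
    order = list(rng.permutation(docs))
    judged = {d: int(g) for d, g in
              zip(docs, rng.integers(0, 3, size=n_docs))
              if rng.random() < 0.7}
    return order, judged


class TestOracleEquivalence:
    """Randomized agreement with naive reference implementations."""

    def test_two_hundred_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            order, judged = random_instance(rng)
            rl = ranked("q", order)
            q = qrels_for("q", judged)
            assert precision_at_k(rl, q, 10, 1) == pytest.approx(
                ref_precision_at_k(order, judged, 10, 1), abs=1e-9)
            assert precision_at_k(rl, q, 10, 2) == pytest.approx(
                ref_precision_at_k(order, judged, 10, 2), abs=1e-9)
            assert average_precision(rl, q) == pytest.approx(
                ref_average_precision(order, judged, 1), abs=1e-9)
            assert ndcg_at_k(rl, q, 10) == pytest.approx(
                ref_ndcg_at_k(order, judged, 10), abs=1e-9)

    def test_nonrelevant_tail_permutation_invariance(self):
        head = ["a", "b"]
        judged = {"a": 2, "b": 1}
        tails = [["x", "y", "z"], ["z", "x", "y"]]
        vals = []
        for tail in tails:
            rl = ranked("q", head + tail)
            q = qrels_for("q", judged)
            vals.append((precision_at_k(rl, q, 5, 1), ndcg_at_k(rl, q, 5),
                         average_precision(rl, q)))
        assert vals[0] == vals[1]


def full_sample_view(qid, grade_of, n_strata=1):
    """SampledQrels with every judged doc pooled and sampled at rate 1."""
    docs = sorted(grade_of)
    pool = {(qid, d): str(1 + (i % n_strata)) for i, d in enumerate(docs)}
    rates = {(qid, str(s + 1)): 1.0 for s in range(n_strata)}
    grades = {(qid, d): grade_of[d] for d in docs}
    return SampledQrels(pool=pool, rates=rates, grades=grades)


class TestFullSamplingReduction:
    def test_inf_ap_and_inf_ndcg_reduce_exactly(self):
        rng = np.random.default_rng(99)
        for trial in range(100):
            order, judged = random_instance(rng, n_docs=20)
            if not judged:
                continue
            rl = ranked("q", order)
            q = qrels_for("q", judged)
            sq = full_sample_view("q", judged, n_strata=1 + trial % 3)
            assert inf_ap(rl, sq) == pytest.approx(
                average_precision(rl, q), abs=1e-9)
            assert inf_ndcg(rl, sq) == pytest.approx(
                ndcg_at_k(rl, q, k=None), abs=1e-9)


class TestInfAP:
    def test_no_sampled_relevant_scores_zero(self):
        rl = ranked("q", ["a", "b"])
        sq = SampledQrels(pool={("q", "a"): "1"}, rates={("q", "1"): 0.5},
                          grades={("q", "a"): 0})
        assert inf_ap(rl, sq) == 0.0

    def test_missing_rate_errors(self):
        with pytest.raises(ValueError, match="rate"):
            SampledQrels(pool={("q", "a"): "1"}, rates={},
                         grades={("q", "a"): 1})

    def test_enumeration_expectation_on_fixed_pool(self):
        """Mean over all equally-likely 4-of-8 samples matches the
        exhaustively enumerated expectation of the stated estimator."""
        pool_docs = list("abcdefgh")
        true_grades = {"a": 2, "b": 0, "c": 1, "d": 0,
                       "e": 1, "f": 0, "g": 2, "h": 0}
        order = list("abxcdefgyh")  # x, y outside the pool
        rl = ranked("q", order)
        p = 4 / 8
        got_vals, ref_vals = [], []
        for sample in itertools.combinations(pool_docs, 4):
            grades = {d: true_grades[d] for d in sample}
            sq = SampledQrels(
                pool={("q", d): "1" for d in pool_docs},
                rates={("q", "1"): p},
                grades={("q", d): g for d, g in grades.items()})
            got_vals.append(inf_ap(rl, sq))
            ref_vals.append(ref_inf_ap(order, {d: "1" for d in pool_docs},
                                       {"1": p}, grades))
        assert np.mean(got_vals) == pytest.approx(np.mean(ref_vals), abs=1e-9)
        for g, r in zip(got_vals, ref_vals):
            assert g == pytest.approx(r, abs=1e-9)


class TestInfNDCG:
    def test_two_stratum_hand_evaluation(self):
        # stratum 1 (p=1.0): d1=2, d2=1, d3=0 all judged
        # stratum 2 (p=0.5): pooled d4,d5,d6; only d4 sampled, grade 1
        # ranked: d1 d4 d2 d7 d5 d3   (d7 outside pool)
        sq = SampledQrels(
            pool={("q", d): "1" for d in ("d1", "d2", "d3")} |
                 {("q", d): "2" for d in ("d4", "d5", "d6")},
            rates={("q", "1"): 1.0, ("q", "2"): 0.5},
            grades={("q", "d1"): 2, ("q", "d2"): 1, ("q", "d3"): 0,
                    ("q", "d4"): 1})
        rl = ranked("q", ["d1", "d4", "d2", "d7", "d5", "d3"])
        # step-by-step arithmetic of the estimator:
        g_hat_2 = 1.0                     # mean sampled gain in stratum 2
        dcg = (2 / math.log2(2) + 1 / math.log2(3) + 1 / math.log2(4)
               + 0 + g_hat_2 / math.log2(6) + 0)
        # estimated counts: N2 = 1 (stratum 1); N1 = 1 + 1/0.5 = 3
        idcg = (2 / math.log2(2) + 1 / math.log2(3) + 1 / math.log2(4)
                + 1 / math.log2(5))
        assert inf_ndcg(rl, sq) == pytest.approx(dcg / idcg, abs=1e-12)

    def test_fractional_ideal_remainder(self):
        # single stratum p=0.4: one sampled grade-2 doc scales to 2.5 docs
        sq = SampledQrels(
            pool={("q", d): "1" for d in ("a", "b", "c", "d", "e")},
            rates={("q", "1"): 0.4},
            grades={("q", "a"): 2, ("q", "b"): 0})
        rl = ranked("q", ["a", "b", "c"])
        g_hat = 1.0  # (2 + 0) / 2
        dcg = 2 / math.log2(2) + 0 + g_hat / math.log2(4)
        # N2 = 2.5: two full ranks then 0.5 * 2 at rank 3
        idcg = 2 + 2 / math.log2(3) + 0.5 * 2 / math.log2(4)
        assert inf_ndcg(rl, sq) == pytest.approx(dcg / idcg, abs=1e-12)

    def test_empty_ranked_list_scores_zero(self):
        sq = SampledQrels(pool={("q", "a"): "1"}, rates={("q", "1"): 1.0},
                          grades={("q", "a"): 2})
        assert inf_ndcg(RankedList(qid="q"), sq) == 0.0

    def test_value_clamped_to_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            order, judged = random_instance(rng, n_docs=15)
            docs = sorted(judged)
            if not docs:
                continue
            sq = SampledQrels(
                pool={("q", d): "1" for d in docs},
                rates={("q", "1"): 0.5},
                grades={("q", d): judged[d] for d in docs[::2]})
            v = inf_ndcg(ranked("q", order), sq)
            assert 0.0 <= v <= 1.0

    def test_estimator_consistency_as_rate_grows(self):
        """|infNDCG - NDCG| shrinks (on average) as the sampling rate
        approaches exhaustive judging."""
        rng = np.random.default_rng(17)
        docs = [f"d{i}" for i in range(40)]
        grade_of = {d: int(g) for d, g in
                    zip(docs, rng.integers(0, 3, size=len(docs)))}
        order = list(rng.permutation(docs))
        rl = ranked("q", order)
        exact = ndcg_at_k(rl, qrels_for("q", grade_of), k=None)
        errors = []
        for rate in (0.25, 0.5, 0.75, 1.0):
            diffs = []
            for rep in range(200):
                n_take = int(round(rate * len(docs)))
                chosen = rng.choice(docs, size=n_take, replace=False)
                sq = SampledQrels(
                    pool={("q", d): "1" for d in docs},
                    rates={("q", "1"): rate},
                    grades={("q", d): grade_of[d] for d in chosen})
                diffs.append(abs(inf_ndcg(rl, sq) - exact))
            errors.append(float(np.mean(diffs)))
        assert errors[-1] == pytest.approx(0.0, abs=1e-12)
        assert errors[0] >= errors[1] >= errors[2] >= errors[3]


class TestEvaluateRun:
    def _fixture(self):
        lists = {
            "q1": ranked("q1", ["a", "b", "c"]),
            "q2": ranked("q2", ["x", "y"]),
        }
        qrels = Qrels(grades={("q1", "a"): 2, ("q1", "c"): 1,
                              ("q2", "y"): 2, ("q2", "z"): 1})
        return lists, qrels

    def test_report_structure_and_means(self):
        lists, qrels = self._fixture()
        report = evaluate_run(lists, qrels)
        assert set(report.per_query) == {"q1", "q2"}
        for key, mean in report.means.items():
            per = [report.per_query[q][key] for q in ("q1", "q2")]
            assert mean == pytest.approx(sum(per) / 2)
            assert all(0.0 <= v <= 1.0 for v in per)

    def test_means_equal_per_metric_oracles(self):
        lists, qrels = self._fixture()
        report = evaluate_run(lists, qrels)
        for qid, rl in lists.items():
            judged = {d: g for (q, d), g in qrels.grades.items() if q == qid}
            order = rl.doc_ids()
            row = report.per_query[qid]
            assert row["P@10+partial"] == pytest.approx(
                ref_precision_at_k(order, judged, 10, 1), abs=1e-9)
            assert row["P@10-partial"] == pytest.approx(
                ref_precision_at_k(order, judged, 10, 2), abs=1e-9)
            assert row["NDCG@10"] == pytest.approx(
                ref_ndcg_at_k(order, judged, 10), abs=1e-9)
            assert row["infAP"] == pytest.approx(
                ref_average_precision(order, judged, 1), abs=1e-9)

    def test_unknown_query_excluded_with_warning(self, caplog):
        lists, qrels = self._fixture()
        lists["q9"] = ranked("q9", ["a"])
        with caplog.at_level("WARNING"):
            report = evaluate_run(lists, qrels)
        assert report.excluded_qids == ["q9"]
        assert "q9" not in report.per_query

    def test_run_file_round_trip_evaluation(self, tmp_path):
        from meshir import write_run
        lists, qrels = self._fixture()
        path = tmp_path / "run.txt"
        write_run(list(lists.values()), "r1", path)
        direct = evaluate_run(lists, qrels)
        from_file = evaluate_run(path, qrels)
        assert direct.means == pytest.approx(from_file.means)

    def test_report_writers(self, tmp_path):
        import json
        lists, qrels = self._fixture()
        report = evaluate_run(lists, qrels)
        report.to_tsv(tmp_path / "r.tsv")
        report.to_json(tmp_path / "r.json")
        lines = (tmp_path / "r.tsv").read_text().strip().splitlines()
        assert lines[0].startswith("qid\t") and lines[-1].startswith("MEAN\t")
        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["means"].keys() == report.means.keys()


class TestQrelsIO:
    def test_qrels_round_trip(self, tmp_path):
        q = Qrels(grades={("q1", "d1"): 2, ("q1", "d2"): 0, ("q2", "d9"): 1})
        write_qrels(q, tmp_path / "qrels.txt")
        assert parse_qrels(tmp_path / "qrels.txt").grades == q.grades

    def test_sampled_qrels_round_trip(self, tmp_path):
        sq = SampledQrels(
            pool={("q1", "d1"): "1", ("q1", "d2"): "2", ("q1", "d3"): "2"},
            rates={("q1", "1"): 1.0, ("q1", "2"): 0.5},
            grades={("q1", "d1"): 2, ("q1", "d2"): 1})
        write_sampled_qrels(sq, tmp_path / "sq.txt")
        back = parse_sampled_qrels(tmp_path / "sq.txt")
        assert back.pool == sq.pool
        assert back.rates == sq.rates
        assert back.grades == sq.grades

    @pytest.mark.parametrize("line", [
        "q1 0 d1", "q1 0 d1 7", "q1 0 d1 x"])
    def test_strict_parser_reports_line_numbers(self, tmp_path, line):
        p = tmp_path / "qrels.txt"
        p.write_text(line + "\n")
        with pytest.raises(ValueError, match=":1"):
            parse_qrels(p)

    def test_grade_outside_range_rejected(self):
        with pytest.raises(ValueError):
            Qrels(grades={("q", "d"): 3})
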