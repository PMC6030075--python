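import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prognote.evaluation import (
    brier,
    calibration_deciles,
    evaluate_predictions,
    precision_recall_auc,
    roc_auc,
    stratified_auc,
)


def auc_pair_counting(scores, labels):
    """Exhaustive Mann-Whitney pair count; ties contribute 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_constant_scores_give_exactly_half(self):
        labels = np.array([1, 0, 1, 1, 0, 1])
        auc, lo, hi, _ = roc_auc(np.full(6, 0.8), labels)
        assert auc == 0.5
        assert auc == auc_pair_counting(np.full(6, 0.8), labels)

    def test_perfect_separation(self):
        labels = np.array([0, 1, 0, 1])
        auc, *_ = roc_auc(labels.astype(float), labels)
        assert auc == 1.0

    def test_matches_pair_counting_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc, *_ = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_thirty_listed_pairs(self):
        rng = np.random.default_rng(7)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        auc, *_ = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_best_cutoff_maximizes_youden(self):
        scores = np.array([0.1, 0.2, 0.6, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        *_, cutoff = roc_auc(scores, labels)
        assert cutoff == pytest.approx(0.7)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        n = 200
        labels = rng.integers(0, 2, size=n)
        scores = labels * 0.5 + rng.random(n) * 0.5
        pids = np.repeat(np.arange(n // 4), 4)
        auc, lo, hi, _ = roc_auc(scores, labels, patient_ids=pids,
                                 n_boot=100, seed=0)
        assert lo <= auc <= hi
        assert hi - lo < 0.3

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(25)
        labels = rng.integers(0, 2, size=25)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a1, *_ = roc_auc(scores, labels)
        a2, *_ = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestBrier:
    def test_perfect_probabilities(self):
        assert brier([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0

    def test_constant_half(self):
        assert brier([0.5] * 8, [1, 0, 1, 0, 1, 1, 0, 0]) == pytest.approx(0.25)

    def test_ten_listed_pairs_match_direct_formula(self):
        rng = np.random.default_rng(2)
        scores = rng.random(10)
        labels = rng.integers(0, 2, size=10)
        expected = np.mean([(s - l) ** 2 for s, l in zip(scores, labels)])
        assert brier(scores, labels) == pytest.approx(expected, abs=1e-15)

    def test_prevalence_constant_predictor_closed_form(self):
        labels = np.array([1] * 70 + [0] * 30)
        p = labels.mean()
        assert brier(np.full(100, p), labels) == pytest.approx(p * (1 - p), abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            brier([], [])


def decile_recount(scores, labels):
    rows = []
    for b in range(10):
        lo, hi = b / 10, (b + 1) / 10
        sel = [(s, l) for s, l in zip(scores, labels)
               if (lo <= s < hi) or (b == 9 and s == 1.0)]
        rows.append((b + 1, len(sel),
                     np.mean([l for _, l in sel]) * 100 if sel else None))
    return rows


class TestCalibrationDeciles:
    def test_bin_assignment_edges(self):
        table = calibration_deciles([0.05, 0.15], [1, 0])
        assert table.loc[table.bin == 1, "n"].item() == 1
        assert table.loc[table.bin == 2, "n"].item() == 1

    def test_top_bin_all_positive(self):
        table = calibration_deciles([0.95] * 5, [1] * 5)
        row = table[table.bin == 10].iloc[0]
        assert row.n == 5
        assert row.observed_survival_pct == pytest.approx(100.0)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        scores = rng.random(500)
        labels = rng.integers(0, 2, size=500)
        table = calibration_deciles(scores, labels)
        for (b, n, obs) in decile_recount(scores, labels):
            row = table[table.bin == b].iloc[0]
            assert row.n == n
            if obs is not None:
                assert row.observed_survival_pct == pytest.approx(obs)

    def test_counts_sum_to_evaluated_visits(self):
        rng = np.random.default_rng(4)
        scores = rng.random(333)
        table = calibration_deciles(scores, rng.integers(0, 2, size=333))
        assert table.n.sum() == 333

    def test_score_of_one_lands_in_top_bin(self):
        table = calibration_deciles([1.0], [1])
        assert table.loc[table.bin == 10, "n"].item() == 1


class TestStratifiedAuc:
    def test_single_stratum_equals_global(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        global_auc, *_ = roc_auc(scores, labels)
        out = stratified_auc(scores, labels, ["all"] * 40)
        assert out["all"] == pytest.approx(global_auc)

    def test_identical_multisets_give_equal_aucs(self):
        scores = [0.2, 0.8, 0.4, 0.2, 0.8, 0.4]
        labels = [0, 1, 1, 0, 1, 1]
        strata = ["a", "a", "a", "b", "b", "b"]
        out = stratified_auc(scores, labels, strata)
        assert out["a"] == pytest.approx(out["b"])

    def test_three_strata_match_pair_counting(self):
        rng = np.random.default_rng(6)
        scores = rng.random(90)
        labels = rng.integers(0, 2, size=90)
        strata = np.repeat(["x", "y", "z"], 30)
        for st_ in "xyz":
            sel = strata == st_
            if len(set(labels[sel])) < 2:
                labels[np.flatnonzero(sel)[0]] = 1 - labels[np.flatnonzero(sel)[0]]
        out = stratified_auc(scores, labels, strata)
        for st_ in "xyz":
            sel = strata == st_
            assert out[st_] == pytest.approx(
                auc_pair_counting(scores[sel], labels[sel]), abs=1e-12
            )

    def test_missing_class_reported_as_none(self):
        out = stratified_auc([0.1, 0.9, 0.5], [1, 1, 0], ["a", "a", "b"])
        assert out["a"] is None
        assert out["b"] is None


class TestEvaluatePredictions:
    def _frame(self):
        rng = np.random.default_rng(8)
        rows = []
        for pid in range(30):
            for t in range(4):
                label = rng.choice(["POS", "NEG", "UNDEFINED"], p=[0.7, 0.2, 0.1])
                rows.append({
                    "patient_id": f"P{pid:02d}", "visit_index": t,
                    "visit_date": "2015-01-01", "note_id": f"P{pid:02d}-n{t}",
                    "p_survival": rng.random(), "true_label": label,
                })
        return pd.DataFrame(rows)

    def test_report_excludes_undefined(self):
        frame = self._frame()
        report = evaluate_predictions(frame, n_boot=20, seed=0)
        assert report.n_evaluated == (frame.true_label != "UNDEFINED").sum()
        assert report.calibration.n.sum() == report.n_evaluated
        assert 0 <= report.brier <= 1
        assert 0 <= report.pr_auc <= 1

    def test_strata_propagate(self):
        frame = self._frame()
        strata = {f"P{pid:02d}": ("lung" if pid % 2 else "breast") for pid in range(30)}
        report = evaluate_predictions(frame, strata=strata, n_boot=0, seed=0)
        assert set(report.per_stratum_auc) == {"lung", "breast"}
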