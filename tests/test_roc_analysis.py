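"""ROC construction, best-accuracy cutoffs, and pair combinations."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import ustscreen as u
from ustscreen.errors import ValidationError
from ustscreen.roc_analysis import (
    CutoffClassifier,
    PairCombinationClassifier,
    auc_concordance,
)

from oracles import auc_pair_count, best_accuracy_scan


class TestRocCurve:
    @pytest.mark.parametrize(
        "cases, controls, expected_auc",
        [
            ([0.8, 0.6], [0.7, 0.5], 0.75),  # 3 of 4 case/control pairs concordant
            ([3, 4], [1, 2], 1.0),  # complete separation
            ([1, 2, 3], [1, 2, 3], 0.5),  # identical multisets, ties = 1/2
        ],
    )
    def test_auc_by_concordance(self, cases, controls, expected_auc):
        curve = u.roc_curve(cases, controls)
        assert curve.auc == pytest.approx(expected_auc)

    def test_endpoints_are_corners(self):
        rng = np.random.default_rng(0)
        curve = u.roc_curve(rng.normal(1, 1, 20), rng.normal(0, 1, 25))
        np.testing.assert_allclose(curve.points[0], [0.0, 0.0])
        np.testing.assert_allclose(curve.points[-1], [1.0, 1.0])

    def test_auc_matches_sklearn_on_random_instances(self):
        """Concordance AUC equals sklearn's roc_auc_score (independent route)."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            n1, n2 = rng.integers(2, 15, size=2)
            x = np.round(rng.normal(0.5, 1, n1), 1)  # rounding induces ties
            y = np.round(rng.normal(0, 1, n2), 1)
            curve = u.roc_curve(x, y, "case_high")
            ref = roc_auc_score([1] * n1 + [0] * n2, np.concatenate([x, y]))
            assert curve.auc == pytest.approx(ref, abs=1e-12)

    def test_auc_equals_normalized_u_statistic(self):
        """Cross-module oracle: AUC = U/(n1*n2) from the Mann-Whitney screen."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            n1, n2 = rng.integers(2, 12, size=2)
            x, y = rng.normal(0.3, 1, n1), rng.normal(0, 1, n2)
            u_stat, _ = u.mann_whitney(x, y)
            assert u.roc_curve(x, y, "case_high").auc == pytest.approx(u_stat / (n1 * n2))

    def test_direction_reversal_flips_auc(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        hi = u.roc_curve(x, y, "case_high").auc
        lo = u.roc_curve(x, y, "case_low").auc
        assert hi + lo == pytest.approx(1.0)

    def test_auto_direction_never_below_half(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x, y = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
            assert u.roc_curve(x, y, "auto").auc >= 0.5

    def test_auc_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(5)
        x, y = rng.lognormal(1, 0.5, 20), rng.lognormal(0.5, 0.5, 20)
        base = u.roc_curve(x, y, "case_high").auc
        assert u.roc_curve(np.log10(x), np.log10(y), "case_high").auc == pytest.approx(base)
        assert u.roc_curve(3 * x + 7, 3 * y + 7, "case_high").auc == pytest.approx(base)

    def test_trapezoid_area_equals_concordance(self):
        rng = np.random.default_rng(6)
        x = np.round(rng.normal(0.5, 1, 15), 1)
        y = np.round(rng.normal(0, 1, 12), 1)
        curve = u.roc_curve(x, y, "case_high")
        trap = np.trapezoid(curve.points[:, 1], curve.points[:, 0])
        assert trap == pytest.approx(curve.auc, abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            u.roc_curve([], [1.0])


class TestBestAccuracyCutoff:
    def test_separable_toy(self):
        curve = u.roc_curve([3, 4], [1, 2], "case_high")
        assert (curve.best_cutoff, curve.best_sensitivity,
                curve.best_specificity, curve.best_accuracy) == (2.5, 1.0, 1.0, 1.0)

    def test_interior_cutoff_on_overlapping_classes(self):
        # exhaustive scan over the 4 interior midpoints gives 0.6 at 2.5
        curve = u.roc_curve([1, 3, 4], [2, 5], "case_high")
        assert curve.best_cutoff == pytest.approx(2.5)
        assert curve.best_accuracy == pytest.approx(0.6)

    def test_fully_tied_degenerate_input(self):
        curve = u.roc_curve([1.0], [1.0], "case_high")
        assert curve.best_accuracy == pytest.approx(0.5)
        assert np.isfinite(curve.best_cutoff)

    def test_matches_exhaustive_scan_oracle(self):
        """Best cutoff equals brute-force threshold scan on 1000 random instances."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n1, n2 = rng.integers(1, 10, size=2)
            x = np.round(rng.normal(0.5, 1, n1), 1)
            y = np.round(rng.normal(0, 1, n2), 1)
            direction = "case_high" if rng.random() < 0.5 else "case_low"
            curve = u.roc_curve(x, y, direction)
            t, sens, spec, acc = best_accuracy_scan(x, y, direction)
            assert curve.best_cutoff == pytest.approx(t)
            assert curve.best_accuracy == pytest.approx(acc)
            assert curve.best_sensitivity == pytest.approx(sens)

    def test_accuracy_at_least_majority_class(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n1, n2 = rng.integers(1, 12, size=2)
            x, y = rng.normal(0, 1, n1), rng.normal(0, 1, n2)
            curve = u.roc_curve(x, y, "auto")
            majority = max(n1, n2) / (n1 + n2)
            assert curve.best_accuracy >= majority - 1e-12


def _ratio_matrix_from_logs(logs: pd.DataFrame) -> u.PairRatioMatrix:
    """Wrap per-pair log10 ratio columns into a PairRatioMatrix."""
    values = 10.0**logs
    pairs = [tuple(c.split("/")) for c in logs.columns]
    mirnas = sorted({m for p in pairs for m in p})
    return u.PairRatioMatrix(mirnas=mirnas, pairs=pairs, values=values)


class TestCombinePairs:
    def _planted(self, seed, n=30, d=1.19, n_pairs=2):
        """Independent standard-normal log-ratios, cases shifted by d (AUC ~ 0.8)."""
        rng = np.random.default_rng(seed)
        subjects = [f"s{i}" for i in range(2 * n)]
        labels = pd.Series([True] * n + [False] * n, index=subjects)
        cols = {}
        for j in range(n_pairs):
            vals = rng.normal(0, 1, 2 * n)
            vals[:n] += d
            cols[f"miR-n{j}/miR-d{j}"] = vals
        return _ratio_matrix_from_logs(pd.DataFrame(cols, index=subjects)), labels

    def test_single_member_reproduces_pair_auc(self):
        matrix, labels = self._planted(0, n_pairs=1)
        col = matrix.values["miR-n0/miR-d0"]
        pair_auc = auc_concordance(col[labels].to_numpy(), col[~labels].to_numpy())
        combo = u.combine_pairs(matrix, [("miR-n0", "miR-d0")], labels)
        assert combo.curve.auc == pytest.approx(pair_auc)

    def test_duplicated_member_is_invariant(self):
        matrix, labels = self._planted(1, n_pairs=1)
        single = u.combine_pairs(matrix, [("miR-n0", "miR-d0")], labels)
        double = u.combine_pairs(
            matrix, [("miR-n0", "miR-d0"), ("miR-n0", "miR-d0")], labels
        )
        assert double.curve.auc == pytest.approx(single.curve.auc)

    def test_combining_independent_signals_improves_auc(self):
        """Averaging two independent ~0.8-AUC pairs beats each member in >= 90% of sims."""
        wins = 0
        n_sims = 200
        for seed in range(n_sims):
            matrix, labels = self._planted(1000 + seed)
            members = [("miR-n0", "miR-d0"), ("miR-n1", "miR-d1")]
            member_aucs = []
            for col in matrix.values.columns:
                v = matrix.values[col]
                member_aucs.append(
                    auc_concordance(v[labels].to_numpy(), v[~labels].to_numpy())
                )
            combo = u.combine_pairs(matrix, members, labels)
            wins += combo.curve.auc > max(member_aucs)
        assert wins >= 0.9 * n_sims, f"combination won only {wins}/{n_sims}"

    def test_incomplete_subjects_excluded_and_reported(self):
        matrix, labels = self._planted(2)
        matrix.values.iloc[0, 0] = np.nan
        combo = u.combine_pairs(
            matrix, [("miR-n0", "miR-d0"), ("miR-n1", "miR-d1")], labels
        )
        assert combo.excluded_subjects == [matrix.values.index[0]]

    def test_unknown_member_rejected(self):
        matrix, labels = self._planted(3)
        with pytest.raises(ValidationError):
            u.combine_pairs(matrix, [("miR-x", "miR-y")], labels)

    def test_vote_method_runs(self):
        matrix, labels = self._planted(4)
        combo = u.combine_pairs(
            matrix, [("miR-n0", "miR-d0"), ("miR-n1", "miR-d1")], labels, method="vote"
        )
        assert 0.5 <= combo.curve.auc <= 1.0


class TestEstimators:
    def test_cutoff_classifier_reproduces_curve_confusion(self):
        rng = np.random.default_rng(9)
        y = np.array([1] * 20 + [0] * 20)
        scores = rng.normal(0, 1, 40) + y
        clf = CutoffClassifier().fit(scores.reshape(-1, 1), y)
        pred = clf.predict(scores.reshape(-1, 1))
        acc = (pred == y).mean()
        assert acc == pytest.approx(clf.accuracy_)

    def test_pair_combination_classifier_matches_combine_pairs(self):
        rng = np.random.default_rng(10)
        subjects = [f"s{i}" for i in range(40)]
        labels = pd.Series([True] * 20 + [False] * 20, index=subjects)
        logs = pd.DataFrame(
            {
                "miR-a/miR-b": rng.normal(0, 1, 40) + labels.to_numpy() * 1.0,
                "miR-c/miR-d": rng.normal(0, 1, 40) + labels.to_numpy() * 1.0,
            },
            index=subjects,
        )
        matrix = _ratio_matrix_from_logs(logs)
        members = [("miR-a", "miR-b"), ("miR-c", "miR-d")]
        combo = u.combine_pairs(matrix, members, labels)
        clf = PairCombinationClassifier(members=members).fit(matrix.values, labels)
        assert clf.auc_ == pytest.approx(combo.curve.auc)
        assert clf.cutoff_ == pytest.approx(combo.curve.best_cutoff)
        # resubstitution predictions match the fitted confusion matrix
        pred = clf.predict(matrix.values)
        acc = (pred == labels.to_numpy()).mean()
        assert acc == pytest.approx(clf.accuracy_)
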