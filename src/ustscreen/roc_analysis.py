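"""ROC curves, best-overall-accuracy cutoffs, and multi-pair score combination.

AUC is computed as the tie-adjusted concordance probability (ties count 1/2),
which equals the normalized Mann-Whitney statistic U/(n_case * n_control) and,
by construction, the trapezoid area under the empirical ROC. Candidate cutoffs
are midpoints between adjacent distinct pooled score values; the reported
operating point is the cutoff maximizing overall accuracy (TP+TN)/N, with ties
resolved toward higher sensitivity and then the lower threshold — a screening
test prefers not to miss cases.

Sentinel thresholds beyond the observed extremes anchor the curve at (0,0) and
(1,1). A sentinel cutoff classifies every subject identically, so it is chosen
as the operating point only when that strictly beats every interior split
(degenerate or heavily imbalanced inputs); otherwise the cutoff lies strictly
inside the observed score range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ValidationError
from .pair_ratio import PairRatioMatrix, pair_label

DIRECTIONS = ("auto", "case_high", "case_low")


def auc_concordance(scores_case: np.ndarray, scores_control: np.ndarray) -> float:
    """P(random case score > random control score), ties scoring 1/2.

    Computed via midranks: U = sum(ranks of cases) - n1(n1+1)/2, AUC = U/(n1*n2).
    """
    x = np.asarray(scores_case, float)
    y = np.asarray(scores_control, float)
    n1, n2 = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


@dataclass
class RocCurve:
    """Empirical ROC of a case/control score with its best-accuracy cutoff.

    ``direction`` records which side of the threshold is called pathological:
    ``case_high`` predicts case when score > cutoff, ``case_low`` when
    score < cutoff. ``points`` runs from (0, 0) to (1, 1) in (1-specificity,
    sensitivity) coordinates, one point per threshold.
    """

    thresholds: np.ndarray
    points: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    direction: str
    n_case: int
    n_control: int
    interior: np.ndarray = field(repr=False, default=None)  # mask of non-sentinel thresholds
    best_cutoff: float = float("nan")
    best_sensitivity: float = float("nan")
    best_specificity: float = float("nan")
    best_accuracy: float = float("nan")


def _sentinels(values: np.ndarray) -> tuple[float, float]:
    lo, hi = float(values.min()), float(values.max())
    if lo > 0:  # ratio-like scores: keep sentinels positive
        return lo / 2.0, hi * 2.0
    return lo - 1.0, hi + 1.0


def roc_curve(
    scores_case: Sequence[float],
    scores_control: Sequence[float],
    direction: str = "auto",
) -> RocCurve:
    """Build the empirical ROC curve and its best-accuracy operating point.

    ``direction='auto'`` picks the orientation whose AUC is >= 0.5. Missing
    scores must be removed by the caller; each class needs at least one value.
    """
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    x = np.asarray(scores_case, float)
    y = np.asarray(scores_control, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("roc_curve: both classes need at least one score")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("roc_curve: scores must not contain missing values")

    auc_high = auc_concordance(x, y)
    if direction == "auto":
        direction = "case_high" if auc_high >= 0.5 else "case_low"
    auc = auc_high if direction == "case_high" else 1.0 - auc_high

    pooled = np.unique(np.concatenate([x, y]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    lo, hi = _sentinels(pooled)
    thresholds = np.concatenate([[lo], mids, [hi]])
    interior = np.zeros(thresholds.shape, dtype=bool)
    interior[1:-1] = True

    if direction == "case_high":
        sens = (x[None, :] > thresholds[:, None]).mean(axis=1)
        spec = (y[None, :] <= thresholds[:, None]).mean(axis=1)
    else:
        sens = (x[None, :] < thresholds[:, None]).mean(axis=1)
        spec = (y[None, :] >= thresholds[:, None]).mean(axis=1)

    # order points from (0,0) to (1,1)
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    pts = np.column_stack([fpr, sens])[order]

    curve = RocCurve(
        thresholds=thresholds,
        points=pts,
        sensitivities=sens,
        specificities=spec,
        auc=float(auc),
        direction=direction,
        n_case=len(x),
        n_control=len(y),
        interior=interior,
    )
    cutoff, bsens, bspec, bacc = best_accuracy_cutoff(curve, len(x), len(y))
    curve.best_cutoff = cutoff
    curve.best_sensitivity = bsens
    curve.best_specificity = bspec
    curve.best_accuracy = bacc
    return curve


def best_accuracy_cutoff(
    curve: RocCurve, n_case: int, n_control: int
) -> tuple[float, float, float, float]:
    """Threshold maximizing overall accuracy (TP+TN)/(n_case+n_control).

    Interior midpoints are preferred: a sentinel (outside the observed range)
    is chosen only when it strictly improves accuracy — e.g. heavily
    imbalanced classes where calling everyone the majority class beats any
    interior split — or when the pooled scores have a single distinct value.
    Remaining ties are broken toward higher sensitivity, then the lower
    threshold.
    """
    n = n_case + n_control
    acc = (curve.sensitivities * n_case + curve.specificities * n_control) / n
    candidates = np.arange(len(curve.thresholds))
    # lexicographic argmax: accuracy desc, interior first, sens desc, threshold asc
    best = min(
        candidates,
        key=lambda i: (-acc[i], ~curve.interior[i], -curve.sensitivities[i], curve.thresholds[i]),
    )
    return (
        float(curve.thresholds[best]),
        float(curve.sensitivities[best]),
        float(curve.specificities[best]),
        float(acc[best]),
    )


# ---------------------------------------------------------------------------
# pair combination


@dataclass
class PairCombination:
    """Several pairs merged into one per-subject score.

    The default rule averages per-pair standardized log10 ratios: each member
    pair's log10 values are centered and scaled with the pooled mean/SD of the
    evaluation set and sign-oriented so that higher means more case-like; the
    subject score is the (equal-weight) mean across members. A single-member
    combination is a monotone transform of that pair's ratio, so it reproduces
    the pair's ranking — and hence its AUC — exactly.
    """

    member_pairs: list[tuple[str, str]]
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    signs: np.ndarray
    method: str
    vote_cutoffs: np.ndarray | None
    combined_scores: pd.Series
    excluded_subjects: list[str]
    curve: RocCurve


def _member_log_values(matrix: PairRatioMatrix, members) -> pd.DataFrame:
    known = set(matrix.pairs)
    cols = {}
    for j, (num, den) in enumerate(members):  # positional keys: members may repeat
        if (num, den) not in known and (den, num) not in known:
            raise ValidationError(f"pair {pair_label(num, den)} not present in ratio matrix")
        cols[f"{j}:{pair_label(num, den)}"] = np.log10(matrix.column(num, den).astype(float))
    return pd.DataFrame(cols, index=matrix.values.index)


def combine_pairs(
    matrix: PairRatioMatrix,
    members: Sequence[tuple[str, str]],
    labels: pd.Series,
    method: str = "mean",
) -> PairCombination:
    """Fit a multi-pair combination score and evaluate it through the ROC.

    ``labels`` maps subject -> True (case) / False (control). Subjects missing
    any member value are excluded and reported. ``method='mean'`` is the
    standardized-log-mean rule; ``method='vote'`` scores each subject by the
    fraction of members whose own best-accuracy cutoff votes "case".
    """
    if method not in ("mean", "vote"):
        raise ValidationError("combination method must be 'mean' or 'vote'")
    members = [tuple(m) for m in members]
    if not members:
        raise ValidationError("combination needs at least one member pair")
    logs = _member_log_values(matrix, members)
    labels = labels.reindex(logs.index).dropna().astype(bool)
    logs = logs.loc[labels.index]
    complete = logs.notna().all(axis=1)
    excluded = list(logs.index[~complete])
    logs = logs[complete]
    y = labels[complete]
    if (y.sum() < 2) or ((~y).sum() < 2):
        raise ValidationError("need >= 2 complete-case subjects per class to combine pairs")

    means = logs.mean(axis=0).to_numpy()
    sds = logs.std(axis=0, ddof=1).to_numpy()
    signs = np.ones(len(members))
    vote_cutoffs = None
    for j, col in enumerate(logs.columns):
        member_auc = auc_concordance(logs[col][y].to_numpy(), logs[col][~y].to_numpy())
        if member_auc < 0.5:
            signs[j] = -1.0
    if method == "vote":
        vote_cutoffs = np.empty(len(members))
        for j, col in enumerate(logs.columns):
            c = roc_curve(logs[col][y].to_numpy(), logs[col][~y].to_numpy(), "auto")
            vote_cutoffs[j] = c.best_cutoff
            signs[j] = 1.0 if c.direction == "case_high" else -1.0

    weights = np.full(len(members), 1.0 / len(members))
    scores = combination_scores(
        logs, means=means, sds=sds, signs=signs, weights=weights,
        method=method, vote_cutoffs=vote_cutoffs,
    )
    curve = roc_curve(scores[y].to_numpy(), scores[~y].to_numpy(), "case_high")
    return PairCombination(
        member_pairs=members,
        weights=weights,
        means=means,
        sds=sds,
        signs=signs,
        method=method,
        vote_cutoffs=vote_cutoffs,
        combined_scores=scores,
        excluded_subjects=excluded,
        curve=curve,
    )


def combination_scores(
    logs: pd.DataFrame,
    *,
    means: np.ndarray,
    sds: np.ndarray,
    signs: np.ndarray,
    weights: np.ndarray,
    method: str = "mean",
    vote_cutoffs: np.ndarray | None = None,
) -> pd.Series:
    """Apply frozen combination parameters to log10 member values."""
    if method == "mean":
        safe_sd = np.where(sds > 0, sds, 1.0)
        z = signs * (logs.to_numpy() - means) / safe_sd
        z[:, sds == 0] = 0.0
    else:
        z = (signs * (logs.to_numpy() - vote_cutoffs) > 0).astype(float)
    return pd.Series(z @ weights, index=logs.index)


# ---------------------------------------------------------------------------
# sklearn estimators


class CutoffClassifier(BaseEstimator, ClassifierMixin):
    """Single-score threshold classifier at the best-accuracy ROC cutoff.

    Fit on a 1-column array (or 1-d vector) of scores with binary labels;
    predicts 1 (case) on the pathological side of the fitted cutoff.
    """

    def __init__(self, direction: str = "auto"):
        self.direction = direction

    def fit(self, X, y):
        scores = np.asarray(X, float).reshape(len(y), -1)
        if scores.shape[1] != 1:
            raise ValidationError("CutoffClassifier expects a single score column")
        scores = scores[:, 0]
        y = np.asarray(y).astype(bool)
        curve = roc_curve(scores[y], scores[~y], self.direction)
        self.classes_ = np.array([0, 1])
        self.curve_ = curve
        self.cutoff_ = curve.best_cutoff
        self.direction_ = curve.direction
        self.auc_ = curve.auc
        self.sensitivity_ = curve.best_sensitivity
        self.specificity_ = curve.best_specificity
        self.accuracy_ = curve.best_accuracy
        return self

    def decision_function(self, X):
        s = np.asarray(X, float).reshape(-1)
        return s - self.cutoff_ if self.direction_ == "case_high" else self.cutoff_ - s

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


class PairCombinationClassifier(BaseEstimator, ClassifierMixin):
    """Multi-pair combination score with a best-accuracy cutoff, as a classifier.

    ``members`` are (numerator, denominator) pairs to average; X is a
    subject x pair ratio DataFrame (columns "num/den", linear scale). The
    standardization constants, orientations and the cutoff are frozen at fit
    time, so predictions on held-out subjects use the training calibration.
    """

    def __init__(self, members: Sequence[tuple[str, str]] = (), method: str = "mean"):
        self.members = members
        self.method = method

    def _logs(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for j, (num, den) in enumerate(self.members_):
            lbl = pair_label(num, den)
            rev = pair_label(den, num)
            if lbl in X.columns:
                vals = X[lbl].astype(float)
            elif rev in X.columns:
                from .pair_ratio import RECIPROCAL_PRODUCT

                vals = RECIPROCAL_PRODUCT / X[rev].astype(float)
            else:
                raise ValidationError(f"ratio matrix lacks pair {lbl}")
            cols[f"{j}:{lbl}"] = np.log10(vals)
        return pd.DataFrame(cols, index=X.index)

    def fit(self, X: pd.DataFrame, y):
        self.members_ = [tuple(m) for m in self.members]
        if not self.members_:
            raise ValidationError("no member pairs given")
        y = pd.Series(np.asarray(y).astype(bool), index=X.index)
        logs = self._logs(X)
        labels = y.reindex(logs.index).astype(bool)
        complete = logs.notna().all(axis=1)
        self.excluded_subjects_ = list(logs.index[~complete])
        logs, labels = logs[complete], labels[complete]
        if labels.sum() < 2 or (~labels).sum() < 2:
            raise ValidationError("need >= 2 complete-case subjects per class")
        self.means_ = logs.mean(axis=0).to_numpy()
        self.sds_ = logs.std(axis=0, ddof=1).to_numpy()
        self.signs_ = np.ones(len(self.members_))
        self.vote_cutoffs_ = None
        for j, col in enumerate(logs.columns):
            a = auc_concordance(logs[col][labels].to_numpy(), logs[col][~labels].to_numpy())
            if a < 0.5:
                self.signs_[j] = -1.0
        if self.method == "vote":
            self.vote_cutoffs_ = np.empty(len(self.members_))
            for j, col in enumerate(logs.columns):
                c = roc_curve(logs[col][labels].to_numpy(), logs[col][~labels].to_numpy(), "auto")
                self.vote_cutoffs_[j] = c.best_cutoff
                self.signs_[j] = 1.0 if c.direction == "case_high" else -1.0
        self.weights_ = np.full(len(self.members_), 1.0 / len(self.members_))
        scores = combination_scores(
            logs, means=self.means_, sds=self.sds_, signs=self.signs_,
            weights=self.weights_, method=self.method, vote_cutoffs=self.vote_cutoffs_,
        )
        curve = roc_curve(scores[labels].to_numpy(), scores[~labels].to_numpy(), "case_high")
        self.curve_ = curve
        self.cutoff_ = curve.best_cutoff
        self.auc_ = curve.auc
        self.accuracy_ = curve.best_accuracy
        self.sensitivity_ = curve.best_sensitivity
        self.specificity_ = curve.best_specificity
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X: pd.DataFrame):
        logs = self._logs(X)
        scores = combination_scores(
            logs, means=self.means_, sds=self.sds_, signs=self.signs_,
            weights=self.weights_, method=self.method, vote_cutoffs=self.vote_cutoffs_,
        )
        return (scores - self.cutoff_).to_numpy()

    def predict(self, X: pd.DataFrame):
        return (self.decision_function(X) > 0).astype(int)
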