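"""Exhaustive nonparametric screening of miRNA-pair ratios.

Every unordered pair's ratio distribution is compared between two subject
groups with a two-sided Mann-Whitney U test; significance is judged against a
Bonferroni-corrected threshold whose denominator is always the full
combinatorial pair count of the panel, m(m-1)/2, regardless of how many pairs
survive data-completeness filters — a panel of 8 miRNAs tests against
0.05/28, a panel of 18 against 0.05/153. Each screened pair also carries its
ROC summary (AUC, best-accuracy cutoff, sensitivity/specificity/accuracy) so
a single table ranks candidate biomarker pairs.

Pairs are reported in the orientation whose AUC is >= 0.5 (cases tend to have
the higher ratio); the reverse orientation is the reciprocal and carries the
same information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .pair_ratio import PairRatioMatrix, RECIPROCAL_PRODUCT, pair_label
from .roc_analysis import roc_curve

#: group sizes at or below which the exact U distribution is enumerated
EXACT_N_MAX = 10


@dataclass
class PairScreenResult:
    """Screening summary for one miRNA pair (reported orientation)."""

    pair: tuple[str, str]
    n_case: int
    n_control: int
    u_statistic: float
    p_value: float
    bonferroni_alpha: float
    significant: bool
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    note: str = ""

    @property
    def label(self) -> str:
        return pair_label(*self.pair)


@dataclass(frozen=True)
class PowerParams:
    """Inputs to the case-control sample-size estimate.

    ``standardized_difference`` is the between-group mean difference divided
    by the common standard deviation.
    """

    alpha: float
    power: float
    standardized_difference: float

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if not (0 < self.power < 1):
            raise ValidationError("power must be in (0, 1)")
        if self.standardized_difference <= 0:
            raise ValidationError("standardized_difference must be > 0")


@dataclass(frozen=True)
class SampleSizeResult:
    n_per_group: int
    n_total: int
    formula: str


def mann_whitney(group_a, group_b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group_a, p-value).

    ``mode='auto'`` enumerates the exact null distribution when
    min(n_a, n_b) <= 10 and the pooled data are tie-free, and otherwise uses
    the normal approximation with midrank tie correction and continuity
    correction. Two identical samples (zero pooled variance) give p = 1.
    """
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError("mode must be 'auto', 'exact' or 'normal'")
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 non-missing values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # all values identical across both groups
        return len(a) * len(b) / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "exact" or (mode == "auto" and min(len(a), len(b)) <= EXACT_N_MAX and not has_ties):
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni_alpha(panel_size: int, family_alpha: float = 0.05) -> float:
    """Family-wise threshold: family_alpha divided by the pair count m(m-1)/2."""
    if panel_size < 2:
        raise ValidationError("panel_size must be >= 2")
    if not (0 < family_alpha <= 1):
        raise ValidationError("family_alpha must be in (0, 1]")
    return family_alpha / (panel_size * (panel_size - 1) / 2)


def screen_pairs(
    matrix: PairRatioMatrix,
    labels: pd.Series,
    family_alpha: float = 0.05,
    panel_size: int | None = None,
    mode: str = "auto",
) -> list[PairScreenResult]:
    """Screen every pair in the matrix between cases and controls.

    ``labels`` maps subject_id -> True (case) / False (control); subjects
    absent from ``labels`` are ignored. Missing ratios are dropped per pair
    (pairwise deletion), so each pair may have its own n. Pairs with fewer
    than 2 usable subjects in either class are flagged ``insufficient data``
    and sorted last. Results are sorted by ascending p-value, ties broken by
    pair label.
    """
    labels = pd.Series(labels).dropna().astype(bool)
    if bool(labels.all()) or not bool(labels.any()):
        raise ValidationError("labels must contain both cases and controls")
    if panel_size is None:
        panel_size = len(matrix.mirnas)
    alpha_corr = bonferroni_alpha(panel_size, family_alpha)

    case_ids = labels.index[labels]
    ctrl_ids = labels.index[~labels]
    results: list[PairScreenResult] = []
    for num, den in matrix.pairs:
        col = matrix.values[pair_label(num, den)]
        x = col.reindex(case_ids).dropna().to_numpy(float)
        y = col.reindex(ctrl_ids).dropna().to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            results.append(
                PairScreenResult(
                    pair=(num, den), n_case=len(x), n_control=len(y),
                    u_statistic=float("nan"), p_value=float("nan"),
                    bonferroni_alpha=alpha_corr, significant=False,
                    auc=float("nan"), cutoff=float("nan"),
                    sensitivity=float("nan"), specificity=float("nan"),
                    accuracy=float("nan"), note="insufficient data",
                )
            )
            continue
        u, p = mann_whitney(x, y, mode=mode)
        auc_high = u / (len(x) * len(y))
        if auc_high < 0.5:
            # report the orientation with AUC >= 0.5: flip numerator/denominator
            num, den = den, num
            x, y = RECIPROCAL_PRODUCT / x, RECIPROCAL_PRODUCT / y
            u = len(x) * len(y) - u
        curve = roc_curve(x, y, direction="case_high")
        results.append(
            PairScreenResult(
                pair=(num, den), n_case=len(x), n_control=len(y),
                u_statistic=u, p_value=p, bonferroni_alpha=alpha_corr,
                significant=bool(p < alpha_corr), auc=curve.auc,
                cutoff=curve.best_cutoff, sensitivity=curve.best_sensitivity,
                specificity=curve.best_specificity, accuracy=curve.best_accuracy,
            )
        )
    results.sort(key=lambda r: (r.p_value if r.p_value == r.p_value else math.inf, r.label))
    return results


def sample_size(params: PowerParams) -> SampleSizeResult:
    """Equal-allocation two-group sample size from the normal approximation.

    n per group = ceil( 2 * (z_{1-alpha/2} + z_{power})^2 / d^2 ), total = 2n.
    The returned object carries the formula string for auditability.
    """
    z_alpha = stats.norm.ppf(1 - params.alpha / 2)
    z_beta = stats.norm.ppf(params.power)
    d = params.standardized_difference
    n_per_group = math.ceil(2 * (z_alpha + z_beta) ** 2 / d**2)
    return SampleSizeResult(
        n_per_group=n_per_group,
        n_total=2 * n_per_group,
        formula="n_per_group = ceil(2*(z_{1-alpha/2} + z_{power})^2 / d^2); n_total = 2*n_per_group",
    )


class PairScreenSelector(BaseEstimator):
    """Sklearn-style feature selector over a pair-ratio matrix.

    ``fit(X, y)`` screens every ratio column (X: subject x pair DataFrame,
    y: binary labels) and keeps the Bonferroni-significant pairs, best-p
    first, truncated to ``max_pairs``; ``transform`` returns the selected
    columns. ``panel_size`` fixes the Bonferroni denominator; by default it is
    inferred from the pair columns' distinct miRNA names.
    """

    def __init__(self, family_alpha: float = 0.05, max_pairs: int | None = None,
                 panel_size: int | None = None, mode: str = "auto"):
        self.family_alpha = family_alpha
        self.max_pairs = max_pairs
        self.panel_size = panel_size
        self.mode = mode

    def fit(self, X: pd.DataFrame, y):
        mirnas = sorted({name for col in X.columns for name in col.split("/")})
        pairs = [tuple(col.split("/")) for col in X.columns]
        matrix = PairRatioMatrix(mirnas=mirnas, pairs=pairs, values=X)
        labels = pd.Series(np.asarray(y).astype(bool), index=X.index)
        self.results_ = screen_pairs(
            matrix, labels, family_alpha=self.family_alpha,
            panel_size=self.panel_size or len(mirnas), mode=self.mode,
        )
        sig = [r for r in self.results_ if r.significant]
        if self.max_pairs is not None:
            sig = sig[: self.max_pairs]
        self.selected_results_ = sig
        self.selected_pairs_ = [r.pair for r in sig]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = []
        for num, den in self.selected_pairs_:
            lbl, rev = pair_label(num, den), pair_label(den, num)
            cols.append(lbl if lbl in X.columns else rev)
        return X[cols]
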