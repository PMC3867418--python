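"""The pair-ratio statistic: within-subject miRNA concentration ratios.

A single RT-qPCR cycle corresponds to a two-fold concentration difference, so
for two miRNAs measured in the same sample the quantity ``2**(-dCq) * 100``
with ``dCq = Cq(numerator) - Cq(denominator)`` estimates their concentration
ratio (scaled by 100). Because any sample-wide nuisance — extraction yield,
RT-qPCR inhibition — shifts all Cq values of a subject by the same constant,
it cancels exactly in every pair ratio. That cancellation is the entire point
of using pairs instead of single-miRNA levels, and this module is where it
happens.

Ratios are carried on the linear scale; take ``log10`` only for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .panel_io import CqDataset

RATIO_SCALE = 100.0
#: value(a,b) * value(b,a) for any defined pair (= RATIO_SCALE**2).
RECIPROCAL_PRODUCT = RATIO_SCALE**2


def compute_ratio(cq_num, cq_den):
    """``2**(-(cq_num - cq_den)) * 100`` — the pair statistic.

    Accepts scalars or numpy arrays; NaN inputs propagate to NaN outputs
    (missing in, missing out — never an exception).
    """
    cq_num = np.asarray(cq_num, dtype=float)
    cq_den = np.asarray(cq_den, dtype=float)
    out = RATIO_SCALE * np.exp2(-(cq_num - cq_den))
    return out if out.ndim else float(out)


def sum_ratio(cq_values_num: Sequence[float], cq_values_den: Sequence[float]) -> float:
    """Ratio with sums of several miRNAs in the numerator and/or denominator.

    Summation happens on the linear concentration scale (``2**-Cq``), since a
    "sum of miRNAs" is a sum of amounts and Cq is logarithmic:
    ``100 * sum_i 2**-cq_num_i / sum_j 2**-cq_den_j``. With singleton lists
    this reduces exactly to :func:`compute_ratio`. Any missing member makes
    the result missing; empty lists are a validation error.
    """
    num = np.asarray(cq_values_num, dtype=float)
    den = np.asarray(cq_values_den, dtype=float)
    if num.size == 0 or den.size == 0:
        raise ValidationError("sum_ratio: numerator and denominator lists must be nonempty")
    if np.isnan(num).any() or np.isnan(den).any():
        return float("nan")
    return float(RATIO_SCALE * np.exp2(-num).sum() / np.exp2(-den).sum())


def pair_label(numerator: str, denominator: str) -> str:
    return f"{numerator}/{denominator}"


@dataclass
class PairRatioMatrix:
    """Subject x pair grid of ratio values.

    ``pairs`` lists each unordered pair once, members in lexicographic order
    (canonical orientation); ``values`` columns are labelled
    ``"numerator/denominator"``. For a panel of m miRNAs there are
    m(m-1)/2 pairs.
    """

    mirnas: list[str]
    pairs: list[tuple[str, str]]
    values: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def column(self, numerator: str, denominator: str) -> pd.Series:
        """Values for an ordered pair; the reverse orientation is 10^4 / value."""
        key = (numerator, denominator)
        if key in set(self.pairs):
            return self.values[pair_label(*key)]
        rev = (denominator, numerator)
        if rev in set(self.pairs):
            return RECIPROCAL_PRODUCT / self.values[pair_label(*rev)]
        raise ValidationError(f"pair {pair_label(*key)} not in matrix")

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index=True)


def all_pair_ratios(ds: CqDataset | pd.DataFrame) -> PairRatioMatrix:
    """Compute ratios for every unordered miRNA pair, per subject.

    Accepts an aggregated :class:`CqDataset` or a bare subject x miRNA
    consensus-Cq DataFrame. Missing consensus Cq for either member makes that
    subject's ratio missing (pairwise deletion happens downstream, per pair).
    """
    if isinstance(ds, CqDataset):
        if ds.aggregated is None:
            raise ValidationError("dataset must be aggregated before computing pair ratios")
        wide = ds.aggregated
    else:
        wide = ds
    names = sorted(wide.columns)
    if len(names) < 2:
        raise ValidationError("need a panel of at least 2 miRNAs to form pairs")
    pairs = list(combinations(names, 2))
    cols = {
        pair_label(a, b): compute_ratio(wide[a].to_numpy(), wide[b].to_numpy())
        for a, b in pairs
    }
    values = pd.DataFrame(cols, index=wide.index)
    return PairRatioMatrix(mirnas=names, pairs=pairs, values=values)


class PairRatioTransformer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: consensus-Cq matrix -> pair-ratio matrix.

    Input X is a DataFrame of subject x miRNA consensus Cq values; the output
    is the subject x pair DataFrame of ``2**-dCq * 100`` values. Stateless
    apart from recording the panel seen at fit.
    """

    def fit(self, X: pd.DataFrame, y=None):
        if X.shape[1] < 2:
            raise ValidationError("need >= 2 miRNA columns")
        self.mirnas_ = sorted(X.columns)
        self.pairs_ = list(combinations(self.mirnas_, 2))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = set(self.mirnas_) - set(X.columns)
        if missing:
            raise ValidationError(f"input lacks fitted miRNA column(s): {sorted(missing)}")
        return all_pair_ratios(X[self.mirnas_]).values

    def get_feature_names_out(self, input_features=None):
        return np.asarray([pair_label(a, b) for a, b in self.pairs_], dtype=object)
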