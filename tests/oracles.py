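"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: exhaustive enumeration and full scans,
written without reference to the library code they validate.
"""

from itertools import combinations

import numpy as np


def mw_u(x, y):
    """U statistic of x against y by direct pair counting (ties = 1/2)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return gt + 0.5 * eq


def exact_mw_pvalue(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of group labelings.

    Enumerates every way of assigning len(x) of the pooled values to the first
    group and counts assignments whose U is at least as far from the null mean
    n1*n2/2 as the observed U. Valid for tie-free data (where the U null
    distribution is symmetric); feasible for n1+n2 <= ~12.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    center = n1 * len(y) / 2.0
    observed = abs(mw_u(x, y) - center)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = mw_u(pooled[mask], pooled[~mask])
        hits += abs(u - center) >= observed - 1e-12
        total += 1
    return hits / total


def best_accuracy_scan(cases, controls, direction):
    """Exhaustive best-accuracy operating point scan.

    Candidates are the interior midpoints plus the below/above sentinels;
    preference order is accuracy desc, interior before sentinel, sensitivity
    desc, lower cutoff. Returns (cutoff, sensitivity, specificity, accuracy).
    """
    cases, controls = np.asarray(cases, float), np.asarray(controls, float)
    pooled = np.unique(np.concatenate([cases, controls]))
    lo, hi = pooled[0], pooled[-1]
    # all-positive scores (ratio-like) get multiplicative sentinels
    sentinels = [lo / 2.0, hi * 2.0] if lo > 0 else [lo - 1.0, hi + 1.0]
    cands = [(t, True) for t in (pooled[:-1] + pooled[1:]) / 2.0]
    cands += [(t, False) for t in sentinels]
    best = None
    for t, interior in cands:
        if direction == "case_high":
            sens = (cases > t).mean()
            spec = (controls <= t).mean()
        else:
            sens = (cases < t).mean()
            spec = (controls >= t).mean()
        acc = (sens * len(cases) + spec * len(controls)) / (len(cases) + len(controls))
        key = (-acc, not interior, -sens, t)
        if best is None or key < best[0]:
            best = (key, (t, sens, spec, acc))
    return best[1]


def auc_pair_count(cases, controls):
    """AUC by direct concordance counting."""
    return mw_u(cases, controls) / (len(cases) * len(controls))
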