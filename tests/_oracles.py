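"""Independent oracles used by unit and acceptance tests.

These are deliberately written from the textbook definitions, separate from
the package implementations they check: a plain expansion/inflation MCL
loop without pruning or adaptive self-loops, and the Mann-Whitney identity
for AUCROC.
"""

import numpy as np
from scipy.stats import mannwhitneyu


def reference_mcl_partition(weights: np.ndarray, inflation: float,
                            self_loop: float = 1.0, iters: int = 200):
    """Textbook MCL on a dense symmetric weight matrix.

    Returns the partition as a set of frozensets of node indices. Clusters
    are read off the idempotent limit: each row with positive diagonal is
    an attractor, its positive entries form a cluster, overlapping clusters
    are merged.
    """
    m = weights.astype(float).copy()
    np.fill_diagonal(m, self_loop)
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(iters):
        m = np.linalg.matrix_power(m, 2)
        m = m ** inflation
        m /= m.sum(axis=0, keepdims=True)
    n = m.shape[0]
    clusters = []
    for i in range(n):
        if m[i, i] > 1e-6:
            support = set(np.nonzero(m[i] > 1e-6)[0].tolist())
            merged = [c for c in clusters if c & support]
            for c in merged:
                support |= c
                clusters.remove(c)
            clusters.append(support)
    return {frozenset(c) for c in clusters}


def mann_whitney_auc(scores, labels) -> float:
    """AUCROC via the rank-sum identity U / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def finite_difference_gradient(loss_fn, params: dict, key: str, idx,
                               h: float = 1e-6) -> float:
    """Central-difference derivative of ``loss_fn()`` wrt params[key][idx]."""
    orig = params[key][idx]
    params[key][idx] = orig + h
    lp = loss_fn()
    params[key][idx] = orig - h
    lm = loss_fn()
    params[key][idx] = orig
    return (lp - lm) / (2 * h)
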