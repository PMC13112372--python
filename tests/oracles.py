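"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive (enumeration / direct definitions) and
shares no code with the implementation it checks.
"""

from itertools import combinations
from math import comb

import numpy as np


def bh_min_over_tails(pvalues):
    """BH adjusted p-values by the literal min-over-tails definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_idx, i in enumerate(order):
        tail = [
            m * p[order[j]] / (j + 1) for j in range(rank_idx, m)
        ]
        adj[i] = min(1.0, min(tail))
    return adj


def hypergeom_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    total = comb(N, n)
    upper = min(K, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, upper + 1)) / total


def auc_pair_counting(scores, labels):
    """AUC as the fraction of (case, control) pairs ranked correctly,
    ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (pos.size * neg.size)
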