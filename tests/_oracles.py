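"""Independent brute-force oracles used by the test suite.

Deliberately naive O(n²)/exponential implementations kept free of any code
path from the package under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_u(a, b) -> float:
    """#(a > b) + ½·#(a == b) by double loop."""
    return float(sum((x > y) + 0.5 * (x == y) for x in a for y in b))


def brute_exact_p(a, b) -> float:
    """Two-sided permutation p of the U statistic by full enumeration."""
    combined = list(a) + list(b)
    n1 = len(a)
    idx = range(len(combined))
    centre = n1 * len(b) / 2.0
    d_obs = abs(brute_u(a, b) - centre)
    hits = total = 0
    for pick in itertools.combinations(idx, n1):
        chosen = set(pick)
        aa = [combined[i] for i in pick]
        bb = [combined[i] for i in idx if i not in chosen]
        total += 1
        if abs(brute_u(aa, bb) - centre) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def brute_auc(pos_scores, neg_scores) -> float:
    """P(pos > neg) with ties half-weighted, by double loop."""
    n = len(pos_scores) * len(neg_scores)
    return brute_u(pos_scores, neg_scores) / n


def brute_youden(delta_ct, labels, orientation) -> float:
    """Best J over every midpoint threshold (plus ±∞) by exhaustive scan.

    ``orientation`` follows the package convention: HGG_low_delta_ct means
    predict HGG iff ΔCt ≤ t.
    """
    d = np.asarray(delta_ct, float)
    lab = np.asarray(labels)
    keep = np.isfinite(d)
    d, lab = d[keep], lab[keep]
    pos, neg = d[lab == "HGG"], d[lab != "HGG"]
    values = np.unique(d)
    mids = (values[:-1] + values[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    best = -np.inf
    for t in thresholds:
        if orientation == "HGG_low_delta_ct":
            sens = np.mean(pos <= t)
            spec = np.mean(neg > t)
        else:
            sens = np.mean(pos >= t)
            spec = np.mean(neg < t)
        best = max(best, sens + spec - 1.0)
    return float(best)
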