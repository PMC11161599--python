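"""Independent partition-metric oracles used by the test suite.

Everything here works directly on label vectors via explicit pair
enumeration or probability tables — never through the package's
contingency-table code paths — so agreement is a genuine cross-check.
"""

import itertools
import math

import numpy as np


def set_partitions(n, max_blocks):
    """All label vectors of n items into at most max_blocks blocks
    (canonical first-appearance labeling, so each partition appears once)."""
    out = []

    def rec(prefix, used):
        if len(prefix) == n:
            out.append(tuple(prefix))
            return
        for lab in range(min(used + 1, max_blocks)):
            rec(prefix + [lab], max(used, lab + 1))

    rec([], 0)
    return out


def pair_arrays(n):
    idx = np.array(list(itertools.combinations(range(n), 2)))
    return idx[:, 0], idx[:, 1]


def ari_pairs(a, b, ia, ib):
    """ARI from explicit pair counting: (TP+TN - E)/(C(n,2) - E) form."""
    a, b = np.asarray(a), np.asarray(b)
    same_a = a[ia] == a[ib]
    same_b = b[ia] == b[ib]
    tp = np.sum(same_a & same_b)
    fp = np.sum(same_a & ~same_b)
    fn = np.sum(~same_a & same_b)
    total = len(ia)
    expected = (tp + fp) * (tp + fn) / total
    max_index = 0.5 * ((tp + fp) + (tp + fn))
    if max_index == expected:
        return 1.0 if tp == expected else 0.0
    return (tp - expected) / (max_index - expected)


def fmi_pairs(a, b, ia, ib):
    a, b = np.asarray(a), np.asarray(b)
    same_a = a[ia] == a[ib]
    same_b = b[ia] == b[ib]
    tp = np.sum(same_a & same_b)
    fp = np.sum(same_a & ~same_b)
    fn = np.sum(~same_a & same_b)
    if tp == 0:
        return 0.0
    return math.sqrt(tp / (tp + fp) * tp / (tp + fn))


def nmi_probability(a, b):
    """NMI from probability tables: I / sqrt(H_a * H_b), natural log."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    mi = 0.0
    for la in set(a.tolist()):
        for lb in set(b.tolist()):
            p_ab = np.sum((a == la) & (b == lb)) / n
            if p_ab > 0:
                p_a = np.sum(a == la) / n
                p_b = np.sum(b == lb) / n
                mi += p_ab * math.log(p_ab / (p_a * p_b))
    def entropy(x):
        return -sum(
            (np.sum(x == l) / n) * math.log(np.sum(x == l) / n) for l in set(x.tolist())
        )
    h = entropy(a) * entropy(b)
    if h <= 0:
        return 0.0
    return max(mi, 0.0) / math.sqrt(h)


def jaccard_sets(a, b, la, lb):
    """Jaccard index of two clusters as explicit cell-index sets."""
    sa = {i for i, x in enumerate(a) if x == la}
    sb = {i for i, x in enumerate(b) if x == lb}
    return len(sa & sb) / len(sa | sb) if sa | sb else 0.0


def jaccard_best_match(a, b):
    """Mean over b's clusters of the best Jaccard against any a-cluster."""
    return float(
        np.mean(
            [
                max(jaccard_sets(a, b, la, lb) for la in set(a))
                for lb in set(b)
            ]
        )
    )


def purity_counts(a, b):
    """For each a-cluster take its most common b-label; sum and normalize."""
    total = 0
    for la in set(a):
        members = [b[i] for i, x in enumerate(a) if x == la]
        total += max(members.count(lb) for lb in set(members))
    return total / len(a)
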