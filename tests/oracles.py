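"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity from first principles (double loops, full
enumeration, pair counting) and deliberately shares no code with the
implementation it validates.
"""

import itertools
import math

import numpy as np


def naive_cosine(X):
    """Double-loop column cosine distances."""
    n = X.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            u, v = X[:, i], X[:, j]
            D[i, j] = 1.0 - (u @ v) / (math.sqrt(u @ u) * math.sqrt(v @ v))
    return D


def naive_agglomerate(labels, D, method="average"):
    """From-scratch agglomeration recomputing cluster distances over all leaf
    pairs at every step, with smallest-label tie-breaking."""
    clusters = {i: frozenset([i]) for i in range(len(labels))}
    merges = []
    nid = len(labels)
    while len(clusters) > 1:
        candidates = []
        for a, b in itertools.combinations(sorted(clusters), 2):
            pairs = [D[i][j] for i in clusters[a] for j in clusters[b]]
            if method == "average":
                d = sum(pairs) / len(pairs)
            elif method == "complete":
                d = max(pairs)
            else:
                d = min(pairs)
            la = min(labels[i] for i in clusters[a])
            lb = min(labels[i] for i in clusters[b])
            candidates.append(((d, *sorted((la, lb))), a, b))
        (d, _, _), a, b = min(candidates)
        clusters[nid] = clusters.pop(a) | clusters.pop(b)
        merges.append((min(a, b), max(a, b), d, len(clusters[nid])))
        nid += 1
    return merges


def enumerate_signed_rank_p(diffs):
    """Exact two-sided signed-rank p by full 2^n enumeration of sign vectors."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    observed = min(w_plus, ranks.sum() - w_plus)
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        s = np.asarray(signs)
        wp = ranks[s > 0].sum()
        if min(wp, ranks.sum() - wp) <= observed + 1e-12:
            count += 1
    return count / 2 ** n


def pair_count_ari(labels_a, labels_b):
    """Adjusted Rand index by explicit pair counting."""
    n = len(labels_a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    maximum = ((ss + sd) + (ss + ds)) / 2
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)
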