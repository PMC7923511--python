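"""Independent brute-force oracles used by the test suite.

Everything here is a literal per-position / per-candidate transcription of the
defining formulas, kept deliberately separate from (and slower than) the
package implementations it checks.
"""

import itertools
import math


def recount(u, v):
    """Per-position recount of the 2x2 contingency table."""
    n11 = n10 = n01 = n00 = 0
    for a, b in zip(u, v):
        if a and b:
            n11 += 1
        elif a and not b:
            n10 += 1
        elif not a and b:
            n01 += 1
        else:
            n00 += 1
    return n11, n10, n01, n00


def metric_by_formula(name, u, v):
    """Literal transcription of each metric's defining formula."""
    n11, n10, n01, n00 = recount(u, v)
    n = n11 + n10 + n01 + n00
    if name in ("jaccard", "binary"):
        den = n11 + n10 + n01
        return 0.0 if den == 0 else 1.0 - n11 / den
    if name == "sokal-michener":
        return 1.0 - (n11 + n00) / n
    if name == "hamming":
        return (n10 + n01) / n
    if name == "russell-rao":
        return 1.0 - n11 / n
    if name == "pearson":
        den = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
        if den == 0:
            return 0.0 if (n10 + n01) == 0 else 1.0
        phi = (n11 * n00 - n10 * n01) / math.sqrt(den)
        return (1.0 - phi) / 2.0
    if name == "goodman-kruskal":
        sigma = max(n11, n10) + max(n01, n00) + max(n11, n01) + max(n10, n00)
        sigma_p = max(n11 + n01, n10 + n00) + max(n11 + n10, n01 + n00)
        if 2 * n == sigma_p:
            return 0.0
        return 1.0 - (sigma - sigma_p) / (2 * n - sigma_p)
    if name in ("manhattan", "canberra"):
        return float(n10 + n01)
    if name == "euclidean":
        return math.sqrt(n10 + n01)
    raise KeyError(name)


def grid_argmax_dimension(eigenvalues, n, thetas):
    """Dense-grid argmax of L(q) - theta*q (ties -> largest q)."""
    d = len(eigenvalues)
    pos = sum(1 for x in eigenvalues if x > 0)
    q_max = min(d - 1, pos - 1)
    L = []
    for q in range(q_max + 1):
        head = sum(math.log(eigenvalues[j]) for j in range(q))
        tail = sum(eigenvalues[q:])
        L.append(-(n / 2.0) * (head + (d - q) * math.log(tail / (d - q))))
    out = []
    for theta in thetas:
        best_q, best_val = 0, -math.inf
        for q in range(q_max + 1):
            val = L[q] - theta * q
            if val >= best_val:  # ties -> largest q
                best_val, best_q = val, q
        out.append(best_q)
    return out


def exhaustive_pam_cost(D, K):
    """Minimum total distance over all C(n, K) medoid sets."""
    n = len(D)
    best = math.inf
    for medoids in itertools.combinations(range(n), K):
        cost = sum(min(D[i][m] for m in medoids) for i in range(n))
        best = min(best, cost)
    return best


def broken_stick_threshold(k, d):
    """b_k = (1/d) * sum_{i=k..d} 1/i, transcribed directly."""
    return sum(1.0 / i for i in range(k, d + 1)) / d
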