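"""Definition-literal reference implementations used only by tests.

Everything here is written with explicit loops, directly from the defining
formulas, and stays independent of the package's vectorized code paths.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
from scipy.stats import rankdata


def kendalls_w_loops(series) -> float:
    """Kendall's W from first principles: explicit rank matrix, loop sums."""
    series = np.asarray(series, dtype=float)
    k, t = series.shape
    ranks = np.zeros((k, t))
    for i in range(k):
        ranks[i] = rankdata(series[i])
    r = [0.0] * t
    for tt in range(t):
        for i in range(k):
            r[tt] += ranks[i][tt]
    rbar = sum(r) / t
    ss = sum((x - rbar) ** 2 for x in r)
    return 12.0 * ss / (k * k * (t**3 - t))


def pearson_loops(a, b) -> float:
    a = list(map(float, a))
    b = list(map(float, b))
    t = len(a)
    ma, mb = sum(a) / t, sum(b) / t
    cov = sum((a[i] - ma) * (b[i] - mb) for i in range(t)) / t
    sa = math.sqrt(sum((x - ma) ** 2 for x in a) / t)
    sb = math.sqrt(sum((x - mb) ** 2 for x in b) / t)
    return cov / (sa * sb)


def mcut_loops(regions, f) -> float:
    """MinMaxCut with ordered-pair sums, explicit quadruple loop."""
    total = 0.0
    for i, pi in enumerate(regions):
        within = 0.0
        for u in pi:
            for v in pi:
                if u != v:
                    within += f[u, v]
        between = 0.0
        for j, pj in enumerate(regions):
            if j == i:
                continue
            for u in pi:
                for v in pj:
                    between += f[u, v]
        total += between / within
    return total


def ssc_objective_loops(labels, f, P, e, lam, alpha) -> float:
    """The full clustering objective, summed with explicit loops."""
    n = len(labels)
    total = 0.0
    for c in sorted(set(labels)):
        idx = [u for u in range(n) if labels[u] == c]
        num = 0.0
        for u in idx:
            for v in idx:
                if u != v:
                    num += f[u, v]
                if P is not None:
                    num += lam * alpha * P[u, v]
                if e is not None:
                    num += lam * (1.0 - alpha) * e[u, v]
        denom = 0.0
        for u in idx:
            for v in range(n):
                denom += f[u, v]
        total += num / denom
    return total


def normalized_association_loops(labels, f) -> float:
    """Normalized-cut data term alone (within-sum over cluster degree)."""
    n = len(labels)
    total = 0.0
    for c in sorted(set(labels)):
        idx = [u for u in range(n) if labels[u] == c]
        num = sum(f[u, v] for u in idx for v in idx if u != v)
        denom = sum(f[u, v] for u in idx for v in range(n))
        total += num / denom
    return total


def modified_si_loops(labels, f) -> float:
    n = len(labels)
    clusters = sorted(set(labels))
    vals = []
    for c in clusters:
        idx = [u for u in range(n) if labels[u] == c]
        nc = len(idx)
        a = sum(f[u, v] for u in idx for v in idx if u != v) / (nc * (nc - 1))
        rest = [v for v in range(n) if labels[v] != c]
        b = sum(f[u, v] for u in idx for v in rest) / (nc * (n - nc))
        vals.append((a - b) / max(a, b))
    return sum(vals) / len(vals)


def entropy_loops(prob_rows, base: str = "e") -> float:
    """Mean per-voxel entropy of renormalized label frequencies."""
    log = math.log if base == "e" else math.log2
    hs = []
    for row in prob_rows:
        tot = sum(row)
        if tot == 0:
            continue
        h = 0.0
        for p in row:
            pr = p / tot
            if pr > 0:
                h -= pr * log(pr)
        hs.append(h)
    return sum(hs) / len(hs)


def mpm_rules_loops(probs, labels_order, cum_thresh=0.60, single_thresh=0.50,
                    nb_means=None):
    """Rule-literal MPM decision for a single voxel's frequency vector.

    Returns 0 (excluded) or the assigned label.  ``nb_means`` gives the
    3x3x3-neighborhood mean frequency per label for the tie-break; defaults
    to the voxel's own frequencies (no spatial context).
    """
    cum = sum(probs)
    if not (cum >= cum_thresh or max(probs) >= single_thresh):
        return 0
    top = max(probs)
    tied = [i for i, p in enumerate(probs) if p == top]
    if len(tied) == 1:
        return labels_order[tied[0]]
    if nb_means is None:
        nb_means = probs
    best_nb = max(nb_means[i] for i in tied)
    for i in tied:  # ascending: lowest label wins residual ties
        if nb_means[i] == best_nb:
            return labels_order[i]
    raise AssertionError("unreachable")


def partitions_into_k(n: int, k: int):
    """All partitions of range(n) into exactly k nonempty blocks, as label
    vectors in restricted-growth form (labels 1..k)."""

    def rec(i, labels, n_used):
        if i == n:
            if n_used == k:
                yield labels.copy()
            return
        if n - i < k - n_used:
            return
        for lab in range(1, n_used + 1):
            labels[i] = lab
            yield from rec(i + 1, labels, n_used)
        if n_used < k:
            labels[i] = n_used + 1
            yield from rec(i + 1, labels, n_used + 1)

    yield from rec(0, [0] * n, 0)


def best_label_matching(overlap) -> dict:
    """Brute-force over permutations maximizing total overlap (k x k table)."""
    k = overlap.shape[0]
    best, best_val = None, -1.0
    for perm in permutations(range(k)):
        val = sum(overlap[i, perm[i]] for i in range(k))
        if val > best_val:
            best, best_val = perm, val
    return {i + 1: best[i] + 1 for i in range(k)}


def random_similarity(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric similarity in [0, 2] with zero diagonal."""
    r = rng.uniform(-1.0, 1.0, size=(n, n))
    r = (r + r.T) / 2.0
    f = r + 1.0
    np.fill_diagonal(f, 0.0)
    return f
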