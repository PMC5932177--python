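"""Semi-supervised spectral clustering by weighted kernel k-means, plus the
unsupervised normalized-cut (NCUT) baseline.

The objective maximized over partitions {g_c} of the N ROI voxels into k
clusters is

    J = sum_c [ sum_{u,v in g_c, u!=v} f_uv
                + lam*alpha     * sum_{u,v in g_c} P_uv
                + lam*(1-alpha) * sum_{u,v in g_c} e_uv ]
              / sum_{u in g_c, v in G} f_uv

where f is the functional similarity (r + 1), P restricts f to pairs inside
the same prior region, and e restricts f to spatially adjacent pairs.  With
lam = 0 this is the normalized association (the NCUT data term).  All three
numerator matrices have zero diagonals.

The optimizer exploits the standard equivalence between graph-cut objectives
and weighted kernel k-means: with per-voxel weights w_u = d_u = sum_v f_uv
(the denominators all use f only) and kernel

    K = sigma * diag(1/w) + diag(1/w) @ W @ diag(1/w),
    W = f + lam*alpha*P + lam*(1-alpha)*e,

minimizing the weighted kernel k-means distortion is, up to the constant
sigma*k, equivalent to maximizing J.  sigma is the smallest diagonal shift
making K positive semidefinite, which guarantees the distortion (hence J)
improves monotonically every iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

from .graph import build_similarity_graph
from .io_nifti import LabelMap, ROIMask, VoxelTimeSeriesMatrix
from .prior_extraction import PriorSet

logger = logging.getLogger(__name__)


@dataclass
class SSCConfig:
    """Tunable parameters of the SSC solver.

    k : number of clusters (>= 2).
    lam : weight of the combined prior + spatial terms (lambda >= 0).
    alpha : balance between prior (alpha) and spatial (1 - alpha) terms.
    n_restarts : restarts of the solver; the best objective wins.
    connectivity : spatial neighbor definition for the e matrix (6/18/26).
    """

    k: int = 3
    lam: float = 2.0
    alpha: float = 0.5
    max_iter: int = 100
    n_restarts: int = 10
    tol: float = 1e-8
    seed: int = 0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class Parcellation:
    """A labeling of the ROI voxels with optimization provenance."""

    labels: np.ndarray  # length N, values 1..k, coords order
    objective: float
    method: str  # "ssc" | "ncut"
    config: SSCConfig
    converged: bool = True
    n_iter: int = 0
    objective_trace: list[float] = field(default_factory=list)


def build_prior_matrix(priors: PriorSet, f: np.ndarray) -> np.ndarray:
    """P_uv = f_uv if u and v lie in the same prior region, else 0."""
    n = f.shape[0]
    P = np.zeros_like(f)
    for reg in priors.regions:
        ix = np.ix_(reg, reg)
        P[ix] = f[ix]
    np.fill_diagonal(P, 0.0)
    _ = n
    return P


def _as_dense(m) -> np.ndarray:
    return m.toarray() if sp.issparse(m) else np.asarray(m, dtype=float)


def ssc_objective(
    labels: np.ndarray,
    f: np.ndarray,
    P: np.ndarray | None,
    e,
    lam: float,
    alpha: float,
) -> float:
    """Evaluate J for a given labeling (labels in 1..k, every cluster nonempty).

    With lam = 0 this is the normalized-association data term alone.
    """
    labels = np.asarray(labels)
    if labels.min() < 1:
        raise ValueError("labels must be 1-based cluster indices")
    e_d = _as_dense(e) if e is not None else None
    ks = range(1, int(labels.max()) + 1)
    degree = f.sum(axis=1)
    total = 0.0
    for c in ks:
        idx = np.flatnonzero(labels == c)
        if len(idx) == 0:
            raise ValueError(f"empty cluster {c}")
        denom = float(degree[idx].sum())
        sub_f = f[np.ix_(idx, idx)]
        num = float(sub_f.sum() - np.trace(sub_f))
        if lam > 0:
            if P is not None and alpha > 0:
                num += lam * alpha * float(P[np.ix_(idx, idx)].sum())
            if e_d is not None and alpha < 1:
                num += lam * (1.0 - alpha) * float(e_d[np.ix_(idx, idx)].sum())
        total += num / denom
    return total


def _combined_affinity(f, P, e, lam, alpha) -> np.ndarray:
    W = f.copy()
    if lam > 0:
        if P is not None and alpha > 0:
            W += lam * alpha * P
        if e is not None and alpha < 1:
            W += lam * (1.0 - alpha) * _as_dense(e)
    return W


def _psd_shift(W: np.ndarray, w: np.ndarray) -> float:
    """Smallest diagonal shift sigma making sigma*diag(1/w) + D^-1 W D^-1 PSD."""
    inv_w = 1.0 / w
    M = inv_w[:, None] * W * inv_w[None, :]
    lam_min = float(np.linalg.eigvalsh(M)[0])
    return max(0.0, -lam_min) * float(w.max()) + 1e-12


def weighted_kernel_kmeans(
    W_combined: np.ndarray,
    weights: np.ndarray,
    k: int,
    init_labels: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    f: np.ndarray | None = None,
    sigma: float | None = None,
) -> tuple[np.ndarray, list[float], bool, int]:
    """One run of weighted kernel k-means on the combined affinity.

    Parameters
    ----------
    W_combined : (N, N) symmetric combined numerator affinity.
    weights : (N,) positive voxel weights (the f-degrees).
    init_labels : starting labels in 1..k; every label must appear.
    f : similarity used for the objective trace (defaults to W_combined,
        i.e. the trace reports the objective whose numerator is W_combined).
    sigma : precomputed PSD shift (computed here if None).

    Returns
    -------
    (labels, objective_trace, converged, n_iter); the trace reports
    J(labels) = sum_c W_within(c) / deg_f(c) after each iteration and is
    non-decreasing.
    """
    W = np.asarray(W_combined, dtype=float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("combined affinity must be symmetric")
    w = np.asarray(weights, dtype=float)
    if np.all(w == 0):
        raise ValueError("weights are all zero")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    n = W.shape[0]
    if f is None:
        f = W

    if sigma is None:
        sigma = _psd_shift(W, w)

    def trace_objective(lab: np.ndarray) -> float:
        tot = 0.0
        for c in range(1, k + 1):
            idx = np.flatnonzero(lab == c)
            sub = W[np.ix_(idx, idx)]
            tot += float(sub.sum()) / float(w[idx].sum())
        return tot

    labels = np.asarray(init_labels, dtype=np.int32).copy()
    if set(np.unique(labels)) != set(range(1, k + 1)):
        # repair: seed missing labels with arbitrary voxels
        missing = sorted(set(range(1, k + 1)) - set(np.unique(labels)))
        counts = np.bincount(labels, minlength=k + 1)
        for m in missing:
            donor = int(np.argmax(counts[1:])) + 1
            cand = np.flatnonzero(labels == donor)
            labels[cand[0]] = m
            counts = np.bincount(labels, minlength=k + 1)

    # Kernel entries needed by the assignment step.  With K as in the module
    # docstring, the per-cluster distance (dropping the K_uu constant) is
    #   dist(u, c) = -2 * sum_{v in g_c} w_v K_uv / s_c
    #                + sum_{v,v' in g_c} w_v w_v' K_vv' / s_c^2
    # and w_v K_uv = W_uv / w_u + sigma * [v == u].
    trace: list[float] = []
    converged = False
    prev_obj = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        onehot = np.zeros((n, k))
        onehot[np.arange(n), labels - 1] = 1.0
        s = w @ onehot  # cluster weight sums, length k
        if np.any(s <= 0):
            raise RuntimeError("cluster weight sum collapsed to zero")
        Wsum = W @ onehot  # (N, k): sum_{v in g_c} W_uv

        # quadratic term: sum_{v,v'} w_v w_v' K_vv' = 1^T W 1 (cluster block)
        #                 + sigma * s_c  (diagonal of sigma/w scaled by w^2)
        quad = np.einsum("nc,nc->c", onehot, Wsum) + sigma * s  # length k
        second = quad / (s * s)

        # first term: sum_{v in g_c} w_v K_uv = W_uc / w_u + sigma * [u in g_c]
        first = -2.0 * (Wsum / w[:, None] + sigma * onehot) / s[None, :]
        dist = first + second[None, :]

        new_labels = np.argmin(dist, axis=1).astype(np.int32) + 1
        # stability tie-break: keep the current label when it is within 1e-12
        cur_dist = dist[np.arange(n), labels - 1]
        best_dist = dist[np.arange(n), new_labels - 1]
        keep = cur_dist <= best_dist + 1e-12
        new_labels[keep] = labels[keep]

        # empty-cluster rescue: move the voxel with the worst affinity to its
        # own cluster into each empty one
        counts = np.bincount(new_labels, minlength=k + 1)[1:]
        for c in np.flatnonzero(counts == 0):
            onehot_new = np.zeros((n, k))
            onehot_new[np.arange(n), new_labels - 1] = 1.0
            within_aff = (W @ onehot_new)[np.arange(n), new_labels - 1] / w
            movable = np.flatnonzero(counts[new_labels - 1] > 1)
            if len(movable) == 0:
                break
            worst = movable[np.argmin(within_aff[movable])]
            new_labels[worst] = c + 1
            counts = np.bincount(new_labels, minlength=k + 1)[1:]

        obj = trace_objective(new_labels)
        if obj < prev_obj - 1e-9:
            logger.warning("objective decreased at iter %d: %g -> %g", it, prev_obj, obj)
        trace.append(obj)
        changed = int(np.sum(new_labels != labels))
        labels = new_labels
        if changed == 0 or (prev_obj > -np.inf and obj - prev_obj < tol):
            converged = True
            prev_obj = obj
            break
        prev_obj = obj

    # Incremental refinement: the PSD shift makes the batch phase
    # conservative (large shifts bias points toward their current cluster),
    # so polish with single-point moves that directly increase the
    # normalized-association objective.  Only strictly improving moves are
    # accepted, which keeps the objective trace monotone.
    labels, ref_trace = _refine_single_moves(labels, W, w, k, max_moves=20 * n)
    trace.extend(ref_trace)
    return labels, trace, converged, it


def _refine_single_moves(
    labels: np.ndarray, W: np.ndarray, w: np.ndarray, k: int, max_moves: int
) -> tuple[np.ndarray, list[float]]:
    """Greedy first-improvement hill climbing on J by moving one voxel at a
    time; maintains incremental cluster sums for O(k) move evaluation."""
    labels = labels.copy()
    n = len(labels)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels - 1] = 1.0
    S = W @ onehot  # S[u, c] = sum_{v in g_c} W_uv
    s = w @ onehot  # cluster weight sums
    B = np.einsum("nc,nc->c", onehot, S)  # cluster block sums (ordered pairs)
    counts = np.bincount(labels, minlength=k + 1)[1:]
    trace: list[float] = []
    moves = 0
    improved = True
    while improved and moves < max_moves:
        improved = False
        for u in range(n):
            a = labels[u] - 1
            if counts[a] <= 1:
                continue
            base = B[a] / s[a]
            new_a = (B[a] - 2.0 * S[u, a]) / (s[a] - w[u])
            best_gain, best_b = 0.0, -1
            for b in range(k):
                if b == a:
                    continue
                gain = (
                    new_a
                    + (B[b] + 2.0 * S[u, b]) / (s[b] + w[u])
                    - base
                    - B[b] / s[b]
                )
                if gain > best_gain + 1e-12:
                    best_gain, best_b = gain, b
            if best_b >= 0:
                b = best_b
                B[a] -= 2.0 * S[u, a]
                B[b] += 2.0 * S[u, b]
                s[a] -= w[u]
                s[b] += w[u]
                counts[a] -= 1
                counts[b] += 1
                S[:, a] -= W[:, u]
                S[:, b] += W[:, u]
                labels[u] = b + 1
                moves += 1
                trace.append(float((B / s).sum()))
                improved = True
                if moves >= max_moves:
                    break
    return labels, trace


def _init_from_priors(priors: PriorSet, f: np.ndarray, k: int) -> np.ndarray:
    """Prior voxels take their prior's label; the rest join the prior of
    maximal mean similarity."""
    if len(priors.regions) != k:
        raise ValueError("number of prior regions must equal k")
    n = f.shape[0]
    labels = np.zeros(n, dtype=np.int32)
    for i, reg in enumerate(priors.regions, start=1):
        labels[reg] = i
    free = np.flatnonzero(labels == 0)
    if len(free) > 0:
        mean_sim = np.stack(
            [f[np.ix_(free, reg)].mean(axis=1) for reg in priors.regions], axis=1
        )
        labels[free] = np.argmax(mean_sim, axis=1) + 1
    return labels


def _perturb_labels(labels: np.ndarray, frac: float, k: int, rng: np.random.Generator,
                    frozen: np.ndarray | None = None) -> np.ndarray:
    out = labels.copy()
    cand = np.arange(len(labels)) if frozen is None else np.flatnonzero(~frozen)
    n_flip = int(round(frac * len(cand)))
    if n_flip == 0:
        return out
    flip = rng.choice(cand, size=n_flip, replace=False)
    out[flip] = rng.integers(1, k + 1, size=n_flip)
    return out


def _kmeanspp_init(f: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding on the similarity graph: pick k mutually
    dissimilar seed voxels, assign everyone to the most similar seed."""
    n = f.shape[0]
    seeds = [int(rng.integers(n))]
    for _ in range(k - 1):
        # dissimilarity to the closest chosen seed; f in [0, 2]
        d = np.min(2.0 - f[:, seeds], axis=1)
        d[seeds] = 0.0
        p = d / d.sum() if d.sum() > 0 else np.full(n, 1.0 / n)
        seeds.append(int(rng.choice(n, p=p)))
    labels = np.argmax(f[:, seeds], axis=1).astype(np.int32) + 1
    for i, sv in enumerate(seeds, start=1):
        labels[sv] = i
    return labels


def _solve_multistart(
    W: np.ndarray,
    weights: np.ndarray,
    k: int,
    inits: list[np.ndarray],
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool, int, list[float]]:
    sigma = _psd_shift(W, weights)
    best = None
    for init in inits:
        labels, trace, conv, n_iter = weighted_kernel_kmeans(
            W, weights, k, init, max_iter=max_iter, tol=tol, sigma=sigma
        )
        obj = trace[-1] if trace else -np.inf
        if best is None or obj > best[1]:
            best = (labels, obj, conv, n_iter, trace)
    assert best is not None
    return best


def _relabel_to_priors(labels: np.ndarray, priors: PriorSet, k: int) -> np.ndarray:
    """Optimal one-to-one relabeling of clusters onto prior identities by
    maximum overlap with the prior regions."""
    overlap = np.zeros((k, k))
    for c in range(1, k + 1):
        members = labels == c
        for i, reg in enumerate(priors.regions, start=1):
            overlap[c - 1, i - 1] = int(members[reg].sum())
    row, col = linear_sum_assignment(-overlap)
    mapping = {r + 1: c + 1 for r, c in zip(row, col)}
    return np.array([mapping[c] for c in labels], dtype=np.int32)


def parcellate_ssc(
    ts: VoxelTimeSeriesMatrix,
    roi: ROIMask,
    priors: PriorSet,
    config: SSCConfig,
) -> Parcellation:
    """End-to-end SSC parcellation of one ROI.

    Builds the similarity graph, assembles the combined affinity
    W = f + lam*alpha*P + lam*(1-alpha)*e, initializes from the priors and
    runs the solver with ``n_restarts`` perturbed restarts; deterministic for
    a fixed config seed.
    """
    g = build_similarity_graph(ts, roi, connectivity=config.connectivity)
    P = build_prior_matrix(priors, g.f)
    W = _combined_affinity(g.f, P, g.e, config.lam, config.alpha)

    rng = np.random.default_rng(config.seed)
    base = _init_from_priors(priors, g.f, config.k)
    prior_mask = priors.prior_of_voxel(g.n_voxels) > 0
    inits = [base]
    for _ in range(config.n_restarts - 1):
        inits.append(_perturb_labels(base, 0.2, config.k, rng, frozen=prior_mask))

    labels, obj, conv, n_iter, trace = _solve_multistart(
        W, g.degree, config.k, inits, config.max_iter, config.tol
    )
    # the objective is label-permutation invariant, so anchor cluster
    # identities back to the priors: each cluster takes the label of the
    # prior region it overlaps most (subregions are named after their prior)
    labels = _relabel_to_priors(labels, priors, config.k)
    final_obj = ssc_objective(labels, g.f, P, g.e, config.lam, config.alpha)
    return Parcellation(
        labels=labels, objective=final_obj, method="ssc", config=config,
        converged=conv, n_iter=n_iter, objective_trace=trace,
    )


def parcellate_ncut(
    ts: VoxelTimeSeriesMatrix,
    roi: ROIMask,
    k: int,
    seed: int = 0,
    config: SSCConfig | None = None,
) -> Parcellation:
    """Unsupervised normalized-cut baseline: the same solver with lam = 0
    and k-means++-style random initializations."""
    if config is None:
        config = SSCConfig(k=k, lam=0.0, seed=seed)
    else:
        config = replace(config, k=k, lam=0.0, seed=seed)
    g = build_similarity_graph(ts, roi, connectivity=config.connectivity)
    rng = np.random.default_rng(seed)
    inits = [_kmeanspp_init(g.f, k, rng) for _ in range(config.n_restarts)]
    labels, obj, conv, n_iter, trace = _solve_multistart(
        g.f, g.degree, k, inits, config.max_iter, config.tol
    )
    final_obj = ssc_objective(labels, g.f, None, None, 0.0, 0.0)
    return Parcellation(
        labels=labels, objective=final_obj, method="ncut", config=config,
        converged=conv, n_iter=n_iter, objective_trace=trace,
    )


def match_labels(parc: Parcellation, atlas: LabelMap, roi: ROIMask) -> Parcellation:
    """Relabel clusters to the atlas subregions they overlap most.

    Solved as an optimal one-to-one assignment on the k x k overlap-count
    matrix (total overlap maximized); ties resolved by processing larger
    clusters first toward lower atlas labels, which the assignment solver's
    deterministic ordering reproduces.
    """
    atlas_in_roi = atlas.labels[tuple(roi.coords.T)]
    cluster_ids = sorted(np.unique(parc.labels))
    atlas_ids = sorted(int(v) for v in np.unique(atlas_in_roi) if v != 0)
    overlap = np.zeros((len(cluster_ids), len(atlas_ids)))
    for i, c in enumerate(cluster_ids):
        for j, a in enumerate(atlas_ids):
            overlap[i, j] = np.sum((parc.labels == c) & (atlas_in_roi == a))
    row, col = linear_sum_assignment(-overlap)
    mapping = {cluster_ids[i]: atlas_ids[j] for i, j in zip(row, col)}
    new_labels = np.array([mapping.get(c, c) for c in parc.labels], dtype=np.int32)
    return replace(parc, labels=new_labels)
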