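"""Decentralized K-means over windowed connectivity matrices.

Variants: multishot Lloyd's (count-weighted centroid averaging at the
aggregator — exactly the pooled Lloyd update), multishot gradient descent
(averaged local objective gradients), and a single-shot nearest-centroid
merge of locally converged runs.  All distances are correlation distance.

Internally every vector is standardized once (zero mean, unit norm), under
which ``1 - corr(u, v)`` is ``1 - u.v`` and the correlation-distance Frechet
mean of a cluster is the standardized mean of its members — this is what
makes Lloyd's update both exact and monotone in inertia.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .consortium import Consortium

__all__ = [
    "ClusterResult",
    "correlation_distance",
    "multishot_lloyd",
    "multishot_gradient",
    "singleshot_merge",
    "two_stage_clustering",
    "pooled_lloyd",
    "decentralized_silhouette",
]


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - Pearson correlation`` of two vectors; in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise ValueError("correlation distance undefined for zero-variance vectors")
    return float(1.0 - (uc @ vc) / (nu * nv))


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-variance row cannot be used with correlation distance")
    return Xc / norms


def _assign(Xs: np.ndarray, Cs: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels and distances (ties -> lowest index)."""
    D = 1.0 - Xs @ Cs.T
    labels = np.argmin(D, axis=1)
    return labels, D[np.arange(len(labels)), labels]


@dataclass
class ClusterResult:
    """Centroids, per-site labels and the optimizer trace."""

    C: np.ndarray  # k x p, standardized rows
    site_labels: List[np.ndarray]  # grouped by site index (single entry when pooled)
    inertia_trace: List[float]
    iterations: int
    variant: str
    counts: np.ndarray  # members per cluster at convergence
    C0: Optional[np.ndarray] = None
    weighted_average_ok: bool = True
    silhouette: Optional[float] = None

    @property
    def k(self) -> int:
        return self.C.shape[0]

    @property
    def labels(self) -> np.ndarray:
        """All labels concatenated in site-index order (0-based clusters)."""
        return np.concatenate(self.site_labels)

    @property
    def inertia(self) -> float:
        return self.inertia_trace[-1] if self.inertia_trace else float("nan")


def _site_data(consortium: Consortium, data_key: str) -> List[np.ndarray]:
    """Standardized per-site window matrices, in site-index order."""
    out = []
    for site in consortium.sites:
        X = np.asarray(site.store[data_key], dtype=float)
        if X.ndim != 2:
            raise ValueError(f"site {site.index} store[{data_key!r}] must be 2-D")
        out.append(_standardize_rows(X))
    return out


def _farthest_candidates(Xs: np.ndarray, dists: np.ndarray, n: int) -> Tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-dists, kind="stable")[:n]
    return Xs[order], dists[order]


def _reseed_empty(
    Cs: np.ndarray,
    empty: np.ndarray,
    site_Xs: Sequence[np.ndarray],
    site_dists: Sequence[np.ndarray],
) -> np.ndarray:
    """Re-seed each empty cluster from the globally farthest point.

    Sites contribute their top candidates; ties break toward the lowest
    site index, matching the pooled implementation's concatenation order.
    """
    n_empty = int(empty.sum())
    cand_vecs = np.vstack([_farthest_candidates(X, d, n_empty)[0] for X, d in zip(site_Xs, site_dists)])
    cand_dists = np.concatenate([_farthest_candidates(X, d, n_empty)[1] for X, d in zip(site_Xs, site_dists)])
    order = np.argsort(-cand_dists, kind="stable")
    Cs = Cs.copy()
    for slot, j in enumerate(np.flatnonzero(empty)):
        Cs[j] = cand_vecs[order[slot]]
    return Cs


def _lloyd_engine(
    site_Xs: Sequence[np.ndarray],
    k: int,
    C_init: np.ndarray,
    max_iter: int,
    tol: float,
    consortium: Optional[Consortium],
    variant: str,
) -> ClusterResult:
    """Shared Lloyd's loop; with a consortium the per-iteration statistics
    are routed through the channel, without one it is the pooled oracle."""
    p = site_Xs[0].shape[1]
    C_init = np.asarray(C_init, dtype=float)
    if C_init.shape != (k, p):
        raise ValueError(f"C_init must be {k} x {p}")
    Cs = _standardize_rows(C_init)
    agg = consortium.aggregator_index if consortium is not None else 0
    site_ids = [s.index for s in consortium.sites] if consortium is not None else [0]

    prev_labels: Optional[List[np.ndarray]] = None
    inertia_trace: List[float] = []
    weighted_ok = True
    counts = np.zeros(k, dtype=int)
    it = 0
    for it in range(1, max_iter + 1):
        if consortium is not None:
            for sid in site_ids:
                if sid != agg:
                    consortium.send("centroids", Cs, agg, sid)
        labels_list, dists_list = [], []
        sums = np.zeros((k, p))
        counts = np.zeros(k, dtype=int)
        local_means: List[Tuple[np.ndarray, np.ndarray]] = []
        for Xs, sid in zip(site_Xs, site_ids):
            labels, dists = _assign(Xs, Cs)
            labels_list.append(labels)
            dists_list.append(dists)
            l_sums = np.zeros((k, p))
            l_counts = np.bincount(labels, minlength=k)
            for j in range(k):
                if l_counts[j]:
                    l_sums[j] = Xs[labels == j].sum(axis=0)
            if consortium is not None and sid != agg:
                l_sums = consortium.send("centroids", l_sums, sid, agg)
                l_counts = consortium.send("counts", l_counts.astype(float), sid, agg).astype(int)
            sums += l_sums
            counts += l_counts
            local_means.append((l_sums, l_counts))
        inertia_trace.append(float(sum(d.sum() for d in dists_list)))

        C_raw = Cs.copy()
        nonempty = counts > 0
        C_raw[nonempty] = sums[nonempty] / counts[nonempty, None]

        # invariant: the global update is the count-weighted average of the
        # local per-cluster means
        wavg = np.zeros((k, p))
        for l_sums, l_counts in local_means:
            wavg += l_sums
        if not np.allclose(wavg[nonempty] / counts[nonempty, None], C_raw[nonempty], atol=1e-10):
            weighted_ok = False  # pragma: no cover

        if np.any(~nonempty):
            Cs_new = _standardize_rows(C_raw[nonempty]) if nonempty.any() else C_raw
            full = np.zeros((k, p))
            full[nonempty] = Cs_new
            full = _reseed_empty(full, ~nonempty, site_Xs, dists_list)
            Cs_new = full
        else:
            Cs_new = _standardize_rows(C_raw)

        stable = prev_labels is not None and all(
            np.array_equal(a, b) for a, b in zip(labels_list, prev_labels)
        )
        displacement = float(np.max(np.linalg.norm(Cs_new - Cs, axis=1)))
        prev_labels = labels_list
        if stable or displacement < tol:
            break
        Cs = Cs_new

    return ClusterResult(
        C=Cs,
        site_labels=prev_labels if prev_labels is not None else [],
        inertia_trace=inertia_trace,
        iterations=it,
        variant=variant,
        counts=counts,
        weighted_average_ok=weighted_ok,
    )


def pooled_lloyd(
    X: np.ndarray, k: int, C_init: np.ndarray, max_iter: int = 300, tol: float = 1e-9
) -> ClusterResult:
    """Pooled Lloyd's K-means under correlation distance (reference)."""
    return _lloyd_engine([_standardize_rows(X)], k, C_init, max_iter, tol, None, "pooled_lloyd")


def multishot_lloyd(
    consortium: Consortium,
    data_key: str,
    k: int,
    C_init: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> ClusterResult:
    """Multishot decentralized Lloyd's: local assignments + count-weighted
    centroid averaging at the aggregator, each iteration equal to the
    pooled update."""
    site_Xs = _site_data(consortium, data_key)
    return _lloyd_engine(site_Xs, k, C_init, max_iter, tol, consortium, "lloyd")


def multishot_gradient(
    consortium: Consortium,
    data_key: str,
    k: int,
    C_init: np.ndarray,
    lr: float = 0.5,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> ClusterResult:
    """Multishot decentralized gradient descent on the K-means objective.

    Each site sends the gradient of the local objective w.r.t. the
    centroids; the aggregator averages them weighted by local member counts
    and takes a step ``C <- C - lr * g``.  Five consecutive inertia
    increases halve the learning rate.
    """
    if lr <= 0:
        raise ValueError("learning rate must be positive")
    site_Xs = _site_data(consortium, data_key)
    p = site_Xs[0].shape[1]
    Cs = _standardize_rows(np.asarray(C_init, dtype=float))
    agg = consortium.aggregator_index
    inertia_trace: List[float] = []
    labels_list: List[np.ndarray] = []
    bad_streak = 0
    it = 0
    for it in range(1, max_iter + 1):
        for site in consortium.sites:
            if site.index != agg:
                consortium.send("centroids", Cs, agg, site.index)
        grad_sum = np.zeros((k, p))
        counts = np.zeros(k, dtype=int)
        labels_list = []
        inertia = 0.0
        for Xs, site in zip(site_Xs, consortium.sites):
            labels, dists = _assign(Xs, Cs)
            labels_list.append(labels)
            inertia += float(dists.sum())
            l_counts = np.bincount(labels, minlength=k)
            l_grad = np.zeros((k, p))
            for j in range(k):
                if l_counts[j]:
                    l_grad[j] = l_counts[j] * Cs[j] - Xs[labels == j].sum(axis=0)
            if site.index != agg:
                l_grad = consortium.send("gradients", l_grad, site.index, agg)
                l_counts = consortium.send("counts", l_counts.astype(float), site.index, agg).astype(int)
            grad_sum += l_grad
            counts += l_counts
        inertia_trace.append(inertia)
        if len(inertia_trace) > 1 and inertia_trace[-1] > inertia_trace[-2] + 1e-12:
            bad_streak += 1
            if bad_streak >= 5:
                lr *= 0.5
                bad_streak = 0
                warnings.warn(f"gradient dK-means diverging; halving lr to {lr}", RuntimeWarning)
        else:
            bad_streak = 0
        g = np.zeros((k, p))
        nonempty = counts > 0
        g[nonempty] = grad_sum[nonempty] / counts[nonempty, None]
        C_new = Cs - lr * g
        Cs_new = _standardize_rows(C_new)
        displacement = float(np.max(np.linalg.norm(Cs_new - Cs, axis=1)))
        Cs = Cs_new
        if displacement < tol:
            break
    return ClusterResult(
        C=Cs,
        site_labels=labels_list,
        inertia_trace=inertia_trace,
        iterations=it,
        variant="gradient",
        counts=np.bincount(np.concatenate(labels_list), minlength=k),
    )


def _weighted_lloyd(
    X: np.ndarray, w: np.ndarray, k: int, C_init: np.ndarray, max_iter: int = 300, tol: float = 1e-9
) -> np.ndarray:
    """Weighted Lloyd's on standardized rows; returns centroids only."""
    Xs = _standardize_rows(X)
    Cs = _standardize_rows(C_init)
    for _ in range(max_iter):
        labels, dists = _assign(Xs, Cs)
        C_raw = Cs.copy()
        for j in range(k):
            mask = labels == j
            if w[mask].sum() > 0:
                C_raw[j] = (Xs[mask] * w[mask, None]).sum(axis=0) / w[mask].sum()
            else:
                far = int(np.argmax(dists))
                C_raw[j] = Xs[far]
        Cs_new = _standardize_rows(C_raw)
        if float(np.max(np.linalg.norm(Cs_new - Cs, axis=1))) < tol:
            Cs = Cs_new
            break
        Cs = Cs_new
    return Cs


def singleshot_merge(
    consortium: Consortium,
    data_key: str,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> ClusterResult:
    """Single-shot dK-means: local runs to convergence, then a
    count-weighted nearest-centroid merge at the aggregator."""
    site_Xs = _site_data(consortium, data_key)
    agg = consortium.aggregator_index
    all_centroids: List[np.ndarray] = []
    all_weights: List[np.ndarray] = []
    for Xs, site in zip(site_Xs, consortium.sites):
        rng = np.random.default_rng([seed, site.index])
        k_local = min(k, Xs.shape[0])
        if k_local < k:
            warnings.warn(
                f"site {site.index} has only {Xs.shape[0]} windows; contributing {k_local} centroids",
                RuntimeWarning,
            )
        init = Xs[rng.choice(Xs.shape[0], size=k_local, replace=False)]
        local = _lloyd_engine([Xs], k_local, init, max_iter, tol, None, "local_lloyd")
        keep = local.counts > 0
        C_loc = local.C[keep]
        w_loc = local.counts[keep].astype(float)
        if site.index != agg:
            C_loc = consortium.send("centroids", C_loc, site.index, agg)
            w_loc = consortium.send("counts", w_loc, site.index, agg)
        all_centroids.append(C_loc)
        all_weights.append(w_loc)
    pool = np.vstack(all_centroids)
    weights = np.concatenate(all_weights)
    rng = np.random.default_rng([seed, consortium.n_sites])
    init = pool[rng.choice(pool.shape[0], size=min(k, pool.shape[0]), replace=False)]
    Cs = _weighted_lloyd(pool, weights, min(k, pool.shape[0]), init, max_iter, tol)

    site_labels = []
    inertia = 0.0
    for Xs, site in zip(site_Xs, consortium.sites):
        if site.index != agg:
            consortium.send("centroids", Cs, agg, site.index)
        labels, dists = _assign(Xs, Cs)
        site_labels.append(labels)
        inertia += float(dists.sum())
    return ClusterResult(
        C=Cs,
        site_labels=site_labels,
        inertia_trace=[inertia],
        iterations=1,
        variant="singleshot",
        counts=np.bincount(np.concatenate(site_labels), minlength=Cs.shape[0]),
    )


def decentralized_silhouette(
    site_Xs: Sequence[np.ndarray], site_labels: Sequence[np.ndarray]
) -> Optional[float]:
    """Count-weighted mean of per-site silhouette scores under correlation
    distance.  Sites where a silhouette is undefined (fewer than two
    clusters present locally) are skipped; ``None`` when no site counts."""
    from sklearn.metrics import silhouette_score

    scores, weights = [], []
    for Xs, labels in zip(site_Xs, site_labels):
        if len(labels) < 3 or len(np.unique(labels)) < 2:
            continue
        scores.append(silhouette_score(Xs, labels, metric="correlation"))
        weights.append(len(labels))
    if not scores:
        return None
    return float(np.average(scores, weights=weights))


def _draw_global_init(
    consortium: Consortium, site_Xs: Sequence[np.ndarray], k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw k windows uniformly from all sites' local data (as statistics
    routed through the channel when they leave their site)."""
    counts = np.array([X.shape[0] for X in site_Xs])
    total = counts.sum()
    if total < k:
        raise ValueError(f"cannot draw {k} initial centroids from {total} windows")
    flat = rng.choice(total, size=k, replace=False)
    bounds = np.concatenate([[0], np.cumsum(counts)])
    agg = consortium.aggregator_index
    rows = []
    for idx in flat:
        site_idx = int(np.searchsorted(bounds, idx, side="right") - 1)
        row = site_Xs[site_idx][idx - bounds[site_idx]]
        if consortium.sites[site_idx].index != agg:
            row = consortium.send("centroids", row.reshape(1, -1), site_idx, agg)[0]
        rows.append(row)
    return np.vstack(rows)


def two_stage_clustering(
    consortium: Consortium,
    k: int,
    n_init: int = 20,
    seed: int = 0,
    variant: str = "lloyd",
    exemplar_key: str = "exemplars",
    data_key: str = "windows",
    max_iter: int = 300,
    tol: float = 1e-9,
    lr: float = 0.5,
) -> ClusterResult:
    """Exemplar-then-full two-stage decentralized clustering.

    Stage 1 clusters the exemplar windows from ``n_init`` seeded random
    initializations (centroids drawn uniformly from local exemplar data)
    and keeps the run with the best decentralized silhouette; stage 2
    clusters all windows starting from those centroids.
    """
    variants = {"lloyd": multishot_lloyd, "gradient": multishot_gradient}
    if variant == "singleshot":
        res = singleshot_merge(consortium, data_key, k, seed=seed, max_iter=max_iter, tol=tol)
        return res
    if variant not in variants:
        raise KeyError(f"unknown variant {variant!r}")
    run = variants[variant]

    ex_Xs = _site_data(consortium, exemplar_key)
    rng = np.random.default_rng(seed)
    best: Optional[ClusterResult] = None
    best_score = -np.inf
    for _ in range(n_init):
        C_init = _draw_global_init(consortium, ex_Xs, k, rng)
        kwargs = {"max_iter": max_iter, "tol": tol}
        if variant == "gradient":
            kwargs["lr"] = lr
        res = run(consortium, exemplar_key, k, C_init, **kwargs)
        score = decentralized_silhouette(ex_Xs, res.site_labels)
        if score is None:
            score = -res.inertia  # degenerate fallback: prefer lower inertia
        if score > best_score:
            best_score = score
            best = res
    assert best is not None

    kwargs = {"max_iter": max_iter, "tol": tol}
    if variant == "gradient":
        kwargs["lr"] = lr
    final = run(consortium, data_key, k, best.C, **kwargs)
    final.C0 = best.C
    final.silhouette = float(best_score) if np.isfinite(best_score) else None
    return final
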