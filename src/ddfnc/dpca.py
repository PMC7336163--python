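"""Decentralized two-stage PCA: local PCA, serial round-robin global PCA
and its recursive, cluster-parallel variant.

The travelling statistic is an :class:`EigenPackage` — left singular
vectors scaled by their singular values.  Stacking two packages column-wise
preserves the Gram matrix of the union of the underlying data blocks, which
is why a chain of local reductions can recover the pooled principal
subspace without any raw data leaving a site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from joblib import Parallel, delayed

from .consortium import Consortium

__all__ = [
    "EigenPackage",
    "local_pca",
    "normalize_top_columns",
    "global_pca",
    "parallel_global_pca",
    "matrix_rank",
    "fix_signs",
]

#: Singular values below RANK_RTOL * sigma_max are treated as zero.
RANK_RTOL = 1e-10


def matrix_rank(X: np.ndarray) -> int:
    """Numerical rank with the package-wide relative tolerance."""
    s = np.linalg.svd(np.asarray(X, dtype=float), compute_uv=False)
    if s.size == 0 or s[0] <= 0:
        return 0
    return int(np.count_nonzero(s > RANK_RTOL * s[0]))


def fix_signs(U: np.ndarray) -> np.ndarray:
    """Resolve SVD sign ambiguity: largest-magnitude entry of each column
    is made positive (first occurrence wins on ties)."""
    U = np.array(U, copy=True)
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return U


@dataclass
class EigenPackage:
    """Scaled spatial eigenvectors: ``P = U^(k) Sigma^(k)``.

    Columns are ordered by non-increasing singular value.  ``provenance``
    records which sites contributed, in reduction order.
    """

    P: np.ndarray
    k: int
    provenance: List[int] = field(default_factory=list)
    U: Optional[np.ndarray] = None
    singular_values: Optional[np.ndarray] = None

    @property
    def d(self) -> int:
        return self.P.shape[0]

    def save(self, path) -> None:
        """Serialize to an ``.npz`` container with metadata."""
        np.savez(
            path,
            P=self.P,
            k=np.array(self.k),
            provenance=np.asarray(self.provenance, dtype=int),
        )

    @classmethod
    def load(cls, path) -> "EigenPackage":
        with np.load(path) as z:
            return cls(P=z["P"], k=int(z["k"]), provenance=z["provenance"].tolist())


def local_pca(X: np.ndarray, k: int, provenance: Optional[List[int]] = None) -> EigenPackage:
    """Rank-``k`` local PCA via SVD; returns ``P = U^(k) Sigma^(k)``.

    ``U^(k)`` and ``Sigma^(k)`` are retained on the package for local reuse.
    """
    X = np.asarray(X, dtype=float)
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if not np.any(X):
        raise ValueError("cannot compute PCA of an all-zero matrix")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(d, n)={min(X.shape)}")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    Uk, sk = U[:, :k], s[:k]
    return EigenPackage(
        P=Uk * sk,
        k=k,
        provenance=list(provenance) if provenance else [],
        U=Uk,
        singular_values=sk,
    )


def normalize_top_columns(P: np.ndarray, r_prime: int) -> np.ndarray:
    """Return the first ``r_prime`` columns of ``P`` scaled to unit norm."""
    P = np.asarray(P, dtype=float)
    if r_prime <= 0 or r_prime > P.shape[1]:
        raise ValueError(f"r'={r_prime} must be in 1..{P.shape[1]}")
    top = P[:, :r_prime]
    norms = np.linalg.norm(top, axis=0)
    if np.any(norms == 0):
        raise ValueError("degenerate component: zero-norm column among the top columns")
    return top / norms


def _site_matrices(consortium: Consortium, data_key: str) -> List[np.ndarray]:
    mats = []
    for site in consortium.ordered_sites():
        if data_key in site.store:
            mats.append(np.asarray(site.store[data_key], dtype=float))
        else:
            mats.append(np.hstack([sub.data for sub in site.subjects]))
    return mats


def _merge(pkg_in: EigenPackage, X_local: np.ndarray, k: int, site: int) -> EigenPackage:
    """One round-robin step: reduce local data, stack with the incoming
    package, and re-reduce the stack.

    The stack is reduced to ``min(k, rank(stack))`` columns, i.e. the
    package is allowed to grow up to ``k`` columns as sites accumulate.
    Capping it instead at the per-site local rank collapses the package to
    the smallest site rank and destroys pooled equivalence.
    """
    k_loc = min(k, matrix_rank(X_local))
    P_loc = local_pca(X_local, k_loc).P
    stack = np.hstack([P_loc, pkg_in.P])
    k_out = min(k, matrix_rank(stack))
    out = local_pca(stack, k_out)
    out.provenance = pkg_in.provenance + [site]
    return out


def _serial_reduce(
    mats: Sequence[np.ndarray],
    k: int,
    site_ids: Sequence[int],
    consortium: Optional[Consortium] = None,
) -> EigenPackage:
    """Round-robin reduction of ``mats`` (already in visit order)."""
    pkg = local_pca(mats[0], min(k, matrix_rank(mats[0])), provenance=[site_ids[0]])
    for j in range(1, len(mats)):
        if consortium is not None:
            delivered = consortium.send("eigen_package", pkg.P, int(site_ids[j - 1]), int(site_ids[j]))
            pkg = EigenPackage(P=delivered, k=pkg.k, provenance=pkg.provenance)
        pkg = _merge(pkg, mats[j], k, int(site_ids[j]))
    return pkg


def global_pca(
    consortium: Consortium,
    r: int,
    k: int,
    data_key: str = "preprocessed",
) -> np.ndarray:
    """Serial round-robin decentralized PCA over the consortium's order.

    Each site reduces its local matrix, stacks the result with the package
    received from its predecessor and re-reduces; the terminal site (the
    aggregator) normalizes the top ``min(r, rank)`` columns.  Exactly
    ``s - 1`` eigen packages cross the channel.
    """
    if k < r:
        raise ValueError(f"local rank k={k} must be >= final rank r={r}")
    mats = _site_matrices(consortium, data_key)
    site_ids = [int(i) for i in consortium.order]
    pkg = _serial_reduce(mats, k, site_ids, consortium=consortium)
    return _finalize(pkg, r)


def _finalize(pkg: EigenPackage, r: int) -> np.ndarray:
    r_prime = min(r, matrix_rank(pkg.P))
    if r_prime < r:
        warnings.warn(
            f"rank collapsed below the requested {r} components; returning {r_prime}",
            RuntimeWarning,
        )
    return fix_signs(normalize_top_columns(pkg.P, r_prime))


def _chunk(items: Sequence, C: int) -> List[Sequence]:
    """Split into floor(len/C) clusters of size C; the last cluster absorbs
    the remainder so no site is dropped."""
    K = len(items) // C
    bounds = [(c * C, (c + 1) * C if c < K - 1 else len(items)) for c in range(K)]
    return [items[a:b] for a, b in bounds]


def _parallel_reduce(
    mats: Sequence[np.ndarray],
    k: int,
    site_ids: Sequence[int],
    C: int,
    B: int,
    consortium: Optional[Consortium],
    n_jobs: int,
) -> EigenPackage:
    s = len(mats)
    K = s // C
    if K <= B:
        return _serial_reduce(mats, k, site_ids, consortium=consortium)
    clusters = _chunk(list(zip(mats, site_ids)), C)

    def reduce_cluster(cluster):
        cmats, cids = zip(*cluster)
        return _serial_reduce(cmats, k, cids, consortium=consortium)

    if n_jobs != 1 and consortium is None:
        packages = Parallel(n_jobs=n_jobs, backend="threading")(
            delayed(reduce_cluster)(cl) for cl in clusters
        )
    else:
        # with a shared traffic log, run clusters sequentially so the log
        # order is deterministic; correctness is scheduling-independent
        packages = [reduce_cluster(cl) for cl in clusters]

    carrier_ids = [pkg.provenance[-1] for pkg in packages]
    return _parallel_reduce(
        [pkg.P for pkg in packages], k, carrier_ids, C, B, consortium, n_jobs
    )


def parallel_global_pca(
    consortium: Consortium,
    r: int,
    k: int,
    C: int = 2,
    B: int = 1,
    data_key: str = "preprocessed",
    n_jobs: int = 1,
) -> np.ndarray:
    """Recursive cluster-parallel decentralized PCA.

    The consortium is split into ``floor(s / C)`` clusters; each cluster
    runs the serial reduction independently (these are the steps that may
    execute concurrently) and the resulting packages are recursively
    reduced until one package remains at the final aggregator.  With
    ``C == s`` (or any ``s < C``) this is exactly the serial path.

    With ``n_jobs != 1`` cluster reductions run on a thread pool and bypass
    the traffic log (whose ordering must stay deterministic); use the
    default for audited runs.
    """
    if C < 2:
        raise ValueError("cluster size C must be >= 2")
    if B < 1:
        raise ValueError("base cluster size B must be >= 1")
    if k < r:
        raise ValueError(f"local rank k={k} must be >= final rank r={r}")
    mats = _site_matrices(consortium, data_key)
    site_ids = [int(i) for i in consortium.order]
    if consortium.n_sites < C:
        return global_pca(consortium, r, k, data_key=data_key)
    channel_owner = None if n_jobs != 1 else consortium
    pkg = _parallel_reduce(mats, k, site_ids, C, B, channel_owner, n_jobs)
    return _finalize(pkg, r)


def recursion_tree_sizes(s: int, C: int, B: int = 1) -> List[int]:
    """Cluster counts at each recursion level (e.g. s=8, C=2 -> [4, 2, 1])."""
    sizes: List[int] = []
    while s // C > B:
        s = s // C
        sizes.append(s)
    sizes.append(1)
    return sizes


def expected_messages(s: int) -> int:
    """Eigen packages sent by any reduction tree over ``s`` sites."""
    return s - 1
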