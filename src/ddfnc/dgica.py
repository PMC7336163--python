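"""Decentralized group ICA: subject preprocessing, two-stage decentralized
PCA, aggregator-side whitening + ICA, broadcast of the spatial maps and
GICA1 back-reconstruction.

ICA orientation convention: spatial independence.  The whitened global
eigenvector matrix ``Uw`` (voxels x r) is treated as r signals sampled over
voxels; the unmixing matrix ``W`` acts on ``Uw.T`` and the broadcast spatial
maps are ``A_hat = Uw @ W.T`` (columns = maximally independent voxel maps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .consortium import Consortium
from .dpca import (
    fix_signs,
    global_pca,
    local_pca,
    matrix_rank,
    normalize_top_columns,
    parallel_global_pca,
)

__all__ = [
    "IcaResult",
    "SubjectDecomposition",
    "preprocess_subject",
    "whiten",
    "infomax_ica",
    "kurtosis_ica",
    "ICA_VARIANTS",
    "run_dgica",
    "pooled_gica",
    "back_reconstruct",
]


@dataclass
class IcaResult:
    """Unmixing matrix plus the broadcast spatial maps.

    The conceptual global unmixing over all timepoints is never
    materialized; only ``A_hat`` (voxels x r) crosses the network.
    """

    W: np.ndarray
    A_hat: np.ndarray
    ica_variant: str
    iterations: int
    converged: bool
    final_lr: float = 0.0
    U: Optional[np.ndarray] = None
    whitener: Optional["Whitener"] = None

    @property
    def r(self) -> int:
        return self.W.shape[0]


@dataclass
class SubjectDecomposition:
    """Per-subject timecourses and spatial maps from back-reconstruction."""

    S_hat: np.ndarray  # r x N_im
    A_hat_im: np.ndarray  # d x r


def preprocess_subject(
    X_im: np.ndarray, k1: int, variance_normalize: bool = False
) -> np.ndarray:
    """Center columns, then reduce/whiten the temporal dimension to ``k1``.

    Each column (timepoint) has its mean over voxels removed; the centered
    matrix is reduced by local PCA and the top ``k1`` columns are scaled to
    unit norm.  With ``variance_normalize`` the singular values are divided
    out instead (orthonormal output).  ``k1`` above the rank is truncated
    with a warning.
    """
    X = np.asarray(X_im, dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    rank = matrix_rank(Xc)
    if k1 > rank:
        warnings.warn(
            f"k1={k1} exceeds the centered subject rank {rank}; truncating", RuntimeWarning
        )
        k1 = rank
    pkg = local_pca(Xc, k1)
    if variance_normalize:
        return pkg.U[:, :k1].copy()
    return normalize_top_columns(pkg.P, k1)


@dataclass
class Whitener:
    """Invertible whitening transform for the columns of a d x r matrix."""

    mean: np.ndarray
    forward: np.ndarray  # r x r
    inverse: np.ndarray  # r x r

    def apply(self, U: np.ndarray) -> np.ndarray:
        return (U - self.mean) @ self.forward

    def unapply(self, Uw: np.ndarray) -> np.ndarray:
        return Uw @ self.inverse + self.mean


def whiten(U: np.ndarray) -> Tuple[np.ndarray, Whitener]:
    """Decorrelate the columns of ``U`` to unit sample variance.

    Returns the whitened matrix and the retained transform.  Symmetric
    (ZCA) whitening is used, so the transform is unique and deterministic.
    """
    U = np.asarray(U, dtype=float)
    d, r = U.shape
    mean = U.mean(axis=0, keepdims=True)
    Uc = U - mean
    cov = (Uc.T @ Uc) / (d - 1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * evals[-1]:
        raise np.linalg.LinAlgError("rank-deficient input cannot be whitened")
    forward = evecs @ np.diag(evals ** -0.5) @ evecs.T
    inverse = evecs @ np.diag(evals ** 0.5) @ evecs.T
    return Uc @ forward, Whitener(mean=mean, forward=forward, inverse=inverse)


def infomax_ica(
    Uw: np.ndarray,
    lr: Optional[float] = None,
    max_iter: int = 512,
    tol: float = 1e-7,
    seed: int = 0,
) -> IcaResult:
    """Natural-gradient infomax ICA with a logistic nonlinearity.

    Block updates over a seeded permutation of the voxel samples;
    ``W <- W + lr (I + (1 - 2 g(WY)) (WY)^T / block) W`` with
    ``g`` the logistic sigmoid (super-Gaussian prior).  The learning rate
    anneals by 0.9 whenever the angle between successive weight updates
    exceeds 60 degrees.  Deterministic under a fixed seed.
    """
    Y = np.asarray(Uw, dtype=float).T  # r x d, samples are voxels
    r, d = Y.shape
    if r < 2:
        raise ValueError("need at least two components for ICA")
    if lr is None:
        lr = 0.015 / np.log(r)
    rng = np.random.default_rng(seed)
    block = int(min(np.ceil(np.sqrt(d / 3.0)), d))
    W = np.eye(r)
    I = np.eye(r)
    anneal_deg = np.cos(np.deg2rad(60.0))
    prev_delta: Optional[np.ndarray] = None
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        perm = rng.permutation(d)
        W_old = W.copy()
        for start in range(0, d - block + 1, block):
            Yb = Y[:, perm[start : start + block]]
            Ub = W @ Yb
            gb = 1.0 / (1.0 + np.exp(-Ub))
            W = W + lr * (I + ((1.0 - 2.0 * gb) @ Ub.T) / Yb.shape[1]) @ W
            if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > 1e8:
                # blow-up: restart from identity at a lower rate
                W = np.eye(r)
                prev_delta = None
                lr *= 0.5
                warnings.warn("infomax weights blew up; restarting with halved lr", RuntimeWarning)
                break
        delta = W - W_old
        change = float(np.linalg.norm(delta) / max(np.linalg.norm(W_old), 1e-30))
        if prev_delta is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(prev_delta)
            if denom > 0 and (delta.ravel() @ prev_delta.ravel()) / denom < anneal_deg:
                lr *= 0.9
        prev_delta = delta
        if change < tol:
            break
    converged = change < tol
    if not converged:
        warnings.warn(
            f"infomax did not reach tol={tol} after {max_iter} iterations", RuntimeWarning
        )
    A_hat = np.asarray(Uw, dtype=float) @ W.T
    return IcaResult(
        W=W,
        A_hat=A_hat,
        ica_variant="infomax",
        iterations=it,
        converged=converged,
        final_lr=lr,
    )


def kurtosis_ica(
    Uw: np.ndarray,
    lr: Optional[float] = None,  # unused; kept for registry signature parity
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
) -> IcaResult:
    """Kurtosis-based fixed-point ICA (deflationary, cubic nonlinearity).

    An alternative aggregator-side algorithm for the variant-comparison
    experiment; deterministic under a fixed seed (random orthogonal init).
    """
    Y = np.asarray(Uw, dtype=float).T
    r, d = Y.shape
    if r < 2:
        raise ValueError("need at least two components for ICA")
    rng = np.random.default_rng(seed)
    init = np.linalg.qr(rng.standard_normal((r, r)))[0]
    W = np.zeros((r, r))
    total_it = 0
    converged_all = True
    for j in range(r):
        w = init[j].copy()
        w /= np.linalg.norm(w)
        for it in range(1, max_iter + 1):
            wx = w @ Y
            w_new = (Y * wx**3).mean(axis=1) - 3.0 * w
            # deflate against already-extracted rows
            for i in range(j):
                w_new -= (w_new @ W[i]) * W[i]
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                break
            w_new /= nrm
            if abs(abs(w_new @ w) - 1.0) < tol:
                w = w_new
                break
            w = w_new
        else:
            converged_all = False
        total_it += it
        W[j] = w
    A_hat = np.asarray(Uw, dtype=float) @ W.T
    return IcaResult(
        W=W,
        A_hat=A_hat,
        ica_variant="kurtosis",
        iterations=total_it,
        converged=converged_all,
    )


#: Pluggable aggregator-side ICA registry.  The single-shot "merging error"
#: style variants deliberately have no entry here.
ICA_VARIANTS: Dict[str, Callable[..., IcaResult]] = {
    "infomax": infomax_ica,
    "kurtosis": kurtosis_ica,
}


def _preprocess_sites(consortium: Consortium, k1: int, variance_normalize: bool = False) -> None:
    for site in consortium.sites:
        pre = [preprocess_subject(sub.data, k1, variance_normalize) for sub in site.subjects]
        site.store["preprocessed_subjects"] = pre
        site.store["preprocessed"] = np.hstack(pre)


def run_dgica(
    consortium: Consortium,
    r: int,
    k1: int = 120,
    k2: Optional[int] = None,
    ica_variant: str = "infomax",
    pca_variant: str = "serial",
    seed: int = 0,
    C: int = 2,
    B: int = 1,
    max_iter: int = 512,
    tol: float = 1e-7,
    variance_normalize: bool = False,
) -> IcaResult:
    """Run decentralized group ICA end to end on a consortium.

    Subject preprocessing happens on every site; the two-stage PCA reduces
    to ``r`` global spatial eigenvectors at the aggregator (serial or
    parallel route); the aggregator whitens, runs the selected ICA variant
    and broadcasts the spatial maps to all other sites.
    """
    if k2 is None:
        k2 = 5 * r
    if k2 < 5 * r:
        warnings.warn(f"k2={k2} is below the recommended 5*r={5 * r}", RuntimeWarning)
    if ica_variant not in ICA_VARIANTS:
        raise KeyError(f"unknown ICA variant {ica_variant!r}; have {sorted(ICA_VARIANTS)}")

    _preprocess_sites(consortium, k1, variance_normalize)

    if pca_variant == "serial":
        U = global_pca(consortium, r, k2, data_key="preprocessed")
    elif pca_variant == "parallel":
        U = parallel_global_pca(consortium, r, k2, C=C, B=B, data_key="preprocessed")
    else:
        raise ValueError("pca_variant must be 'serial' or 'parallel'")

    Uw, whitener = whiten(U)
    result = ICA_VARIANTS[ica_variant](Uw, max_iter=max_iter, tol=tol, seed=seed)
    result.U = U
    result.whitener = whitener

    agg = consortium.aggregator_index
    consortium.aggregator.store["A_hat"] = result.A_hat
    for site in consortium.sites:
        if site.index != agg:
            site.store["A_hat"] = consortium.send("unmixing_maps", result.A_hat, agg, site.index)
    return result


def pooled_gica(
    subjects: List[np.ndarray],
    r: int,
    k1: int = 120,
    ica_variant: str = "infomax",
    seed: int = 0,
    max_iter: int = 512,
    tol: float = 1e-7,
    variance_normalize: bool = False,
) -> IcaResult:
    """Pooled oracle: identical preprocessing, single pooled PCA, same ICA.

    Serves as the centralized reference the decentralized route is compared
    against (same ICA seed so only the PCA stage differs).
    """
    pre = np.hstack([preprocess_subject(X, k1, variance_normalize) for X in subjects])
    r_eff = min(r, matrix_rank(pre))
    U = fix_signs(normalize_top_columns(local_pca(pre, r_eff).P, r_eff))
    Uw, whitener = whiten(U)
    result = ICA_VARIANTS[ica_variant](Uw, max_iter=max_iter, tol=tol, seed=seed)
    result.U = U
    result.whitener = whitener
    return result


def back_reconstruct(A_hat: np.ndarray, X_im: np.ndarray, rcond: float = 1e-10) -> SubjectDecomposition:
    """GICA1 back-reconstruction for one subject.

    ``S_hat`` is the least-squares solution of ``A_hat @ S = X_im``;
    the subject spatial maps are ``X_im @ pinv(S_hat)``.
    """
    A_hat = np.asarray(A_hat, dtype=float)
    X_im = np.asarray(X_im, dtype=float)
    if matrix_rank(A_hat) < A_hat.shape[1]:
        raise ValueError("broadcast maps must have full column rank")
    S_hat, *_ = np.linalg.lstsq(A_hat, X_im, rcond=rcond)
    if matrix_rank(S_hat) < S_hat.shape[0]:
        warnings.warn("rank-deficient subject timecourses; using tolerant pseudo-inverse", RuntimeWarning)
    A_hat_im = X_im @ np.linalg.pinv(S_hat, rcond=rcond)
    return SubjectDecomposition(S_hat=S_hat, A_hat_im=A_hat_im)
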