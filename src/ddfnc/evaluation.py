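"""Quality metrics and group statistics: Moreau-Amari ISI, Hungarian
matching of components/centroids, reference-subset selection, subject-median
state matrices and two-sample t-test group contrasts.

Matching cost is sign-agnostic (``1 - |corr|``) because both SVD and ICA
carry a per-component sign ambiguity; signs are reconciled after matching.
The group contrast uses a pooled-variance two-sample t by default (Welch
behind a flag) and applies no multiple-comparison correction — consumers
inspect raw element-wise maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import ttest_ind

from .dfnc import WindowStack, devectorize_corr
from .dkmeans import ClusterResult

__all__ = [
    "MatchReport",
    "GroupStateContrast",
    "amari_isi",
    "hungarian_match",
    "match_reference_components",
    "remap_connectivity",
    "group_state_contrast",
]


def amari_isi(P: np.ndarray) -> float:
    """Moreau-Amari inter-symbol interference index in [0, 1].

    ``sum_rows(sum_j |p_ij| / max_j |p_ij| - 1) + sum_cols(...)`` normalized
    by ``2 r (r - 1)``.  Zero iff ``P`` is a scaled permutation; invariant
    to row/column permutation and scaling.
    """
    P = np.abs(np.asarray(P, dtype=float))
    r, c = P.shape
    if r != c:
        raise ValueError("ISI is defined for square matrices")
    if r < 2:
        raise ValueError("need at least 2 components")
    row_max = P.max(axis=1)
    col_max = P.max(axis=0)
    if np.any(row_max == 0) or np.any(col_max == 0):
        raise ValueError("all-zero row or column")
    rows = (P / row_max[:, None]).sum(axis=1) - 1.0
    cols = (P / col_max[None, :]).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * r * (r - 1)))


@dataclass
class MatchReport:
    """Hungarian component matching: permutation + matched correlations.

    ``permutation[i]`` is the estimated column matched to reference column
    ``i``; ``correlations[i]`` its signed correlation after sign flips.
    """

    permutation: np.ndarray
    correlations: np.ndarray  # signed, after sign reconciliation
    est_signed: np.ndarray  # est columns reordered/sign-flipped onto ref
    signs: Optional[np.ndarray] = None  # per matched pair, ref order

    @property
    def min_correlation(self) -> float:
        return float(self.correlations.min())

    @property
    def mean_correlation(self) -> float:
        return float(self.correlations.mean())


def _corr_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlation matrix (A cols x B cols)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na = np.linalg.norm(Ac, axis=0)
    nb = np.linalg.norm(Bc, axis=0)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-variance column")
    return (Ac.T @ Bc) / np.outer(na, nb)


def hungarian_match(est: np.ndarray, ref: np.ndarray) -> MatchReport:
    """Match estimated to reference columns, minimizing ``1 - |corr|``.

    Rectangular inputs are matched on the smaller side.  The returned
    ``est_signed`` holds the matched estimated columns, ordered like the
    matched reference columns and sign-flipped to positive correlation.
    """
    R = _corr_columns(est, ref)
    cost = 1.0 - np.abs(R)
    rows, cols = linear_sum_assignment(cost)
    order = np.argsort(cols)
    rows, cols = rows[order], cols[order]
    signs = np.sign(R[rows, cols])
    signs[signs == 0] = 1.0
    matched = np.asarray(est, dtype=float)[:, rows] * signs
    return MatchReport(
        permutation=rows,
        correlations=R[rows, cols] * signs,
        est_signed=matched,
        signs=signs,
    )


def match_reference_components(A_hat: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Indices of the estimated components best matching a reference set.

    With ``m`` reference columns this picks the ``m`` columns of ``A_hat``
    Hungarian-matched to them (the selection step used to retain a
    neurologically meaningful subset of an over-complete decomposition).
    """
    if ref.shape[1] > A_hat.shape[1]:
        raise ValueError("reference set has more components than the estimate")
    R = _corr_columns(A_hat, ref)
    rows, cols = linear_sum_assignment(1.0 - np.abs(R))
    return rows[np.argsort(cols)]


def remap_connectivity(
    vectors: np.ndarray, permutation: np.ndarray, signs: Optional[np.ndarray] = None
) -> np.ndarray:
    """Re-express vectorized pair connectivity in a reference component order.

    Estimated components carry an arbitrary permutation and sign relative
    to a reference decomposition; connectivity entries inherit both.  Given
    the component match (``permutation[i]`` = estimated component for
    reference component ``i``, with ``signs``), each row is devectorized,
    reindexed and sign-corrected so it is directly comparable to
    connectivity expressed in the reference basis.
    """
    from .dfnc import vectorize_corr

    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    r = len(permutation)
    if signs is None:
        signs = np.ones(r)
    flip = np.outer(signs, signs)
    out = np.empty_like(vectors)
    for i, v in enumerate(vectors):
        C = devectorize_corr(v, r)
        out[i] = vectorize_corr(C[np.ix_(permutation, permutation)] * flip)
    return out


@dataclass
class GroupStateContrast:
    """Per-state element-wise group contrast over subject medians."""

    t_matrices: Dict[int, Optional[np.ndarray]]  # state -> r' x r' t map (None when missing)
    p_matrices: Dict[int, Optional[np.ndarray]]
    medians_a: Dict[int, np.ndarray]  # state -> subjects_a x pairs
    medians_b: Dict[int, np.ndarray]
    group_sizes: Tuple[int, int]
    r: int


def group_state_contrast(
    result: ClusterResult,
    stack: WindowStack,
    groups: Mapping[int, str],
    welch: bool = False,
    min_per_group: int = 2,
) -> GroupStateContrast:
    """Two-sample t maps between groups of per-subject state medians.

    For every state, each subject contributes the element-wise median of
    its windows assigned to that state; group A and B medians are compared
    element-wise with a two-sample t-test (pooled variance unless
    ``welch``).  States with fewer than ``min_per_group`` subjects in
    either group get a ``None`` t map.
    """
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    ga, gb = names

    labels = result.labels
    n_windows = [e.n_windows for e in stack.entries]
    if labels.size != sum(n_windows):
        raise ValueError("cluster labels and window stack sizes disagree")
    bounds = np.concatenate([[0], np.cumsum(n_windows)])
    r = stack.entries[0].r
    k = result.k

    med_a: Dict[int, List[np.ndarray]] = {j: [] for j in range(k)}
    med_b: Dict[int, List[np.ndarray]] = {j: [] for j in range(k)}
    for m, entry in enumerate(stack.entries):
        sub_labels = labels[bounds[m] : bounds[m + 1]]
        target = med_a if groups[m] == ga else med_b
        for j in range(k):
            mask = sub_labels == j
            if mask.any():
                target[j].append(np.median(entry.windows[mask], axis=0))

    t_mats: Dict[int, Optional[np.ndarray]] = {}
    p_mats: Dict[int, Optional[np.ndarray]] = {}
    for j in range(k):
        A = np.vstack(med_a[j]) if med_a[j] else np.empty((0, 0))
        B = np.vstack(med_b[j]) if med_b[j] else np.empty((0, 0))
        if A.shape[0] < min_per_group or B.shape[0] < min_per_group:
            t_mats[j] = None
            p_mats[j] = None
            continue
        t, p = ttest_ind(A, B, axis=0, equal_var=not welch)
        t_mats[j] = devectorize_corr(np.nan_to_num(t), r) - np.eye(r)
        p_mats[j] = devectorize_corr(np.nan_to_num(p, nan=1.0), r)
    return GroupStateContrast(
        t_matrices=t_mats,
        p_matrices=p_mats,
        medians_a={j: (np.vstack(v) if v else np.empty((0, 0))) for j, v in med_a.items()},
        medians_b={j: (np.vstack(v) if v else np.empty((0, 0))) for j, v in med_b.items()},
        group_sizes=(
            sum(1 for g in groups.values() if g == ga),
            sum(1 for g in groups.values() if g == gb),
        ),
        r=r,
    )
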