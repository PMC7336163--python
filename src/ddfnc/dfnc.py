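"""Sliding-window connectivity and exemplar-window selection.

Window ``w`` (0-based internally) covers timepoints ``w .. w + t``
inclusive, giving ``N - t`` windows of ``t + 1`` samples each — a
162-timepoint subject with ``t = 22`` yields 140 windows.  User-facing
indices are 1-based; :func:`to_user_index` / :func:`to_internal_index`
centralize the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

__all__ = [
    "WindowEntry",
    "WindowStack",
    "ExemplarSet",
    "sliding_window_corr",
    "select_exemplars",
    "vectorize_corr",
    "devectorize_corr",
    "n_pairs",
    "to_user_index",
    "to_internal_index",
]


def n_pairs(r: int) -> int:
    return r * (r - 1) // 2


def to_user_index(w: int) -> int:
    """Internal 0-based window index -> 1-based user-facing index."""
    return w + 1


def to_internal_index(w: int) -> int:
    return w - 1


def vectorize_corr(C: np.ndarray) -> np.ndarray:
    """Upper triangle (excluding the unit diagonal), row-major."""
    r = C.shape[0]
    iu = np.triu_indices(r, k=1)
    return np.asarray(C, dtype=float)[iu]


def devectorize_corr(v: np.ndarray, r: Optional[int] = None) -> np.ndarray:
    """Inverse of :func:`vectorize_corr`: symmetric with unit diagonal."""
    v = np.asarray(v, dtype=float)
    if r is None:
        r = int(round((1 + np.sqrt(1 + 8 * v.size)) / 2))
    if n_pairs(r) != v.size:
        raise ValueError(f"vector of length {v.size} is not an upper triangle of an {r}x{r} matrix")
    C = np.eye(r)
    iu = np.triu_indices(r, k=1)
    C[iu] = v
    C[(iu[1], iu[0])] = v
    return C


@dataclass
class WindowEntry:
    """One subject's windows x pairs matrix of vectorized correlations."""

    windows: np.ndarray  # n_windows x n_pairs(r)
    t: int
    r: int
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def matrix(self, w: int) -> np.ndarray:
        """Devectorized correlation matrix of internal window ``w``."""
        return devectorize_corr(self.windows[w], self.r)


@dataclass
class WindowStack:
    """Window entries for a collection of subjects (one site or pooled)."""

    entries: List[WindowEntry]

    @property
    def n_subjects(self) -> int:
        return len(self.entries)

    def stacked(self) -> np.ndarray:
        return np.vstack([e.windows for e in self.entries])

    def save_hdf5(self, path) -> None:
        import h5py  # optional heavyweight dep, imported lazily

        with h5py.File(path, "w") as f:
            for i, e in enumerate(self.entries):
                g = f.create_group(f"subject_{i}")
                g.create_dataset("windows", data=e.windows)
                g.attrs["t"] = e.t
                g.attrs["r"] = e.r


@dataclass
class ExemplarSet:
    """Window indices (internal, strictly increasing) of variance maxima."""

    indices: np.ndarray
    fallback_used: bool = False

    @property
    def user_indices(self) -> np.ndarray:
        return self.indices + 1


def sliding_window_corr(S_hat: np.ndarray, t: int) -> WindowEntry:
    """Windowed Pearson correlation of component timecourses.

    ``S_hat`` is components x timepoints.  A component with zero variance
    inside a window contributes 0 to that window's correlation entries and
    the window is flagged degenerate.
    """
    S = np.asarray(S_hat, dtype=float)
    r, N = S.shape
    if t < 2:
        raise ValueError("window length t must be >= 2")
    if t >= N:
        raise ValueError(f"window length t={t} must be < N={N}")
    n_w = N - t
    out = np.empty((n_w, n_pairs(r)))
    degenerate = np.zeros(n_w, dtype=bool)
    iu = np.triu_indices(r, k=1)
    for w in range(n_w):
        seg = S[:, w : w + t + 1]
        sd = seg.std(axis=1)
        bad = sd == 0
        if np.any(bad):
            degenerate[w] = True
            seg = seg.copy()
            sd = sd.copy()
            sd[bad] = 1.0
        centered = seg - seg.mean(axis=1, keepdims=True)
        C = (centered @ centered.T) / (seg.shape[1] * np.outer(sd, sd))
        if np.any(bad):
            C[bad, :] = 0.0
            C[:, bad] = 0.0
        out[w] = C[iu]
    return WindowEntry(windows=out, t=t, r=r, degenerate=degenerate)


def variance_timecourse(entry: WindowEntry) -> np.ndarray:
    """Variance of the windowed connectivity across component pairs, at
    each window (population variance over the vectorized pair entries)."""
    return entry.windows.var(axis=1)


def select_exemplars(entry: WindowEntry, per_pair_variance: bool = False) -> ExemplarSet:
    """Windows at strict local maxima of the connectivity-variance course.

    ``per_pair_variance`` switches to the alternative reading (variance
    over time per pair, summed) kept behind a flag for comparison.  A
    monotone/constant variance course falls back to the single global
    maximum.
    """
    if entry.n_windows < 3:
        raise ValueError("need at least 3 windows to define local maxima")
    if per_pair_variance:
        # variance across windows per pair -> weight pairs, then score each
        # window by its (squared) deviation profile over the weighted pairs
        dev = entry.windows - entry.windows.mean(axis=0, keepdims=True)
        v = (dev**2).mean(axis=1)
    else:
        v = variance_timecourse(entry)
    interior = np.arange(1, len(v) - 1)
    is_max = (v[interior] > v[interior - 1]) & (v[interior] > v[interior + 1])
    idx = interior[is_max]
    if idx.size == 0:
        return ExemplarSet(indices=np.array([int(np.argmax(v))]), fallback_used=True)
    return ExemplarSet(indices=idx, fallback_used=False)
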