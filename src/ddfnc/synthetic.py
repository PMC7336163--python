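"""Synthetic data generators.

Two families: unstructured Gaussian matrices for the PCA-equivalence
experiments, and structured multi-subject mixtures of super-Gaussian
spatial sources whose timecourses switch among a small number of planted
connectivity states — the ground truth every full-pipeline test measures
against.

Data model: each subject is ``X = A S + noise`` where the columns of ``A``
(the spatial maps over voxels) are the statistically independent sources
and ``S`` carries piecewise-stationary timecourses whose within-state
correlation equals the planted state centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GroundTruth",
    "gen_gaussian",
    "gen_state_dataset",
    "random_correlation_matrices",
    "subjects_to_nifti",
    "write_subject_matrix",
]


@dataclass
class GroundTruth:
    """Planted quantities behind a structured synthetic dataset."""

    A: np.ndarray  # voxels x r spatial source maps
    state_centroids: np.ndarray  # k x r x r correlation matrices
    state_sequences: List[np.ndarray]  # per subject, per-timepoint state label
    timecourses: List[np.ndarray]  # per subject, r x T mixing timecourses
    noise_sd: float
    site_of_subject: List[int] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.state_centroids.shape[0]

    @property
    def r(self) -> int:
        return self.A.shape[1]

    def window_labels(self, t: int) -> List[np.ndarray]:
        """Majority planted state per sliding window (windows w..w+t)."""
        out = []
        for seq in self.state_sequences:
            n_w = len(seq) - t
            labels = np.empty(n_w, dtype=int)
            for w in range(n_w):
                votes = np.bincount(seq[w : w + t + 1], minlength=self.n_states)
                labels[w] = int(np.argmax(votes))
            out.append(labels)
        return out


def gen_gaussian(d: int, n: int, seed: int) -> np.ndarray:
    """An i.i.d. standard-normal ``d x n`` matrix (seeded)."""
    if d < 1 or n < 1:
        raise ValueError("d and n must be >= 1")
    return np.random.default_rng(seed).standard_normal((d, n))


def random_correlation_matrices(
    k: int, r: int, rng: np.random.Generator, n_factors: int = 2, min_separation: float = 0.2
) -> np.ndarray:
    """Draw ``k`` distinct, valid ``r x r`` correlation matrices.

    Each is built from a low-rank factor model (strongly patterned, so
    planted states are distinguishable through short-window sample
    correlations) and rejected if too close to an earlier draw.
    """
    out: List[np.ndarray] = []
    attempts = 0
    while len(out) < k:
        attempts += 1
        if attempts > 200 * k:
            raise RuntimeError("could not draw sufficiently distinct correlation matrices")
        G = rng.standard_normal((r, n_factors))
        cov = G @ G.T + 0.1 * np.eye(r)
        dinv = 1.0 / np.sqrt(np.diag(cov))
        C = dinv[:, None] * cov * dinv[None, :]
        if any(np.abs(C - D).mean() < min_separation for D in out):
            continue
        out.append(C)
    return np.stack(out)


def _laplacian(rng: np.random.Generator, size) -> np.ndarray:
    """Unit-variance Laplacian draws (super-Gaussian, ICA-identifiable)."""
    return rng.laplace(scale=1.0 / np.sqrt(2.0), size=size)


def gen_state_dataset(
    d: int,
    n_subjects: int,
    T: int,
    r: int,
    k_states: int,
    dwell: float = 40.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    state_centroids: Optional[np.ndarray] = None,
) -> Tuple[List[np.ndarray], GroundTruth]:
    """Generate multi-subject data with planted connectivity states.

    Each subject's ``r``-dimensional timecourses are piecewise stationary:
    within a state visit of geometric duration (mean ``dwell`` timepoints)
    the timepoints are correlated draws through the Cholesky factor of that
    state's centroid.  Spatial maps are i.i.d. Laplacian.  Returns the list
    of ``d x T`` subject matrices and the :class:`GroundTruth`.
    """
    if k_states < 1:
        raise ValueError("k_states must be >= 1")
    if dwell <= 1:
        raise ValueError("mean dwell must exceed one timepoint")
    rng = np.random.default_rng(seed)

    if state_centroids is None:
        state_centroids = random_correlation_matrices(k_states, r, rng)
    else:
        state_centroids = np.asarray(state_centroids, dtype=float)
        if state_centroids.shape != (k_states, r, r):
            raise ValueError("state_centroids must have shape (k_states, r, r)")
        uniq = {tuple(np.round(C, 12).ravel()) for C in state_centroids}
        if len(uniq) < k_states:
            raise ValueError("k_states exceeds the number of distinct centroids")
    chols = np.stack([np.linalg.cholesky(C) for C in state_centroids])

    A = _laplacian(rng, (d, r))

    subjects: List[np.ndarray] = []
    sequences: List[np.ndarray] = []
    timecourses: List[np.ndarray] = []
    for _ in range(n_subjects):
        seq = np.empty(T, dtype=int)
        S = np.empty((r, T))
        pos = 0
        state = int(rng.integers(k_states))
        while pos < T:
            length = min(T - pos, 1 + int(rng.geometric(1.0 / dwell)))
            Z = rng.standard_normal((r, length))
            S[:, pos : pos + length] = chols[state] @ Z
            seq[pos : pos + length] = state
            pos += length
            if k_states > 1:
                nxt = int(rng.integers(k_states - 1))
                state = nxt if nxt < state else nxt + 1
        X = A @ S
        if noise_sd > 0:
            X = X + noise_sd * rng.standard_normal(X.shape)
        subjects.append(X)
        sequences.append(seq)
        timecourses.append(S)

    truth = GroundTruth(
        A=A,
        state_centroids=state_centroids,
        state_sequences=sequences,
        timecourses=timecourses,
        noise_sd=float(noise_sd),
    )
    return subjects, truth


def write_subject_matrix(path, X: np.ndarray) -> None:
    """Write one subject as plain tab-delimited text (voxels x timepoints)."""
    np.savetxt(path, X, delimiter="\t")


def subjects_to_nifti(subjects: Sequence[np.ndarray], shape3d: Optional[Tuple[int, int, int]] = None):
    """Pack flat voxels x time matrices into 4-D NIfTI images.

    Voxels fill a rectangular volume row-major; a trailing partial slab is
    zero-padded and the mask of real voxels is returned alongside.
    """
    import nibabel as nib

    d = subjects[0].shape[0]
    if shape3d is None:
        side = int(np.ceil(d ** (1.0 / 3.0)))
        shape3d = (side, side, int(np.ceil(d / side / side)))
    n_cells = int(np.prod(shape3d))
    if n_cells < d:
        raise ValueError("shape3d too small for the voxel count")
    mask = np.zeros(n_cells, dtype=bool)
    mask[:d] = True
    images = []
    for X in subjects:
        if X.shape[0] != d:
            raise ValueError("all subjects must share the voxel dimension")
        vol = np.zeros((n_cells, X.shape[1]))
        vol[:d] = X
        img = nib.Nifti1Image(vol.reshape(*shape3d, X.shape[1]), affine=np.eye(4))
        images.append(img)
    return images, mask.reshape(shape3d)
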