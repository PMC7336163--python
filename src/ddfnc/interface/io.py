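"""Readers and writers for subject data and pipeline artifacts."""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

__all__ = ["load_subject_file", "load_subjects", "write_matrix", "write_labels"]


def load_subject_file(path, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Load one subject as a voxels x timepoints matrix.

    4-D NIfTI files are flattened (optionally through a boolean 3-D mask);
    anything else is read as delimited text.
    """
    path = Path(path)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4-D image, got {data.ndim}-D")
        if mask is not None:
            if mask.shape != data.shape[:3]:
                raise ValueError(f"{path}: mask shape {mask.shape} != volume {data.shape[:3]}")
            return data[mask.astype(bool)]
        return data.reshape(-1, data.shape[3])
    return np.loadtxt(path, delimiter="\t")


def load_subjects(
    manifest: Sequence, mask: Optional[np.ndarray] = None
) -> List[np.ndarray]:
    """Load a list of subject files, enforcing a common voxel dimension."""
    subjects = [load_subject_file(p, mask=mask) for p in manifest]
    d = subjects[0].shape[0]
    for p, X in zip(manifest, subjects):
        if X.shape[0] != d:
            raise ValueError(
                f"{p}: voxel dimension {X.shape[0]} differs from first subject's {d}"
            )
    return subjects


def write_matrix(path, M: np.ndarray, header: Optional[str] = None) -> None:
    np.savetxt(path, np.atleast_2d(M), delimiter="\t", header=header or "", comments="")


def write_labels(path, labels: np.ndarray) -> None:
    """1-based cluster labels, one per line."""
    np.savetxt(path, np.asarray(labels, dtype=int) + 1, fmt="%d")
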