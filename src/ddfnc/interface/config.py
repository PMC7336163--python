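"""Pipeline configuration with the headline defaults baked in."""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All consortium and algorithm parameters for one ddFNC run.

    Defaults mirror the headline parameterization: 120 subject-level
    components, 100 global spatial components with site rank ``5 * r``,
    window length 22 and 5 connectivity states.
    """

    seed: int = 0
    site_subject_counts: List[int] = field(default_factory=lambda: [157, 157])
    r: int = 100
    k1: int = 120
    k2: Optional[int] = None  # defaults to 5 * r
    window_length: int = 22
    k: int = 5
    n_init: int = 200
    kmeans_variant: str = "lloyd"
    ica_variant: str = "infomax"
    pca_variant: str = "serial"
    cluster_size: int = 2  # C, for the parallel PCA recursion
    base_cluster_size: int = 1  # B
    lr: float = 0.5  # gradient dK-means step size
    drop_initial_timepoints: int = 0  # real-data postprocessing; off for synthetic
    # synthetic-mode generator parameters (used when no data is supplied)
    synthetic: bool = True
    d: int = 2000
    T: int = 160
    n_states: int = 5
    dwell: float = 40.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.k2 is None:
            self.k2 = 5 * self.r
        if self.k2 < 5 * self.r:
            warnings.warn(
                f"k2={self.k2} below the recommended 5*r={5 * self.r}", RuntimeWarning
            )
        for name in ("r", "k1", "k2", "window_length", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
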