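"""End-to-end ddFNC orchestration.

``run_ddfnc`` wires the stages together: decentralized group ICA ->
back-reconstruction -> sliding windows -> exemplars -> two-stage
decentralized K-means -> (optional) group contrasts, with a privacy audit
of the traffic log after every run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np

from ..consortium import Consortium, build_consortium, privacy_audit
from ..dfnc import WindowStack, n_pairs, select_exemplars, sliding_window_corr
from ..dgica import IcaResult, back_reconstruct, run_dgica
from ..dkmeans import ClusterResult, two_stage_clustering
from ..evaluation import GroupStateContrast, group_state_contrast
from ..synthetic import GroundTruth, gen_state_dataset
from .config import PipelineConfig
from .io import write_labels, write_matrix

__all__ = ["DdfncRun", "run_ddfnc", "prepare_consortium"]


@dataclass
class DdfncRun:
    """Everything a ddFNC invocation produced."""

    config: PipelineConfig
    consortium: Consortium
    ica: IcaResult
    stack: WindowStack
    clusters: ClusterResult
    contrast: Optional[GroupStateContrast] = None
    truth: Optional[GroundTruth] = None

    @property
    def traffic_table(self) -> str:
        return self.consortium.channel.to_table()


def prepare_consortium(
    config: PipelineConfig, subjects: Optional[List[np.ndarray]] = None
) -> tuple[Consortium, Optional[GroundTruth]]:
    """Build the consortium, generating synthetic data when none is given."""
    truth = None
    if subjects is None:
        if not config.synthetic:
            raise ValueError("no subjects supplied and synthetic mode disabled")
        subjects, truth = gen_state_dataset(
            d=config.d,
            n_subjects=sum(config.site_subject_counts),
            T=config.T,
            r=config.r,
            k_states=config.n_states,
            dwell=config.dwell,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
    consortium = build_consortium(config.site_subject_counts, config.seed, subjects=subjects)
    if truth is not None:
        truth.site_of_subject = [s.site for s in consortium.subjects()]
    return consortium, truth


def _window_stage(consortium: Consortium, t: int, drop: int = 0) -> WindowStack:
    """Back-reconstruct, window and select exemplars on every site."""
    entries = []
    for site in consortium.sites:
        A_hat = site.store["A_hat"]
        site_entries = []
        for sub in site.subjects:
            dec = back_reconstruct(A_hat, sub.data)
            S = dec.S_hat[:, drop:] if drop else dec.S_hat
            site_entries.append(sliding_window_corr(S, t))
        site.store["window_entries"] = site_entries
        site.store["windows"] = np.vstack([e.windows for e in site_entries])
        site.store["window_counts"] = [e.n_windows for e in site_entries]
        ex_rows = []
        for e in site_entries:
            ex = select_exemplars(e)
            ex_rows.append(e.windows[ex.indices])
        site.store["exemplars"] = np.vstack(ex_rows)
        entries.extend(site_entries)
    return WindowStack(entries=entries)


def run_ddfnc(
    config: PipelineConfig,
    subjects: Optional[List[np.ndarray]] = None,
    groups: Optional[Mapping[int, str]] = None,
    outdir: Optional[Path] = None,
) -> DdfncRun:
    """Execute the full decentralized dFNC pipeline.

    ``groups`` maps global subject index (site order) to one of two group
    names; when given, per-state group contrasts are computed.  Artifacts
    are written under ``outdir`` when provided, alongside the config and
    traffic log, so a run is reproducible from its output directory.
    """
    consortium, truth = prepare_consortium(config, subjects)

    ica = run_dgica(
        consortium,
        r=config.r,
        k1=config.k1,
        k2=config.k2,
        ica_variant=config.ica_variant,
        pca_variant=config.pca_variant,
        seed=config.seed,
        C=config.cluster_size,
        B=config.base_cluster_size,
    )
    # every site now holds the broadcast maps; the aggregator keeps its own
    consortium.aggregator.store.setdefault("A_hat", ica.A_hat)

    stack = _window_stage(consortium, config.window_length, config.drop_initial_timepoints)

    clusters = two_stage_clustering(
        consortium,
        k=config.k,
        n_init=config.n_init,
        seed=config.seed,
        variant=config.kmeans_variant,
        lr=config.lr,
    )

    r_eff = ica.A_hat.shape[1]
    max_cols = max(config.k1, config.k2 or 0, config.r, config.k, n_pairs(r_eff))
    privacy_audit(consortium, max_cols=max_cols)

    contrast = None
    if groups is not None:
        contrast = group_state_contrast(clusters, stack, groups)

    run = DdfncRun(
        config=config,
        consortium=consortium,
        ica=ica,
        stack=stack,
        clusters=clusters,
        contrast=contrast,
        truth=truth,
    )
    if outdir is not None:
        _write_artifacts(run, Path(outdir))
    return run


def _write_artifacts(run: DdfncRun, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    run.config.to_file(outdir / "config.yaml")
    write_matrix(outdir / "centroids.tsv", run.clusters.C)
    write_labels(outdir / "labels.tsv", run.clusters.labels)
    write_matrix(outdir / "spatial_maps.tsv", run.ica.A_hat)
    (outdir / "traffic.tsv").write_text(run.traffic_table)
    if run.contrast is not None:
        for state, t_mat in run.contrast.t_matrices.items():
            if t_mat is not None:
                write_matrix(outdir / f"tmap_state{state + 1}.tsv", t_mat)
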