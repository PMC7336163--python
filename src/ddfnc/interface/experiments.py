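"""Stage-level comparison experiments on synthetic data.

Each experiment returns a tidy ``pandas.DataFrame``; runtime numbers are
reported but never asserted anywhere (they are hardware-dependent).
"""

from __future__ import annotations

import time
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ..consortium import build_consortium
from ..dgica import ICA_VARIANTS, pooled_gica, run_dgica, whiten
from ..dkmeans import multishot_gradient, multishot_lloyd, pooled_lloyd
from ..dpca import fix_signs, global_pca, local_pca, normalize_top_columns, parallel_global_pca
from ..evaluation import amari_isi, hungarian_match
from ..synthetic import gen_gaussian, gen_state_dataset
from ..dfnc import sliding_window_corr

__all__ = ["run_experiments"]


def _split_columns(X: np.ndarray, n_sites: int) -> List[np.ndarray]:
    return np.array_split(X, n_sites, axis=1)


def _consortium_with(mats: List[np.ndarray], seed: int):
    cons = build_consortium([1] * len(mats), seed=seed)
    for site, M in zip(cons.sites, mats):
        site.store["preprocessed"] = M
        site.subjects = []
    return cons


def pca_equivalence(reps: int = 50, seed: int = 0, d: int = 100, n: int = 100,
                    n_sites: int = 10, r: int = 10, k: Optional[int] = None) -> pd.DataFrame:
    """Correlation of decentralized vs pooled principal components."""
    if k is None:
        k = 5 * r
    rows = []
    for rep in range(reps):
        X = gen_gaussian(d, n, seed + rep)
        pooled = fix_signs(np.linalg.svd(X, full_matrices=False)[0][:, :r])
        for variant in ("serial", "parallel"):
            cons = _consortium_with(_split_columns(X, n_sites), seed + rep)
            if variant == "serial":
                U = global_pca(cons, r, k)
            else:
                U = parallel_global_pca(cons, r, k, C=2, B=1)
            C = np.corrcoef(U.T, pooled.T)[:r, r:]
            diag = np.abs(np.diag(C))
            off = np.abs(C[~np.eye(r, dtype=bool)])
            rows.append(
                {"rep": rep, "variant": variant, "mean_diag": diag.mean(),
                 "min_diag": diag.min(), "mean_offdiag": off.mean()}
            )
    return pd.DataFrame(rows)


def pca_runtime(seed: int = 0, d: int = 400, n_per_subject: int = 20) -> pd.DataFrame:
    """Wall-time of serial vs parallel PCA in three scaling scenarios."""
    rows = []
    scenarios = {
        "a_more_subjects_2_sites": [(2, m) for m in (8, 16, 32)],
        "b_more_sites_fixed_subjects": [(s, 64 // s) for s in (2, 4, 8, 16)],
        "c_grow_both": [(s, s) for s in (2, 4, 8)],
    }
    for name, grid in scenarios.items():
        for n_sites, subs_per_site in grid:
            X = gen_gaussian(d, n_per_subject * subs_per_site * n_sites, seed)
            mats = _split_columns(X, n_sites)
            for variant in ("serial", "parallel"):
                cons = _consortium_with(mats, seed)
                cons.channel.keep_payloads = False
                t0 = time.perf_counter()
                if variant == "serial":
                    global_pca(cons, 10, 50)
                else:
                    parallel_global_pca(cons, 10, 50, C=2, B=1, n_jobs=-1)
                rows.append(
                    {"scenario": name, "sites": n_sites, "subjects": subs_per_site * n_sites,
                     "variant": variant, "seconds": time.perf_counter() - t0}
                )
    return pd.DataFrame(rows)


def ica_comparison(reps: int = 10, seed: int = 0, d: int = 3000, r: int = 8) -> pd.DataFrame:
    """ISI of each registered ICA variant against planted spatial sources."""
    rows = []
    for rep in range(reps):
        subjects, truth = gen_state_dataset(
            d=d, n_subjects=4, T=120, r=r, k_states=2, noise_sd=0.0, seed=seed + rep
        )
        pre = np.hstack(subjects)
        U = fix_signs(normalize_top_columns(local_pca(pre, r).P, r))
        Uw, _ = whiten(U)
        # mixing from planted maps into the whitened PCA basis
        M = np.linalg.lstsq(Uw, truth.A, rcond=None)[0]
        for name, fn in ICA_VARIANTS.items():
            t0 = time.perf_counter()
            res = fn(Uw, seed=seed + rep)
            rows.append(
                {"rep": rep, "variant": name, "isi": amari_isi(res.W @ M),
                 "seconds": time.perf_counter() - t0}
            )
    return pd.DataFrame(rows)


def kmeans_equivalence(seed: int = 0, n_subjects: int = 12, n_sites: int = 2,
                       r: int = 8, T: int = 120, t: int = 22, k: int = 3) -> pd.DataFrame:
    """Matched centroid correlations: decentralized variants vs pooled."""
    subjects, truth = gen_state_dataset(
        d=200, n_subjects=n_subjects, T=T, r=r, k_states=k, seed=seed
    )
    counts = [n_subjects // n_sites] * n_sites
    counts[-1] += n_subjects - sum(counts)
    cons = build_consortium(counts, seed=seed, subjects=subjects)
    idx = 0
    for site in cons.sites:
        entries = [sliding_window_corr(truth.timecourses[idx + m], t) for m in range(site.n_subjects)]
        site.store["windows"] = np.vstack([e.windows for e in entries])
        idx += site.n_subjects
    pooled_X = np.vstack([s.store["windows"] for s in cons.sites])
    rng = np.random.default_rng(seed)
    C0 = pooled_X[rng.choice(pooled_X.shape[0], size=k, replace=False)]
    ref = pooled_lloyd(pooled_X, k, C0)
    rows = []
    for variant, fn in (("lloyd", multishot_lloyd), ("gradient", multishot_gradient)):
        res = fn(cons, "windows", k, C0)
        match = hungarian_match(res.C.T, ref.C.T)
        rows.append(
            {"variant": variant, "min_corr": match.min_correlation,
             "mean_corr": match.mean_correlation, "iterations": res.iterations}
        )
    return pd.DataFrame(rows)


_EXPERIMENTS = {
    "pca_equivalence": pca_equivalence,
    "pca_runtime": pca_runtime,
    "ica_comparison": ica_comparison,
    "kmeans_equivalence": kmeans_equivalence,
}


def run_experiments(which: str, seed: int = 0, **kwargs) -> pd.DataFrame:
    """Dispatch one of the named experiments; returns its report table."""
    if which not in _EXPERIMENTS:
        raise KeyError(f"unknown experiment {which!r}; have {sorted(_EXPERIMENTS)}")
    return _EXPERIMENTS[which](seed=seed, **kwargs)
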