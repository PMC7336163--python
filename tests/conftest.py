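import numpy as np
import pytest

from ddfnc.consortium import build_consortium
from ddfnc.dfnc import select_exemplars, sliding_window_corr
from ddfnc.synthetic import gen_state_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def attach_timecourse_windows(consortium, truth, t=22):
    """Window the generated timecourses onto each site's store (used by
    clustering tests that bypass the ICA stage)."""
    idx = 0
    for site in consortium.sites:
        entries = [
            sliding_window_corr(truth.timecourses[idx + m], t)
            for m in range(site.n_subjects)
        ]
        site.store["windows"] = np.vstack([e.windows for e in entries])
        site.store["window_counts"] = [e.n_windows for e in entries]
        site.store["exemplars"] = np.vstack(
            [e.windows[select_exemplars(e).indices] for e in entries]
        )
        idx += site.n_subjects
    return consortium


@pytest.fixture(scope="session")
def planted_dataset():
    """Planted 5-state dataset: 2 sites x 20 subjects, 10 components."""
    subjects, truth = gen_state_dataset(
        d=500, n_subjects=40, T=160, r=10, k_states=5, dwell=60.0, noise_sd=0.05, seed=2
    )
    return subjects, truth


@pytest.fixture
def planted_consortium(planted_dataset):
    subjects, truth = planted_dataset
    cons = build_consortium([20, 20], seed=2, subjects=subjects)
    return attach_timecourse_windows(cons, truth), truth
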