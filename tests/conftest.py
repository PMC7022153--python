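import numpy as np
import pandas as pd
import pytest

import fcdev


@pytest.fixture(scope="session")
def small_parc():
    return fcdev.make_parcellation(16, 4, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted mixed MI structure, reused read-only."""
    cfg = fcdev.SimulationConfig(n_subjects=80, n_cortical=16, n_subcortical=4, seed=7)
    return fcdev.simulate_cohort(cfg)


def make_meta(n_scans, seed=0, n_subjects=None, one_scan_each=False):
    """Random scan metadata for growth-model tests."""
    rng = np.random.default_rng(seed)
    if one_scan_each:
        subj = np.arange(n_scans)
    else:
        n_subjects = n_subjects or max(2, n_scans // 2)
        subj = rng.integers(0, n_subjects, n_scans)
    return pd.DataFrame(
        {
            "scan_id": [f"s{i}" for i in range(n_scans)],
            "subject_id": [f"subj{int(s)}" for s in subj],
            "age": rng.uniform(14, 26, n_scans),
            "sex": rng.integers(0, 2, n_scans),
            "site": rng.choice(["A", "B"], n_scans),
        }
    )


@pytest.fixture
def meta_factory():
    return make_meta
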