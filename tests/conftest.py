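"""Shared fixtures: one small synthetic cohort and its decomposition.

Session-scoped so the (comparatively) expensive signal generation and
wavelet decomposition run once for the whole suite.
"""

import numpy as np
import pytest

from pdeeg import decomposition as dec
from pdeeg.pipeline import train_feature_models
from pdeeg.protocol import build_compact_protocol
from pdeeg.synth import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def compact_schedule():
    return build_compact_protocol(seed=7)


@pytest.fixture(scope="session")
def small_cohort(compact_schedule):
    """6 PD + 6 healthy recordings under default generator settings."""
    recs, meta = generate_cohort(6, compact_schedule, GeneratorConfig(seed=42))
    return recs, meta


@pytest.fixture(scope="session")
def small_basis(small_cohort):
    recs, _ = small_cohort
    windows = np.vstack([dec.sliding_windows(r.samples)[::20]
                         for r in recs[:4]])
    return dec.select_best_basis(windows, depth=5)


@pytest.fixture(scope="session")
def small_bafs(small_cohort, small_basis):
    recs, _ = small_cohort
    return [dec.baf_timecourses(r.samples, small_basis) for r in recs]


@pytest.fixture(scope="session")
def feature_models(small_cohort, small_bafs):
    recs, _ = small_cohort
    hidx = [i for i, r in enumerate(recs) if r.group == "healthy"]
    return train_feature_models([small_bafs[i] for i in hidx],
                                [recs[i].labels for i in hidx],
                                anchor_bafs=small_bafs)
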