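"""Shared fixtures: the reference simulated cohort and derived objects.

The heavier objects (activities, network) are session-scoped so the planted
recovery, mining and bootstrap tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mechnet import build_network, single_sample_activities
from mechnet.datatypes import Signature
from mechnet.simulate import make_cohort

COHORT_SEED = 11
ACTIVITY_SEED = 42
N_PERM = 1000


@pytest.fixture(scope="session")
def cohort():
    """The reference simulated cohort (expression, gene sets, regulons, truth)."""
    return make_cohort(rng_seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_activities(cohort):
    expr, genesets, regulons, _ = cohort
    return single_sample_activities(expr, genesets, regulons,
                                    n_perm=N_PERM, rng_seed=ACTIVITY_SEED)


@pytest.fixture(scope="session")
def cohort_network(cohort_activities):
    return build_network(cohort_activities.trs, cohort_activities.pathways,
                         fdr_threshold=0.05)


@pytest.fixture
def toy_signature():
    """20 genes with scores 20..1 (g01 strongest)."""
    ids = np.array([f"g{i + 1:02d}" for i in range(20)], dtype=object)
    return Signature(ids, np.arange(20, 0, -1).astype(float))


def make_signature(scores, prefix="g") -> Signature:
    scores = np.asarray(scores, dtype=float)
    ids = np.array([f"{prefix}{i + 1:03d}" for i in range(len(scores))], dtype=object)
    return Signature(ids, scores)
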