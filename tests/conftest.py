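"""Shared fixtures.

The three posterior fits (parameter recovery, planted-shift adjustment,
signature benchmark) are expensive, so each is computed once per session and
shared by the acceptance tests and any property tests that inspect the same
results.
"""

import numpy as np
import pandas as pd
import pytest

from sparsesig import experiments
from sparsesig.catalogue import COLUMNS


@pytest.fixture(scope="session")
def recovery_result():
    return experiments.recovery_study(sampler_seed=101)


@pytest.fixture(scope="session")
def adjustment_result():
    return experiments.adjustment_study(sampler_seed=31)


@pytest.fixture(scope="session")
def benchmark_result():
    return experiments.benchmark_study(sampler_seed=41)


@pytest.fixture
def tiny_catalogue():
    """Two datasets x two cell types, fully observed, hand-enumerable."""
    rows = []
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(6)]
    for ds, ct, sample in [
        ("dsA", "ct0", "a1"), ("dsA", "ct1", "a2"),
        ("dsB", "ct0", "b1"), ("dsB", "ct1", "b2"),
    ]:
        for g in genes:
            rows.append((sample, g, ct, ds, int(rng.integers(1, 400))))
    return pd.DataFrame(rows, columns=COLUMNS)
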