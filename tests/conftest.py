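"""Shared fixtures: synthetic benchmark datasets and trained ensembles.

The heavyweight objects (the ~1900-complex benchmark, the trained ensemble
and its shuffled-label control) are session-scoped so the planted-signal
tests share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from atomscreen.model import GCNEnsemble, TrainingConfig
from atomscreen.synth import FixtureSpec, build_training_dataset, gen_toy_library

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The full synthetic benchmark: ~1900 labelled complexes over 12 targets."""
    return build_training_dataset(FixtureSpec())


@pytest.fixture(scope="session")
def small_dataset():
    """A small 7-target benchmark for fast training-behaviour tests."""
    return build_training_dataset(FixtureSpec(n_ligands=140, n_targets=7))


@pytest.fixture(scope="session")
def toy_library():
    """60 grammar molecules with fingerprints for similarity/clustering tests."""
    from atomscreen.chem import FingerprintConfig, fingerprint_matrix

    mols = gen_toy_library(FixtureSpec(n_ligands=60))
    fingerprint_matrix(mols, FingerprintConfig())
    return mols


@pytest.fixture(scope="session")
def trained_ensemble(benchmark_dataset):
    """The six-member ensemble trained under the study conditions."""
    ds = benchmark_dataset
    ens = GCNEnsemble(training=TrainingConfig(seed=BENCHMARK_SEED))
    return ens.fit(ds["graphs"], ds["y"], ds["groups"], ds["sequences"])


@pytest.fixture(scope="session")
def control_labels(benchmark_dataset):
    """Activity labels permuted within each target (grouped permutation control)."""
    ds = benchmark_dataset
    rng = np.random.default_rng(123)
    y = ds["y"].copy()
    for t in sorted(set(ds["groups"])):
        idx = np.flatnonzero((ds["groups"] == t) & ~np.isnan(y[:, 0]))
        y[idx, 0] = rng.permutation(y[idx, 0])
    return y


@pytest.fixture(scope="session")
def control_ensemble(benchmark_dataset, control_labels):
    """The same protocol trained on the shuffled-label control."""
    ds = benchmark_dataset
    ens = GCNEnsemble(training=TrainingConfig(seed=BENCHMARK_SEED))
    return ens.fit(ds["graphs"], control_labels, ds["groups"], ds["sequences"])
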