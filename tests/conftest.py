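import numpy as np
import pandas as pd
import pytest

from strandcoop.datatypes import ExpressionStudy
from strandcoop.simulate import SimulationConfig, simulate_cohort


TINY = dict(
    n_cancers=3,
    affected_cancers=2,
    n_tumor=15,
    n_normal=10,
    n_genes=400,
    n_precursors=10,
    n_singletons=10,
    n_pathways=5,
    pathway_size=30,
    targets_per_strand=20,
    pathway_targets_per_strand=12,
    cotarget_overlap=4,
    n_confounded_genes=50,
    lines_per_lineage=4,
)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(**TINY)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config, seed=7)


@pytest.fixture()
def small_study():
    """Hand-built 3-feature x 4-sample expression study."""
    counts = pd.DataFrame(
        [[10, 20, 5, 8], [0, 0, 2, 3], [100, 80, 90, 70]],
        index=["fA", "fB", "fC"],
        columns=["t1", "t2", "n1", "n2"],
    )
    norm = counts / counts.sum(axis=0) * 1e6
    groups = pd.Series(
        ["tumor", "tumor", "normal", "normal"], index=counts.columns
    )
    return ExpressionStudy(
        cancer_type="TEST",
        raw_counts=counts,
        normalized=norm,
        feature_kind="miRNA",
        sample_groups=groups,
    )


def nb_counts(rng, mu, phi, shape):
    """Reference NB sampler with var = mu + phi mu^2 (used by tests only)."""
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=shape)
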