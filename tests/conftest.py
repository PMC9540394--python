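import numpy as np
import pandas as pd
import pytest

from tgxddi import SimConfig, TrainingSet, generate_training_set
from tgxddi.tgx_classifier import DDI, NON_DDI, NSCModel


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Down-scaled study design for fast count-matrix tests."""
    return SimConfig(seed=7, n_probes=300, depth_mean=50_000.0)


@pytest.fixture(scope="session")
def default_training() -> TrainingSet:
    train, _ = generate_training_set(SimConfig(seed=11))
    return train


@pytest.fixture()
def toy_training() -> TrainingSet:
    """Two well-separated classes in a 2-gene panel (along the (1,1) axis)."""
    rng = np.random.default_rng(3)
    ddi = rng.normal(-1.0, 0.05, size=(2, 4))
    non = rng.normal(1.0, 0.05, size=(2, 4))
    profiles = pd.DataFrame(
        np.hstack([ddi, non]),
        index=["g1", "g2"],
        columns=[f"D{i}" for i in range(4)] + [f"N{i}" for i in range(4)],
    )
    labels = pd.Series([DDI] * 4 + [NON_DDI] * 4, index=profiles.columns)
    return TrainingSet(profiles, labels)


@pytest.fixture()
def unit_toy_model() -> NSCModel:
    """Hand-built NSC model: centroids (1,1) / (-1,-1), unit dispersions."""
    cents = np.array([[1.0, -1.0], [1.0, -1.0]])
    return NSCModel(
        gene_ids=["g1", "g2"],
        classes=[DDI, NON_DDI],
        overall_centroid=np.zeros(2),
        class_centroids=cents,
        shrunken_centroids=cents,
        pooled_sd=np.ones(2),
        s0=0.0,
        m_k=np.array([0.5, 0.5]),
        delta=0.0,
        d_scores=cents.copy(),
        d_shrunk=cents.copy(),
        priors=np.array([0.5, 0.5]),
    )
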