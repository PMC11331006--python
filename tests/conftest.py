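import numpy as np
import pytest

from msfn.cnn import CNNConfig
from msfn.ensemble import EnsembleConfig
from msfn.preprocess import align_patients, derive_labels, preprocess_view
from msfn.resgcn import ResGCNConfig
from msfn.synthetic import CohortConfig, generate_cohort


def make_views_labels(signal=1.0, seed=0, n=150, **cfg_kwargs):
    """Preprocessed, aligned views + labels for a synthetic cohort."""
    config = CohortConfig(
        n_patients=n,
        seed=seed,
        signal_strength={"clinical": signal, "expression": signal, "cnv": signal},
        **cfg_kwargs,
    )
    cohort = generate_cohort(config)
    views = {v: preprocess_view(b) for v, b in cohort.views.items()}
    labels = derive_labels(cohort.survival)
    views, labels = align_patients(views, labels)
    return views, labels


@pytest.fixture(scope="session")
def cohort_views_labels():
    """Moderate-signal cohort shared by the slower integration tests."""
    return make_views_labels(signal=1.5, seed=11, n=150)


@pytest.fixture(scope="session")
def fast_branch_configs():
    """Reduced branch sizes keeping integration tests quick."""
    return dict(
        resgcn_config=ResGCNConfig(hidden_dim=16, fusion_dim=16, epochs=60, patience=15),
        cnn_config=CNNConfig(n_filters=4, fc_units=16, epochs=20),
        ensemble_config=EnsembleConfig(n_boost_rounds=20, base_forest_trees=5),
        n_select={"expression": 15, "cnv": 10},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
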