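import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from deamipred.chimeric_model import build_model, featurize_labeled, train
from deamipred.global_embedding import make_mock_embedder
from deamipred.io_formats import ChainSequence, RunConfig
from deamipred.labeling import label_sites
from deamipred.synthetic_data import SyntheticSpec, generate


@pytest.fixture(scope="session")
def fast_config() -> RunConfig:
    """Small widths / few epochs so training-dependent tests stay fast."""
    return RunConfig(
        window_size=7,
        embedder_name="mock-d16-s0",
        seed=0,
        hidden_widths=(16, 8),
        dropout=0.1,
        token_dim=6,
        lstm_hidden=8,
        learning_rate=3e-3,
        weight_decay=1e-2,
        batch_size=64,
        max_epochs=25,
        patience=5,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """6-molecule synthetic dataset: (chains, measured sites, ground truth)."""
    spec = SyntheticSpec(seed=3, n_molecules=6, fraction_tolerance=0.2)
    return generate(spec)


@pytest.fixture(scope="session")
def small_features(small_dataset, fast_config):
    chains, sites, _ = small_dataset
    labeled = label_sites(sites)
    embedder = make_mock_embedder(16, 0)
    return featurize_labeled(labeled, chains, embedder, fast_config.window_size)


def _split(features, seed=0):
    idx = np.arange(len(features))
    tr, va = train_test_split(idx, test_size=0.15, stratify=features.y, random_state=seed)
    return features.subset(tr), features.subset(va)


@pytest.fixture(scope="session")
def trained_local_model(small_features, fast_config):
    tr, va = _split(small_features)
    model = build_model("local_only", "classification", fast_config, small_features.dim)
    return train(model, tr, va, fast_config)


@pytest.fixture(scope="session")
def trained_global_model(small_features, fast_config):
    tr, va = _split(small_features)
    model = build_model("global_only", "classification", fast_config, small_features.dim)
    return train(model, tr, va, fast_config)


@pytest.fixture(scope="session")
def trained_chimeric_regressor(small_features, fast_config):
    tr, va = _split(small_features)
    model = build_model("chimeric", "regression", fast_config, small_features.dim)
    return train(model, tr, va, fast_config)


@pytest.fixture
def toy_chain() -> ChainSequence:
    return ChainSequence("mAbX", "HC", "ADNGSQWNKLMNSTVNNY")
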