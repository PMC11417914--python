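"""Default desk-scale synthetic benchmark used by tests and reports.

45 molecules, ~12% active sites, mock embedder. Hyperparameters are
deliberately smaller than the package defaults so a full 5-fold
cross-validation of all three variants stays in the single-CPU budget;
everything is recorded in the returned RunConfig.
"""

from __future__ import annotations

from .chimeric_model import FeatureSet, featurize_labeled
from .global_embedding import make_mock_embedder
from .io_formats import RunConfig
from .labeling import LabeledSite, label_sites
from .synthetic_data import SyntheticSpec, generate

BENCHMARK_EMBED_DIM = 48


def benchmark_config(seed: int = 7, window_size: int = 11) -> RunConfig:
    return RunConfig(
        window_size=window_size,
        embedder_name=f"mock-d{BENCHMARK_EMBED_DIM}-s0",
        seed=seed,
        hidden_widths=(64, 32),
        dropout=0.3,
        token_dim=12,
        lstm_hidden=24,
        learning_rate=3e-3,
        weight_decay=1e-2,
        batch_size=64,
        max_epochs=80,
        patience=10,
    )


def make_benchmark_dataset(seed: int = 7):
    """Generate, label: returns (chains, labeled sites, ground truth)."""
    spec = SyntheticSpec(seed=seed)
    chains, sites, truth = generate(spec)
    labeled = label_sites(sites, threshold=spec.label_threshold)
    return chains, labeled, truth


def context_sweep_spec(seed: int = 11) -> SyntheticSpec:
    """Synthetic spec whose labels lean heavily on the +/-5 context rule.

    Successor-motif base rates are scaled down and the planted context
    effect boosted so short windows genuinely lack information; used to
    demonstrate that the window sweep prefers w=11 over w=3.
    """
    from .synthetic_data import DEFAULT_BASE_RATES

    scale = 0.35
    return SyntheticSpec(
        seed=seed,
        n_molecules=90,
        context_sd=1.8,
        noise_sd=0.3,
        base_rates={k: v * scale for k, v in DEFAULT_BASE_RATES.items()},
        other_n_rate=0.0028 * scale,
        q_rate=0.0010 * scale,
    )


def make_benchmark_features(
    seed: int = 7,
    window_size: int | None = None,
    labeled: list[LabeledSite] | None = None,
    chains=None,
) -> FeatureSet:
    config = benchmark_config(seed)
    if labeled is None or chains is None:
        chains, labeled, _ = make_benchmark_dataset(seed)
    embedder = make_mock_embedder(BENCHMARK_EMBED_DIM, 0)
    return featurize_labeled(
        labeled, chains, embedder, window_size or config.window_size
    )
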