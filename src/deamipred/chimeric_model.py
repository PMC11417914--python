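"""The three model variants and their training/inference machinery.

* ``global_only`` — the site's global embedding vector through a dense
  head (two hidden layers, each followed by dropout).
* ``local_only`` — the tokenized local window through the learned
  embedding + bidirectional LSTM encoder, then the dense head.
* ``chimeric`` — concatenation of the raw global site vector and the
  local encoder output, then the dense head.

The classification head outputs one logit (probability after sigmoid);
the regression head outputs three values for the 2/4/8-week extents.
Classification and regression are separate training runs sharing the
architecture. The local encoder is trained jointly with the head; the
global embedder is a frozen upstream feature source.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, ShapeError, TrainingError, ValidationError
from .global_embedding import EmbeddingCache, embed_chain
from .io_formats import (
    ChainSequence,
    RunConfig,
    SitePrediction,
    TARGET_TIME_POINTS,
)
from .labeling import LabeledSite, enumerate_candidate_sites
from .local_sequence import VOCAB, extract_window, windows_to_array
from .nn import Adam, LocalEncoder, MLPHead, bce_with_logits, masked_mse

VARIANTS = ("global_only", "local_only", "chimeric")
TASKS = ("classification", "regression")


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Aligned per-site arrays ready for training or inference."""

    X_global: np.ndarray  # (n, d)
    tokens: np.ndarray  # (n, w) int
    provenance: list[tuple[str, str, int, str]]  # (molecule, chain, position, residue)
    embedder_name: str
    window_size: int
    y: np.ndarray | None = None  # (n,) 0/1 labels
    targets: np.ndarray | None = None  # (n, 3) percent extents, NaN = absent

    def __len__(self) -> int:
        return self.X_global.shape[0]

    @property
    def dim(self) -> int:
        return self.X_global.shape[1]

    def subset(self, idx) -> "FeatureSet":
        idx = np.asarray(idx)
        return FeatureSet(
            X_global=self.X_global[idx],
            tokens=self.tokens[idx],
            provenance=[self.provenance[i] for i in idx],
            embedder_name=self.embedder_name,
            window_size=self.window_size,
            y=self.y[idx] if self.y is not None else None,
            targets=self.targets[idx] if self.targets is not None else None,
        )


def _chain_lookup(chains: Sequence[ChainSequence]) -> dict[tuple[str, str], ChainSequence]:
    return {c.key: c for c in chains}


def featurize_labeled(
    labeled: Sequence[LabeledSite],
    chains: Sequence[ChainSequence],
    embedder,
    window_size: int,
    cache: EmbeddingCache | None = None,
) -> FeatureSet:
    """Join labeled sites against their chains; embed + window each site."""
    lookup = _chain_lookup(chains)
    matrices: dict[tuple[str, str], np.ndarray] = {}
    Xg, toks, prov, ys, targs = [], [], [], [], []
    for ls in labeled:
        s = ls.site
        key = (s.molecule_id, s.chain_id)
        chain = lookup.get(key)
        if chain is None:
            raise ValidationError(f"no chain {key} for site at position {s.position}")
        if s.position > len(chain):
            raise ValidationError(
                f"position {s.position} beyond chain {key} of length {len(chain)}"
            )
        if chain.sequence[s.position - 1] != s.residue:
            raise ValidationError(
                f"residue mismatch at {key}:{s.position}: chain has "
                f"{chain.sequence[s.position - 1]!r}, table says {s.residue!r}"
            )
        if key not in matrices:
            matrices[key] = embed_chain(embedder, chain, cache=cache).vectors
        Xg.append(matrices[key][s.position - 1])
        toks.append(extract_window(chain, s.position, window_size).tokens)
        prov.append((s.molecule_id, s.chain_id, s.position, s.residue))
        ys.append(1 if ls.is_active else 0)
        targs.append([ls.regression_targets.get(t, np.nan) for t in TARGET_TIME_POINTS])
    return FeatureSet(
        X_global=np.array(Xg) if Xg else np.zeros((0, embedder.dim)),
        tokens=np.array(toks, dtype=np.int64) if toks else np.zeros((0, window_size), np.int64),
        provenance=prov,
        embedder_name=embedder.name,
        window_size=window_size,
        y=np.array(ys, dtype=np.int64),
        targets=np.array(targs, dtype=np.float64),
    )


def featurize_candidates(
    chains: Sequence[ChainSequence],
    embedder,
    window_size: int,
    cache: EmbeddingCache | None = None,
) -> FeatureSet:
    """Featurize every N/Q site of every chain (screening mode; no labels)."""
    Xg, toks, prov = [], [], []
    for chain in chains:
        matrix = embed_chain(embedder, chain, cache=cache).vectors
        for pos, residue in enumerate_candidate_sites(chain):
            Xg.append(matrix[pos - 1])
            toks.append(extract_window(chain, pos, window_size).tokens)
            prov.append((chain.molecule_id, chain.chain_id, pos, residue))
    return FeatureSet(
        X_global=np.array(Xg) if Xg else np.zeros((0, embedder.dim)),
        tokens=np.array(toks, dtype=np.int64) if toks else np.zeros((0, window_size), np.int64),
        provenance=prov,
        embedder_name=embedder.name,
        window_size=window_size,
    )


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

class _Network:
    """Wires encoder and head for one (variant, task) pair; owns no state."""

    def __init__(self, variant: str, task: str, config: RunConfig, d: int):
        if variant not in VARIANTS:
            raise ConfigError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        if task not in TASKS:
            raise ConfigError(f"unknown task {task!r}; expected one of {TASKS}")
        if variant != "local_only" and d <= 0:
            raise ConfigError(f"embedding dimension must be positive, got {d}")
        self.variant = variant
        self.task = task
        self.d = d
        self.config = config
        self.encoder = (
            None
            if variant == "global_only"
            else LocalEncoder(len(VOCAB), config.window_size, config.token_dim, config.lstm_hidden)
        )
        if variant == "global_only":
            head_in = d
        elif variant == "local_only":
            head_in = self.encoder.out_dim
        else:
            head_in = d + self.encoder.out_dim
        out_dim = 1 if task == "classification" else len(TARGET_TIME_POINTS)
        self.head = MLPHead(head_in, config.hidden_widths, out_dim, config.dropout)

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        params = {f"head.{k}": v for k, v in self.head.init_params(rng).items()}
        if self.encoder is not None:
            params.update({f"enc.{k}": v for k, v in self.encoder.init_params(rng).items()})
        return params

    def _split(self, params: Mapping[str, np.ndarray]):
        head_p = {k[5:]: v for k, v in params.items() if k.startswith("head.")}
        enc_p = {k[4:]: v for k, v in params.items() if k.startswith("enc.")}
        return head_p, enc_p

    def forward(self, Xg, tokens, params, train=False, rng=None):
        head_p, enc_p = self._split(params)
        enc_cache = None
        if self.variant == "global_only":
            head_in = Xg
        else:
            local_out, enc_cache = self.encoder.forward(tokens, enc_p)
            head_in = local_out if self.variant == "local_only" else np.concatenate([Xg, local_out], axis=1)
        out, head_cache = self.head.forward(head_in, head_p, train=train, rng=rng)
        return out, (head_cache, enc_cache, head_p)

    def backward(self, dout, cache):
        head_cache, enc_cache, head_p = cache
        head_grads, din = self.head.backward(dout, head_p, head_cache)
        grads = {f"head.{k}": v for k, v in head_grads.items()}
        if self.encoder is not None:
            dlocal = din if self.variant == "local_only" else din[:, self.d :]
            enc_grads = self.encoder.backward(dlocal, enc_cache)
            grads.update({f"enc.{k}": v for k, v in enc_grads.items()})
        return grads


@dataclass
class UntrainedModel:
    """Architecture handle produced by :func:`build_model`."""

    variant: str
    task: str
    config: RunConfig
    d: int
    network: _Network = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.network is None:
            self.network = _Network(self.variant, self.task, self.config, self.d)

    @property
    def head_input_dim(self) -> int:
        return self.network.head.widths[0]


@dataclass
class TrainedModel:
    """Learned weights plus everything needed to reproduce the forward pass."""

    variant: str
    task: str
    config: RunConfig
    d: int
    params: dict[str, np.ndarray]
    epochs_run: int
    best_epoch: int
    val_losses: list[float]
    embedder_name: str = ""
    network: _Network = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.network is None:
            self.network = _Network(self.variant, self.task, self.config, self.d)

    # -- inference ---------------------------------------------------------

    def _check_features(self, features: FeatureSet) -> None:
        if self.variant != "local_only" and features.dim != self.d:
            raise ShapeError(f"expected global dim {self.d}, got {features.dim}")
        if self.variant != "global_only" and features.tokens.shape[1] != self.config.window_size:
            raise ShapeError(
                f"expected window width {self.config.window_size}, got {features.tokens.shape[1]}"
            )

    def raw_outputs(self, features: FeatureSet) -> np.ndarray:
        self._check_features(features)
        out, _ = self.network.forward(features.X_global, features.tokens, self.params)
        return out

    def predict_proba(self, features: FeatureSet) -> np.ndarray:
        if self.task != "classification":
            raise ValidationError("predict_proba requires a classification model")
        from .nn import _sigmoid

        return _sigmoid(self.raw_outputs(features).ravel())

    def predict_extents(self, features: FeatureSet) -> np.ndarray:
        if self.task != "regression":
            raise ValidationError("predict_extents requires a regression model")
        return np.clip(self.raw_outputs(features) * 100.0, 0.0, 100.0)

    def score_windows(self, tokens: np.ndarray) -> np.ndarray:
        """Probabilities for raw token windows (local_only classifiers only)."""
        if self.variant != "local_only" or self.task != "classification":
            raise ValidationError("score_windows requires a local_only classifier")
        from .nn import _sigmoid

        out, _ = self.network.forward(None, np.asarray(tokens, np.int64), self.params)
        return _sigmoid(out.ravel())

    # -- persistence -------------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params)
        meta = {
            "format_version": self.FORMAT_VERSION,
            "variant": self.variant,
            "task": self.task,
            "d": self.d,
            "config": self.config.to_dict(),
            "epochs_run": self.epochs_run,
            "best_epoch": self.best_epoch,
            "val_losses": self.val_losses,
            "embedder_name": self.embedder_name,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        if meta.get("format_version") != cls.FORMAT_VERSION:
            raise ValidationError(
                f"checkpoint format {meta.get('format_version')} != {cls.FORMAT_VERSION}"
            )
        with np.load(directory / "weights.npz") as npz:
            params = {k: npz[k].copy() for k in npz.files}
        return cls(
            variant=meta["variant"],
            task=meta["task"],
            config=RunConfig.from_dict(
                {**meta["config"], "hidden_widths": tuple(meta["config"]["hidden_widths"])}
            ),
            d=meta["d"],
            params=params,
            epochs_run=meta["epochs_run"],
            best_epoch=meta["best_epoch"],
            val_losses=meta["val_losses"],
            embedder_name=meta.get("embedder_name", ""),
        )


def build_model(variant: str, task: str, config: RunConfig, d: int) -> UntrainedModel:
    """Assemble an untrained model for the given variant/task."""
    return UntrainedModel(variant=variant, task=task, config=config, d=d)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _epoch_loss(network: _Network, features: FeatureSet, params, task: str,
                sample_weight=None) -> float:
    out, _ = network.forward(features.X_global, features.tokens, params)
    if task == "classification":
        loss, _ = bce_with_logits(out, features.y, sample_weight)
    else:
        y = features.targets / 100.0
        mask = ~np.isnan(y)
        loss, _ = masked_mse(out, np.nan_to_num(y), mask)
    return loss


def train(
    model: UntrainedModel,
    train_features: FeatureSet,
    val_features: FeatureSet,
    config: RunConfig | None = None,
) -> TrainedModel:
    """Seeded mini-batch training with early stopping on validation loss.

    Stops once the validation objective has failed to improve for more
    than ``patience`` consecutive epochs and restores the
    best-validation-epoch weights.
    """
    config = config or model.config
    network = model.network
    task = model.task
    if len(train_features) == 0:
        raise TrainingError("empty training set")
    if len(val_features) == 0:
        raise TrainingError("empty validation set")
    if task == "classification":
        classes = np.unique(train_features.y)
        if classes.size < 2:
            raise TrainingError(
                "training split contains a single class; use a stratified split "
                "so both active and inactive sites are present"
            )
    rng = np.random.default_rng(config.seed)
    params = network.init_params(rng)
    optimizer = Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)

    weights_all = None
    if task == "classification" and config.class_weighting:
        n = len(train_features)
        n_pos = int(train_features.y.sum())
        w_pos = n / (2.0 * n_pos)
        w_neg = n / (2.0 * (n - n_pos))
        weights_all = np.where(train_features.y == 1, w_pos, w_neg).astype(np.float64)

    n = len(train_features)
    best_loss = np.inf
    best_params = None
    best_epoch = -1
    since_best = 0
    val_losses: list[float] = []
    epochs_run = 0
    for epoch in range(config.max_epochs):
        epochs_run = epoch + 1
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            batch = train_features.subset(idx)
            out, cache = network.forward(batch.X_global, batch.tokens, params, train=True, rng=rng)
            if task == "classification":
                sw = weights_all[idx] if weights_all is not None else None
                _, dout = bce_with_logits(out, batch.y, sw)
            else:
                y = batch.targets / 100.0
                mask = ~np.isnan(y)
                _, dout = masked_mse(out, np.nan_to_num(y), mask)
            grads = network.backward(dout, cache)
            optimizer.step(params, grads)
        val_loss = _epoch_loss(network, val_features, params, task)
        val_losses.append(val_loss)
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_params = copy.deepcopy(params)
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
    return TrainedModel(
        variant=model.variant,
        task=task,
        config=config,
        d=model.d,
        params=best_params if best_params is not None else params,
        epochs_run=epochs_run,
        best_epoch=best_epoch,
        val_losses=val_losses,
        embedder_name=train_features.embedder_name,
    )


def predict(model: TrainedModel, features: FeatureSet) -> list[SitePrediction]:
    """Deterministic inference; labels thresholded strictly at the config threshold."""
    preds: list[SitePrediction] = []
    if model.task == "classification":
        probs = model.predict_proba(features)
        for (mol, chain, pos, residue), p in zip(features.provenance, probs):
            preds.append(
                SitePrediction(
                    molecule_id=mol,
                    chain_id=chain,
                    position=pos,
                    residue=residue,
                    probability=float(p),
                    predicted_label="active" if p > model.config.decision_threshold else "inactive",
                )
            )
    else:
        extents = model.predict_extents(features)
        for (mol, chain, pos, residue), row in zip(features.provenance, extents):
            preds.append(
                SitePrediction(
                    molecule_id=mol,
                    chain_id=chain,
                    position=pos,
                    residue=residue,
                    probability=0.0,
                    predicted_label="inactive",
                    predicted_extents=tuple(float(v) for v in row),
                )
            )
    return preds
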