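"""Per-residue contextual embeddings via pluggable backends.

Two backends exist:

* ``MockEmbedder`` — a deterministic, dependency-free stand-in whose
  per-residue vector is a weighted sum of seeded hash vectors keyed by
  (residue identity, offset) over the 5-residue neighborhood, so context
  changes the vector but identical inputs give bitwise-identical output
  across processes.
* ``EsmEmbedder`` — thin wrapper over a real transformer protein language
  model (d = 1280 for the 650M-parameter default); requires ``torch`` and
  ``fair-esm`` which are optional and imported lazily.

Backends expose ``name``, ``dim``, ``max_length`` and ``embed(sequence)``.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CapacityError, ConfigError, ValidationError
from .io_formats import ChainSequence


@dataclass
class EmbeddingMatrix:
    """n x d matrix of per-residue vectors for one chain (boundary tokens removed)."""

    molecule_id: str
    chain_id: str
    vectors: np.ndarray
    embedder_name: str

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValidationError("vectors must be 2-D (n x d)")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class SiteVector:
    molecule_id: str
    chain_id: str
    position: int  # 1-based
    vector: np.ndarray


def extract_site_vector(matrix: EmbeddingMatrix, position: int) -> SiteVector:
    """Row ``position`` (1-based) of the embedding matrix, unchanged."""
    if not (1 <= position <= matrix.n):
        raise IndexError(
            f"position {position} out of range 1..{matrix.n} for "
            f"{matrix.molecule_id}|{matrix.chain_id}"
        )
    return SiteVector(
        molecule_id=matrix.molecule_id,
        chain_id=matrix.chain_id,
        position=position,
        vector=matrix.vectors[position - 1],
    )


class MockEmbedder:
    """Deterministic context-sensitive embedding backend for tests and desk runs.

    Each (neighborhood offset in -2..2, residue) pair maps to a fixed unit
    vector derived from a cryptographic hash of (seed, offset, residue);
    the embedding of a position is the weight-decayed sum over its
    5-residue neighborhood, with '^'/'$' boundary markers past the termini.
    """

    _OFFSETS = (-2, -1, 0, 1, 2)
    _WEIGHTS = (0.5, 0.8, 1.0, 0.8, 0.5)

    def __init__(self, d: int = 64, seed: int = 0):
        if d < 1:
            raise ConfigError(f"embedding dimension must be >= 1, got {d}")
        self.dim = int(d)
        self.seed = int(seed)
        self.name = f"mock-d{self.dim}-s{self.seed}"
        self.max_length = 100_000
        self._table: dict[tuple[int, str], np.ndarray] = {}

    def _vec(self, offset: int, residue: str) -> np.ndarray:
        key = (offset, residue)
        v = self._table.get(key)
        if v is None:
            digest = hashlib.blake2b(
                f"{self.seed}|{offset}|{residue}".encode(), digest_size=16
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            v = rng.standard_normal(self.dim)
            v /= np.linalg.norm(v)
            self._table[key] = v
        return v

    def embed(self, sequence: str) -> np.ndarray:
        n = len(sequence)
        padded = "^^" + sequence + "$$"
        out = np.zeros((n, self.dim), dtype=np.float64)
        for i in range(n):
            acc = out[i]
            for off, w in zip(self._OFFSETS, self._WEIGHTS):
                acc += w * self._vec(off, padded[i + 2 + off])
        return out


class EsmEmbedder:
    """Real protein-language-model backend (optional; needs torch + fair-esm).

    Uses the final transformer layer's hidden states with boundary tokens
    stripped, giving an n x 1280 matrix for the default 650M model.
    """

    def __init__(self, model_name: str = "esm2_t33_650M_UR50D"):
        try:
            import esm  # type: ignore
            import torch  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the ESM backend requires the optional 'fair-esm' and 'torch' "
                "packages; use a mock embedder (e.g. 'mock-d64-s0') otherwise"
            ) from exc
        model, alphabet = esm.pretrained.load_model_and_alphabet(model_name)
        model.eval()
        self._model = model
        self._converter = alphabet.get_batch_converter()
        self._layer = model.num_layers
        self.dim = model.embed_dim
        self.name = model_name
        self.max_length = 1022

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - optional
        import torch

        _, _, tokens = self._converter([("chain", sequence)])
        with torch.no_grad():
            result = self._model(tokens, repr_layers=[self._layer])
        reps = result["representations"][self._layer][0, 1 : len(sequence) + 1]
        return reps.cpu().numpy().astype(np.float64)


_MOCK_RE = re.compile(r"^mock-d(\d+)-s(\d+)$")


def make_mock_embedder(d: int, seed: int) -> MockEmbedder:
    return MockEmbedder(d=d, seed=seed)


def get_embedder(name: str):
    """Resolve an embedder by name: ``mock-d<dim>-s<seed>`` or an ESM model name."""
    m = _MOCK_RE.match(name)
    if m:
        return MockEmbedder(d=int(m.group(1)), seed=int(m.group(2)))
    return EsmEmbedder(name)


class EmbeddingCache:
    """On-disk cache of embedding matrices keyed by (embedder name, sequence digest)."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, embedder_name: str, sequence: str) -> Path:
        digest = hashlib.sha256(sequence.encode()).hexdigest()[:32]
        safe = re.sub(r"[^A-Za-z0-9_.-]", "_", embedder_name)
        return self.directory / f"{safe}__{digest}.npy"

    def get(self, embedder_name: str, sequence: str) -> np.ndarray | None:
        p = self._path(embedder_name, sequence)
        return np.load(p) if p.exists() else None

    def put(self, embedder_name: str, sequence: str, vectors: np.ndarray) -> None:
        np.save(self._path(embedder_name, sequence), vectors)


def embed_chain(backend, chain: ChainSequence, cache: EmbeddingCache | None = None) -> EmbeddingMatrix:
    """Embed one chain: one d-vector per residue, aligned 1:1 with positions.

    Raises :class:`CapacityError` when the chain exceeds the backend's
    maximum context; there is no silent truncation.
    """
    if len(chain) > backend.max_length:
        raise CapacityError(
            f"chain {chain.molecule_id}|{chain.chain_id} has {len(chain)} residues, "
            f"exceeding backend {backend.name!r} capacity of {backend.max_length}"
        )
    vectors = cache.get(backend.name, chain.sequence) if cache else None
    if vectors is None:
        vectors = backend.embed(chain.sequence)
        if cache:
            cache.put(backend.name, chain.sequence, vectors)
    if vectors.shape[0] != len(chain):
        raise ValidationError(
            f"backend returned {vectors.shape[0]} rows for a {len(chain)}-residue chain"
        )
    return EmbeddingMatrix(
        molecule_id=chain.molecule_id,
        chain_id=chain.chain_id,
        vectors=vectors,
        embedder_name=backend.name,
    )
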