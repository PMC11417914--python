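"""Readers and writers for the package's external representations.

Formats handled here:

* FASTA chain sequences (headers ``moleculeID|chainID``; a missing ``|``
  falls back to chain id ``chain1``),
* site-specific deamidation time-course tables (CSV, one row per site,
  percent columns for t = 0, 1, 2, 4, 8 weeks),
* labeled datasets (time-course dialect plus label/target columns),
* prediction reports,
* run configuration (YAML or JSON, auto-detected by extension).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import ConfigError, ParseError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Legal residue alphabet: the 20 amino acids plus 'X' for unknown.
ALPHABET = frozenset(AMINO_ACIDS + "X")

#: Stress time points in weeks at which extents are measured.
TIME_POINTS = (0, 1, 2, 4, 8)

#: Time points used as regression targets.
TARGET_TIME_POINTS = (2, 4, 8)

_PCT_COLUMNS = {0: "pct_t0", 1: "pct_1wk", 2: "pct_2wk", 4: "pct_4wk", 8: "pct_8wk"}

TIMECOURSE_COLUMNS = [
    "molecule_id",
    "chain_id",
    "position",
    "residue",
    *_PCT_COLUMNS.values(),
    "covered",
]

PREDICTION_COLUMNS = [
    "molecule",
    "chain",
    "position",
    "residue",
    "probability",
    "predicted_label",
    "pred_extent_2wk",
    "pred_extent_4wk",
    "pred_extent_8wk",
]


@dataclass(frozen=True)
class ChainSequence:
    """One antibody chain: identifier pair plus validated residue string."""

    molecule_id: str
    chain_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(
                f"empty sequence for {self.molecule_id}|{self.chain_id}"
            )
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in ALPHABET:
                raise ValidationError(
                    f"illegal residue {ch!r} at position {i} in "
                    f"{self.molecule_id}|{self.chain_id}"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.molecule_id, self.chain_id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SiteTimeCourse:
    """Measured %-deamidation of one N/Q site across the stress time course.

    ``extents`` maps week -> percent; absent keys are unmeasured points.
    ``covered`` is False when the peptide map had no coverage for the site.
    """

    molecule_id: str
    chain_id: str
    position: int  # 1-based within the chain
    residue: str
    extents: dict[int, float] = field(default_factory=dict)
    covered: bool = True

    def __post_init__(self) -> None:
        if self.residue not in ("N", "Q"):
            raise ValidationError(
                f"site residue must be N or Q, got {self.residue!r} at "
                f"{self.molecule_id}|{self.chain_id}:{self.position}"
            )
        if self.position < 1:
            raise ValidationError(f"position must be 1-based, got {self.position}")
        for t, v in self.extents.items():
            if t not in TIME_POINTS:
                raise ValidationError(f"unknown time point {t} weeks")
            if not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"extent {v} out of [0, 100] at "
                    f"{self.molecule_id}|{self.chain_id}:{self.position}, t={t}wk"
                )

    @property
    def site_key(self) -> tuple[str, str, int]:
        return (self.molecule_id, self.chain_id, self.position)


@dataclass
class SitePrediction:
    """Model output for one candidate site."""

    molecule_id: str
    chain_id: str
    position: int
    residue: str
    probability: float
    predicted_label: str  # "active" | "inactive"
    predicted_extents: tuple[float, float, float] | None = None  # t = 2, 4, 8 wk

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(f"probability {self.probability} out of [0, 1]")
        if self.predicted_label not in ("active", "inactive"):
            raise ValidationError(f"bad label {self.predicted_label!r}")
        if self.predicted_extents is not None:
            for v in self.predicted_extents:
                if not (0.0 <= v <= 100.0):
                    raise ValidationError(f"predicted extent {v} out of [0, 100]")


@dataclass
class RunConfig:
    """Everything a run needs to be reproducible.

    Training hyperparameters default to the values used throughout the
    package; they are all overridable and travel with model checkpoints.
    """

    window_size: int = 31
    embedder_name: str = "mock-d64-s0"
    label_threshold: float = 1.0  # percent increment that makes a site a hot spot
    decision_threshold: float = 0.5
    seed: int = 0
    # head
    hidden_widths: tuple[int, ...] = (256, 64)
    dropout: float = 0.3
    # local encoder
    token_dim: int = 16
    lstm_hidden: int = 64
    # optimization
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.1
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ConfigError(f"window_size must be odd and >= 3, got {self.window_size}")
        if not (0.0 <= self.decision_threshold <= 1.0):
            raise ConfigError("decision_threshold must be in [0, 1]")
        if self.label_threshold < 0:
            raise ConfigError("label_threshold must be >= 0")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must be in [0, 1)")
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigError("val_fraction must be in (0, 1)")
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_widths"] = list(self.hidden_widths)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items()})


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta_header(header: str) -> tuple[str, str]:
    """Split a ``moleculeID|chainID`` header; default chain id is ``chain1``."""
    header = header.strip()
    if "|" in header:
        molecule, chain = header.split("|", 1)
        molecule, chain = molecule.strip(), chain.strip()
    else:
        molecule, chain = header, "chain1"
    if not molecule:
        raise ParseError(f"empty molecule id in FASTA header {header!r}")
    return molecule, chain


def read_fasta(path: str | Path) -> list[ChainSequence]:
    """Parse a FASTA file of antibody chains.

    Sequences are upper-cased and trailing ``*`` stop symbols stripped.
    Raises :class:`ParseError` on malformed records and
    :class:`ValidationError` on illegal residues (naming residue and
    position).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                break
    chains: list[ChainSequence] = []
    seen: set[tuple[str, str]] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        molecule, chain = parse_fasta_header(record.description or record.id)
        seq = str(record.seq).upper().rstrip("*")
        try:
            cs = ChainSequence(molecule, chain, seq)
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {record.id!r}: {exc}") from exc
        if cs.key in seen:
            raise ParseError(f"{path}: duplicate chain {molecule}|{chain}")
        seen.add(cs.key)
        chains.append(cs)
    return chains


def write_fasta(chains: Iterable[ChainSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(f">{c.molecule_id}|{c.chain_id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Time-course tables
# ---------------------------------------------------------------------------

def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, float)) and not isinstance(v, bool):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ParseError(f"cannot interpret {v!r} as a boolean")


def read_timecourse_table(path: str | Path) -> list[SiteTimeCourse]:
    """Read a site time-course CSV (see :data:`TIMECOURSE_COLUMNS`).

    Blank percent cells become absent extents; uncovered rows carry no
    extents regardless of cell contents.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    sites: list[SiteTimeCourse] = []
    for idx, row in df.iterrows():
        extents: dict[int, float] = {}
        covered = _parse_bool(row["covered"])
        if covered:
            for t, col in _PCT_COLUMNS.items():
                v = row[col]
                if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
                    continue
                extents[t] = float(v)
        try:
            sites.append(
                SiteTimeCourse(
                    molecule_id=str(row["molecule_id"]),
                    chain_id=str(row["chain_id"]),
                    position=int(row["position"]),
                    residue=str(row["residue"]).strip().upper(),
                    extents=extents,
                    covered=covered,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return sites


def write_timecourse_table(sites: Iterable[SiteTimeCourse], path: str | Path) -> None:
    rows = []
    for s in sites:
        row: dict = {
            "molecule_id": s.molecule_id,
            "chain_id": s.chain_id,
            "position": s.position,
            "residue": s.residue,
            "covered": s.covered,
        }
        for t, col in _PCT_COLUMNS.items():
            row[col] = round(s.extents[t], 4) if t in s.extents else None
        rows.append(row)
    df = pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def write_predictions(predictions: Sequence[SitePrediction], path: str | Path) -> None:
    """Serialize predictions as CSV; the header is always written."""
    rows = []
    for p in predictions:
        ext = p.predicted_extents
        rows.append(
            {
                "molecule": p.molecule_id,
                "chain": p.chain_id,
                "position": p.position,
                "residue": p.residue,
                "probability": round(p.probability, 4),
                "predicted_label": p.predicted_label,
                "pred_extent_2wk": round(ext[0], 4) if ext else None,
                "pred_extent_4wk": round(ext[1], 4) if ext else None,
                "pred_extent_8wk": round(ext[2], 4) if ext else None,
            }
        )
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[SitePrediction]:
    df = pd.read_csv(path)
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    out = []
    for _, row in df.iterrows():
        ext_vals = [row[f"pred_extent_{t}wk"] for t in TARGET_TIME_POINTS]
        has_ext = not any(v is None or (isinstance(v, float) and math.isnan(v)) for v in ext_vals)
        out.append(
            SitePrediction(
                molecule_id=str(row["molecule"]),
                chain_id=str(row["chain"]),
                position=int(row["position"]),
                residue=str(row["residue"]),
                probability=float(row["probability"]),
                predicted_label=str(row["predicted_label"]),
                predicted_extents=tuple(float(v) for v in ext_vals) if has_ext else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML (.yml/.yaml) or JSON (.json)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        data = yaml.safe_load(text)
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise ConfigError(f"unrecognized config extension {path.suffix!r}")
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if "hidden_widths" in data:
        data["hidden_widths"] = tuple(data["hidden_widths"])
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        raise ConfigError(f"unrecognized config extension {path.suffix!r}")
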