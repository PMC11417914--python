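"""Fixed-width token windows around candidate sites.

The window of odd width ``w`` carries (w-1)/2 residues on each side of the
center N/Q; positions past either chain terminus are PAD tokens. Windows
never cross chain boundaries. Encoding to fixed-length vectors is done by
the learned local encoder in :mod:`deamipred.nn` (token embedding followed
by a bidirectional LSTM whose final states are concatenated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import AMINO_ACIDS, ChainSequence

PAD_TOKEN = "-"

MIN_WINDOW = 3
MAX_WINDOW = 61


class TokenVocabulary:
    """Dense token<->id bijection over {PAD, 20 amino acids, X}; PAD id is 0."""

    def __init__(self) -> None:
        letters = [PAD_TOKEN] + list(AMINO_ACIDS) + ["X"]
        self._to_id = {ch: i for i, ch in enumerate(letters)}
        self._to_token = letters

    def __len__(self) -> int:
        return len(self._to_token)

    @property
    def pad_id(self) -> int:
        return 0

    def encode(self, token: str) -> int:
        try:
            return self._to_id[token]
        except KeyError:
            raise ValidationError(f"unknown token {token!r}") from None

    def decode(self, token_id: int) -> str:
        if not (0 <= token_id < len(self._to_token)):
            raise ValidationError(f"unknown token id {token_id}")
        return self._to_token[token_id]


VOCAB = TokenVocabulary()


@dataclass
class LocalWindow:
    """w token ids centered on an N/Q site, PAD-filled past the termini."""

    tokens: tuple[int, ...]
    molecule_id: str
    chain_id: str
    position: int  # 1-based center position in the chain

    @property
    def width(self) -> int:
        return len(self.tokens)

    @property
    def center_index(self) -> int:
        return (len(self.tokens) - 1) // 2

    def decode(self, vocab: TokenVocabulary = VOCAB) -> str:
        """Window as text, PADs included (use .strip(PAD) for the subsequence)."""
        return "".join(vocab.decode(t) for t in self.tokens)


def _check_window_size(w: int) -> None:
    if w % 2 == 0 or not (MIN_WINDOW <= w <= MAX_WINDOW):
        raise ValidationError(f"window size must be odd and in [{MIN_WINDOW}, {MAX_WINDOW}], got {w}")


def extract_window(
    chain: ChainSequence, position: int, w: int, vocab: TokenVocabulary = VOCAB
) -> LocalWindow:
    """Tokenized window of width ``w`` centered on ``position`` (1-based)."""
    _check_window_size(w)
    if not (1 <= position <= len(chain)):
        raise ValidationError(f"position {position} outside chain of length {len(chain)}")
    center = chain.sequence[position - 1]
    if center not in ("N", "Q"):
        raise ValidationError(
            f"window center must be N or Q, got {center!r} at "
            f"{chain.molecule_id}|{chain.chain_id}:{position}"
        )
    half = (w - 1) // 2
    i = position - 1
    tokens = []
    for j in range(i - half, i + half + 1):
        if 0 <= j < len(chain):
            tokens.append(vocab.encode(chain.sequence[j]))
        else:
            tokens.append(vocab.pad_id)
    return LocalWindow(
        tokens=tuple(tokens),
        molecule_id=chain.molecule_id,
        chain_id=chain.chain_id,
        position=position,
    )


def windows_to_array(windows: Sequence[LocalWindow]) -> np.ndarray:
    """Stack windows into an (n, w) int array; widths must agree."""
    if not windows:
        return np.zeros((0, 0), dtype=np.int64)
    w = windows[0].width
    for win in windows:
        if win.width != w:
            raise ValidationError(f"mixed window widths {win.width} vs {w}")
    return np.array([win.tokens for win in windows], dtype=np.int64)


def encode_local(windows: Sequence[LocalWindow], encoder) -> np.ndarray:
    """Encode windows to fixed-length vectors with a trained local encoder.

    ``encoder`` is a :class:`deamipred.nn.LocalEncoder`; output shape is
    (n, 2 * hidden width). Deterministic at inference.
    """
    tokens = windows_to_array(windows)
    if tokens.size and tokens.shape[1] != encoder.window_size:
        raise ValidationError(
            f"window width {tokens.shape[1]} does not match encoder width {encoder.window_size}"
        )
    out, _ = encoder.forward(tokens)
    return out
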