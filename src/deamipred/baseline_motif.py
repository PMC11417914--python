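"""The canonical NG/NS/NN motif comparator and the motif-probing routine.

``motif_classify`` is the empirical baseline that simply flags an N
followed by G, S or N as a hot spot. ``probe_motifs`` interrogates a
trained local_only classifier by scoring synthetic windows that isolate a
single neighbor slot (all other positions PAD), ranking the 20 amino
acids by the probability they induce at the X+1 or X-1 position next to
a center N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chimeric_model import TrainedModel
from .errors import ValidationError
from .io_formats import AMINO_ACIDS, ChainSequence
from .local_sequence import VOCAB

DEFAULT_MOTIFS = frozenset({"NG", "NS", "NN"})

DIRECTIONS = ("X+1", "X-1")


@dataclass(frozen=True)
class MotifRule:
    """Set of flagged successor dipeptides; each must start with N."""

    motifs: frozenset[str] = DEFAULT_MOTIFS

    def __post_init__(self) -> None:
        for m in self.motifs:
            if len(m) != 2 or m[0] != "N":
                raise ValidationError(f"motif {m!r} must be a dipeptide starting with N")


def motif_classify(chain: ChainSequence, position: int, rule: MotifRule = MotifRule()) -> str:
    """``active`` iff the site is an N whose dipeptide (N, successor) is flagged.

    Q sites and a chain-terminal N (no successor) are always inactive.
    """
    if not (1 <= position <= len(chain)):
        raise ValidationError(f"position {position} outside chain of length {len(chain)}")
    residue = chain.sequence[position - 1]
    if residue not in ("N", "Q"):
        raise ValidationError(f"motif baseline applies to N/Q sites, got {residue!r}")
    if residue != "N" or position == len(chain):
        return "inactive"
    dipeptide = residue + chain.sequence[position]
    return "active" if dipeptide in rule.motifs else "inactive"


@dataclass
class MotifScoreTable:
    """20 probe scores for one direction, sorted descending by score."""

    direction: str
    table: pd.DataFrame = field(repr=False)

    def top(self, n: int = 3) -> list[str]:
        return list(self.table.head(n)["motif"])


def probe_motifs(local_model: TrainedModel, direction: str) -> MotifScoreTable:
    """Score each amino acid at the probed slot beside a center N.

    Probe windows are all-PAD except the center (N) and the probed slot,
    isolating that slot's marginal effect on the model probability.
    """
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if local_model.variant != "local_only" or local_model.task != "classification":
        raise ValidationError("probe_motifs requires a trained local_only classifier")
    w = local_model.config.window_size
    if w < 3:
        raise ValidationError("probing needs a window size of at least 3")
    center = (w - 1) // 2
    slot = center + 1 if direction == "X+1" else center - 1
    windows = np.full((len(AMINO_ACIDS), w), VOCAB.pad_id, dtype=np.int64)
    windows[:, center] = VOCAB.encode("N")
    for row, aa in enumerate(AMINO_ACIDS):
        windows[row, slot] = VOCAB.encode(aa)
    scores = local_model.score_windows(windows)
    motifs = [("N" + aa) if direction == "X+1" else (aa + "N") for aa in AMINO_ACIDS]
    df = pd.DataFrame({"motif": motifs, "direction": direction, "score": scores})
    df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    return MotifScoreTable(direction=direction, table=df)
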