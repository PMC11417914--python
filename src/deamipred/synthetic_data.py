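"""Generator for antibody-like chains and deamidation time courses.

The proprietary measured dataset behind the method is not public, so this
module fabricates one with the same statistical structure: ~12% active
sites, successor-motif-dominated first-order kinetics (NG >> NS ~ NN >
other N dipeptides > Q sites), predecessor multipliers boosting S/E/W,
a smooth seeded context effect over the +/-5 neighborhood, Gaussian
measurement noise, LOQ censoring at 0.1% and occasional loss of peptide
coverage.

Noiseless kinetics are saturating first-order: D(t) = Dmax * (1 - e^(-kt)).
A site's ground-truth label is ``active`` exactly when its first-week
noiseless increment Dmax * (1 - e^(-k)) exceeds the labeling threshold,
i.e. when k > -ln(1 - threshold / Dmax), so the labeling rule applied to
noiseless data reproduces ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ValidationError
from .io_formats import AMINO_ACIDS, ChainSequence, SiteTimeCourse, TIME_POINTS

# Rough IgG-like residue composition (relative weights).
ANTIBODY_COMPOSITION = {
    "A": 7.2, "C": 2.2, "D": 5.2, "E": 5.8, "F": 3.8, "G": 7.2, "H": 2.0,
    "I": 3.2, "K": 6.6, "L": 7.6, "M": 1.2, "N": 4.4, "P": 6.8, "Q": 4.6,
    "R": 4.2, "S": 11.6, "T": 8.6, "V": 9.2, "W": 1.6, "Y": 4.4,
}

#: Neighborhood offsets contributing to the planted context effect
#: (the immediate +/-1 neighbors act through explicit rate factors instead).
CONTEXT_OFFSETS = (-5, -4, -3, -2, 2, 3, 4, 5)

DEFAULT_BASE_RATES = {  # per-week rate constants by successor dipeptide
    "NG": 0.60,
    "NS": 0.040,
    "NN": 0.032,
    "NT": 0.010,
    "ND": 0.009,
    "NH": 0.007,
}
DEFAULT_OTHER_N_RATE = 0.0028
DEFAULT_Q_RATE = 0.0010
DEFAULT_X1_MULTIPLIERS = {"S": 2.2, "E": 2.0, "W": 1.8, "G": 1.3}


@dataclass
class SyntheticSpec:
    """Calibration constants for one synthetic dataset."""

    n_molecules: int = 45
    hc_length: tuple[int, int] = (180, 250)
    lc_length: tuple[int, int] = (110, 160)
    target_active_fraction: float = 0.12
    fraction_tolerance: float = 0.05
    base_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    other_n_rate: float = DEFAULT_OTHER_N_RATE
    q_rate: float = DEFAULT_Q_RATE
    x1_multipliers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_X1_MULTIPLIERS))
    context_sd: float = 1.0
    noise_sd: float = 0.4  # percent
    loq: float = 0.1  # percent; measured values below this report as 0
    dmax: float = 50.0  # percent plateau of the kinetic curve
    label_threshold: float = 1.0  # percent increment defining a hot spot
    missingness: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.base_rates.values()) or self.other_n_rate < 0 or self.q_rate < 0:
            raise ValidationError("rate constants must be >= 0")
        if not (0.0 <= self.target_active_fraction <= 1.0):
            raise ValidationError("target_active_fraction must be in [0, 1]")
        if self.loq < 0:
            raise ValidationError("LOQ must be >= 0")
        if not (0.0 < self.dmax <= 100.0):
            raise ValidationError("dmax must be in (0, 100]")
        if not (0.0 <= self.missingness < 1.0):
            raise ValidationError("missingness must be in [0, 1)")

    @property
    def rate_threshold(self) -> float:
        """Rate above which the noiseless first-week increment exceeds the threshold."""
        return -math.log(1.0 - self.label_threshold / self.dmax)


def kinetic_extent(k: float, t: float, dmax: float) -> float:
    """Saturating first-order extent Dmax * (1 - e^(-k t)), in percent."""
    if k < 0 or t < 0:
        raise ValidationError("k and t must be >= 0")
    if not (0.0 < dmax <= 100.0):
        raise ValidationError("dmax must be in (0, 100]")
    return dmax * (1.0 - math.exp(-k * t))


def _context_coefficients(spec: SyntheticSpec) -> np.ndarray:
    """Planted smooth context rule: coef[offset_index, residue_index].

    Scaled so the summed effect has standard deviation ~= context_sd.
    """
    rng = np.random.default_rng([spec.seed, 0xC0])
    scale = spec.context_sd / math.sqrt(len(CONTEXT_OFFSETS))
    coef = rng.normal(0.0, scale, size=(len(CONTEXT_OFFSETS), len(AMINO_ACIDS)))
    # center against the residue composition so the expected effect is ~0
    # regardless of the coefficient draw (keeps the active fraction stable
    # across seeds)
    w = np.array([ANTIBODY_COMPOSITION[aa] for aa in AMINO_ACIDS])
    coef -= (coef * (w / w.sum())).sum(axis=1, keepdims=True)
    return coef


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def site_rate(sequence: str, position: int, spec: SyntheticSpec, coef: np.ndarray) -> float:
    """Deterministic per-week rate constant for the N/Q site at 1-based position."""
    i = position - 1
    residue = sequence[i]
    if residue == "Q":
        base = spec.q_rate
    else:
        successor = sequence[i + 1] if i + 1 < len(sequence) else None
        base = spec.base_rates.get("N" + successor, spec.other_n_rate) if successor else spec.other_n_rate
    mult = spec.x1_multipliers.get(sequence[i - 1], 1.0) if i > 0 else 1.0
    effect = 0.0
    for oi, off in enumerate(CONTEXT_OFFSETS):
        j = i + off
        if 0 <= j < len(sequence):
            effect += coef[oi, _AA_INDEX[sequence[j]]]
    return base * mult * math.exp(effect)


def generate(
    spec: SyntheticSpec,
) -> tuple[list[ChainSequence], list[SiteTimeCourse], pd.DataFrame]:
    """Produce (chains, measured time courses, ground truth).

    Ground truth is a DataFrame with one row per N/Q site: the true rate
    constant ``k``, the ``true_label``, coverage, and noiseless extents
    ``d_t0`` ... ``d_8wk``. Fully deterministic for a fixed spec.
    """
    rng = np.random.default_rng([spec.seed, 0xDA])
    coef = _context_coefficients(spec)
    letters = np.array(list(ANTIBODY_COMPOSITION))
    weights = np.array(list(ANTIBODY_COMPOSITION.values()))
    weights = weights / weights.sum()

    chains: list[ChainSequence] = []
    sites: list[SiteTimeCourse] = []
    truth_rows: list[dict] = []
    k_thr = spec.rate_threshold

    for mi in range(spec.n_molecules):
        molecule = f"syn{mi + 1:03d}"
        for chain_id, (lo, hi) in (("HC", spec.hc_length), ("LC", spec.lc_length)):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(letters, size=length, p=weights))
            chain = ChainSequence(molecule, chain_id, seq)
            chains.append(chain)
            for pos in range(1, length + 1):
                residue = seq[pos - 1]
                if residue not in ("N", "Q"):
                    continue
                k = site_rate(seq, pos, spec, coef)
                noiseless = {t: kinetic_extent(k, t, spec.dmax) for t in TIME_POINTS}
                covered = bool(rng.random() >= spec.missingness)
                extents: dict[int, float] = {}
                if covered:
                    for t in TIME_POINTS:
                        v = noiseless[t] + rng.normal(0.0, spec.noise_sd)
                        v = float(np.clip(v, 0.0, 100.0))
                        extents[t] = 0.0 if v < spec.loq else v
                sites.append(
                    SiteTimeCourse(
                        molecule_id=molecule,
                        chain_id=chain_id,
                        position=pos,
                        residue=residue,
                        extents=extents,
                        covered=covered,
                    )
                )
                truth_rows.append(
                    {
                        "molecule_id": molecule,
                        "chain_id": chain_id,
                        "position": pos,
                        "residue": residue,
                        "k": k,
                        "true_label": "active" if k > k_thr else "inactive",
                        "covered": covered,
                        **{f"d_{'t0' if t == 0 else str(t) + 'wk'}": noiseless[t] for t in TIME_POINTS},
                    }
                )

    truth = pd.DataFrame(truth_rows)
    realized = float((truth["true_label"] == "active").mean()) if len(truth) else 0.0
    if abs(realized - spec.target_active_fraction) > spec.fraction_tolerance:
        raise GenerationError(
            f"realized active fraction {realized:.3f} misses target "
            f"{spec.target_active_fraction:.3f} by more than "
            f"{spec.fraction_tolerance:.3f}; adjust base rates / context_sd "
            f"({len(truth)} sites generated)"
        )
    return chains, sites, truth
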