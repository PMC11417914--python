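"""Turn measured time courses into hot-spot labels and regression targets.

A site is a hot spot when the measured deamidation extent climbs by more
than ``threshold`` percent (strictly) over either of the first two
intervals of the stress study: t0 -> 1 week, or 1 week -> 2 weeks.
Uncovered sites and sites with no measurable extents are inactive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError
from .io_formats import ChainSequence, SiteTimeCourse, TARGET_TIME_POINTS

ACTIVE = "active"
INACTIVE = "inactive"


@dataclass
class LabeledSite:
    """A site joined with its binary label and 2/4/8-week regression targets."""

    site: SiteTimeCourse
    label: str
    regression_targets: dict[int, float]

    @property
    def is_active(self) -> bool:
        return self.label == ACTIVE


@dataclass(frozen=True)
class DatasetSummary:
    n_total: int
    n_active: int
    n_inactive: int
    active_fraction: float


def label_site(site: SiteTimeCourse, threshold: float = 1.0) -> LabeledSite:
    """Apply the increment rule to one site.

    Absent extents are treated as 0 when differencing. The inequality is
    strict: an increment exactly equal to ``threshold`` does not fire.
    """
    if not site.covered or not site.extents:
        return LabeledSite(site=site, label=INACTIVE, regression_targets={})
    e = {t: site.extents.get(t, 0.0) for t in (0, 1, 2)}
    active = (e[1] - e[0] > threshold) or (e[2] - e[1] > threshold)
    targets = {t: site.extents[t] for t in TARGET_TIME_POINTS if t in site.extents}
    return LabeledSite(site=site, label=ACTIVE if active else INACTIVE, regression_targets=targets)


def label_sites(sites: Iterable[SiteTimeCourse], threshold: float = 1.0) -> list[LabeledSite]:
    return [label_site(s, threshold) for s in sites]


def enumerate_candidate_sites(chain: ChainSequence) -> list[tuple[int, str]]:
    """All 1-based (position, residue) pairs whose residue is N or Q."""
    return [(i, ch) for i, ch in enumerate(chain.sequence, start=1) if ch in ("N", "Q")]


def summarize_dataset(labeled: Sequence[LabeledSite]) -> DatasetSummary:
    n_total = len(labeled)
    n_active = sum(1 for s in labeled if s.is_active)
    n_inactive = n_total - n_active
    fraction = n_active / n_total if n_total else 0.0
    return DatasetSummary(n_total, n_active, n_inactive, fraction)


# ---------------------------------------------------------------------------
# Labeled-dataset CSV (time-course dialect + label/target columns)
# ---------------------------------------------------------------------------

LABELED_COLUMNS = [
    "molecule_id",
    "chain_id",
    "position",
    "residue",
    "covered",
    "label",
    "target_2wk",
    "target_4wk",
    "target_8wk",
]


def write_labeled_dataset(labeled: Sequence[LabeledSite], path) -> None:
    rows = []
    for ls in labeled:
        s = ls.site
        rows.append(
            {
                "molecule_id": s.molecule_id,
                "chain_id": s.chain_id,
                "position": s.position,
                "residue": s.residue,
                "covered": s.covered,
                "label": ls.label,
                **{
                    f"target_{t}wk": round(ls.regression_targets[t], 4)
                    if t in ls.regression_targets
                    else None
                    for t in TARGET_TIME_POINTS
                },
            }
        )
    pd.DataFrame(rows, columns=LABELED_COLUMNS).to_csv(path, index=False)


def read_labeled_dataset(path) -> list[LabeledSite]:
    df = pd.read_csv(path)
    missing = [c for c in LABELED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    out = []
    for _, row in df.iterrows():
        targets = {}
        for t in TARGET_TIME_POINTS:
            v = row[f"target_{t}wk"]
            if pd.notna(v):
                targets[t] = float(v)
        site = SiteTimeCourse(
            molecule_id=str(row["molecule_id"]),
            chain_id=str(row["chain_id"]),
            position=int(row["position"]),
            residue=str(row["residue"]),
            extents={},
            covered=bool(row["covered"]),
        )
        out.append(LabeledSite(site=site, label=str(row["label"]), regression_targets=targets))
    return out
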