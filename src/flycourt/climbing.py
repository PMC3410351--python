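"""Negative-geotaxis (climbing) assay scoring.

Flies are tapped to the bottom of a vial and left for 18 s; a fly passes
if it climbs at least 1 cm.  The standard design uses 5 vials of 10 flies
per genotype.  Scores are pooled pass fractions; with equal vial sizes the
pooled fraction coincides with the per-vial average, and partitioning the
same flies into different vials never changes the score.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Sequence

__all__ = [
    "ClimbingTrial",
    "climbing_score",
    "climbing_reduction_pct",
    "read_climbing",
    "write_climbing",
]

CLIMBING_COLUMNS = ("vial_id", "genotype", "age_days", "n_flies", "n_passed")


@dataclass(frozen=True)
class ClimbingTrial:
    """One vial: how many of its flies climbed >= 1 cm within 18 s."""

    vial_id: str
    genotype: str
    n_flies: int
    n_passed: int
    age_days: int | None = None

    def __post_init__(self) -> None:
        if self.n_flies <= 0:
            raise ValueError(f"vial {self.vial_id!r}: n_flies must be positive")
        if not 0 <= self.n_passed <= self.n_flies:
            raise ValueError(
                f"vial {self.vial_id!r}: n_passed {self.n_passed} outside "
                f"[0, {self.n_flies}]"
            )


def climbing_score(
    trials: Sequence[ClimbingTrial],
    genotype: str,
    age_days: int | None = None,
) -> float:
    """Pooled pass fraction for one genotype (optionally one age group)."""
    group = [
        t
        for t in trials
        if t.genotype == genotype and (age_days is None or t.age_days == age_days)
    ]
    if not group:
        raise ValueError(f"no climbing trials for genotype {genotype!r}")
    return sum(t.n_passed for t in group) / sum(t.n_flies for t in group)


def climbing_reduction_pct(score_pd: float, score_ctrl: float) -> float:
    """Percent reduction in climbing ability relative to control.

    Control is set as displaying 100% climbing ability; a disease-group
    score of 0.648 against a control score of 0.9 is a 28% reduction.
    """
    if score_ctrl <= 0:
        raise ValueError(f"control score must be positive, got {score_ctrl}")
    return 100.0 * (1.0 - score_pd / score_ctrl)


def write_climbing(
    trials: Iterable[ClimbingTrial], path: str | PathLike
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CLIMBING_COLUMNS)
        for t in trials:
            writer.writerow(
                [t.vial_id, t.genotype,
                 "" if t.age_days is None else t.age_days,
                 t.n_flies, t.n_passed]
            )


def read_climbing(path: str | PathLike) -> list[ClimbingTrial]:
    trials: list[ClimbingTrial] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != CLIMBING_COLUMNS:
            raise ValueError(
                f"{path}: bad header {header!r}, expected "
                f"{','.join(CLIMBING_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            vial_id, genotype, age_days, n_flies, n_passed = (
                c.strip() for c in row
            )
            try:
                trials.append(
                    ClimbingTrial(
                        vial_id=vial_id,
                        genotype=genotype,
                        age_days=int(age_days) if age_days else None,
                        n_flies=int(n_flies),
                        n_passed=int(n_passed),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return trials
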