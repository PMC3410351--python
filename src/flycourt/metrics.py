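"""Per-couple courtship parameters, normalizations, and group comparisons.

Each couple yields a :class:`ParameterVector` of eight features: summed
orientation and wing-vibration bout time, licking / attempted-copulation /
non-sexual-encounter (NSE) counts, whether copulation occurred, the total
observed time, and the sexual focus index

    SFI = 1 / (NSE + 1),

a dimensionless measure in (0, 1] that is high when the male's encounters
with the female usually lead to courtship.  The Boolean ``healthy`` label
(wild-type control vs. alpha-synuclein A30P) is the dependent variable for
rule-based diagnosis.

Group-level analysis normalizes time-based traits to percent of session
time and count-based traits to count x 100 / total time (NSE deliberately
stays un-normalized: it occurs mostly before any sexual activity starts),
then expresses each trait of the Parkinson's-model group relative to the
control group and sums the six traits into a composite courtship score
with control fixed at 100%.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from os import PathLike
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ethogram import CourtshipSession, Element

__all__ = [
    "FEATURES",
    "COUNT_FEATURES",
    "BOOLEAN_FEATURES",
    "ParameterVector",
    "GroupSummary",
    "parameter_vector",
    "feature_value",
    "time_fraction_pct",
    "count_rate_norm",
    "relative_activity_pct",
    "copulation_reduction_pct",
    "group_summary",
    "relative_activities",
    "composite_score",
    "vectors_to_dataframe",
    "vectors_from_dataframe",
    "write_vectors",
    "read_vectors",
]

#: The eight per-fly features available to the rule-based classifier,
#: in canonical order.
FEATURES: tuple[str, ...] = (
    "orientation_time_s",
    "vibration_time_s",
    "licking_count",
    "atc_count",
    "copulated",
    "nse_count",
    "total_time_s",
    "sfi",
)

COUNT_FEATURES: frozenset[str] = frozenset(
    {"licking_count", "atc_count", "nse_count"}
)
BOOLEAN_FEATURES: frozenset[str] = frozenset({"copulated"})


@dataclass
class ParameterVector:
    """The per-couple feature vector plus its Boolean health label.

    ``sfi`` is computed from ``nse_count`` on construction; passing an
    inconsistent value raises.
    """

    couple_id: str
    healthy: bool
    orientation_time_s: float
    vibration_time_s: float
    licking_count: int
    atc_count: int
    copulated: bool
    nse_count: int
    total_time_s: float
    sfi: float | None = None
    genotype: str | None = None

    def __post_init__(self) -> None:
        for name in ("licking_count", "atc_count", "nse_count"):
            value = getattr(self, name)
            if value != int(value) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value}")
            setattr(self, name, int(value))
        expected_sfi = 1.0 / (self.nse_count + 1)
        if self.sfi is None:
            self.sfi = expected_sfi
        elif not math.isclose(self.sfi, expected_sfi, rel_tol=1e-9):
            raise ValueError(
                f"sfi {self.sfi} inconsistent with nse_count {self.nse_count} "
                f"(expected {expected_sfi})"
            )
        if self.orientation_time_s > self.total_time_s + 1e-6:
            raise ValueError("orientation time exceeds total time")
        if self.vibration_time_s > self.total_time_s + 1e-6:
            raise ValueError("vibration time exceeds total time")
        if self.genotype is None:
            self.genotype = "control" if self.healthy else "a30p"


def parameter_vector(
    session: CourtshipSession, healthy: bool | None = None
) -> ParameterVector:
    """Extract the per-couple parameter vector from a validated session.

    ``healthy`` defaults to ``genotype == "control"``.
    """
    if healthy is None:
        healthy = session.genotype == "control"
    orientation = sum(ev.duration_s for ev in session.events_of(Element.ORIENTATION))
    vibration = sum(ev.duration_s for ev in session.events_of(Element.VIBRATION))
    return ParameterVector(
        couple_id=session.couple_id,
        healthy=healthy,
        genotype=session.genotype,
        orientation_time_s=orientation,
        vibration_time_s=vibration,
        licking_count=len(session.events_of(Element.LICKING)),
        atc_count=len(session.events_of(Element.ATTEMPTED_COPULATION)),
        copulated=session.copulated,
        nse_count=len(session.events_of(Element.NSE)),
        total_time_s=session.total_time_s,
    )


def feature_value(vector: ParameterVector, feature: str) -> float:
    """Numeric value of one of the eight features (Booleans as 0/1)."""
    if feature not in FEATURES:
        raise ValueError(
            f"unknown feature {feature!r}; expected one of {FEATURES}"
        )
    return float(getattr(vector, feature))


def time_fraction_pct(time_s: float, total_s: float) -> float:
    """Percent of session time spent in a behavior: 100 * time / total."""
    if total_s <= 0:
        raise ValueError(f"total time must be positive, got {total_s}")
    if not 0 <= time_s <= total_s + 1e-6:
        raise ValueError(f"time {time_s} outside [0, {total_s}]")
    return 100.0 * time_s / total_s

def count_rate_norm(count: float, total_s: float) -> float:
    """Count normalized per session length: count * 100 / total time."""
    if total_s <= 0:
        raise ValueError(f"total time must be positive, got {total_s}")
    return count * 100.0 / total_s


def relative_activity_pct(mean_pd: float, mean_ctrl: float) -> float:
    """A trait mean of the disease group as percent of the control mean.

    Returned unrounded; reports conventionally print the nearest whole
    percent.  Scale-invariant: (k*a, k*b) equals (a, b) for k > 0.
    """
    if mean_ctrl <= 0:
        raise ValueError(f"control mean must be positive, got {mean_ctrl}")
    return 100.0 * mean_pd / mean_ctrl


def copulation_reduction_pct(n_pd: int, n_ctrl: int) -> float:
    """Percent fewer copulations in the disease group, to one decimal."""
    if n_ctrl <= 0:
        raise ValueError(f"control copulation count must be positive, got {n_ctrl}")
    return round(100.0 * (1.0 - n_pd / n_ctrl), 1)


@dataclass
class GroupSummary:
    """Per-genotype means of the normalized traits.

    Copulation is binary per couple, so ``copulation_total`` is the summed
    number of copulating couples in the group, not a mean.
    """

    genotype: str
    n: int
    mean_orientation_pct: float
    mean_vibration_pct: float
    mean_licking_norm: float
    mean_atc_norm: float
    copulation_total: int
    mean_nse: float
    mean_sfi: float

    def __post_init__(self) -> None:
        for pct in (self.mean_orientation_pct, self.mean_vibration_pct):
            if not 0 <= pct <= 100 + 1e-9:
                raise ValueError(f"percentage {pct} outside [0, 100]")

    def to_dict(self) -> dict:
        return asdict(self)


def group_summary(
    vectors: Sequence[ParameterVector], genotype: str
) -> GroupSummary:
    """Summarize one genotype group from per-couple parameter vectors.

    Normalization happens per couple (each couple's own total time) before
    averaging, which up-weights fast-copulating males.
    """
    group = [v for v in vectors if v.genotype == genotype]
    if not group:
        raise ValueError(f"no vectors with genotype {genotype!r}")
    n = len(group)
    # fsum: the means are exactly invariant under permutation of the group
    return GroupSummary(
        genotype=genotype,
        n=n,
        mean_orientation_pct=math.fsum(
            time_fraction_pct(v.orientation_time_s, v.total_time_s) for v in group
        )
        / n,
        mean_vibration_pct=math.fsum(
            time_fraction_pct(v.vibration_time_s, v.total_time_s) for v in group
        )
        / n,
        mean_licking_norm=math.fsum(
            count_rate_norm(v.licking_count, v.total_time_s) for v in group
        )
        / n,
        mean_atc_norm=math.fsum(
            count_rate_norm(v.atc_count, v.total_time_s) for v in group
        )
        / n,
        copulation_total=sum(v.copulated for v in group),
        mean_nse=sum(v.nse_count for v in group) / n,
        mean_sfi=math.fsum(v.sfi for v in group) / n,
    )


#: The six traits entering the composite score, mapped to the GroupSummary
#: attribute holding each trait's group-level value.  SFI (not raw NSE) is
#: the sixth trait so that every component increases with better courtship
#: performance.
COMPOSITE_TRAITS: tuple[tuple[str, str], ...] = (
    ("orientation", "mean_orientation_pct"),
    ("vibration", "mean_vibration_pct"),
    ("licking", "mean_licking_norm"),
    ("attempted_copulation", "mean_atc_norm"),
    ("copulation", "copulation_total"),
    ("sfi", "mean_sfi"),
)


def relative_activities(
    summary_pd: GroupSummary, summary_ctrl: GroupSummary
) -> dict[str, float]:
    """Each of the six traits as percent activity relative to control."""
    out: dict[str, float] = {}
    for trait, attr in COMPOSITE_TRAITS:
        out[trait] = relative_activity_pct(
            getattr(summary_pd, attr), getattr(summary_ctrl, attr)
        )
    return out


def composite_score(
    summary_pd: GroupSummary, summary_ctrl: GroupSummary
) -> float:
    """Composite courtship score: the six relative activities summed and
    rescaled so that the control group scores exactly 100%."""
    rel = relative_activities(summary_pd, summary_ctrl)
    return sum(rel.values()) / len(rel)


# ---------------------------------------------------------------------------
# Tabular interchange

_VECTOR_COLUMNS = (
    "couple_id",
    "genotype",
    "healthy",
    "orientation_time_s",
    "vibration_time_s",
    "licking_count",
    "atc_count",
    "copulated",
    "nse_count",
    "total_time_s",
    "sfi",
)


def vectors_to_dataframe(vectors: Iterable[ParameterVector]) -> pd.DataFrame:
    rows = [{c: getattr(v, c) for c in _VECTOR_COLUMNS} for v in vectors]
    return pd.DataFrame(rows, columns=_VECTOR_COLUMNS)


def vectors_from_dataframe(df: pd.DataFrame) -> list[ParameterVector]:
    missing = set(_VECTOR_COLUMNS) - {"sfi"} - set(df.columns)
    if missing:
        raise ValueError(f"parameter-vector table missing columns {sorted(missing)}")
    vectors = []
    for rec in df.to_dict("records"):
        vectors.append(
            ParameterVector(
                couple_id=str(rec["couple_id"]),
                genotype=str(rec["genotype"]),
                healthy=bool(rec["healthy"]),
                orientation_time_s=float(rec["orientation_time_s"]),
                vibration_time_s=float(rec["vibration_time_s"]),
                licking_count=int(rec["licking_count"]),
                atc_count=int(rec["atc_count"]),
                copulated=bool(rec["copulated"]),
                nse_count=int(rec["nse_count"]),
                total_time_s=float(rec["total_time_s"]),
            )
        )
    return vectors


def write_vectors(
    vectors: Iterable[ParameterVector], path: str | PathLike
) -> None:
    vectors_to_dataframe(vectors).to_csv(path, index=False)


def read_vectors(path: str | PathLike) -> list[ParameterVector]:
    return vectors_from_dataframe(pd.read_csv(path))


def summaries_to_json(
    summaries: Mapping[str, GroupSummary], path: str | PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({k: s.to_dict() for k, s in summaries.items()}, fh, indent=2)
        fh.write("\n")
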