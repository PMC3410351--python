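"""Event-log data model and I/O for *Drosophila* courtship sessions.

A session is one male-female couple observed in a mating chamber for up to
``observation_cap_s`` seconds (600 s in the standard design) or until
copulation begins, whichever comes first.  Every behavioral bout is one
:class:`EventRecord`: an element of the male courtship ritual (orientation
toward the female, wing vibration, licking, attempted copulation,
copulation) or a non-sexual encounter (NSE) — a male-female encounter not
followed by any sexual activity, recorded as an instantaneous event.

Sessions are serialized as plain CSV, one row per event, with columns
``couple_id,genotype,element,start_s,end_s``.  Times are seconds, written
with two-decimal precision.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

__all__ = [
    "Element",
    "EventRecord",
    "CourtshipSession",
    "ParseError",
    "ValidationError",
    "GENOTYPES",
    "SESSION_COLUMNS",
    "read_sessions",
    "write_sessions",
    "total_time",
    "ritual_time",
]

#: Default genotype vocabulary: wild-type Oregon-R controls and flies
#: expressing the familial-Parkinson's A30P mutant of human alpha-synuclein
#: pan-neurally.
GENOTYPES: frozenset[str] = frozenset({"control", "a30p"})

SESSION_COLUMNS = ("couple_id", "genotype", "element", "start_s", "end_s")

#: Absolute slack (seconds) used when comparing recorded times against the
#: session bounds; covers two-decimal rounding on write.
_TIME_EPS = 5e-3


class ParseError(ValueError):
    """A session file row could not be parsed; the message names the line."""


class ValidationError(ValueError):
    """A session violates an invariant; the message names couple and rule."""


class Element(str, enum.Enum):
    """Behavioral elements scored during a courtship session."""

    ORIENTATION = "orientation"
    VIBRATION = "vibration"
    LICKING = "licking"
    ATTEMPTED_COPULATION = "attempted_copulation"
    COPULATION = "copulation"
    NSE = "nse"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


@dataclass(frozen=True)
class EventRecord:
    """One behavioral bout: an element with start and end times in seconds.

    NSEs are instantaneous encounters and default to ``end_s == start_s``.
    """

    element: Element
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "element", Element(self.element))
        start = float(self.start_s)
        end = float(self.end_s)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)
        if not (math.isfinite(start) and math.isfinite(end)):
            raise ValidationError("event times must be finite")
        if start < 0:
            raise ValidationError(f"event start {start} is negative")
        if end < start:
            raise ValidationError(f"event end {end} precedes start {start}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class CourtshipSession:
    """A couple's full annotated observation with its genotype label.

    ``total_time_s`` is derived: the copulation start time if the couple
    copulated (the observation ends there), otherwise the observation cap.
    """

    couple_id: str
    genotype: str
    events: list[EventRecord] = field(default_factory=list)
    observation_cap_s: float = 600.0

    @property
    def total_time_s(self) -> float:
        for ev in self.events:
            if ev.element is Element.COPULATION:
                return ev.start_s
        return self.observation_cap_s

    @property
    def copulated(self) -> bool:
        return any(ev.element is Element.COPULATION for ev in self.events)

    def events_of(self, element: Element) -> list[EventRecord]:
        return [ev for ev in self.events if ev.element is element]

    def validate(self, genotypes: frozenset[str] = GENOTYPES) -> None:
        """Raise :class:`ValidationError` on the first violated invariant."""
        cid = self.couple_id
        if not cid:
            raise ValidationError("couple_id must be non-empty")
        if self.genotype not in genotypes:
            raise ValidationError(
                f"couple {cid!r}: unknown genotype {self.genotype!r} "
                f"(expected one of {sorted(genotypes)})"
            )
        if self.observation_cap_s <= 0:
            raise ValidationError(f"couple {cid!r}: non-positive observation cap")

        copulations = self.events_of(Element.COPULATION)
        if len(copulations) > 1:
            raise ValidationError(
                f"couple {cid!r}: more than one copulation event in a session"
            )
        total = self.total_time_s
        if not 0 < total <= self.observation_cap_s + _TIME_EPS:
            raise ValidationError(
                f"couple {cid!r}: total time {total} outside "
                f"(0, {self.observation_cap_s}]"
            )
        for ev in self.events:
            if ev.end_s > self.observation_cap_s + _TIME_EPS:
                raise ValidationError(
                    f"couple {cid!r}: event ends at {ev.end_s} after the "
                    f"{self.observation_cap_s} s observation cap"
                )
            if ev.element is not Element.COPULATION and ev.end_s > total + _TIME_EPS:
                raise ValidationError(
                    f"couple {cid!r}: {ev.element} event ends at {ev.end_s} "
                    f"after the session ended at {total}"
                )
        # Bouts of one element must not overlap each other; bouts of
        # different elements may (a male can orient while vibrating).
        for element in Element:
            bouts = sorted(self.events_of(element), key=lambda e: (e.start_s, e.end_s))
            for prev, nxt in zip(bouts, bouts[1:]):
                if nxt.start_s < prev.end_s - _TIME_EPS:
                    raise ValidationError(
                        f"couple {cid!r}: overlapping {element} bouts "
                        f"({prev.start_s}-{prev.end_s} and {nxt.start_s}-{nxt.end_s})"
                    )
            dur = sum(b.duration_s for b in bouts)
            if dur > total + _TIME_EPS * max(1, len(bouts)):
                raise ValidationError(
                    f"couple {cid!r}: summed {element} bout time {dur:.2f} "
                    f"exceeds total time {total:.2f}"
                )


def total_time(session: CourtshipSession) -> float:
    """Total observed time: copulation start if copulated, else the cap.

    Invariant under reordering of the event list.
    """
    return session.total_time_s


#: Elements of the courtship ritual proper (everything but NSE).
COURTSHIP_ELEMENTS = (
    Element.ORIENTATION,
    Element.VIBRATION,
    Element.LICKING,
    Element.ATTEMPTED_COPULATION,
    Element.COPULATION,
)


def ritual_time(session: CourtshipSession, from_first_act: bool = False) -> float:
    """Duration of the ritual window.

    By default this is the total observed time (:func:`total_time`).  With
    ``from_first_act=True`` it is measured from the onset of the first
    courtship element (NSEs excluded) to the session end — an alternative
    reading of "ritual time" that discounts an inactive lead-in.  Returns
    0 for a session with no courtship act under that reading.
    """
    end = session.total_time_s
    if not from_first_act:
        return end
    starts = [
        ev.start_s for ev in session.events if ev.element in COURTSHIP_ELEMENTS
    ]
    if not starts:
        return 0.0
    return end - min(starts)


def _fmt_time(t: float) -> str:
    return f"{t:.2f}"


def write_sessions(
    sessions: Sequence[CourtshipSession], path: str | PathLike
) -> None:
    """Write sessions to CSV, one row per event, times at 2 decimals.

    The file is re-readable by :func:`read_sessions` with identical field
    values provided times lie on the centisecond grid.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_COLUMNS)
        for session in sessions:
            for ev in sorted(session.events, key=lambda e: (e.start_s, e.end_s)):
                writer.writerow(
                    [
                        session.couple_id,
                        session.genotype,
                        ev.element.value,
                        _fmt_time(ev.start_s),
                        _fmt_time(ev.end_s),
                    ]
                )


def read_sessions(
    path: str | PathLike,
    observation_cap_s: float = 600.0,
    genotypes: frozenset[str] = GENOTYPES,
) -> list[CourtshipSession]:
    """Read and validate a session CSV.

    Rows are grouped by ``couple_id``; events are ordered by start time and
    sessions by couple id.  Malformed rows raise :class:`ParseError` naming
    the offending line; invariant violations raise
    :class:`ValidationError` naming the couple and the rule.
    """
    by_couple: dict[str, CourtshipSession] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header "
                             f"{','.join(SESSION_COLUMNS)}") from None
        if tuple(h.strip() for h in header) != SESSION_COLUMNS:
            raise ParseError(
                f"{path}: bad header {header!r}, expected "
                f"{','.join(SESSION_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(SESSION_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(SESSION_COLUMNS)} "
                    f"fields, got {len(row)}"
                )
            couple_id, genotype, element, start_s, end_s = (c.strip() for c in row)
            try:
                ev = EventRecord(Element(element), float(start_s), float(end_s))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            session = by_couple.get(couple_id)
            if session is None:
                session = CourtshipSession(
                    couple_id=couple_id,
                    genotype=genotype,
                    observation_cap_s=observation_cap_s,
                )
                by_couple[couple_id] = session
            elif session.genotype != genotype:
                raise ValidationError(
                    f"couple {couple_id!r}: conflicting genotype labels "
                    f"{session.genotype!r} and {genotype!r}"
                )
            session.events.append(ev)

    sessions = [by_couple[cid] for cid in sorted(by_couple)]
    for session in sessions:
        session.events.sort(key=lambda e: (e.start_s, e.end_s))
        session.validate(genotypes=genotypes)
    return sessions


def iter_event_rows(
    sessions: Iterable[CourtshipSession],
) -> Iterable[tuple[str, str, str, float, float]]:
    """Yield flat (couple_id, genotype, element, start_s, end_s) tuples."""
    for session in sessions:
        for ev in session.events:
            yield (
                session.couple_id,
                session.genotype,
                ev.element.value,
                ev.start_s,
                ev.end_s,
            )
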