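"""Packaged reference data: the published diagnostic rule set and a
synthetic evaluation cohort reproducing its reported confusion structure.

The reference rule set is the seven-condition "if and only if" diagnostic
derived from a 56-couple courtship screen of wild-type (Oregon-R) males
versus males expressing the A30P alpha-synuclein mutant pan-neurally.
Four of its seven conditions test the non-sexual-encounter count, making
NSE the dominant diagnostic feature.  Interval endpoints are kept exactly
as published; the published per-condition averages, some of which are
internally inconsistent, are carried as annotation only and never used in
classification.

The raw per-fly recordings behind that screen were never released, so
:func:`synthetic_evaluation_vectors` constructs a synthetic stand-in
cohort of 56 parameter vectors whose confusion structure under the
reference rule set matches the published evaluation exactly: 23 of 28
healthy flies satisfy at least one condition and 23 of 28 sick flies
satisfy none, giving a success rate of 46/56 = 0.821 and an improvement
factor of 0.5/0.179 = 2.8.
"""

from __future__ import annotations

from importlib import resources

from .metrics import ParameterVector
from .rules import RuleSet, ruleset_from_dict

__all__ = [
    "reference_ruleset",
    "reference_ruleset_path",
    "synthetic_evaluation_vectors",
]

_RULES_RESOURCE = "data/reference_rules.json"


def reference_ruleset_path() -> str:
    """Filesystem path of the packaged reference rule-set JSON."""
    return str(resources.files("flycourt").joinpath(_RULES_RESOURCE))


def reference_ruleset() -> RuleSet:
    """Load the packaged seven-condition diagnostic rule set."""
    import json

    text = (
        resources.files("flycourt").joinpath(_RULES_RESOURCE).read_text("utf-8")
    )
    return ruleset_from_dict(json.loads(text))


def _vector(
    couple_id: str, healthy: bool, hit: bool, jitter: int
) -> ParameterVector:
    # An NSE count of 4 satisfies the rule set's first condition; an NSE
    # count of 18-25 avoids all four NSE intervals.  Orientation far below
    # 294 s, total time at the 600 s cap, and zero attempted copulations
    # avoid the remaining conditions, so each vector's classification is
    # controlled entirely by its NSE count.
    nse = 4 if hit else 18 + jitter
    return ParameterVector(
        couple_id=couple_id,
        healthy=healthy,
        orientation_time_s=80.0 + 7.0 * jitter,
        vibration_time_s=30.0 + 3.0 * jitter,
        licking_count=5 + jitter,
        atc_count=0,
        copulated=False,
        nse_count=nse,
        total_time_s=600.0,
    )


def synthetic_evaluation_vectors() -> list[ParameterVector]:
    """Synthetic 56-couple cohort matching the published confusion counts.

    Returns 28 healthy vectors of which 23 satisfy the reference rule set,
    and 28 sick vectors of which 23 satisfy none of its conditions.  The
    individual feature values are constructed, not measured; only the
    hit/miss pattern is meaningful.
    """
    vectors: list[ParameterVector] = []
    for i in range(28):
        vectors.append(
            _vector(f"healthy-{i:02d}", healthy=True, hit=i < 23, jitter=i % 8)
        )
    for i in range(28):
        vectors.append(
            _vector(f"sick-{i:02d}", healthy=False, hit=i >= 23, jitter=i % 8)
        )
    return vectors
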