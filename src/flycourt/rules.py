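"""Interval-condition rules and the "if and only if" rule-set classifier.

A :class:`Condition` is an inclusive interval test on one of the eight
per-fly features (an ``exact_count`` condition is the degenerate interval
``low == high`` on a count feature).  A :class:`Rule` is a conjunction of
one or more conditions predicting a health label.  A :class:`RuleSet`
holds healthy-predicting rules with disjunction ("if and only if")
semantics: a fly satisfying at least one rule's conjunction is classified
healthy, a fly satisfying none is classified sick — the rule set is
treated as simultaneously necessary and sufficient for health.

:func:`evaluate` scores a rule set on labeled data: the two-sided success
rate, the empirical conditional probabilities P(healthy | some condition
holds) and P(sick | none holds), and the improvement factor — the error
rate of a chance guess at the given class prior divided by the observed
error rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Sequence

from .metrics import FEATURES, ParameterVector, feature_value

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "ClassificationReport",
    "HEALTHY",
    "SICK",
    "condition_holds",
    "classify",
    "evaluate",
    "load_ruleset",
    "save_ruleset",
    "ruleset_to_dict",
    "ruleset_from_dict",
]

HEALTHY = "healthy"
SICK = "sick"
_LABELS = (HEALTHY, SICK)


@dataclass(frozen=True)
class Condition:
    """Inclusive interval test ``low <= feature <= high``.

    ``note`` carries free-text annotation (e.g. a reported within-interval
    average) and does not participate in equality.
    """

    feature: str
    kind: str = "interval"
    low: float = -math.inf
    high: float = math.inf
    note: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(
                f"unknown feature {self.feature!r}; expected one of {FEATURES}"
            )
        if self.kind not in ("interval", "exact_count"):
            raise ValueError(f"unknown condition kind {self.kind!r}")
        if self.low > self.high:
            raise ValueError(f"empty interval [{self.low}, {self.high}]")
        if self.kind == "exact_count":
            if self.low != self.high or self.low != int(self.low):
                raise ValueError(
                    "exact_count requires integer low == high, got "
                    f"[{self.low}, {self.high}]"
                )

    def holds(self, vector: ParameterVector) -> bool:
        value = feature_value(vector, self.feature)
        return self.low <= value <= self.high

    def describe(self) -> str:
        if self.kind == "exact_count":
            return f"{self.feature} == {int(self.low):d}"
        return f"{self.low:g} <= {self.feature} <= {self.high:g}"


def condition_holds(vector: ParameterVector, condition: Condition) -> bool:
    """True iff the feature value lies in the closed interval."""
    return condition.holds(vector)


@dataclass(frozen=True)
class Rule:
    """Conjunction of conditions predicting a health label.

    ``probability`` and ``support`` are the empirical confidence
    P(label | conjunction) and the number of covered cases of the
    predicted class on the dataset the rule was mined from.
    """

    conditions: tuple[Condition, ...]
    predicted: str = HEALTHY
    probability: float | None = None
    support: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if not self.conditions:
            raise ValueError("a rule needs at least one condition")
        if self.predicted not in _LABELS:
            raise ValueError(f"predicted label must be one of {_LABELS}")
        if self.probability is not None and not 0 <= self.probability <= 1:
            raise ValueError(f"probability {self.probability} outside [0, 1]")

    def matches(self, vector: ParameterVector) -> bool:
        return all(c.holds(vector) for c in self.conditions)

    def describe(self) -> str:
        body = " & ".join(c.describe() for c in self.conditions)
        return f"if {body} then {self.predicted}"


@dataclass(frozen=True)
class RuleSet:
    """Disjunction of healthy-predicting rules with iff semantics."""

    rules: tuple[Rule, ...]
    name: str = "ruleset"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        if not self.rules:
            raise ValueError("rule set must be non-empty")
        for rule in self.rules:
            if rule.predicted != HEALTHY:
                raise ValueError(
                    "iff rule sets contain healthy-predicting rules only"
                )

    def hits(self, vector: ParameterVector) -> bool:
        return any(rule.matches(vector) for rule in self.rules)


def classify(vector: ParameterVector, ruleset: RuleSet) -> str:
    """healthy iff at least one rule's conjunction holds, else sick."""
    return HEALTHY if ruleset.hits(vector) else SICK


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and summary statistics for a rule-set evaluation.

    ``improvement_factor`` is the baseline error of a chance guess at the
    given prior, ``min(prior, 1 - prior)``, divided by the observed error
    ``1 - success_rate``; ``inf`` when the classifier is perfect.
    ``p_healthy_given_hit`` / ``p_sick_given_miss`` are ``nan`` when no
    vector hits (resp. misses) the rule set.
    """

    n_total: int
    n_correct: int
    n_hits: int
    n_healthy_hits: int
    n_sick_misses: int
    success_rate: float
    p_healthy_given_hit: float
    p_sick_given_miss: float
    prior: float
    improvement_factor: float

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "n_hits": self.n_hits,
            "n_healthy_hits": self.n_healthy_hits,
            "n_sick_misses": self.n_sick_misses,
            "success_rate": self.success_rate,
            "p_healthy_given_hit": self.p_healthy_given_hit,
            "p_sick_given_miss": self.p_sick_given_miss,
            "prior": self.prior,
            "improvement_factor": self.improvement_factor,
        }
        return d


def evaluate(
    dataset: Sequence[ParameterVector],
    ruleset: RuleSet,
    prior: float = 0.5,
) -> ClassificationReport:
    """Score a rule set against the ``healthy`` labels of a dataset."""
    if not dataset:
        raise ValueError("dataset must be non-empty")
    if not 0 < prior < 1:
        raise ValueError(f"prior must lie in (0, 1), got {prior}")
    hits = [ruleset.hits(v) for v in dataset]
    n_total = len(dataset)
    n_hits = sum(hits)
    n_miss = n_total - n_hits
    n_healthy_hits = sum(h and v.healthy for h, v in zip(hits, dataset))
    n_sick_misses = sum((not h) and (not v.healthy) for h, v in zip(hits, dataset))
    n_correct = n_healthy_hits + n_sick_misses
    success_rate = n_correct / n_total
    baseline_error = min(prior, 1.0 - prior)
    observed_error = 1.0 - success_rate
    improvement = (
        math.inf if observed_error == 0 else baseline_error / observed_error
    )
    return ClassificationReport(
        n_total=n_total,
        n_correct=n_correct,
        n_hits=n_hits,
        n_healthy_hits=n_healthy_hits,
        n_sick_misses=n_sick_misses,
        success_rate=success_rate,
        p_healthy_given_hit=(n_healthy_hits / n_hits) if n_hits else math.nan,
        p_sick_given_miss=(n_sick_misses / n_miss) if n_miss else math.nan,
        prior=prior,
        improvement_factor=improvement,
    )


# ---------------------------------------------------------------------------
# JSON interchange
#
# Schema: {"name": str, "rules": [{"predicted": str, "probability": float?,
#          "support": int?, "conditions": [{"feature", "kind", "low",
#          "high", "note"?}]}]}
# Unbounded interval ends are serialized as null.


def _num_out(x: float) -> float | None:
    return None if math.isinf(x) else x


def _num_in(x: float | None, default: float) -> float:
    return default if x is None else float(x)


def ruleset_to_dict(ruleset: RuleSet) -> dict:
    return {
        "name": ruleset.name,
        "rules": [
            {
                "predicted": r.predicted,
                "probability": r.probability,
                "support": r.support,
                "conditions": [
                    {
                        "feature": c.feature,
                        "kind": c.kind,
                        "low": _num_out(c.low),
                        "high": _num_out(c.high),
                        **({"note": c.note} if c.note else {}),
                    }
                    for c in r.conditions
                ],
            }
            for r in ruleset.rules
        ],
    }


def ruleset_from_dict(data: dict) -> RuleSet:
    rules = []
    for rd in data["rules"]:
        conditions = tuple(
            Condition(
                feature=cd["feature"],
                kind=cd.get("kind", "interval"),
                low=_num_in(cd.get("low"), -math.inf),
                high=_num_in(cd.get("high"), math.inf),
                note=cd.get("note"),
            )
            for cd in rd["conditions"]
        )
        rules.append(
            Rule(
                conditions=conditions,
                predicted=rd.get("predicted", HEALTHY),
                probability=rd.get("probability"),
                support=rd.get("support"),
            )
        )
    return RuleSet(rules=tuple(rules), name=data.get("name", "ruleset"))


def save_ruleset(ruleset: RuleSet, path: str | PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(ruleset_to_dict(ruleset), fh, indent=2)
        fh.write("\n")


def load_ruleset(path: str | PathLike) -> RuleSet:
    with open(path, encoding="utf-8") as fh:
        return ruleset_from_dict(json.load(fh))
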