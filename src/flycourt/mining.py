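"""Association-rule mining over the eight courtship features.

The miner enumerates *every* conjunction (up to a configured size) of
interval conditions on the per-fly features and keeps those whose
empirical confidence P(label | conjunction) and support meet the
configured thresholds, for both the healthy and the sick target label.
From the surviving healthy-predicting rules a greedy forward selection
assembles an "if and only if" rule set: a disjunction treated as both
necessary and sufficient for the healthy label, chosen to maximize the
two-sided success rate on the training data.

Candidate conditions are data-driven: interval endpoints are observed
feature values (exhaustive on small datasets, equal-frequency quantile
endpoints on large ones), so the search space is finite and the
enumeration provably covers all distinguishable intervals.  Mining is
fully deterministic: iteration orders are fixed and there is no
randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .metrics import BOOLEAN_FEATURES, FEATURES, ParameterVector, feature_value
from .rules import (
    HEALTHY,
    SICK,
    ClassificationReport,
    Condition,
    Rule,
    RuleSet,
    evaluate,
)

__all__ = [
    "MiningConfig",
    "candidate_conditions",
    "mine_rules",
    "select_iff_ruleset",
]

#: Datasets with at most this many rows use every observed value as a
#: candidate interval endpoint; larger datasets fall back to
#: equal-frequency binning.
EXHAUSTIVE_ROW_LIMIT = 64

#: Number of equal-frequency bins used for candidate endpoints when the
#: dataset is too large for exhaustive endpoint enumeration.
DEFAULT_BINS = 8


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and search-space limits for rule mining.

    ``min_probability`` is the minimum empirical confidence
    P(label | conjunction); values at or above the threshold qualify.
    ``min_support`` is an absolute count of covered cases of the predicted
    class (duplicating every row doubles supports, so thresholds do not
    rescale automatically).  ``max_intervals_per_feature`` of ``None``
    selects the default endpoint policy: exhaustive observed-value
    endpoints up to ``EXHAUSTIVE_ROW_LIMIT`` rows, otherwise
    ``DEFAULT_BINS`` equal-frequency bins.
    """

    min_probability: float = 0.8
    min_support: int = 2
    max_conjunction: int = 2
    max_intervals_per_feature: int | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.min_probability <= 1:
            raise ValueError(
                f"min_probability must lie in (0.5, 1], got {self.min_probability}"
            )
        if self.min_support < 1:
            raise ValueError(f"min_support must be >= 1, got {self.min_support}")
        if self.max_conjunction not in (1, 2, 3):
            raise ValueError(
                f"max_conjunction must be 1, 2 or 3, got {self.max_conjunction}"
            )
        if (
            self.max_intervals_per_feature is not None
            and self.max_intervals_per_feature < 1
        ):
            raise ValueError("max_intervals_per_feature must be >= 1")


def _value_matrix(dataset: Sequence[ParameterVector]) -> np.ndarray:
    return np.array(
        [[feature_value(v, f) for f in FEATURES] for v in dataset], dtype=float
    )


def _candidate_endpoints(values: np.ndarray, cfg: MiningConfig) -> np.ndarray:
    """Sorted unique candidate endpoints for one feature column."""
    unique = np.unique(values)
    n_rows = values.size
    bins: int | None
    if cfg.max_intervals_per_feature is not None:
        bins = cfg.max_intervals_per_feature
    elif n_rows > EXHAUSTIVE_ROW_LIMIT:
        bins = DEFAULT_BINS
    else:
        bins = None
    if bins is not None and unique.size > bins + 1:
        qs = np.linspace(0.0, 1.0, bins + 1)
        unique = np.unique(
            np.quantile(values, qs, method="closest_observation")
        )
    return unique


def _feature_conditions(
    feature: str, values: np.ndarray, cfg: MiningConfig
) -> list[Condition]:
    """All candidate conditions on one feature, in deterministic order."""
    endpoints = _candidate_endpoints(values, cfg)
    conds: list[Condition] = []
    if feature in BOOLEAN_FEATURES:
        for v in endpoints:  # no [0, 1] interval: it is always true
            conds.append(
                Condition(feature=feature, kind="exact_count", low=v, high=v)
            )
        return conds
    from .metrics import COUNT_FEATURES

    is_count = feature in COUNT_FEATURES
    for i in range(endpoints.size):
        for j in range(i, endpoints.size):
            low, high = float(endpoints[i]), float(endpoints[j])
            kind = "exact_count" if is_count and low == high else "interval"
            conds.append(Condition(feature=feature, kind=kind, low=low, high=high))
    return conds


def candidate_conditions(
    dataset: Sequence[ParameterVector], cfg: MiningConfig | None = None
) -> list[Condition]:
    """Every candidate interval condition over the eight features.

    For count and Boolean features these are all contiguous runs of
    observed values; for continuous features, all intervals whose inclusive
    endpoints are observed values (or quantile-selected endpoints in
    binned mode).  Deduplicated and deterministically ordered.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    cfg = cfg or MiningConfig()
    V = _value_matrix(dataset)
    out: list[Condition] = []
    for fi, feature in enumerate(FEATURES):
        out.extend(_feature_conditions(feature, V[:, fi], cfg))
    return out


def _condition_key(c: Condition) -> tuple:
    return (c.feature, c.low, c.high, c.kind)


def _masks(
    conds: list[Condition], values: np.ndarray
) -> np.ndarray:
    """Boolean matrix (n_conditions x n_rows) of condition satisfaction."""
    if not conds:
        return np.zeros((0, values.size), dtype=bool)
    lows = np.array([c.low for c in conds])[:, None]
    highs = np.array([c.high for c in conds])[:, None]
    return (values[None, :] >= lows) & (values[None, :] <= highs)


def mine_rules(
    dataset: Sequence[ParameterVector], cfg: MiningConfig | None = None
) -> list[Rule]:
    """All qualifying conjunctive rules for both target labels.

    A conjunction qualifies when its empirical confidence is at least
    ``min_probability`` and it covers at least ``min_support`` cases of the
    predicted label.  A qualifying conjunction is pruned when a proper
    sub-conjunction already qualifies for the same label with confidence
    at least as high (the longer rule adds nothing).  Output order is
    deterministic; each rule carries its empirical probability and
    support.  Invariant under permutation of the dataset rows.
    """
    cfg = cfg or MiningConfig()
    if not dataset:
        raise ValueError("dataset must be non-empty")
    y = np.array([v.healthy for v in dataset], dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both healthy and sick labels must be present")

    V = _value_matrix(dataset)
    feat_conds: list[list[Condition]] = []
    feat_masks: list[np.ndarray] = []
    for fi, feature in enumerate(FEATURES):
        conds = _feature_conditions(feature, V[:, fi], cfg)
        feat_conds.append(conds)
        feat_masks.append(_masks(conds, V[:, fi]))

    minp = cfg.min_probability
    mins = cfg.min_support
    rules: list[Rule] = []
    # confidence of every qualifying conjunction, for superset pruning
    qual_prob: dict[tuple[str, frozenset], float] = {}

    # -- single conditions ------------------------------------------------
    single_stats: list[dict[str, tuple[np.ndarray, np.ndarray]]] = []
    for fi, feature in enumerate(FEATURES):
        M = feat_masks[fi]
        tot = M.sum(axis=1)
        pos = M[:, y].sum(axis=1)
        stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for label, n_label in ((HEALTHY, pos), (SICK, tot - pos)):
            with np.errstate(invalid="ignore", divide="ignore"):
                prob = np.where(tot > 0, n_label / np.maximum(tot, 1), 0.0)
            qual = (tot > 0) & (prob >= minp) & (n_label >= mins)
            stats[label] = (prob, qual)
            for ci in np.nonzero(qual)[0]:
                cond = feat_conds[fi][ci]
                rules.append(
                    Rule(
                        conditions=(cond,),
                        predicted=label,
                        probability=float(prob[ci]),
                        support=int(n_label[ci]),
                    )
                )
                qual_prob[(label, frozenset([_condition_key(cond)]))] = float(
                    prob[ci]
                )
        single_stats.append(stats)

    if cfg.max_conjunction >= 2:
        # pair-level pruning metadata is only consumed by the triple stage
        pair_prob = qual_prob if cfg.max_conjunction >= 3 else None
        rules.extend(
            _mine_pairs(feat_conds, feat_masks, y, cfg, single_stats, pair_prob)
        )
    if cfg.max_conjunction >= 3:
        rules.extend(_mine_triples(feat_conds, feat_masks, y, cfg, qual_prob))
    return rules


def _mine_pairs(feat_conds, feat_masks, y, cfg, single_stats, qual_prob):
    """Two-condition conjunctions across distinct features, vectorized."""
    minp, mins = cfg.min_probability, cfg.min_support
    rules: list[Rule] = []
    n_feat = len(feat_conds)
    for fi, fj in combinations(range(n_feat), 2):
        Mi, Mj = feat_masks[fi], feat_masks[fj]
        if not (Mi.size and Mj.size):
            continue
        Ai = Mi.astype(np.int64)
        Aj = Mj.astype(np.int64)
        tot = Ai @ Aj.T
        pos = Ai[:, y] @ Aj[:, y].T
        for label, n_label in ((HEALTHY, pos), (SICK, tot - pos)):
            with np.errstate(invalid="ignore", divide="ignore"):
                prob = np.where(tot > 0, n_label / np.maximum(tot, 1), 0.0)
            qual = (tot > 0) & (prob >= minp) & (n_label >= mins)
            # prune pairs dominated by a qualifying single condition
            pi, qi = single_stats[fi][label]
            pj, qj = single_stats[fj][label]
            dominated = (qi[:, None] & (pi[:, None] >= prob)) | (
                qj[None, :] & (pj[None, :] >= prob)
            )
            keep = qual & ~dominated
            for ci, cj in np.argwhere(keep):
                conds = (feat_conds[fi][ci], feat_conds[fj][cj])
                p = float(prob[ci, cj])
                rules.append(
                    Rule(
                        conditions=conds,
                        predicted=label,
                        probability=p,
                        support=int(n_label[ci, cj]),
                    )
                )
                if qual_prob is not None:
                    key = (label, frozenset(_condition_key(c) for c in conds))
                    qual_prob[key] = p
    return rules


def _mine_triples(feat_conds, feat_masks, y, cfg, qual_prob):
    """Three-condition conjunctions.

    Quadratic matrix products inside a loop over the first feature's
    conditions; intended for small candidate spaces (tiny datasets or
    binned endpoints).
    """
    minp, mins = cfg.min_probability, cfg.min_support
    rules: list[Rule] = []
    n_feat = len(feat_conds)
    for fi, fj, fk in combinations(range(n_feat), 3):
        Mi, Mj, Mk = feat_masks[fi], feat_masks[fj], feat_masks[fk]
        if not (Mi.size and Mj.size and Mk.size):
            continue
        for ci in range(Mi.shape[0]):
            rows = Mi[ci]
            if not rows.any():
                continue
            Aj = Mj[:, rows].astype(np.int64)
            Ak = Mk[:, rows].astype(np.int64)
            y_sub = y[rows]
            tot = Aj @ Ak.T
            pos = Aj[:, y_sub] @ Ak[:, y_sub].T
            for label, n_label in ((HEALTHY, pos), (SICK, tot - pos)):
                with np.errstate(invalid="ignore", divide="ignore"):
                    prob = np.where(tot > 0, n_label / np.maximum(tot, 1), 0.0)
                qual = (tot > 0) & (prob >= minp) & (n_label >= mins)
                for cj, ck in np.argwhere(qual):
                    conds = (
                        feat_conds[fi][ci],
                        feat_conds[fj][cj],
                        feat_conds[fk][ck],
                    )
                    p = float(prob[cj, ck])
                    keys = [_condition_key(c) for c in conds]
                    dominated = False
                    for r in (1, 2):
                        for sub in combinations(keys, r):
                            sub_p = qual_prob.get((label, frozenset(sub)))
                            if sub_p is not None and sub_p >= p:
                                dominated = True
                                break
                        if dominated:
                            break
                    if dominated:
                        continue
                    rules.append(
                        Rule(
                            conditions=conds,
                            predicted=label,
                            probability=p,
                            support=int(n_label[cj, ck]),
                        )
                    )
                    qual_prob[(label, frozenset(keys))] = p
    return rules


def _rule_mask(rule: Rule, V: np.ndarray) -> np.ndarray:
    mask = np.ones(V.shape[0], dtype=bool)
    for c in rule.conditions:
        col = V[:, FEATURES.index(c.feature)]
        mask &= (col >= c.low) & (col <= c.high)
    return mask


def _tie_key(rule: Rule, support: int) -> tuple:
    return (
        -support,
        len(rule.conditions),
        tuple(_condition_key(c) for c in rule.conditions),
        rule.predicted,
    )


def select_iff_ruleset(
    rules: Sequence[Rule],
    dataset: Sequence[ParameterVector],
    name: str = "mined-iff",
    prior: float = 0.5,
) -> tuple[RuleSet, ClassificationReport]:
    """Greedy forward selection of an "if and only if" rule set.

    Starting from the empty disjunction (everything classified sick), the
    healthy-predicting rule that most increases the two-sided success rate
    is added repeatedly until no addition strictly improves it.  Ties are
    broken by higher support, then fewer conditions, then a fixed lexical
    order.  Returns the selected rule set together with its evaluation on
    the dataset.
    """
    healthy_rules = [r for r in rules if r.predicted == HEALTHY]
    if not healthy_rules:
        raise ValueError("no healthy-predicting rules to select from")
    if not dataset:
        raise ValueError("dataset must be non-empty")

    V = _value_matrix(dataset)
    y = np.array([v.healthy for v in dataset], dtype=bool)
    masks = np.stack([_rule_mask(r, V) for r in healthy_rules])
    supports = np.array(
        [
            r.support if r.support is not None else int((m & y).sum())
            for r, m in zip(healthy_rules, masks)
        ]
    )

    covered = np.zeros(len(dataset), dtype=bool)
    current_correct = int((~y).sum())  # empty disjunction: all sick
    selected: list[Rule] = []
    remaining = list(range(len(healthy_rules)))

    while remaining:
        cand = np.array(remaining)
        new_cov = covered[None, :] | masks[cand]
        new_correct = (new_cov & y).sum(axis=1) + (~new_cov & ~y).sum(axis=1)
        best = int(new_correct.max())
        if best <= current_correct:
            break
        pool = [
            int(cand[k]) for k in np.nonzero(new_correct == best)[0]
        ]
        choice = min(
            pool, key=lambda idx: _tie_key(healthy_rules[idx], int(supports[idx]))
        )
        selected.append(healthy_rules[choice])
        covered |= masks[choice]
        current_correct = best
        remaining.remove(choice)

    if not selected:
        raise ValueError(
            "no rule improves on the empty (always-sick) rule set"
        )
    ruleset = RuleSet(rules=tuple(selected), name=name)
    return ruleset, evaluate(dataset, ruleset, prior=prior)
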