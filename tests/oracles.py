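"""Independent brute-force oracles for the rule miner.

Deliberately naive: plain-Python enumeration over all candidate
conditions and conjunctions, with no shared code paths with
``flycourt.mining`` beyond the public ``Condition`` container and the
feature accessor.  Only usable on tiny datasets.
"""

from __future__ import annotations

from itertools import combinations

from flycourt import FEATURES, HEALTHY, SICK, RuleSet, evaluate
from flycourt.metrics import BOOLEAN_FEATURES, feature_value


def oracle_candidate_intervals(dataset):
    """{feature: [(low, high), ...]} — every observed-endpoint interval."""
    out = {}
    for feature in FEATURES:
        observed = sorted({feature_value(v, feature) for v in dataset})
        if feature in BOOLEAN_FEATURES:
            out[feature] = [(v, v) for v in observed]
        else:
            out[feature] = [
                (lo, hi)
                for i, lo in enumerate(observed)
                for hi in observed[i:]
            ]
    return out


def _matches(vector, conjunction):
    return all(
        lo <= feature_value(vector, feat) <= hi for feat, lo, hi in conjunction
    )


def _stats(dataset, conjunction):
    covered = [v for v in dataset if _matches(v, conjunction)]
    n_healthy = sum(v.healthy for v in covered)
    return len(covered), n_healthy


def oracle_mine(dataset, min_probability=0.8, min_support=2, max_conjunction=2):
    """All qualifying, non-dominated conjunctions as a canonical set.

    Each element is ``(label, frozenset of (feature, low, high),
    probability, support)``.
    """
    intervals = oracle_candidate_intervals(dataset)
    flat = [
        (feat, lo, hi) for feat in FEATURES for lo, hi in intervals[feat]
    ]
    qualifying = {}  # (label, frozenset of conds) -> (prob, support)
    for size in range(1, max_conjunction + 1):
        for combo in combinations(flat, size):
            feats = [c[0] for c in combo]
            if len(set(feats)) != size:
                continue
            tot, n_healthy = _stats(dataset, combo)
            if tot == 0:
                continue
            for label, n_label in (
                (HEALTHY, n_healthy),
                (SICK, tot - n_healthy),
            ):
                prob = n_label / tot
                if prob >= min_probability and n_label >= min_support:
                    qualifying[(label, frozenset(combo))] = (prob, n_label)
    # prune conjunctions dominated by an equally-or-more-probable subset
    out = set()
    for (label, conds), (prob, support) in qualifying.items():
        dominated = False
        for r in range(1, len(conds)):
            for sub in combinations(conds, r):
                hit = qualifying.get((label, frozenset(sub)))
                if hit is not None and hit[0] >= prob:
                    dominated = True
                    break
            if dominated:
                break
        if not dominated:
            out.add((label, conds, prob, support))
    return out


def canonical_rules(rules):
    """Mined Rule objects in the oracle's canonical-set form."""
    return {
        (
            r.predicted,
            frozenset((c.feature, c.low, c.high) for c in r.conditions),
            r.probability,
            r.support,
        )
        for r in rules
    }


def oracle_best_success(rules, dataset, max_size=7):
    """Best two-sided success rate over all rule subsets up to max_size."""
    healthy_rules = [r for r in rules if r.predicted == HEALTHY]
    best = sum(not v.healthy for v in dataset) / len(dataset)  # empty set
    for size in range(1, min(max_size, len(healthy_rules)) + 1):
        for combo in combinations(healthy_rules, size):
            report = evaluate(dataset, RuleSet(rules=combo, name="oracle"))
            best = max(best, report.success_rate)
    return best
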