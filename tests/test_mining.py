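import pytest

from flycourt import (
    HEALTHY,
    GeneratorConfig,
    MiningConfig,
    candidate_conditions,
    generate_sessions,
    mine_rules,
    parameter_vector,
    select_iff_ruleset,
)
from flycourt.rules import Rule, evaluate

from conftest import make_vector
from oracles import (
    canonical_rules,
    oracle_best_success,
    oracle_candidate_intervals,
    oracle_mine,
)


class TestCandidateConditions:
    def test_contiguous_runs_of_count_values(self):
        vecs = [make_vector(f"c{i}", i < 2, nse=n) for i, n in enumerate([1, 2, 3])]
        conds = [
            (c.low, c.high)
            for c in candidate_conditions(vecs)
            if c.feature == "nse_count"
        ]
        assert sorted(conds) == [(1, 1), (1, 2), (1, 3), (2, 2), (2, 3), (3, 3)]

    def test_boolean_feature_yields_singletons_only(self):
        vecs = [
            make_vector("a", True, copulated=True),
            make_vector("b", False, copulated=False),
        ]
        conds = [
            (c.low, c.high)
            for c in candidate_conditions(vecs)
            if c.feature == "copulated"
        ]
        assert conds == [(0.0, 0.0), (1.0, 1.0)]

    def test_matches_oracle_enumeration(self, noisy_dataset):
        got = candidate_conditions(noisy_dataset)
        expected = oracle_candidate_intervals(noisy_dataset)
        by_feature: dict[str, list] = {}
        for c in got:
            by_feature.setdefault(c.feature, []).append((c.low, c.high))
        for feature, intervals in expected.items():
            assert sorted(by_feature[feature]) == sorted(intervals)

    def test_deduplicated(self, separable_dataset):
        conds = candidate_conditions(separable_dataset)
        assert len(conds) == len(set(conds))

    def test_binned_mode_caps_endpoints(self):
        vecs = [
            make_vector(f"c{i}", i % 2 == 0, orientation=float(i), nse=i)
            for i in range(30)
        ]
        cfg = MiningConfig(max_intervals_per_feature=4)
        conds = [
            c for c in candidate_conditions(vecs, cfg)
            if c.feature == "orientation_time_s"
        ]
        # at most 5 endpoints -> at most 15 intervals
        assert len(conds) <= 15


class TestMineRules:
    def test_separable_toy_contains_perfect_rule(self, separable_dataset):
        rules = mine_rules(separable_dataset)
        perfect = [
            r
            for r in rules
            if r.predicted == HEALTHY
            and len(r.conditions) == 1
            and r.conditions[0].feature == "nse_count"
            and (r.conditions[0].low, r.conditions[0].high) == (2, 5)
            and r.probability == 1.0
        ]
        assert perfect

    @pytest.mark.parametrize("dataset_name", ["separable_dataset", "noisy_dataset"])
    @pytest.mark.parametrize("max_conjunction", [1, 2])
    def test_agrees_with_bruteforce_oracle(
        self, dataset_name, max_conjunction, request
    ):
        dataset = request.getfixturevalue(dataset_name)
        cfg = MiningConfig(max_conjunction=max_conjunction)
        got = canonical_rules(mine_rules(dataset, cfg))
        expected = oracle_mine(
            dataset,
            min_probability=cfg.min_probability,
            min_support=cfg.min_support,
            max_conjunction=max_conjunction,
        )
        assert got == expected

    def test_triples_agree_with_oracle_on_tiny_data(self):
        dataset = [
            make_vector("h1", True, nse=2, atc=1, licking=3),
            make_vector("h2", True, nse=3, atc=1, licking=8),
            make_vector("h3", True, nse=2, atc=2, licking=3),
            make_vector("s1", False, nse=3, atc=2, licking=8),
            make_vector("s2", False, nse=9, atc=1, licking=3),
            make_vector("s3", False, nse=2, atc=2, licking=8),
        ]
        cfg = MiningConfig(max_conjunction=3, min_support=1, min_probability=0.9)
        got = canonical_rules(mine_rules(dataset, cfg))
        expected = oracle_mine(
            dataset, min_probability=0.9, min_support=1, max_conjunction=3
        )
        assert got == expected

    def test_threshold_monotonicity(self, noisy_dataset):
        base = canonical_rules(mine_rules(noisy_dataset, MiningConfig()))
        stricter_prob = canonical_rules(
            mine_rules(noisy_dataset, MiningConfig(min_probability=1.0))
        )
        stricter_support = canonical_rules(
            mine_rules(noisy_dataset, MiningConfig(min_support=3))
        )
        assert {r[:2] for r in stricter_prob} <= {r[:2] for r in base}
        assert {r[:2] for r in stricter_support} <= {r[:2] for r in base}

    def test_permutation_invariance(self, noisy_dataset):
        a = canonical_rules(mine_rules(noisy_dataset))
        b = canonical_rules(mine_rules(list(reversed(noisy_dataset))))
        assert a == b

    def test_self_consistency_audit(self, noisy_dataset):
        for rule in mine_rules(noisy_dataset):
            covered = [v for v in noisy_dataset if rule.matches(v)]
            n_label = sum(
                (v.healthy if rule.predicted == HEALTHY else not v.healthy)
                for v in covered
            )
            assert rule.support == n_label
            assert rule.probability == n_label / len(covered)
            assert rule.probability >= 0.8
            assert rule.support >= 2

    def test_single_label_dataset_rejected(self):
        vecs = [make_vector(f"c{i}", True, nse=i) for i in range(4)]
        with pytest.raises(ValueError, match="label"):
            mine_rules(vecs)


class TestSelectIffRuleset:
    def test_separable_reaches_perfect_success(self, separable_dataset):
        rules = mine_rules(separable_dataset)
        ruleset, report = select_iff_ruleset(rules, separable_dataset)
        assert report.success_rate == 1.0
        assert all(r.predicted == HEALTHY for r in ruleset.rules)

    @pytest.mark.parametrize("dataset_name", ["separable_dataset", "noisy_dataset"])
    def test_matches_exhaustive_subset_search(self, dataset_name, request):
        dataset = request.getfixturevalue(dataset_name)
        # restrict to single-condition rules on the NSE feature to keep the
        # exhaustive subset oracle tractable
        rules = [
            r
            for r in mine_rules(dataset, MiningConfig(max_conjunction=1))
            if r.conditions[0].feature == "nse_count"
        ]
        n_healthy = sum(r.predicted == HEALTHY for r in rules)
        assert 0 < n_healthy <= 12  # keeps the subset enumeration tractable
        ruleset, report = select_iff_ruleset(rules, dataset)
        assert report.success_rate == oracle_best_success(rules, dataset)

    def test_selection_is_deterministic(self, noisy_dataset):
        rules = mine_rules(noisy_dataset)
        a, _ = select_iff_ruleset(rules, noisy_dataset)
        b, _ = select_iff_ruleset(list(reversed(rules)), noisy_dataset)
        assert a == b

    def test_report_is_consistent_with_ruleset(self, noisy_dataset):
        rules = mine_rules(noisy_dataset)
        ruleset, report = select_iff_ruleset(rules, noisy_dataset)
        assert report == evaluate(noisy_dataset, ruleset)

    def test_no_healthy_rules_rejected(self, noisy_dataset):
        sick_only = [
            Rule(
                conditions=(r.conditions),
                predicted="sick",
                probability=r.probability,
                support=r.support,
            )
            for r in mine_rules(noisy_dataset)[:3]
        ]
        with pytest.raises(ValueError, match="healthy"):
            select_iff_ruleset(sick_only, noisy_dataset)


def test_mined_diagnostic_on_synthetic_cohort():
    """End-to-end regression: mining the default two-group cohort yields a
    rule set that classifies the training cohort well above chance."""
    sessions = generate_sessions(GeneratorConfig(n_per_group=28, seed=42))
    vectors = [parameter_vector(s) for s in sessions]
    rules = mine_rules(vectors)
    ruleset, report = select_iff_ruleset(rules, vectors)
    assert report.success_rate >= 0.7
    assert len(ruleset.rules) >= 1
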