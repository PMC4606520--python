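"""A priori engine: support counting, candidate generation, frequent
itemsets, class-association rules, maximal rules and motif annotation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kirpatterns import (
    Item,
    annotate_rule_with_motifs,
    apriori_gen,
    frequent_itemsets,
    make_itemset,
    maximal_perfect_rules,
    mine_class_association_rules,
    support_count,
    to_transactions,
)

from conftest import (
    brute_force_class_rules,
    brute_force_frequent,
    make_perfect_rule_family,
    random_transactions,
)


@pytest.fixture
def toy_tx(toy):
    return to_transactions(toy)


class TestSupportCount:
    def test_printed_first_rule_frequency(self, toy_tx):
        assert support_count(toy_tx, make_itemset(("g1", 0), ("C", 0))) == 12

    def test_empty_itemset_is_vacuously_supported(self, toy_tx):
        assert support_count(toy_tx, frozenset()) == 20

    def test_contradictory_itemset_is_unconstructible(self):
        with pytest.raises(ValueError, match="two values"):
            make_itemset(("g1", 1), ("g1", 0))

    @given(st.integers(0, 2**31 - 1))
    def test_anti_monotone_along_random_chains(self, seed):
        rng = np.random.default_rng(seed)
        tx, _ = random_transactions(rng, n_attrs=6, n_rows=15)
        items = sorted({i for t in tx for i in t})
        rng.shuffle(items)
        chain, used = [], set()
        for item in items:
            if item.attribute not in used:
                used.add(item.attribute)
                chain.append(item)
        prev = len(tx)
        for size in range(1, len(chain) + 1):
            count = support_count(tx, frozenset(chain[:size]))
            assert count <= prev
            prev = count


class TestAprioriGen:
    def test_full_join_of_attribute_distinct_singletons(self):
        singles = [make_itemset(("a", 1)), make_itemset(("b", 1)), make_itemset(("c", 0))]
        cands = apriori_gen(singles)
        assert sorted(tuple(sorted(c)) for c in cands) == [
            (Item("a", 1), Item("b", 1)),
            (Item("a", 1), Item("c", 0)),
            (Item("b", 1), Item("c", 0)),
        ]

    def test_same_attribute_values_never_join(self):
        singles = [make_itemset(("a", 0)), make_itemset(("a", 1))]
        assert apriori_gen(singles) == []

    def test_prune_discards_candidate_with_infrequent_subset(self):
        pairs = [
            make_itemset(("a", 1), ("b", 1)),
            make_itemset(("a", 1), ("c", 1)),
        ]
        # {b=1, c=1} is not frequent, so {a,b,c} must be pruned
        assert apriori_gen(pairs) == []

    def test_mixed_sizes_rejected(self):
        with pytest.raises(ValueError):
            apriori_gen([make_itemset(("a", 1)), make_itemset(("a", 1), ("b", 1))])


class TestFrequentItemsets:
    def test_toy_contains_full_disease_pattern(self, toy_tx):
        out = frequent_itemsets(toy_tx, min_support_count=1)
        level3 = dict(out[3])
        assert level3[make_itemset(("g1", 1), ("g2", 1), ("C", 1))] == 6

    def test_threshold_above_dataset_size_is_empty(self, toy_tx):
        assert frequent_itemsets(toy_tx, min_support_count=21) == {}

    def test_toy_matches_power_set_scan(self, toy_tx):
        for threshold in (1, 3, 6, 10):
            got = frequent_itemsets(toy_tx, min_support_count=threshold)
            expected = brute_force_frequent(toy_tx, threshold)
            assert {k: dict(v) for k, v in got.items()} == {
                k: dict(v) for k, v in expected.items()
            }

    def test_random_datasets_match_brute_force(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n_attrs = int(rng.integers(3, 7))
            tx, _ = random_transactions(rng, n_attrs, int(rng.integers(8, 31)))
            threshold = int(rng.integers(1, 6))
            got = frequent_itemsets(tx, threshold)
            expected = brute_force_frequent(tx, threshold)
            assert {k: dict(v) for k, v in got.items()} == {
                k: dict(v) for k, v in expected.items()
            }


class TestClassAssociationRules:
    def test_toy_mines_exactly_the_six_printed_rules(self, toy_tx):
        rs = mine_class_association_rules(toy_tx, "C", 1, 0.9, "both")
        printed = [
            ({("g1", 0)}, 0, 12),
            ({("g2", 0)}, 0, 8),
            ({("g1", 0), ("g2", 0)}, 0, 6),
            ({("g1", 0), ("g2", 1)}, 0, 6),
            ({("g1", 1), ("g2", 1)}, 1, 6),
            ({("g1", 1), ("g2", 0)}, 0, 2),
        ]
        got = [
            (
                {(i.attribute, i.value) for i in r.antecedent},
                next(iter(r.consequent)).value,
                r.support_count,
            )
            for r in rs
        ]
        assert got == printed

    def test_class_filter_keeps_single_disease_rule(self, toy_tx):
        rs = mine_class_association_rules(toy_tx, "C", 1, 0.9, 1)
        assert len(rs) == 1
        (rule,) = rs.rules
        assert rule.antecedent == make_itemset(("g1", 1), ("g2", 1))
        assert rule.support_count == 6 and rule.confidence == 1.0

    def test_sub_threshold_confidence_excluded(self, toy_tx):
        # confidence of g1=1 => C=1 is 6/8 = 0.75
        rs = mine_class_association_rules(toy_tx, "C", 1, 0.75, 1)
        assert make_itemset(("g1", 1)) in [r.antecedent for r in rs]
        rs = mine_class_association_rules(toy_tx, "C", 1, 0.9, 1)
        assert make_itemset(("g1", 1)) not in [r.antecedent for r in rs]

    def test_invalid_thresholds_rejected(self, toy_tx):
        with pytest.raises(ValueError):
            mine_class_association_rules(toy_tx, "C", 1, 1.5)
        with pytest.raises(ValueError):
            mine_class_association_rules(toy_tx, "C", 0, 0.9)

    def test_random_datasets_match_brute_force(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            n_attrs = int(rng.integers(3, 7))
            tx, cls = random_transactions(rng, n_attrs, int(rng.integers(8, 31)))
            min_count = int(rng.integers(1, 5))
            min_conf = float(rng.choice([0.5, 0.8, 0.9, 1.0]))
            rs = mine_class_association_rules(tx, cls, min_count, min_conf, "both")
            got = {(r.antecedent, r.consequent, r.support_count) for r in rs}
            assert got == brute_force_class_rules(tx, cls, min_count, min_conf)

    def test_metric_identities(self):
        rng = np.random.default_rng(123)
        tx, cls = random_transactions(rng, 5, 30)
        rs = mine_class_association_rules(tx, cls, 1, 0.0, "both")
        n = len(tx)
        for r in rs:
            ant_supp = support_count(tx, r.antecedent)
            joint = support_count(tx, r.antecedent | r.consequent)
            assert r.support_count == joint
            assert r.confidence * ant_supp == pytest.approx(joint, abs=1e-9)
            assert r.support == pytest.approx(joint / n)
            cons_supp = support_count(tx, r.consequent)
            assert r.correlation == pytest.approx(
                (joint / n) / ((ant_supp / n) * (cons_supp / n))
            )
            # lift is symmetric in antecedent and consequent
            assert r.correlation == pytest.approx(
                (joint / n) / ((cons_supp / n) * (ant_supp / n))
            )

    def test_perfect_confidence_rules_have_no_counterexamples(self):
        rng = np.random.default_rng(321)
        tx, cls = random_transactions(rng, 6, 25)
        rs = mine_class_association_rules(tx, cls, 1, 1.0, "both")
        for r in rs:
            for t in tx:
                if r.antecedent <= t:
                    assert r.consequent <= t

    def test_max_antecedent_cap(self, toy_tx):
        rs = mine_class_association_rules(toy_tx, "C", 1, 0.9, "both", max_antecedent=1)
        assert all(len(r.antecedent) == 1 for r in rs)
        assert len(rs) == 2


class TestMaximalRules:
    def test_published_family_reduces_to_the_eight_condition_rule(self, rule_family):
        maximal = maximal_perfect_rules(rule_family)
        assert len(maximal) == 1
        assert len(maximal[0].antecedent) == 8
        assert maximal[0].antecedent == make_itemset(
            ("2DL1", 1), ("2DL2", 1), ("2DL3", 1), ("2DL5", 1),
            ("2DS2", 0), ("2DS4", 1), ("2DP1", 1), ("3DL1", 1),
        )

    def test_single_rule_is_its_own_maximum(self, rule_family):
        assert maximal_perfect_rules([rule_family[0]]) == [rule_family[0]]

    def test_empty_ruleset_gives_empty_list(self):
        assert maximal_perfect_rules([]) == []

    def test_different_support_groups_kept_separately(self, rule_family):
        from dataclasses import replace

        other = replace(rule_family[0], support_count=11, support=11 / 343)
        maximal = maximal_perfect_rules(rule_family + [other])
        assert len(maximal) == 2
        assert {r.support_count for r in maximal} == {10, 11}


class TestMotifAnnotation:
    def test_maximal_rule_carries_inhibitory_motifs(self, rule_family):
        motifs = annotate_rule_with_motifs(rule_family[-1])
        assert motifs == ["cA01", "tA01"]

    def test_cb03_motif_detected(self):
        from kirpatterns import AssociationRule

        rule = AssociationRule(
            antecedent=make_itemset(
                ("2DL3", 1), ("2DL5", 1), ("2DS5", 1), ("2DP1", 1), ("2DL1", 1)
            ),
            consequent=frozenset({Item("disease", 1)}),
            support_count=1, support=0.1, confidence=1.0, correlation=1.0,
        )
        assert "cB03" in annotate_rule_with_motifs(rule)

    def test_absence_conditions_do_not_satisfy_motifs(self, rule_family):
        # 2DS2=0 appears in the antecedent but must not count as carriage
        motifs = annotate_rule_with_motifs(
            rule_family[-1], {"fake": frozenset({"2DS2"})}
        )
        assert motifs == []
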