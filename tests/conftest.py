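"""Shared fixtures: the toy cohort, typing-report table excerpt, the
published 24-rule family, and brute-force mining oracles."""

from itertools import combinations, product
from math import comb

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kirpatterns import AssociationRule, Cohort, GenotypeRecord, Item, toy_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy() -> Cohort:
    return toy_fixture()


#: Excerpt of a typing report: ✓/blank cells, KIR-prefixed mixed-case
#: headers, class column last (rows 1-5 diseased, 341-343 healthy).
TYPING_REPORT_TSV = """\
Id\tKIR2DL1\tkir2dl2\t2DL3\t2DL5\t2DS1\t2DS2\t2DS3\t2DS4\t2DS5\t2DP1\t3DL1\t3DS1\tDisease
1\t✓\t✓\t✓\t\t\t✓\t\t✓\t\t✓\t\t\t1
2\t✓\t✓\t\t\t\t\t\t✓\t\t✓\t✓\t\t1
3\t✓\t\t✓\t\t\t\t\t✓\t\t✓\t✓\t\t1
4\t✓\t\t✓\t\t\t\t\t✓\t\t✓\t✓\t\t1
5\t✓\t\t✓\t✓\t✓\t\t\t✓\t✓\t✓\t✓\t✓\t1
341\t✓\t\t✓\t\t\t\t\t✓\t\t✓\t✓\t\t0
342\t✓\t\t✓\t\t\t\t\t✓\t\t✓\t✓\t\t0
343\t✓\t✓\t\t✓\t✓\t✓\t\t\t✓\t\t\t✓\t0
"""


@pytest.fixture
def typing_report_tsv() -> str:
    return TYPING_REPORT_TSV


#: The 8 conditions of the published maximal disease rule.
DISEASE_PATTERN_CONDITIONS: tuple[tuple[str, int], ...] = (
    ("2DL1", 1), ("2DL2", 1), ("2DL3", 1), ("2DL5", 1),
    ("2DS2", 0), ("2DS4", 1), ("2DP1", 1), ("3DL1", 1),
)

#: Condition-index subsets of the 24 published rules sharing frequency 10
#: (last one = the full 8-condition rule).
_RULE_FAMILY_INDEX_SETS = (
    (1, 3, 4, 5), (1, 3, 4, 7), (0, 1, 3, 4, 5), (0, 1, 3, 4, 7),
    (1, 2, 3, 4, 5), (1, 2, 3, 4, 7), (1, 3, 4, 5, 6), (1, 3, 4, 5, 7),
    (1, 3, 4, 6, 7), (0, 1, 2, 3, 4, 5), (0, 1, 2, 3, 4, 7),
    (0, 1, 3, 4, 5, 6), (0, 1, 3, 4, 5, 7), (0, 1, 3, 4, 6, 7),
    (1, 2, 3, 4, 5, 6), (1, 2, 3, 4, 5, 7), (1, 2, 3, 4, 6, 7),
    (1, 3, 4, 5, 6, 7), (0, 1, 2, 3, 4, 5, 6), (0, 1, 2, 3, 4, 5, 7),
    (0, 1, 2, 3, 4, 6, 7), (0, 1, 3, 4, 5, 6, 7), (1, 2, 3, 4, 5, 6, 7),
    (0, 1, 2, 3, 4, 5, 6, 7),
)


def make_perfect_rule_family() -> list[AssociationRule]:
    """The published 24-rule family: every antecedent a sub-pattern of
    the 8-condition rule, all with support count 10, consequent class 1."""
    rules = []
    for idx in _RULE_FAMILY_INDEX_SETS:
        antecedent = frozenset(Item(*DISEASE_PATTERN_CONDITIONS[i]) for i in idx)
        rules.append(
            AssociationRule(
                antecedent=antecedent,
                consequent=frozenset({Item("disease", 1)}),
                support_count=10,
                support=10 / 343,
                confidence=1.0,
                correlation=(10 / 343) / ((10 / 343) * (43 / 343)),
            )
        )
    return rules


@pytest.fixture
def rule_family() -> list[AssociationRule]:
    return make_perfect_rule_family()


# ---------------------------------------------------------------- oracles

def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct exact enumeration over the support
    of the hypergeometric distribution (fixed margins)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if r1 in (0, n) or c1 in (0, n):
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = [comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    return sum(w for w in weights if w <= observed) / comb(n, c1)


def brute_force_frequent(transactions, min_count):
    """Power-set scan over all attribute-consistent itemsets."""
    attrs = sorted({it.attribute for t in transactions for it in t})
    out = {}
    for r in range(1, len(attrs) + 1):
        for chosen in combinations(attrs, r):
            for vals in product((0, 1), repeat=r):
                s = frozenset(Item(a, v) for a, v in zip(chosen, vals))
                count = sum(1 for t in transactions if s <= t)
                if count >= min_count:
                    out.setdefault(r, []).append((s, count))
    return out


def brute_force_class_rules(
    transactions, class_attribute, min_count, min_conf, class_values=(0, 1)
):
    """Direct enumeration of every class-association rule."""
    attrs = sorted(
        {it.attribute for t in transactions for it in t} - {class_attribute}
    )
    rules = set()
    for value in class_values:
        consequent = frozenset({Item(class_attribute, value)})
        for r in range(1, len(attrs) + 1):
            for chosen in combinations(attrs, r):
                for vals in product((0, 1), repeat=r):
                    ant = frozenset(Item(a, v) for a, v in zip(chosen, vals))
                    ant_count = sum(1 for t in transactions if ant <= t)
                    joint = sum(
                        1 for t in transactions if ant <= t and consequent <= t
                    )
                    if joint >= min_count and ant_count and joint / ant_count >= min_conf:
                        rules.add((ant, consequent, joint))
    return rules


def random_transactions(rng: np.random.Generator, n_attrs: int, n_rows: int):
    """Random binary dataset in transaction encoding; last attribute
    plays the class role."""
    attrs = [f"a{i}" for i in range(n_attrs - 1)] + ["cls"]
    mat = rng.integers(0, 2, size=(n_rows, n_attrs))
    return [
        frozenset(Item(a, int(v)) for a, v in zip(attrs, row)) for row in mat
    ], "cls"


def random_cohort(rng: np.random.Generator, n: int = 10) -> Cohort:
    from kirpatterns import KIR_GENES

    records = []
    labels = rng.integers(0, 2, size=n)
    if labels.sum() in (0, n):  # keep both classes present
        labels[0], labels[1] = 0, 1
    for i in range(n):
        records.append(
            GenotypeRecord(
                f"s{i}",
                {g: int(v) for g, v in zip(KIR_GENES, rng.integers(0, 2, 12))},
                int(labels[i]),
            )
        )
    return Cohort(records)
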