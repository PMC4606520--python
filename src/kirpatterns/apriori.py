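"""Levelwise (a priori) frequent-itemset mining and class-association
rules over binary attribute=value transactions.

Both values of every attribute are items — ``gene=0`` is as much a
condition as ``gene=1`` — so rules can assert absence.  Rule quality is
measured by support (joint occurrence fraction of antecedent and
consequent), the absolute support count ("frequency"), confidence
(conditional frequency of the consequent given the antecedent) and
correlation (lift: joint probability over the product of marginals).

Support counting uses one arbitrary-precision integer bitmask per item
(bit i set iff transaction i contains the item); the support of an
itemset is the popcount of the AND of its item masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .cohort import Item
from .genes import DEFAULT_MOTIFS

Transaction = frozenset[Item]
Itemset = frozenset[Item]


def make_itemset(*items: tuple[str, int] | Item) -> Itemset:
    """Build an attribute-consistent itemset; contradictions are a type
    error, not a zero-support query."""
    typed = frozenset(Item(a, v) for a, v in items)
    attrs = {it.attribute for it in typed}
    if len(attrs) != len(typed):
        raise ValueError(f"itemset asserts two values for one attribute: {sorted(typed)}")
    return typed


def _check_consistent(itemset: Iterable[Item]) -> Itemset:
    return make_itemset(*itemset)


@dataclass(frozen=True)
class AssociationRule:
    """A mined rule X => Y with its quality measures."""

    antecedent: Itemset
    consequent: Itemset
    support_count: int
    support: float
    confidence: float
    correlation: float

    def __post_init__(self) -> None:
        shared = {i.attribute for i in self.antecedent} & {
            i.attribute for i in self.consequent
        }
        if shared:
            raise ValueError(f"antecedent and consequent share attribute(s) {shared}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    def sort_key(self):
        return (
            -self.confidence,
            -self.support_count,
            len(self.antecedent),
            tuple(sorted(self.antecedent)),
            tuple(sorted(self.consequent)),
        )

    def __str__(self) -> str:
        ant = " ∧ ".join(f"{a}={v}" for a, v in sorted(self.antecedent))
        con = " ∧ ".join(f"{a}={v}" for a, v in sorted(self.consequent))
        return f"IF {ant} THEN {con} ({self.support_count})"


@dataclass
class RuleSet:
    rules: list[AssociationRule]
    mining_config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


class _TransactionIndex:
    """Item -> bitmask index over a transaction list."""

    def __init__(self, transactions: Sequence[Transaction]):
        self.n = len(transactions)
        self.masks: dict[Item, int] = {}
        for i, t in enumerate(transactions):
            bit = 1 << i
            for item in t:
                self.masks[item] = self.masks.get(item, 0) | bit

    def mask(self, itemset: Iterable[Item]) -> int:
        m = (1 << self.n) - 1
        for item in itemset:
            m &= self.masks.get(item, 0)
            if not m:
                return 0
        return m

    def count(self, itemset: Iterable[Item]) -> int:
        return self.mask(itemset).bit_count()


def support_count(transactions: Sequence[Transaction], itemset: Iterable[Item]) -> int:
    """Number of transactions containing every item of ``itemset``.

    The empty itemset is vacuously contained in every transaction.
    """
    itemset = _check_consistent(itemset)
    return _TransactionIndex(transactions).count(itemset)


def apriori_gen(frequent_prev: Sequence[Itemset]) -> list[Itemset]:
    """Candidate generation: join (k-1)-sets sharing k-2 items, then
    prune candidates with any infrequent (k-1)-subset or two values of
    one attribute."""
    if not frequent_prev:
        return []
    sizes = {len(s) for s in frequent_prev}
    if len(sizes) != 1:
        raise ValueError(f"input itemsets must share one size, got sizes {sorted(sizes)}")
    k_minus_1 = sizes.pop()
    prev_set = set(frequent_prev)
    sorted_tuples = sorted(tuple(sorted(s)) for s in frequent_prev)

    # group by shared (k-2)-prefix to join in O(groups * pairs)
    groups: dict[tuple, list[tuple]] = {}
    for t in sorted_tuples:
        groups.setdefault(t[:-1], []).append(t)

    candidates: list[Itemset] = []
    for prefix, members in groups.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a_last, b_last = members[i][-1], members[j][-1]
                if a_last.attribute == b_last.attribute:
                    continue  # would assert two values of one attribute
                cand = frozenset(members[i]) | {b_last}
                if all(cand - {item} in prev_set for item in cand):
                    candidates.append(cand)
    return sorted(candidates, key=lambda s: tuple(sorted(s)))


def frequent_itemsets(
    transactions: Sequence[Transaction],
    min_support_count: int = 1,
    max_size: int | None = None,
) -> dict[int, list[tuple[Itemset, int]]]:
    """Levelwise enumeration of all itemsets with support >= threshold."""
    if min_support_count < 1:
        raise ValueError("min_support_count must be >= 1")
    index = _TransactionIndex(transactions)
    items = sorted(index.masks)
    level = [
        frozenset({it}) for it in items
        if index.masks[it].bit_count() >= min_support_count
    ]
    out: dict[int, list[tuple[Itemset, int]]] = {}
    k = 1
    while level and (max_size is None or k <= max_size):
        out[k] = [(s, index.count(s)) for s in sorted(level, key=lambda s: tuple(sorted(s)))]
        level = [
            c for c in apriori_gen(list(level))
            if index.count(c) >= min_support_count
        ]
        k += 1
    return out


def mine_class_association_rules(
    transactions: Sequence[Transaction],
    class_attribute: str,
    min_support_count: int = 1,
    min_confidence: float = 0.9,
    class_value_filter: Literal[0, 1, "both"] = "both",
    max_antecedent: int | None = None,
) -> RuleSet:
    """Mine rules whose consequent is a single class item.

    The engine runs one levelwise pass per requested class value over
    *antecedent* itemsets, using the joint support with the class item
    as the (anti-monotone) frequency measure; this yields exactly the
    rules with joint support >= ``min_support_count``, from which those
    with confidence >= ``min_confidence`` are kept.  Output order is
    deterministic: confidence desc, support count desc, antecedent size
    asc, then lexicographic.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence {min_confidence} outside [0, 1]")
    if min_support_count < 1:
        raise ValueError("min_support_count must be >= 1")
    index = _TransactionIndex(transactions)
    n = index.n
    class_values = [0, 1] if class_value_filter == "both" else [int(class_value_filter)]
    non_class_items = sorted(
        it for it in index.masks if it.attribute != class_attribute
    )

    rules: list[AssociationRule] = []
    for value in class_values:
        class_item = Item(class_attribute, value)
        class_mask = index.masks.get(class_item, 0)
        class_supp = class_mask.bit_count()
        if class_supp < min_support_count:
            continue
        level = [
            frozenset({it}) for it in non_class_items
            if (index.masks[it] & class_mask).bit_count() >= min_support_count
        ]
        size = 1
        while level and (max_antecedent is None or size <= max_antecedent):
            for antecedent in level:
                ant_mask = index.mask(antecedent)
                joint = (ant_mask & class_mask).bit_count()
                ant_supp = ant_mask.bit_count()
                confidence = joint / ant_supp
                if confidence >= min_confidence:
                    rules.append(
                        AssociationRule(
                            antecedent=antecedent,
                            consequent=frozenset({class_item}),
                            support_count=joint,
                            support=joint / n,
                            confidence=confidence,
                            correlation=(joint / n) / ((ant_supp / n) * (class_supp / n)),
                        )
                    )
            level = [
                c for c in apriori_gen(list(level))
                if (index.mask(c) & class_mask).bit_count() >= min_support_count
            ]
            size += 1

    rules.sort(key=AssociationRule.sort_key)
    return RuleSet(
        rules,
        mining_config={
            "class_attribute": class_attribute,
            "min_support_count": min_support_count,
            "min_confidence": min_confidence,
            "class_value_filter": class_value_filter,
            "max_antecedent": max_antecedent,
            "n_transactions": n,
        },
    )


def maximal_perfect_rules(
    ruleset: RuleSet | Sequence[AssociationRule],
) -> list[AssociationRule]:
    """Drop every rule whose antecedent is a proper subset of another
    rule's antecedent with the same support count and consequent.

    When a whole family of rules shares one frequency because they are
    derivations of a single pattern, only the largest antecedent — the
    pattern itself — survives.
    """
    rules = list(ruleset.rules if isinstance(ruleset, RuleSet) else ruleset)
    groups: dict[tuple, list[AssociationRule]] = {}
    for r in rules:
        groups.setdefault((tuple(sorted(r.consequent)), r.support_count), []).append(r)
    keep = []
    for members in groups.values():
        for r in members:
            if not any(r.antecedent < other.antecedent for other in members):
                keep.append(r)
    keep.sort(
        key=lambda r: (-r.support_count, -len(r.antecedent), tuple(sorted(r.antecedent)))
    )
    return keep


def annotate_rule_with_motifs(
    rule: AssociationRule,
    motif_table: Mapping[str, frozenset[str]] | None = None,
) -> list[str]:
    """Name the haplotype motifs whose gene complements are all asserted
    present (=1) in the rule's antecedent."""
    table = DEFAULT_MOTIFS if motif_table is None else motif_table
    present = {it.attribute for it in rule.antecedent if it.value == 1}
    return [name for name, required in table.items() if required <= present]
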