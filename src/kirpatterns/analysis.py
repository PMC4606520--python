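"""Whole-cohort analysis as a model/results pair.

:class:`KirPatternAnalysis` is constructed from a cohort plus the
analysis configuration; :meth:`fit` runs the stages in order —
univariate per-gene scan, exhaustive multivariate AND-combination
scan, class-association rule mining, maximal-rule extraction with
haplotype-motif annotation, decision-tree induction, and the head-to-
head contingency comparison of the best gene combination against the
best mined rule — returning a :class:`KirPatternResults` that carries
every table, exposes ``summary()``, and serialises to JSON/TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from . import contingency as cst
from .apriori import (
    AssociationRule,
    RuleSet,
    annotate_rule_with_motifs,
    maximal_perfect_rules,
    mine_class_association_rules,
)
from .cohort import Cohort, to_transactions
from .contingency import CombinationResult, ContingencyTable2x2, TestResult
from .genes import DEFAULT_MOTIFS
from .io import read_genotype_table
from .tree import TreeNode, build_tree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonReport:
    """Best statistical combination vs best mined rule, on one cohort."""

    gene_subset: tuple[str, ...]
    combination_table: ContingencyTable2x2
    combination_chi2: TestResult
    combination_fisher: TestResult
    rule: AssociationRule
    rule_table: ContingencyTable2x2
    rule_chi2: TestResult
    rule_fisher: TestResult


def rule_antecedent_table(cohort: Cohort, rule: AssociationRule) -> ContingencyTable2x2:
    """Cross-tabulate antecedent satisfaction (all conditions hold,
    including absence conditions) against class."""
    conditions = {it.attribute: it.value for it in rule.antecedent}
    unknown = set(conditions) - set(cohort.genes)
    if unknown:
        raise KeyError(f"rule tests unknown attribute(s) {sorted(unknown)}")
    a = b = c = d = 0
    for rec in cohort.records:
        sat = all(rec.gene_presence[g] == v for g, v in conditions.items())
        if rec.class_label == 1:
            a, c = a + sat, c + (not sat)
        else:
            b, d = b + sat, d + (not sat)
    return ContingencyTable2x2(a, b, c, d)


def rule_vs_combination_comparison(
    cohort: Cohort, gene_subset: tuple[str, ...], rule: AssociationRule
) -> ComparisonReport:
    """Build both 2x2 tables — AND-carriage of the gene subset vs class,
    and rule-antecedent satisfaction vs class — with chi2 and Fisher."""
    comb_table = cst.make_combination_table(cohort, gene_subset)
    rule_table = rule_antecedent_table(cohort, rule)
    return ComparisonReport(
        gene_subset=tuple(gene_subset),
        combination_table=comb_table,
        combination_chi2=cst.pearson_chi2(comb_table),
        combination_fisher=cst.fisher_exact_two_sided(comb_table),
        rule=rule,
        rule_table=rule_table,
        rule_chi2=cst.pearson_chi2(rule_table),
        rule_fisher=cst.fisher_exact_two_sided(rule_table),
    )


class KirPatternAnalysis:
    """Model object: a cohort plus analysis configuration.

    Parameters mirror the analysis protocol: ``min_support_count`` is
    an absolute record count (default 1 — keep every observed pattern),
    ``min_confidence`` the rule-confidence threshold (default 0.9),
    ``class_value`` the consequent of interest (default 1, disease;
    ``"both"`` mines both consequents), ``alpha`` the significance
    level of the combination scan on raw p-values, with optional
    Bonferroni/Benjamini-Hochberg adjustment.
    """

    def __init__(
        self,
        cohort: Cohort,
        class_value: Literal[0, 1, "both"] = 1,
        min_support_count: int = 1,
        min_confidence: float = 0.9,
        alpha: float = 0.05,
        correction: Literal[None, "bonferroni", "bh"] = None,
        max_antecedent: int | None = None,
        motif_table: Mapping[str, frozenset[str]] | None = None,
        tree_max_depth: int | None = None,
        tree_min_leaf: int = 1,
        tree_prune: bool = False,
        seed: int = 0,
    ):
        self.cohort = cohort
        self.class_value = class_value
        self.min_support_count = min_support_count
        self.min_confidence = min_confidence
        self.alpha = alpha
        self.correction = correction
        self.max_antecedent = max_antecedent
        self.motif_table = dict(motif_table) if motif_table is not None else dict(DEFAULT_MOTIFS)
        self.tree_max_depth = tree_max_depth
        self.tree_min_leaf = tree_min_leaf
        self.tree_prune = tree_prune
        self.seed = seed

    @classmethod
    def from_csv(cls, path, class_column: str | None = None, genes=None, **config):
        return cls(read_genotype_table(path, genes=genes, class_column=class_column), **config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, class_column: str = "disease",
                       genes=None, **config):
        return cls(Cohort.from_dataframe(df, genes=genes, class_column=class_column), **config)

    def config_dict(self) -> dict:
        return {
            "class_value": self.class_value,
            "min_support_count": self.min_support_count,
            "min_confidence": self.min_confidence,
            "alpha": self.alpha,
            "correction": self.correction,
            "max_antecedent": self.max_antecedent,
            "tree_max_depth": self.tree_max_depth,
            "tree_min_leaf": self.tree_min_leaf,
            "tree_prune": self.tree_prune,
            "seed": self.seed,
        }

    def fit(self) -> "KirPatternResults":
        cohort = self.cohort
        logger.info(
            "cohort: %d donors (%d diseased, %d healthy), %d genes",
            len(cohort), cohort.n_diseased, cohort.n_healthy, len(cohort.genes),
        )
        univariate = cst.univariate_scan(cohort)
        combos, n_tested = cst.multivariate_scan(
            cohort, min_size=2, alpha=self.alpha, correction=self.correction
        )
        n_sig = sum(r.significant for r in combos)
        logger.info("combinations tested: %d; significant at alpha=%g: %d",
                    n_tested, self.alpha, n_sig)

        rules = mine_class_association_rules(
            to_transactions(cohort),
            class_attribute=cohort.class_attribute,
            min_support_count=self.min_support_count,
            min_confidence=self.min_confidence,
            class_value_filter=self.class_value,
            max_antecedent=self.max_antecedent,
        )
        n_class1 = sum(
            1 for r in rules if any(i.value == 1 for i in r.consequent)
        )
        logger.info("rules mined: %d (consequent class 1: %d)", len(rules), n_class1)

        perfect = [r for r in rules if r.confidence == 1.0]
        maximal = maximal_perfect_rules(perfect)
        annotations = {
            r: annotate_rule_with_motifs(r, self.motif_table) for r in maximal
        }
        logger.info("confidence-1.0 rules: %d; maximal: %d", len(perfect), len(maximal))

        tree = build_tree(
            cohort, max_depth=self.tree_max_depth, min_leaf=self.tree_min_leaf,
            prune=self.tree_prune, seed=self.seed,
        )

        comparison = None
        sig = [r for r in combos if r.significant] or combos
        best_combo = min(sig, key=lambda r: (r.result.p_value, r.gene_subset))
        best_rule = next(
            (r for r in maximal if any(i.value == 1 for i in r.consequent)), None
        )
        if best_rule is not None:
            comparison = rule_vs_combination_comparison(
                cohort, best_combo.gene_subset, best_rule
            )
        return KirPatternResults(
            model=self, univariate=univariate, combinations=combos,
            n_combinations_tested=n_tested, rules=rules, maximal_rules=maximal,
            rule_annotations=annotations, tree=tree, comparison=comparison,
        )


def _rule_record(rule: AssociationRule, motifs=None) -> dict:
    rec = {
        "antecedent": {i.attribute: i.value for i in sorted(rule.antecedent)},
        "consequent": {i.attribute: i.value for i in sorted(rule.consequent)},
        "support_count": rule.support_count,
        "support": rule.support,
        "confidence": rule.confidence,
        "correlation": rule.correlation,
    }
    if motifs is not None:
        rec["motifs"] = motifs
    return rec


def _table_dict(t: ContingencyTable2x2) -> dict:
    return {"a": t.a, "b": t.b, "c": t.c, "d": t.d}


class KirPatternResults:
    """Fitted analysis: every stage's output plus reporting helpers."""

    def __init__(self, model, univariate, combinations, n_combinations_tested,
                 rules, maximal_rules, rule_annotations, tree, comparison):
        self.model = model
        self.univariate: dict[str, TestResult] = univariate
        self.combinations: list[CombinationResult] = combinations
        self.n_combinations_tested: int = n_combinations_tested
        self.rules: RuleSet = rules
        self.maximal_rules: list[AssociationRule] = maximal_rules
        self.rule_annotations: dict[AssociationRule, list[str]] = rule_annotations
        self.tree: TreeNode = tree
        self.comparison: ComparisonReport | None = comparison

    # -- tabular views -------------------------------------------------
    def univariate_frame(self) -> pd.DataFrame:
        rows = []
        for gene, res in self.univariate.items():
            table = cst.make_combination_table(self.model.cohort, [gene])
            fisher = cst.fisher_exact_two_sided(table)
            rows.append({
                "gene": gene, "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "chi2": res.chi2, "p_chi2": res.p_value, "p_fisher": fisher.p_value,
                "significant": res.p_value <= self.model.alpha and not res.degenerate,
            })
        return pd.DataFrame(rows)

    def combinations_frame(self, significant_only: bool = False) -> pd.DataFrame:
        rows = []
        for r in self.combinations:
            if significant_only and not r.significant:
                continue
            rows.append({
                "genes": "+".join(r.gene_subset), "size": len(r.gene_subset),
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "chi2": r.result.chi2, "p_chi2": r.result.p_value,
                "p_fisher": r.fisher.p_value if r.fisher else float("nan"),
                "significant": r.significant,
            })
        return pd.DataFrame(rows)

    def rules_frame(self, maximal_only: bool = False) -> pd.DataFrame:
        """Tabular rule layout: one column per attribute (blank when the
        rule does not constrain it), plus frequency and metrics."""
        genes = self.model.cohort.genes
        rows = []
        for rule in (self.maximal_rules if maximal_only else self.rules):
            cond = {i.attribute: i.value for i in rule.antecedent}
            row = {g: (f"{g}={cond[g]}" if g in cond else "") for g in genes}
            row["consequent"] = " ".join(
                f"{i.attribute}={i.value}" for i in sorted(rule.consequent)
            )
            row["frequency"] = rule.support_count
            row["confidence"] = rule.confidence
            row["correlation"] = rule.correlation
            rows.append(row)
        return pd.DataFrame(rows)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        cohort = self.model.cohort
        lines = [
            "KIR pattern analysis",
            "=" * 60,
            f"cohort: {len(cohort)} donors "
            f"({cohort.n_diseased} diseased / {cohort.n_healthy} healthy); "
            f"{len(cohort.genes)} genes",
            "",
            "Univariate scan (chi-square, 1 d.f., no continuity correction)",
            self.univariate_frame().to_string(index=False),
            "",
            f"Multivariate AND-combination scan: {self.n_combinations_tested} "
            f"combinations tested, "
            f"{sum(r.significant for r in self.combinations)} significant "
            f"at alpha={self.model.alpha}",
        ]
        top = self.combinations_frame().nsmallest(5, "p_chi2")
        lines += [top.to_string(index=False), ""]
        lines += [
            f"Class-association rules: {len(self.rules)} mined "
            f"(min support count {self.model.min_support_count}, "
            f"min confidence {self.model.min_confidence})",
            f"maximal confidence-1.0 rules: {len(self.maximal_rules)}",
        ]
        for rule in self.maximal_rules[:10]:
            motifs = self.rule_annotations.get(rule, [])
            suffix = f"   [motifs: {', '.join(motifs)}]" if motifs else ""
            lines.append(f"  {rule}{suffix}")
        lines += ["", "Decision tree (information gain):", self.tree.render()]
        if self.comparison is not None:
            c = self.comparison
            lines += [
                "",
                "Comparison — best combination vs best rule",
                f"  combination {'+'.join(c.gene_subset)}: "
                f"table {_table_dict(c.combination_table)} "
                f"chi2={c.combination_chi2.chi2:.2f} p={c.combination_chi2.p_value:.2g}",
                f"  rule {c.rule}: table {_table_dict(c.rule_table)} "
                f"chi2={c.rule_chi2.chi2:.2f} p={c.rule_chi2.p_value:.2g}",
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "config": self.model.config_dict(),
            "cohort": {
                "n": len(self.model.cohort),
                "n_diseased": self.model.cohort.n_diseased,
                "n_healthy": self.model.cohort.n_healthy,
                "genes": list(self.model.cohort.genes),
                "provenance": self.model.cohort.provenance,
            },
            "univariate": {
                g: {"chi2": r.chi2, "p": r.p_value, "degenerate": r.degenerate}
                for g, r in self.univariate.items()
            },
            "multivariate": {
                "n_tested": self.n_combinations_tested,
                "n_significant": sum(r.significant for r in self.combinations),
                "significant": [
                    {
                        "genes": list(r.gene_subset), **_table_dict(r.table),
                        "chi2": r.result.chi2, "p": r.result.p_value,
                    }
                    for r in self.combinations if r.significant
                ],
            },
            "rules": {
                "n": len(self.rules),
                "mining_config": self.rules.mining_config,
                "rules": [_rule_record(r) for r in self.rules],
            },
            "maximal_rules": [
                _rule_record(r, self.rule_annotations.get(r, []))
                for r in self.maximal_rules
            ],
            "tree": self.tree.to_dict(),
        }
        if self.comparison is not None:
            c = self.comparison
            out["comparison"] = {
                "combination": {
                    "genes": list(c.gene_subset),
                    "table": _table_dict(c.combination_table),
                    "chi2": c.combination_chi2.chi2,
                    "p_chi2": c.combination_chi2.p_value,
                    "p_fisher": c.combination_fisher.p_value,
                },
                "rule": {
                    **_rule_record(c.rule),
                    "table": _table_dict(c.rule_table),
                    "chi2": c.rule_chi2.chi2,
                    "p_chi2": c.rule_chi2.p_value,
                    "p_fisher": c.rule_fisher.p_value,
                },
            }
        return out

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def write_report(self, out_dir: str | Path) -> None:
        """Write report.json, rules.tsv, combinations.tsv, tree.txt and
        comparison.tsv under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n")
        self.rules_frame().to_csv(out / "rules.tsv", sep="\t", index=False)
        self.combinations_frame().to_csv(out / "combinations.tsv", sep="\t", index=False)
        (out / "tree.txt").write_text(self.tree.render() + "\n")
        rows = []
        if self.comparison is not None:
            c = self.comparison
            rows = [
                {
                    "kind": "combination", "definition": "+".join(c.gene_subset),
                    **_table_dict(c.combination_table),
                    "chi2": c.combination_chi2.chi2,
                    "p_chi2": c.combination_chi2.p_value,
                    "p_fisher": c.combination_fisher.p_value,
                },
                {
                    "kind": "rule", "definition": str(c.rule),
                    **_table_dict(c.rule_table),
                    "chi2": c.rule_chi2.chi2,
                    "p_chi2": c.rule_chi2.p_value,
                    "p_fisher": c.rule_fisher.p_value,
                },
            ]
        pd.DataFrame(rows).to_csv(out / "comparison.tsv", sep="\t", index=False)
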