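"""2x2 contingency analysis: per-gene scans and exhaustive AND-combination
scans of gene subsets against disease class.

Cell convention throughout (rows = trait, columns = class):

    a = diseased carriers      b = healthy carriers
    c = diseased non-carriers  d = healthy non-carriers

where "carrier" for a gene subset means every gene in the subset is
present (logical AND).  The Pearson statistic is the uncorrected
cross-product form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); no continuity
correction is applied.  The two-sided Fisher p sums the hypergeometric
probabilities of all tables with the same margins that are no more
probable than the observed one, evaluated in exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Literal

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort
from .exceptions import SingleClassError
from .genes import normalize_gene


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell count in {cells}")
        if sum(cells) < 1:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(trait present, trait absent, class 1, class 0) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def expected(self) -> tuple[float, float, float, float]:
        r1, r2, c1, c2 = self.margins
        n = self.n
        return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)


@dataclass(frozen=True)
class TestResult:
    chi2: float | None
    p_value: float
    method: Literal["pearson_chi2", "fisher_exact"]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.chi2 is not None and self.chi2 < 0:
            raise ValueError(f"negative chi2 {self.chi2}")


@dataclass(frozen=True)
class CombinationResult:
    gene_subset: tuple[str, ...]
    table: ContingencyTable2x2
    result: TestResult
    fisher: TestResult | None = None
    significant: bool = False
    p_adjusted: float | None = None


def pearson_chi2(table: ContingencyTable2x2) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table (1 d.f.).

    A zero margin makes the statistic undefined; such tables yield a
    degenerate result (chi2 = 0, p = 1, ``degenerate=True``) rather
    than an exception.
    """
    if any(m == 0 for m in table.margins):
        return TestResult(0.0, 1.0, "pearson_chi2", degenerate=True)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = table.margins
    stat = table.n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return TestResult(float(stat), float(_chi2_dist.sf(stat, 1)), "pearson_chi2")


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact p by exact hypergeometric enumeration.

    With margins fixed, every admissible table's probability has the
    form C(r1,k)C(r2,c1-k)/C(n,c1); integer numerators are compared
    exactly, so probability ties need no floating-point tolerance.
    """
    if any(m == 0 for m in table.margins):
        return TestResult(None, 1.0, "fisher_exact", degenerate=True)
    r1, _, c1, _ = table.margins
    n = table.n
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    observed = weights[table.a]
    p = sum(w for w in weights.values() if w <= observed) / comb(n, c1)
    return TestResult(None, float(p), "fisher_exact")


def make_combination_table(
    cohort: Cohort, gene_subset: Iterable[str]
) -> ContingencyTable2x2:
    """Cross-tabulate joint carriage of a gene subset against class.

    A donor counts as trait-present iff *all* genes of the subset are
    present (AND combination).
    """
    subset = [normalize_gene(g) for g in gene_subset]
    if not subset:
        raise ValueError("gene_subset must be non-empty")
    unknown = [g for g in subset if g not in cohort.genes]
    if unknown:
        raise KeyError(f"unknown gene(s) {unknown}; cohort genes are {cohort.genes}")
    idx = [cohort.genes.index(g) for g in subset]
    present = cohort.gene_matrix()[:, idx].all(axis=1)
    diseased = cohort.class_labels() == 1
    a = int((present & diseased).sum())
    b = int((present & ~diseased).sum())
    c = int((~present & diseased).sum())
    d = int((~present & ~diseased).sum())
    return ContingencyTable2x2(a, b, c, d)


def univariate_scan(cohort: Cohort) -> dict[str, TestResult]:
    """Per-gene Pearson chi-square against class, in cohort gene order."""
    if cohort.n_diseased == 0 or cohort.n_healthy == 0:
        raise SingleClassError("univariate scan requires both classes present")
    return {
        g: pearson_chi2(make_combination_table(cohort, [g])) for g in cohort.genes
    }


def multivariate_scan(
    cohort: Cohort,
    min_size: int = 2,
    alpha: float = 0.05,
    correction: Literal[None, "bonferroni", "bh"] = None,
    with_fisher: bool = True,
) -> tuple[list[CombinationResult], int]:
    """Exhaustive AND-combination scan over all gene subsets.

    Enumerates every subset of size ``min_size``..G in deterministic
    order (by size, then lexicographic by gene name); for G genes and
    ``min_size=2`` that is 2**G - G - 1 combinations.  Significance is
    flagged at ``alpha`` on the chi-square p-value, optionally after
    Bonferroni or Benjamini-Hochberg adjustment (off by default: the
    analysis filters on raw p).  Fisher's exact p is reported alongside
    whenever any expected cell is below 5.
    """
    genes = sorted(cohort.genes)
    G = len(genes)
    if not 1 <= min_size <= G:
        raise ValueError(f"min_size {min_size} outside 1..{G}")
    if cohort.n_diseased == 0 or cohort.n_healthy == 0:
        raise SingleClassError("multivariate scan requires both classes present")

    mat = cohort.gene_matrix()
    diseased = cohort.class_labels() == 1
    n_dis, n_heal = int(diseased.sum()), int((~diseased).sum())

    # one integer bitmask per gene (bit i = record i carries the gene):
    # AND-combination counts become popcounts, far cheaper than slicing
    gene_mask = {
        g: int(
            sum(1 << i for i in np.flatnonzero(mat[:, cohort.genes.index(g)]))
        )
        for g in genes
    }
    dis_mask = int(sum(1 << i for i in np.flatnonzero(diseased)))

    subsets: list[tuple[str, ...]] = []
    tables: list[ContingencyTable2x2] = []
    for size in range(min_size, G + 1):
        for subset in combinations(genes, size):
            m = gene_mask[subset[0]]
            for g in subset[1:]:
                m &= gene_mask[g]
            a = (m & dis_mask).bit_count()
            b = m.bit_count() - a
            subsets.append(subset)
            tables.append(ContingencyTable2x2(a, b, n_dis - a, n_heal - b))

    a_arr = np.array([t.a for t in tables], dtype=float)
    b_arr = np.array([t.b for t in tables], dtype=float)
    c_arr, d_arr = n_dis - a_arr, n_heal - b_arr
    r1, r2 = a_arr + b_arr, c_arr + d_arr
    n = float(n_dis + n_heal)
    denom = r1 * r2 * n_dis * n_heal
    degenerate = (r1 == 0) | (r2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stats = np.where(
            degenerate, 0.0, n * (a_arr * d_arr - b_arr * c_arr) ** 2 / denom
        )
    pvals = np.where(degenerate, 1.0, _chi2_dist.sf(stats, 1))

    if correction == "bonferroni":
        adjusted = np.minimum(pvals * len(pvals), 1.0)
    elif correction == "bh":
        adjusted = multipletests(pvals, method="fdr_bh")[1]
    elif correction is None:
        adjusted = pvals
    else:
        raise ValueError(f"unknown correction {correction!r}")

    results = []
    for subset, table, stat, p, deg, adj in zip(
        subsets, tables, stats, pvals, degenerate, adjusted
    ):
        fisher = None
        if with_fisher and min(table.expected()) < 5:
            fisher = fisher_exact_two_sided(table)
        results.append(
            CombinationResult(
                subset, table,
                TestResult(float(stat), float(p), "pearson_chi2", bool(deg)),
                fisher,
                significant=bool(adj <= alpha and not deg),
                p_adjusted=float(adj) if correction else None,
            )
        )
    return results, len(results)
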