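# Methods

## Data model

A cohort is an ordered list of donors; each donor carries a 0/1
presence flag per gene and a binary class (0 healthy, 1 diseased).
The gene universe is a tuple on the cohort, defaulting to the 12
non-framework KIR genes; the four framework genes (3DL3, 3DP1, 2DL4,
3DL2) are effectively invariant in human populations and are excluded
from the universe rather than carried as constant columns. The model
is deliberately generic in the gene tuple so that small pedagogical
datasets exercise every code path; KIR-specific operations (haplotype
grouping, motif annotation) check that the 12 KIR genes are present
and fail loudly otherwise.

Haplotype-group calls follow the standard gene-content criteria:
carriage of any of {2DL2, 2DL5, 2DS1, 2DS2, 2DS3, 2DS5, 3DS1} marks at
least one group B haplotype; with the full group-A complement
{2DL3, 2DP1, 2DL1, 3DL1, 2DS4} present, zero B genes is called
A-homozygous and one or more is A,B-heterozygous. Genotypes that carry
B genes but lack part of the A complement satisfy neither definition;
they are reported as `B_CARRIER_OTHER` rather than forced into a named
class, because the criteria only define the two named classes when the
A complement is intact. The symmetric gap — no B gene and an
incomplete A complement — is handled the same way; such genotypes are
rare enough that the criteria do not address them, and inventing a
call seemed worse than labelling the residual category.

## Contingency analysis

All 2×2 tables use the cell convention a = diseased carriers,
b = healthy carriers, c = diseased non-carriers, d = healthy
non-carriers, where "carrier" for a gene subset means every gene in
the subset is present (logical AND). The Pearson statistic is the
uncorrected cross-product form with 1 degree of freedom; no Yates
continuity correction is applied, because the analysis this package
reproduces reports uncorrected values (corrected statistics would not
match the reference tables, e.g. 17.4 and 71.86). Tables with a zero
margin have no defined statistic; they return a flagged degenerate
result (χ² = 0, p = 1) instead of raising, so exhaustive scans never
abort mid-way.

The two-sided Fisher test sums the probabilities of all tables with
the observed margins whose hypergeometric probability does not exceed
the observed table's. It is evaluated in exact integer arithmetic
(each probability is an integer numerator over a common binomial
denominator), so probability ties are decided exactly and no
floating-point tie tolerance is needed. The unit tests cross-check it
against `scipy.stats.fisher_exact` on random tables and against an
independently coded enumeration on every table with N ≤ 40.

The multivariate scan enumerates every gene subset of size 2..G in a
fixed order (by size, then lexicographically), 2^G − G − 1 subsets in
total (4083 for G = 12), so result indices are stable across runs.
Carrier counts per subset are computed as popcounts of per-gene
bitmasks. Significance is flagged at α on raw chi-square p-values by
default — the protocol being emulated filters on raw p at 0.05 and
0.0001 — with optional Bonferroni or Benjamini–Hochberg adjustment
(via statsmodels) for users who want family-wise control over the
4083 tests. Fisher's p is reported alongside whenever any expected
cell is below 5, since the classical validity rule for the chi-square
approximation is then violated; both values are always kept because
the reference analysis does not state its switching rule.

## Rule mining

Transactions encode each donor as 13 `attribute=value` items (12 genes
plus the class). Both values of each attribute are items: rules must
be able to condition on absence (e.g. 2DS2=0). Support of an itemset
is the number of transactions containing it; the engine stores one
arbitrary-precision integer bitmask per item and takes popcounts of
ANDs, which keeps 100 full-cohort mining runs under two seconds.

`frequent_itemsets` is the textbook levelwise algorithm: candidate
generation joins (k−1)-sets sharing k−2 items, discards candidates
asserting two values of one attribute, and prunes candidates with any
infrequent (k−1)-subset.

`mine_class_association_rules` runs one levelwise pass per class value
over antecedent itemsets, using the joint support with the class item
as the frequency measure (anti-monotone, so the same join/prune
applies) and emitting a rule when confidence = joint/antecedent
support clears the threshold. This is equivalent to mining all
frequent itemsets and filtering to single-class consequents — the
property suite verifies the equivalence against brute-force
enumeration on random datasets — but explores a much smaller lattice
on real-sized cohorts. The default minimum support count is 1 (keep
every observed pattern, the "support lower bound zero" setting of the
protocol being emulated); support is an absolute count in the engine
because reported rule frequencies are absolute. Rule order is
deterministic: confidence desc, support count desc, antecedent size
asc, lexicographic. A `max_antecedent` cap is available because
unbounded mining at support 1 over both class values visits on the
order of a million itemsets on a 343-donor cohort (seconds to minutes,
memory-heavy); mining only the disease consequent, or at support ≥ 10,
is fast.

`maximal_perfect_rules` removes every rule whose antecedent is a
proper subset of another rule's antecedent with the same support count
and consequent: a family of equally frequent derived rules collapses
onto its generating pattern. Rule identity is by content (antecedent,
consequent, support); no external tool's rule numbering is reproduced.
Motif annotation reports each motif whose gene complement is asserted
present in the antecedent; the default table is
cA01 = {2DL3, 2DP1, 2DL1}, tA01 = {3DL1, 2DS4},
cB03 = {2DL3, 2DL5, 2DS5, 2DP1, 2DL1}, and is fully overridable —
centromeric/telomeric motif inference from unphased gene content is
inherently approximate, so the table is a convenience, not a claim.

## Decision tree

The comparator is plain ID3: split on maximal Shannon information
gain, leaf when pure, when no attribute has positive gain, at the
depth cap, or below the minimum leaf support; majority class at
leaves with ties resolved to class 0 (the conservative call for a
screening context); gain ties broken lexicographically for
determinism. Optional reduced-error pruning holds out a seeded 25%
validation split and collapses subtrees that do not beat their
majority leaf on it. This deliberately does not emulate C4.5/J48
confidence-factor pruning or subtree raising — those are tool-specific
and their settings for the reference runs are unpublished — so
structural claims (which attribute roots the tree, which path predicts
disease) are the meaningful comparisons, not leaf counts.

## Synthetic cohorts

The generator draws exact class sizes (default 300 healthy, 43
diseased — the study design being emulated) with independent per-gene
Bernoulli carriage per class. Defaults encode the one published
per-class contrast, 2DL2 at 0.403 healthy / 0.778 diseased; all other
genes default to 0.5 and must not be read as population estimates.
Pairwise linkage is specified as a joint carriage probability for a
gene pair and sampled as a per-donor multinomial over the four joint
cells (a gene may appear in at most one pair); this is sufficient to
emulate strong pairwise linkage disequilibrium (2DL2–2DS2) without a
full haplotype model, which the downstream analysis — all unphased —
would not see anyway. Planted patterns fix the pattern genes of
seeded, randomly placed donors within each class, and non-planted
donors who satisfy the full pattern by chance are rejection-resampled,
so planted carrier counts are exact in both classes (a pattern planted
10/0 yields the table (10, 0, 33, 300) identically).

What passing tests on synthetic cohorts do and do not show: they
validate the machinery (calibration, exact planted recovery, type-I
error of the scans at nominal α) under independence-plus-planted
structure. Real KIR cohorts have block-wise haplotype correlation
among many genes simultaneously, allele-level variation and
genotyping error, none of which the generator emulates; effect sizes
and rule counts measured on synthetic cohorts say nothing about any
real population. Dataset-dependent totals from the original study
context (counts of significant combinations, total mined rules, an
exact fitted tree) require the original genotypes, which were never
published; the suite covers them only qualitatively.

One stochastic caveat, measured and documented rather than hidden: a
pattern planted in 10 of 43 diseased donors is always recovered as a
perfect support-10 rule, but it is the *literally unique* maximal
perfect rule only in roughly three-quarters of seeds — the random
background occasionally contains another perfect pattern with support
≥ 10 (for instance, a sub-pattern satisfied by 11+ diseased and no
healthy donors, or an extra condition shared by all 10 planted
donors). The recovery tests therefore assert exact recovery of the
planted pattern plus majority-of-seeds literal uniqueness; that is the
statement the construction actually guarantees.

## Pipeline and numerical choices

`KirPatternAnalysis.fit()` runs univariate scan → multivariate scan →
rule mining → maximal-rule extraction and motif annotation → tree →
comparison. The comparison stage rebuilds two 2×2 tables on the same
cohort — carriage of the best combination (smallest raw chi-square p,
ties broken lexicographically) vs satisfaction of the best maximal
perfect disease rule (largest support, then largest antecedent) —
with both test statistics each. Defaults: min support count 1, min
confidence 0.9, consequent class 1, α = 0.05, no correction, no
antecedent cap. Results serialise to sorted-key JSON with no
timestamp, so a rerun with identical cohort and configuration is
byte-identical.

Problem sizes used by the test suite: toy cohort (20 × 2) for all
exact checks; 343-donor synthetic cohorts for scan and recovery
checks (100 seeds for planted recovery); 1000 replicate null cohorts
for the type-I-error calibration; all 135,750 tables with N ≤ 40 for
the Fisher oracle; 50 random datasets of ≤ 8 attributes × ≤ 30
transactions for miner/brute-force equivalence. The full suite runs
in well under a minute on one CPU.

## Known limitations

- Haplotype-group calls and motif annotation are gene-content
  heuristics on unphased data; cis/trans arrangements and 2DL5A/B
  resolution are out of reach of presence/absence typing.
- The miner is exact but exponential in the worst case; with 13
  attributes it is comfortable, but universes beyond ~20 attributes
  need a support threshold or antecedent cap.
- Reduced-error pruning with a 25% holdout is a rough stand-in for
  production tree tooling; the tree exists as a comparator, not a
  classifier to deploy.
- No multiple-testing correction is applied by default anywhere, by
  design; users scanning 4083 combinations for discovery (rather than
  protocol emulation) should switch on `correction="bh"`.
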