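"""Seedable synthetic KIR-genotype cohort generator.

Emulates a case-control presence/absence cohort: exact class sizes,
per-class per-gene carrier probabilities, optional pairwise linkage
(joint carriage probability for a gene pair, standing in for linkage
disequilibrium such as 2DL2-2DS2), and an optional planted genotype
pattern whose carrier counts in each class are exact by construction —
non-planted donors that would satisfy the full pattern by chance are
resampled, so a pattern planted in k diseased and 0 healthy donors has
exactly k carriers, all diseased.

Default conditions mirror the study design the analysis targets:
300 healthy and 43 diseased donors, 2DL2 carriage 0.403 healthy vs
0.778 diseased; the remaining genes default to 0.5 (no published
per-class estimate — not population values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort, GenotypeRecord
from .exceptions import InfeasibleSpecError
from .genes import KIR_GENES, normalize_gene

#: Published per-class carrier contrast used for calibration.
DEFAULT_CARRIER_PROB: dict[int, dict[str, float]] = {
    0: {g: (0.403 if g == "2DL2" else 0.5) for g in KIR_GENES},
    1: {g: (0.778 if g == "2DL2" else 0.5) for g in KIR_GENES},
}

#: The 8-condition disease pattern used in recovery experiments
#: (cA01|tA01 genes plus 2DL2 and 2DL5 present, 2DS2 absent).
CA01_TA01_DISEASE_PATTERN: dict[str, int] = {
    "2DL1": 1, "2DL2": 1, "2DL3": 1, "2DL5": 1,
    "2DS2": 0, "2DS4": 1, "2DP1": 1, "3DL1": 1,
}

# Table of the 20-record two-gene teaching dataset: (g1, g2, C).
_TOY_ROWS: tuple[tuple[int, int, int], ...] = (
    (1, 1, 1), (0, 0, 0), (0, 1, 0), (1, 1, 1), (0, 0, 0),
    (1, 0, 0), (0, 1, 0), (1, 1, 1), (0, 0, 0), (0, 1, 0),
    (1, 1, 1), (0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 1, 0),
    (1, 1, 1), (1, 1, 1), (0, 0, 0), (0, 1, 0), (0, 0, 0),
)


@dataclass(frozen=True)
class PlantedPattern:
    pattern: Mapping[str, int]
    n_in_diseased: int = 0
    n_in_healthy: int = 0


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_healthy: int = 300
    n_diseased: int = 43
    carrier_prob: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: {0: dict(DEFAULT_CARRIER_PROB[0]),
                                 1: dict(DEFAULT_CARRIER_PROB[1])}
    )
    linkage_pairs: tuple[tuple[str, str, float], ...] = ()
    planted_pattern: PlantedPattern | None = None
    seed: int = 0
    genes: tuple[str, ...] = KIR_GENES

    def validate(self) -> None:
        if self.n_healthy < 0 or self.n_diseased < 0 or self.n_healthy + self.n_diseased == 0:
            raise InfeasibleSpecError("class sizes must be non-negative and not both zero")
        for cls in (0, 1):
            probs = self.carrier_prob[cls]
            for g in self.genes:
                p = probs[g]
                if not 0.0 <= p <= 1.0:
                    raise InfeasibleSpecError(f"carrier probability {p} for {g} outside [0,1]")
        seen: set[str] = set()
        for ga, gb, p11 in self.linkage_pairs:
            ga, gb = normalize_gene(ga), normalize_gene(gb)
            if ga in seen or gb in seen:
                raise InfeasibleSpecError(
                    f"gene {ga if ga in seen else gb} appears in more than one linkage pair"
                )
            seen |= {ga, gb}
            for cls in (0, 1):
                pa, pb = self.carrier_prob[cls][ga], self.carrier_prob[cls][gb]
                if p11 > min(pa, pb) + 1e-12 or 1 - pa - pb + p11 < -1e-12:
                    raise InfeasibleSpecError(
                        f"joint probability {p11} for ({ga},{gb}) infeasible with "
                        f"marginals ({pa},{pb}) in class {cls}"
                    )
        if self.planted_pattern is not None:
            pp = self.planted_pattern
            if pp.n_in_diseased > self.n_diseased or pp.n_in_healthy > self.n_healthy:
                raise InfeasibleSpecError("planted counts exceed class sizes")
            unknown = set(map(normalize_gene, pp.pattern)) - set(self.genes)
            if unknown:
                raise InfeasibleSpecError(f"planted pattern names unknown genes {sorted(unknown)}")


def spec_from_dict(config: Mapping, seed: int | None = None) -> SyntheticCohortSpec:
    """Build a spec from a plain config mapping (e.g. parsed YAML).

    Recognised keys: ``n_healthy``, ``n_diseased``, ``seed``,
    ``carrier_prob`` ({"healthy": {gene: p}, "diseased": {...}} deltas
    over the defaults), ``linkage`` ([[geneA, geneB, p11], ...]) and
    ``planted`` ({"pattern": {gene: 0/1}, "n_in_diseased", "n_in_healthy"}).
    """
    carrier = {0: dict(DEFAULT_CARRIER_PROB[0]), 1: dict(DEFAULT_CARRIER_PROB[1])}
    for key, cls in (("healthy", 0), ("diseased", 1)):
        for g, p in (config.get("carrier_prob", {}).get(key, {}) or {}).items():
            carrier[cls][normalize_gene(g)] = float(p)
    planted = None
    if config.get("planted"):
        block = config["planted"]
        planted = PlantedPattern(
            pattern={normalize_gene(g): int(v) for g, v in block["pattern"].items()},
            n_in_diseased=int(block.get("n_in_diseased", 0)),
            n_in_healthy=int(block.get("n_in_healthy", 0)),
        )
    spec = SyntheticCohortSpec(
        n_healthy=int(config.get("n_healthy", 300)),
        n_diseased=int(config.get("n_diseased", 43)),
        carrier_prob=carrier,
        linkage_pairs=tuple(
            (normalize_gene(a), normalize_gene(b), float(p))
            for a, b, p in config.get("linkage", [])
        ),
        planted_pattern=planted,
        seed=int(config.get("seed", 0)),
    )
    if seed is not None:
        spec = replace(spec, seed=seed)
    return spec


def _sample_class(
    rng: np.random.Generator,
    n: int,
    genes: Sequence[str],
    probs: Mapping[str, float],
    linkage: Sequence[tuple[str, str, float]],
) -> np.ndarray:
    mat = np.zeros((n, len(genes)), dtype=np.int8)
    col = {g: j for j, g in enumerate(genes)}
    linked = {g for ga, gb, _ in linkage for g in (ga, gb)}
    for g in genes:
        if g not in linked:
            mat[:, col[g]] = rng.random(n) < probs[g]
    for ga, gb, p11 in linkage:
        pa, pb = probs[ga], probs[gb]
        cells = np.array([p11, pa - p11, pb - p11, 1 - pa - pb + p11]).clip(0)
        cells /= cells.sum()
        draw = rng.choice(4, size=n, p=cells)
        mat[:, col[ga]] = (draw == 0) | (draw == 1)
        mat[:, col[gb]] = (draw == 0) | (draw == 2)
    return mat


def generate(spec: SyntheticCohortSpec) -> Cohort:
    """Draw a cohort under the spec; deterministic under a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.genes
    blocks = []
    pattern_cols = pattern_vals = None
    if spec.planted_pattern is not None:
        norm = {normalize_gene(g): int(v) for g, v in spec.planted_pattern.pattern.items()}
        pattern_cols = np.array([genes.index(g) for g in norm], dtype=int)
        pattern_vals = np.array(list(norm.values()), dtype=np.int8)

    for cls, n in ((0, spec.n_healthy), (1, spec.n_diseased)):
        if n == 0:
            continue
        probs = spec.carrier_prob[cls]
        mat = _sample_class(rng, n, genes, probs, spec.linkage_pairs)
        if pattern_cols is not None:
            n_plant = (
                spec.planted_pattern.n_in_healthy if cls == 0
                else spec.planted_pattern.n_in_diseased
            )
            planted_rows = rng.choice(n, size=n_plant, replace=False) if n_plant else np.array([], dtype=int)
            is_planted = np.zeros(n, dtype=bool)
            is_planted[planted_rows] = True
            mat[np.ix_(planted_rows, pattern_cols)] = pattern_vals
            # exact counts: resample accidental carriers among non-planted rows
            for _ in range(10_000):
                matches = (mat[:, pattern_cols] == pattern_vals).all(axis=1) & ~is_planted
                if not matches.any():
                    break
                redo = np.flatnonzero(matches)
                mat[redo] = _sample_class(rng, len(redo), genes, probs, spec.linkage_pairs)
            else:
                raise InfeasibleSpecError(
                    "could not avoid accidental planted-pattern carriers; "
                    "pattern probability too close to 1"
                )
        blocks.append((cls, mat))

    records = []
    i = 0
    for cls, mat in blocks:
        for row in mat:
            i += 1
            records.append(
                GenotypeRecord(
                    sample_id=str(i),
                    gene_presence={g: int(v) for g, v in zip(genes, row)},
                    class_label=cls,
                )
            )
    return Cohort(
        records,
        genes=genes,
        class_attribute="disease",
        provenance=f"synthetic(seed={spec.seed})",
    )


def toy_fixture() -> Cohort:
    """The 20-record two-gene teaching cohort (attributes g1, g2, class C)."""
    records = [
        GenotypeRecord(str(i + 1), {"g1": g1, "g2": g2}, c)
        for i, (g1, g2, c) in enumerate(_TOY_ROWS)
    ]
    return Cohort(records, genes=("g1", "g2"), class_attribute="C", provenance="toy")
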