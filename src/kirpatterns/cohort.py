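"""Cohort data model: genotype records, carrier frequencies, haplotype
groups and the transaction encoding used by the rule miner.

A cohort is an ordered collection of donors, each typed for a fixed
tuple of presence/absence genes plus a binary disease class
(0 = healthy, 1 = diseased).  For real KIR data the gene tuple is the
12 non-framework KIR genes; the model is generic so that small
pedagogical datasets (two attributes g1/g2) flow through every
operation unchanged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import DegenerateSelectionError, KirPatternsError, SchemaError
from .genes import A_HAPLOTYPE_GENES, B_HAPLOTYPE_GENES, KIR_GENES, normalize_gene


class Item(NamedTuple):
    """An ``attribute = value`` assertion; the unit of itemset mining."""

    attribute: str
    value: int


@dataclass(frozen=True)
class GenotypeRecord:
    """One donor: presence flags per gene plus the disease class."""

    sample_id: str
    gene_presence: Mapping[str, int]
    class_label: int

    def __post_init__(self) -> None:
        for gene, value in self.gene_presence.items():
            if value not in (0, 1):
                raise ValueError(
                    f"gene {gene!r} of sample {self.sample_id!r} has "
                    f"non-binary value {value!r}"
                )
        if self.class_label not in (0, 1):
            raise ValueError(
                f"class label of sample {self.sample_id!r} must be 0 or 1, "
                f"got {self.class_label!r}"
            )

    def __getitem__(self, gene: str) -> int:
        return self.gene_presence[gene]


class HaplotypeGroup(Enum):
    A_HOMOZYGOUS = "A_HOMOZYGOUS"
    AB_HETEROZYGOUS = "AB_HETEROZYGOUS"
    B_CARRIER_OTHER = "B_CARRIER_OTHER"


@dataclass(frozen=True)
class HaplotypeGroupCall:
    group: HaplotypeGroup
    b_genes_present: tuple[str, ...]


@dataclass
class Cohort:
    """Ordered donor collection over a fixed gene tuple.

    ``genes`` fixes both the attribute universe and the reporting
    order; ``class_attribute`` names the disease-status attribute in
    transaction encodings and file output.
    """

    records: list[GenotypeRecord]
    genes: tuple[str, ...] = KIR_GENES
    class_attribute: str = "disease"
    provenance: str = ""
    _matrix_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise KirPatternsError("a cohort must contain at least one record")
        self.genes = tuple(self.genes)
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise KirPatternsError(f"duplicate sample id {rec.sample_id!r}")
            seen.add(rec.sample_id)
            missing = set(self.genes) - set(rec.gene_presence)
            if missing:
                raise SchemaError(
                    f"sample {rec.sample_id!r} lacks genes {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_diseased(self) -> int:
        return sum(r.class_label for r in self.records)

    @property
    def n_healthy(self) -> int:
        return len(self) - self.n_diseased

    def class_labels(self) -> np.ndarray:
        return np.fromiter(
            (r.class_label for r in self.records), dtype=np.int8, count=len(self)
        )

    def gene_matrix(self) -> np.ndarray:
        """Presence matrix, shape ``(n_records, n_genes)`` in cohort order."""
        if self._matrix_cache is None:
            mat = np.empty((len(self), len(self.genes)), dtype=np.int8)
            for i, rec in enumerate(self.records):
                for j, g in enumerate(self.genes):
                    mat[i, j] = rec.gene_presence[g]
            object.__setattr__(self, "_matrix_cache", mat)
        return self._matrix_cache

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        genes: Iterable[str] | None = None,
        class_column: str = "disease",
        id_column: str | None = None,
        provenance: str = "",
    ) -> "Cohort":
        """Build a cohort from a 0/1 DataFrame (one row per donor)."""
        gene_tuple = tuple(genes) if genes is not None else tuple(
            c for c in df.columns if c not in (class_column, id_column)
        )
        records = []
        for pos, (idx, row) in enumerate(df.iterrows()):
            sid = str(row[id_column]) if id_column else str(idx)
            records.append(
                GenotypeRecord(
                    sample_id=sid,
                    gene_presence={g: int(row[g]) for g in gene_tuple},
                    class_label=int(row[class_column]),
                )
            )
        return cls(records, gene_tuple, class_column, provenance)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"sample_id": [r.sample_id for r in self.records]}
        for j, g in enumerate(self.genes):
            data[g] = self.gene_matrix()[:, j]
        data[self.class_attribute] = self.class_labels()
        return pd.DataFrame(data)


def carrier_frequency(
    cohort: Cohort, gene: str, class_filter: Literal[0, 1, "both"] = "both"
) -> float:
    """Fraction of (class-restricted) donors carrying ``gene``.

    Computed by direct counting of carriers over the selected donors.
    """
    gene = normalize_gene(gene)
    if gene not in cohort.genes:
        raise KeyError(f"unknown gene {gene!r}; cohort genes are {cohort.genes}")
    selected = [
        r for r in cohort.records
        if class_filter == "both" or r.class_label == class_filter
    ]
    if not selected:
        raise DegenerateSelectionError(
            f"no records with class {class_filter!r}; frequency undefined"
        )
    return sum(r.gene_presence[gene] for r in selected) / len(selected)


def classify_haplotype_group(record: GenotypeRecord) -> HaplotypeGroupCall:
    """Assign the KIR haplotype-group call for one genotype.

    Carriage of any B-defining gene (2DL2, 2DL5, 2DS1, 2DS2, 2DS3,
    2DS5, 3DS1) marks at least one group B haplotype.  With the full
    group-A complement (2DL3, 2DP1, 2DL1, 3DL1, 2DS4) present, absence
    of every B gene is called A-homozygous, presence of one or more is
    A,B-heterozygous.  Genotypes carrying B genes but lacking part of
    the A complement fall outside both named classes and are reported
    as ``B_CARRIER_OTHER`` rather than forced into a call the criteria
    do not license.
    """
    missing = (B_HAPLOTYPE_GENES | A_HAPLOTYPE_GENES) - set(record.gene_presence)
    if missing:
        raise SchemaError(
            f"haplotype grouping requires the 12 KIR genes; missing {sorted(missing)}"
        )
    b_present = tuple(
        g for g in KIR_GENES if g in B_HAPLOTYPE_GENES and record.gene_presence[g]
    )
    all_a = all(record.gene_presence[g] for g in A_HAPLOTYPE_GENES)
    if all_a and not b_present:
        return HaplotypeGroupCall(HaplotypeGroup.A_HOMOZYGOUS, ())
    if all_a and b_present:
        return HaplotypeGroupCall(HaplotypeGroup.AB_HETEROZYGOUS, b_present)
    return HaplotypeGroupCall(HaplotypeGroup.B_CARRIER_OTHER, b_present)


def haplotype_group_counts(cohort: Cohort) -> Counter:
    """Per-group donor counts; the three groups partition the cohort."""
    return Counter(classify_haplotype_group(r).group for r in cohort.records)


def to_transactions(cohort: Cohort) -> list[frozenset[Item]]:
    """Encode each donor as a transaction of ``attribute=value`` items.

    Every transaction carries exactly one item per gene (value 0 or 1)
    plus one class item, so absence is a first-class condition and the
    encoding is lossless.
    """
    out = []
    for rec in cohort.records:
        items = {Item(g, rec.gene_presence[g]) for g in cohort.genes}
        items.add(Item(cohort.class_attribute, rec.class_label))
        out.append(frozenset(items))
    return out
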