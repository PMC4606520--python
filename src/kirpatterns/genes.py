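"""Gene universe and haplotype-group constants for the KIR system.

The KIR locus (19q13.4) carries 17 genes; four framework genes
(KIR3DL3, KIR3DP1, KIR2DL4, KIR3DL2) are present in virtually all
haplotypes and carry no discriminating signal, so presence/absence
analysis works on the remaining 12 genes.  Haplotypes fall into two
broad groups: group A has fixed, mostly inhibitory content, group B
variable content including activating genes.
"""

from __future__ import annotations

# Canonical short names, in the conventional typing-report order.
KIR_GENES: tuple[str, ...] = (
    "2DL1", "2DL2", "2DL3", "2DL5", "2DS1", "2DS2",
    "2DS3", "2DS4", "2DS5", "2DP1", "3DL1", "3DS1",
)

#: Carriage of any of these marks at least one group B haplotype.
B_HAPLOTYPE_GENES: frozenset[str] = frozenset(
    {"2DL2", "2DL5", "2DS1", "2DS2", "2DS3", "2DS5", "3DS1"}
)

#: The group A gene complement; all five present (and no B gene)
#: defines group-A homozygosity.
A_HAPLOTYPE_GENES: frozenset[str] = frozenset(
    {"2DL3", "2DP1", "2DL1", "3DL1", "2DS4"}
)

#: Centromeric/telomeric haplotype motifs -> genes that must be carried.
#: cB03 is the published motif definition; cA01/tA01 are the canonical
#: inhibitory centromeric/telomeric blocks.
DEFAULT_MOTIFS: dict[str, frozenset[str]] = {
    "cA01": frozenset({"2DL3", "2DP1", "2DL1"}),
    "tA01": frozenset({"3DL1", "2DS4"}),
    "cB03": frozenset({"2DL3", "2DL5", "2DS5", "2DP1", "2DL1"}),
}

_CANONICAL = {g.upper(): g for g in KIR_GENES}


def normalize_gene(name: str) -> str:
    """Map a column/gene label onto its canonical short name.

    Matching is case-insensitive and tolerates an optional ``KIR``
    prefix, so ``"KIR2DL1"``, ``"kir2dl1"`` and ``"2DL1"`` are all the
    gene ``"2DL1"``.  Names outside the KIR universe (e.g. the toy
    attributes ``g1``, ``g2``) are returned stripped but otherwise
    unchanged.
    """
    stripped = name.strip()
    upper = stripped.upper()
    if upper.startswith("KIR"):
        upper = upper[3:]
    return _CANONICAL.get(upper, stripped)
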