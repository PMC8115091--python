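"""Gene-level recessive candidate detection: homozygous and compound
heterozygous SV–SNV combinations affecting coding sequence.

Variants are assigned to genes either through their gene annotation or by
intersection with gene coding intervals (deletions and inversions by
reference footprint, insertions by their 1 bp anchor point). Parental
origin of heterozygous variants is inferred from trio genotypes where the
configuration is informative; compound heterozygous pairs are emitted
unless both origins are known and identical (provably cis). Passing
``use_phase=False`` disables the origin rule and pairs naively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .datamodel import GeneModel, SNVRecord, SVRecord

Variant = Union[SVRecord, SNVRecord]

CODING_CLASSES = {"missense", "lof", "synonymous"}


@dataclass
class GeneVariantEntry:
    variant: Variant
    kind: str  # "sv" | "snv"
    genotype: Tuple[int, int]
    origin: str  # "father" | "mother" | "unknown"


@dataclass
class GeneVariantTable:
    sample: str
    genes: Dict[str, List[GeneVariantEntry]] = field(default_factory=dict)


@dataclass
class RecessiveCandidate:
    gene: str
    mechanism: str  # "hom_sv" | "hom_snv" | "comphet_sv_snv"
    variants: List[GeneVariantEntry]


def infer_origin(rec: Variant, sample: str, trio: Optional[Sequence[str]]) -> str:
    """Parental origin of a het variant from trio genotypes, if informative.

    Father-only carriage implies paternal origin, mother-only maternal;
    both-carrier, neither-carrier, and missing configurations are unknown.
    """
    if trio is None or sample != trio[0]:
        return "unknown"
    father, mother = rec.calls.get(trio[1]), rec.calls.get(trio[2])
    if father is None or mother is None or father.is_missing or mother.is_missing:
        return "unknown"
    if father.is_nonref and not mother.is_nonref:
        return "father"
    if mother.is_nonref and not father.is_nonref:
        return "mother"
    return "unknown"


def _genes_for_sv(rec: SVRecord, genes: Sequence[GeneModel]) -> List[str]:
    s, e = rec.footprint()
    return [g.gene for g in genes if g.chrom == rec.chrom and g.intervals.overlaps(rec.chrom, s, e)]


def _genes_for_snv(rec: SNVRecord, genes: Sequence[GeneModel]) -> List[str]:
    if rec.gene is not None:
        return [rec.gene]
    return [
        g.gene
        for g in genes
        if g.chrom == rec.chrom and g.intervals.overlaps(rec.chrom, rec.pos, rec.pos + 1)
    ]


def build_gene_table(
    svs: Sequence[SVRecord],
    snvs: Sequence[SNVRecord],
    genes: Sequence[GeneModel],
    sample: str,
    trio: Optional[Sequence[str]] = None,
) -> GeneVariantTable:
    """Coding variants carried by ``sample``, grouped per gene.

    An SV spanning several genes' coding intervals appears under each.
    Only coding-class SNVs enter the table.
    """
    table = GeneVariantTable(sample=sample)
    for rec in svs:
        call = rec.calls.get(sample)
        if call is None or not call.is_nonref:
            continue
        for gene in _genes_for_sv(rec, genes):
            table.genes.setdefault(gene, []).append(
                GeneVariantEntry(rec, "sv", call.genotype, infer_origin(rec, sample, trio))
            )
    for rec in snvs:
        call = rec.calls.get(sample)
        if call is None or not call.is_nonref:
            continue
        if rec.func_class not in CODING_CLASSES:
            continue
        for gene in _genes_for_snv(rec, genes):
            table.genes.setdefault(gene, []).append(
                GeneVariantEntry(rec, "snv", call.genotype, infer_origin(rec, sample, trio))
            )
    return table


def _is_lof_qualifying(entry: GeneVariantEntry, lof_qual_min: float) -> bool:
    rec = entry.variant
    return (
        entry.kind == "snv"
        and rec.func_class == "lof"
        and rec.quality is not None
        and rec.quality > lof_qual_min  # strict: "higher than" the cutoff
    )


def _trans_compatible(a: GeneVariantEntry, b: GeneVariantEntry) -> bool:
    """False only when both origins are known and identical (provable cis)."""
    if a.origin == "unknown" or b.origin == "unknown":
        return True
    return a.origin != b.origin


def recessive_candidates(
    table: GeneVariantTable,
    trio: Optional[Sequence[str]] = None,
    lof_qual_min: float = 30.0,
    use_phase: bool = True,
) -> List[RecessiveCandidate]:
    """Per-gene recessive mechanisms for the table's sample.

    Emits homozygous coding SVs (``hom_sv``), homozygous qualifying LoF
    SNVs (``hom_snv``), and het-SV + het-LoF-SNV pairs (``comphet_sv_snv``)
    whose parental origins are not provably cis (unless ``use_phase`` is
    off, reproducing naive unphased pairing).
    """
    out: List[RecessiveCandidate] = []
    for gene, entries in table.genes.items():
        het_svs, het_snvs = [], []
        for entry in entries:
            hom = entry.genotype[0] == entry.genotype[1] and entry.genotype[0] > 0
            if entry.kind == "sv":
                if hom:
                    out.append(RecessiveCandidate(gene, "hom_sv", [entry]))
                else:
                    het_svs.append(entry)
            elif _is_lof_qualifying(entry, lof_qual_min):
                if hom:
                    out.append(RecessiveCandidate(gene, "hom_snv", [entry]))
                else:
                    het_snvs.append(entry)
        for sv_entry in het_svs:
            for snv_entry in het_snvs:
                if not use_phase or _trans_compatible(sv_entry, snv_entry):
                    out.append(
                        RecessiveCandidate(gene, "comphet_sv_snv", [sv_entry, snv_entry])
                    )
    return out
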