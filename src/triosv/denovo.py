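"""De novo SV and SNV candidate filtering and evidence-based classification.

The SV filter applies five criteria to a joint-called cohort:

1. heterozygous alternative allele only in the proband;
2. proband read ratio supporting the alternative allele within
   [ratio_min, ratio_max] (default [0.3, 0.7], inclusive);
3. depth of at least ``min_depth`` reads (default 6) in every sample;
4. homozygous reference genotype in every other sample;
5. zero reads supporting the alternative allele in every other sample.

Candidates are then classified programmatically from read evidence:
any parental alternative-allele read marks a candidate as an inherited
variant whose parental call was missed (the dominant resolution of
apparent de novo SVs); grossly unbalanced proband support or inadequate
depth marks a likely false positive; the remainder stay putative de novo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Set

from .datamodel import SNVRecord, SVRecord
from .mendelian import VIOLATION, mendelian_consistent

logger = logging.getLogger("triosv")


@dataclass
class DenovoSVParams:
    ratio_min: float = 0.3
    ratio_max: float = 0.7
    min_depth: int = 6
    max_other_alt_reads: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio_min < self.ratio_max <= 1.0:
            raise ValueError("need 0 <= ratio_min < ratio_max <= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class CandidateClassification:
    label: str  # inherited | false_positive | putative_de_novo
    reason: str


def denovo_sv_candidates(
    records: Sequence[SVRecord],
    trio: Sequence[str],
    cohort_samples: Optional[Sequence[str]] = None,
    params: Optional[DenovoSVParams] = None,
) -> List[SVRecord]:
    """Apply the five-criterion de novo SV filter for one trio.

    ``cohort_samples`` lists every sample the depth and absence criteria
    apply to (the full joint-called cohort when available, else the trio).
    Records with missing AD/DP in any required sample are excluded with a
    logged reason.
    """
    params = params or DenovoSVParams()
    proband = trio[0]
    samples = list(cohort_samples) if cohort_samples is not None else list(trio)
    if proband not in samples:
        samples = [proband] + samples
    out: List[SVRecord] = []
    for rec in records:
        pcall = rec.calls.get(proband)
        if pcall is None or not (pcall.is_het and pcall.is_nonref):
            continue
        ratio = pcall.alt_ratio
        if ratio is None:
            logger.info("de novo filter: %s excluded, proband AD/DP missing", rec.id)
            continue
        if not params.ratio_min <= ratio <= params.ratio_max:
            continue
        ok = True
        for s in samples:
            call = rec.calls.get(s)
            if call is None or call.depth is None or call.alt_support is None:
                logger.info("de novo filter: %s excluded, AD/DP missing in %s", rec.id, s)
                ok = False
                break
            if call.depth < params.min_depth:
                ok = False
                break
            if s != proband:
                if not call.is_hom_ref:
                    ok = False
                    break
                if call.alt_support > params.max_other_alt_reads:
                    ok = False
                    break
        if ok:
            out.append(rec)
    return out


def denovo_snv_candidates(
    snvs: Sequence[SNVRecord],
    trio: Sequence[str],
    qual_min: float = 30.0,
    classes: Optional[Set[str]] = None,
) -> List[SNVRecord]:
    """Mendelian-violating SNVs in damaging classes.

    Loss-of-function variants are retained at any quality; missense
    variants require quality >= ``qual_min`` (inclusive at the cutoff).
    """
    classes = classes if classes is not None else {"missense", "lof"}
    proband, father, mother = trio
    out: List[SNVRecord] = []
    for rec in snvs:
        if rec.func_class not in classes:
            continue
        verdict = mendelian_consistent(
            rec.calls[proband].genotype,
            rec.calls[father].genotype,
            rec.calls[mother].genotype,
        )
        if verdict != VIOLATION:
            continue
        if rec.func_class == "lof":
            out.append(rec)
        elif rec.quality is not None and rec.quality >= qual_min:
            out.append(rec)
    return out


def classify_candidate(
    record: SVRecord,
    trio: Sequence[str],
    params: Optional[DenovoSVParams] = None,
    relaxed_ratio: tuple = (0.2, 0.8),
) -> CandidateClassification:
    """Classify a de novo candidate from read evidence.

    Inherited: any parental alternative-allele read at a relaxed re-check —
    the parental call was missed, not absent. False positive: proband
    support outside the relaxed ratio band or below minimum depth.
    Otherwise putative de novo.
    """
    params = params or DenovoSVParams()
    proband, father, mother = trio
    for parent in (father, mother):
        call = record.calls.get(parent)
        if call is not None and call.alt_support is not None and call.alt_support >= 1:
            return CandidateClassification(
                label="inherited",
                reason=f"{call.alt_support} alt-supporting reads in {parent}",
            )
    pcall = record.calls.get(proband)
    ratio = pcall.alt_ratio if pcall is not None else None
    if pcall is None or pcall.depth is None or pcall.depth < params.min_depth:
        return CandidateClassification(
            label="false_positive", reason="proband depth below minimum"
        )
    if ratio is None or not relaxed_ratio[0] <= ratio <= relaxed_ratio[1]:
        return CandidateClassification(
            label="false_positive",
            reason=f"proband alt ratio {ratio} outside relaxed band {relaxed_ratio}",
        )
    return CandidateClassification(
        label="putative_de_novo", reason="no parental alt reads, balanced proband support"
    )
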