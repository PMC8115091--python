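"""Mendelian inheritance error (MIE) quantification for trio genotypes.

A child genotype is Mendelian-consistent when its two alleles can be
partitioned so that one is carried by the father and the other by the
mother. Sites with any missing trio genotype are uncounted — excluded from
both numerator and denominator — so MIE rates are fractions of fully
genotyped sites. Genuine de novo events score as violations under this
definition; at structural-variant scale they are negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

from .datamodel import Genotype, SNVRecord, SVRecord, is_autosome, normalize_genotype


class ConfigurationError(ValueError):
    """A pedigree/VCF mismatch (e.g. trio sample absent from the call set)."""


CONSISTENT = "consistent"
VIOLATION = "violation"
UNCOUNTED = "uncounted"


@dataclass
class MieSummary:
    sites_evaluated: int
    violations: int
    uncounted: int

    @property
    def mie_rate(self) -> Optional[float]:
        if self.sites_evaluated == 0:
            return None
        return self.violations / self.sites_evaluated

    @property
    def concordance(self) -> Optional[float]:
        rate = self.mie_rate
        return None if rate is None else 1.0 - rate


def mendelian_consistent(child: Genotype, father: Genotype, mother: Genotype) -> str:
    """Score one trio genotype combination.

    Returns ``"consistent"``, ``"violation"``, or ``"uncounted"`` (any
    missing genotype).
    """
    child = normalize_genotype(child)
    father = normalize_genotype(father)
    mother = normalize_genotype(mother)
    if child is None or father is None or mother is None:
        return UNCOUNTED
    a, b = child
    if (a in father and b in mother) or (b in father and a in mother):
        return CONSISTENT
    return VIOLATION


def mie_summary(
    records: Sequence[Union[SVRecord, SNVRecord]],
    trio: Sequence[str],
    autosomes_only: bool = False,
) -> MieSummary:
    """MIE summary over a record list for one (proband, father, mother) trio."""
    proband, father, mother = trio
    evaluated = violations = uncounted = 0
    first = records[0] if records else None
    if first is not None:
        for s in (proband, father, mother):
            if s not in first.calls:
                raise ConfigurationError(f"trio sample {s!r} absent from call set")
    for rec in records:
        if autosomes_only and not is_autosome(rec.chrom):
            continue
        verdict = mendelian_consistent(
            rec.calls[proband].genotype,
            rec.calls[father].genotype,
            rec.calls[mother].genotype,
        )
        if verdict == UNCOUNTED:
            uncounted += 1
        else:
            evaluated += 1
            if verdict == VIOLATION:
                violations += 1
    return MieSummary(sites_evaluated=evaluated, violations=violations, uncounted=uncounted)


def unique_sample_variants(
    records: Sequence[Union[SVRecord, SNVRecord]], all_samples: Sequence[str]
) -> Dict[str, int]:
    """Count variants carried by exactly one sample in a joint-called cohort.

    A variant is unique to sample *s* iff *s* is non-reference and every
    other sample is homozygous reference. A missing genotype in any other
    sample disqualifies the site: missingness cannot certify absence.
    """
    counts = {s: 0 for s in all_samples}
    for rec in records:
        carrier = None
        ok = True
        for s in all_samples:
            call = rec.calls.get(s)
            if call is None or call.is_missing:
                ok = False
                break
            if call.is_nonref:
                if carrier is None:
                    carrier = s
                else:
                    ok = False
                    break
        if ok and carrier is not None:
            counts[carrier] += 1
    return counts
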