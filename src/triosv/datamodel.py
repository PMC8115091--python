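"""Core domain types for trio SV/SNV analysis.

Coordinates are 0-based, half-open throughout; VCF's 1-based POS is
converted on read and restored on write. Genotypes are unordered pairs of
allele indices (callers in this domain emit unphased genotypes), stored
sorted; a missing genotype is ``None``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

Genotype = Optional[Tuple[int, int]]

SV_TYPES = ("DEL", "INS", "INV")
SNV_FUNC_CLASSES = ("missense", "lof", "synonymous", "noncoding", "other")

_AUTOSOMES = {str(i) for i in range(1, 23)}


def normalize_genotype(gt: Genotype) -> Genotype:
    """Return the genotype as a sorted tuple, or None if any allele is missing."""
    if gt is None:
        return None
    a, b = gt
    if a is None or b is None:
        return None
    return (a, b) if a <= b else (b, a)


def is_autosome(chrom: str) -> bool:
    """True for chr1..chr22 with or without the 'chr' prefix."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name in _AUTOSOMES


@dataclass
class SampleCall:
    """Per-sample genotype call with read support (GT/AD/DP)."""

    genotype: Genotype = None
    depth: Optional[int] = None
    alt_support: Optional[int] = None
    ref_support: Optional[int] = None

    def __post_init__(self) -> None:
        self.genotype = normalize_genotype(self.genotype)
        if self.genotype is not None and min(self.genotype) < 0:
            raise ValueError(f"negative allele index in genotype {self.genotype}")
        for name in ("depth", "alt_support", "ref_support"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if (
            self.depth is not None
            and self.alt_support is not None
            and self.ref_support is not None
            and self.alt_support + self.ref_support > self.depth
        ):
            raise ValueError(
                f"alt_support + ref_support exceeds depth "
                f"({self.alt_support}+{self.ref_support} > {self.depth})"
            )

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def is_hom_ref(self) -> bool:
        return self.genotype == (0, 0)

    @property
    def is_het(self) -> bool:
        return self.genotype is not None and self.genotype[0] != self.genotype[1]

    @property
    def is_hom_alt(self) -> bool:
        g = self.genotype
        return g is not None and g[0] == g[1] and g[0] > 0

    @property
    def is_nonref(self) -> bool:
        return self.genotype is not None and max(self.genotype) > 0

    @property
    def alt_ratio(self) -> Optional[float]:
        """Fraction of reads supporting the alternative allele, or None."""
        if self.depth is None or self.alt_support is None or self.depth == 0:
            return None
        return self.alt_support / self.depth


@dataclass
class SVRecord:
    """One structural variant site with per-sample calls.

    ``svlen`` is the absolute affected length in bp; for insertions it is
    the inserted length and the record occupies a zero-length anchor
    (``end == start``).
    """

    chrom: str
    start: int
    end: int
    svtype: str
    svlen: int
    id: str = "."
    filter_pass: bool = True
    calls: Dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unsupported SVTYPE {self.svtype!r}")
        if self.end < self.start:
            raise ValueError(f"end < start ({self.end} < {self.start})")
        if self.svlen < 1:
            raise ValueError(f"svlen must be >= 1, got {self.svlen}")
        if self.svtype == "INS":
            if self.end != self.start:
                raise ValueError("INS records must have end == start")
        elif self.svlen != self.end - self.start:
            raise ValueError(
                f"{self.svtype} svlen {self.svlen} != end - start {self.end - self.start}"
            )

    def footprint(self) -> Tuple[int, int]:
        """Reference interval for overlap queries; INS is the 1 bp point anchor."""
        if self.svtype == "INS":
            return (self.start, self.start + 1)
        return (self.start, self.end)


@dataclass
class SNVRecord:
    """One single-nucleotide substitution site with per-sample calls."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    quality: Optional[float] = None
    func_class: str = "other"
    gene: Optional[str] = None
    id: str = "."
    filter_pass: bool = True
    calls: Dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bases = {"A", "C", "G", "T"}
        if self.ref_allele not in bases or self.alt_allele not in bases:
            raise ValueError(
                f"alleles must be single bases, got {self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.func_class not in SNV_FUNC_CLASSES:
            raise ValueError(f"unknown func_class {self.func_class!r}")

    @property
    def is_transition(self) -> bool:
        return {self.ref_allele, self.alt_allele} in ({"A", "G"}, {"C", "T"})

    @property
    def site_key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class TrioPedigree:
    """Proband/father/mother identifiers for each trio in a cohort."""

    trios: List[Tuple[str, str, str]]
    all_samples: List[str]

    def __post_init__(self) -> None:
        known = set(self.all_samples)
        for trio in self.trios:
            if len(set(trio)) != 3:
                raise ValueError(f"duplicate sample id within trio {trio}")
            missing = [s for s in trio if s not in known]
            if missing:
                raise ValueError(f"trio samples {missing} not in all_samples")

    def trio_for_proband(self, proband: str) -> Tuple[str, str, str]:
        for trio in self.trios:
            if trio[0] == proband:
                return trio
        raise KeyError(f"no trio with proband {proband!r}")


class RegionSet:
    """Immutable set of half-open genomic intervals with set algebra.

    Intervals are merged (including bookended/adjacent ones) and sorted at
    construction, matching the merge semantics of BEDtools.
    """

    __slots__ = ("_intervals",)

    def __init__(self, intervals: Optional[Iterable[Tuple[str, int, int]]] = None):
        per_contig: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in intervals or ():
            if start > end:
                raise ValueError(f"start > end on {chrom}: [{start}, {end})")
            if start == end:
                continue
            per_contig.setdefault(chrom, []).append((int(start), int(end)))
        merged: Dict[str, np.ndarray] = {}
        for chrom, ivals in per_contig.items():
            ivals.sort()
            out: List[List[int]] = []
            for s, e in ivals:
                if out and s <= out[-1][1]:  # overlap or bookended
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.asarray(out, dtype=np.int64)
        self._intervals = merged

    @classmethod
    def _from_merged(cls, merged: Dict[str, np.ndarray]) -> "RegionSet":
        rs = cls.__new__(cls)
        rs._intervals = {c: a for c, a in merged.items() if len(a)}
        return rs

    @property
    def contigs(self) -> List[str]:
        return sorted(self._intervals)

    def intervals(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) intervals on ``chrom`` (may be empty)."""
        return self._intervals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __iter__(self):
        for chrom in self.contigs:
            for s, e in self._intervals[chrom]:
                yield (chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(a) for a in self._intervals.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return list(self) == list(other)

    @property
    def total_length(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._intervals.values())
        )

    def union(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(list(self) + list(other))

    def intersection(self, other: "RegionSet") -> "RegionSet":
        out: List[Tuple[str, int, int]] = []
        for chrom in self._intervals:
            a, b = self.intervals(chrom), other.intervals(chrom)
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    out.append((chrom, int(s), int(e)))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
        return RegionSet(out)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        out: List[Tuple[str, int, int]] = []
        for chrom in self._intervals:
            b = other.intervals(chrom)
            for s, e in self._intervals[chrom]:
                cur = int(s)
                for bs, be in b:
                    if be <= cur or bs >= e:
                        continue
                    if bs > cur:
                        out.append((chrom, cur, int(bs)))
                    cur = max(cur, int(be))
                    if cur >= e:
                        break
                if cur < e:
                    out.append((chrom, cur, int(e)))
        return RegionSet._from_merged(RegionSet(out)._intervals)

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Total bp of [start, end) covered by this set."""
        a = self.intervals(chrom)
        if not len(a):
            return 0
        lo = bisect.bisect_right(a[:, 1].tolist(), start)
        total = 0
        for s, e in a[lo:]:
            if s >= end:
                break
            total += min(int(e), end) - max(int(s), start)
        return total

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.overlap_length(chrom, start, end) > 0

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals, {self.total_length} bp)"


@dataclass
class GeneModel:
    """A gene's (or its exons') genomic span with GC fraction metadata."""

    gene: str
    chrom: str
    intervals: RegionSet
    gc_fraction: float

    def __post_init__(self) -> None:
        if len(self.intervals) == 0:
            raise ValueError(f"gene {self.gene}: empty interval set")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gene {self.gene}: gc_fraction {self.gc_fraction} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.intervals.total_length

    @property
    def span(self) -> Tuple[int, int]:
        ivals = self.intervals.intervals(self.chrom)
        return int(ivals[0, 0]), int(ivals[-1, 1])
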