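"""SV call-set matching, reciprocal-overlap comparison, SNV set comparison.

The SV matcher reproduces the standard benchmarking rules for
non-sequence-resolved calls: two SVs match when they are of the same type,
their start and end breakpoints each lie within ``refdist`` bp, and the
size ratio (smaller over larger) is at least ``size_ratio_min``. Assignment
is greedy nearest-first 1:1 (deterministic; closest breakpoints win, ties
broken by size-ratio closeness to 1, then input order). Sequence similarity
is never computed — calls are compared by coordinates, type, and size only.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .datamodel import RegionSet, SNVRecord, SVRecord

logger = logging.getLogger("triosv")


@dataclass
class MatchParams:
    """Matching thresholds (all boundaries inclusive)."""

    refdist: int = 1000
    size_ratio_min: float = 0.7
    require_same_type: bool = True
    sizemin: int = 50
    sizemax: int = 1_000_000
    multimatch: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.size_ratio_min <= 1.0:
            raise ValueError("size_ratio_min must be in (0, 1]")
        if self.refdist < 0:
            raise ValueError("refdist must be >= 0")
        if self.sizemin > self.sizemax:
            raise ValueError("sizemin must be <= sizemax")


@dataclass
class MatchResult:
    """Outcome of comparing a comp call set against a base (truth) set.

    ``tp`` counts matched pairs; with multimatch enabled, recall still
    counts each base record once and precision each comp record once.
    Precision/recall are None (not 0) when their denominator is zero.
    """

    pairs: List[Tuple[SVRecord, SVRecord]] = field(default_factory=list)
    tp: int = 0
    fp: int = 0
    fn: int = 0
    precision: Optional[float] = None
    recall: Optional[float] = None


def size_ratio(a: SVRecord, b: SVRecord) -> float:
    return min(a.svlen, b.svlen) / max(a.svlen, b.svlen)


def sv_pair_matches(a: SVRecord, b: SVRecord, params: MatchParams) -> bool:
    """True iff the two records satisfy the pairwise match rule."""
    if a.chrom != b.chrom:
        return False
    if params.require_same_type and a.svtype != b.svtype:
        return False
    if abs(a.start - b.start) > params.refdist:
        return False
    if abs(a.end - b.end) > params.refdist:
        return False
    return size_ratio(a, b) >= params.size_ratio_min


def _size_eligible(r: SVRecord, params: MatchParams) -> bool:
    return params.sizemin <= r.svlen <= params.sizemax


def _candidate_pairs(
    base: Sequence[SVRecord], comp: Sequence[SVRecord], params: MatchParams
) -> List[Tuple[int, float, int, int]]:
    """All matching (base, comp) index pairs keyed by the greedy order."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for j, c in enumerate(comp):
        by_chrom.setdefault(c.chrom, []).append((c.start, j))
    for lst in by_chrom.values():
        lst.sort()
    pairs = []
    for i, b in enumerate(base):
        near = by_chrom.get(b.chrom, [])
        starts = [s for s, _ in near]
        lo = bisect.bisect_left(starts, b.start - params.refdist)
        hi = bisect.bisect_right(starts, b.start + params.refdist)
        for _, j in near[lo:hi]:
            c = comp[j]
            if sv_pair_matches(b, c, params):
                pairs.append((abs(b.start - c.start), 1.0 - size_ratio(b, c), i, j))
    pairs.sort()
    return pairs


def match_callsets(
    base: Sequence[SVRecord], comp: Sequence[SVRecord], params: Optional[MatchParams] = None
) -> MatchResult:
    """Match ``comp`` calls against a ``base`` (truth) set.

    Records outside [sizemin, sizemax] are excluded before matching.
    Without multimatch each record joins at most one pair; with multimatch
    every satisfying pair is recorded and precision/recall count distinct
    comp/base records respectively.
    """
    params = params or MatchParams()
    base = [r for r in base if _size_eligible(r, params)]
    comp = [r for r in comp if _size_eligible(r, params)]
    if base and comp:
        shared = {r.chrom for r in base} & {r.chrom for r in comp}
        if not shared:
            logger.warning("no shared contigs between base and comp call sets")
    result = MatchResult()
    cand = _candidate_pairs(base, comp, params)
    matched_base: set = set()
    matched_comp: set = set()
    for _, _, i, j in cand:
        if params.multimatch:
            result.pairs.append((base[i], comp[j]))
            matched_base.add(i)
            matched_comp.add(j)
        elif i not in matched_base and j not in matched_comp:
            result.pairs.append((base[i], comp[j]))
            matched_base.add(i)
            matched_comp.add(j)
    tp_base, tp_comp = len(matched_base), len(matched_comp)
    result.tp = len(result.pairs) if not params.multimatch else tp_comp
    result.fp = len(comp) - tp_comp
    result.fn = len(base) - tp_base
    if comp:
        result.precision = tp_comp / len(comp)
    if base:
        result.recall = tp_base / len(base)
    return result


def reciprocal_overlap_compare(
    calls: Sequence[SVRecord],
    external: Dict[str, RegionSet],
    frac: float = 0.5,
    refdist: int = 1000,
) -> List[bool]:
    """Flag each call matched against per-type external interval sets.

    DEL/INV are matched by reciprocal footprint overlap of at least ``frac``
    of both lengths. INS calls have no reference footprint, so they match
    when an external insertion interval lies within ``refdist`` of the
    anchor and the size ratio is at least ``frac``.
    """
    flags: List[bool] = []
    for rec in calls:
        ext = external.get(rec.svtype)
        matched = False
        if ext is not None:
            ivals = ext.intervals(rec.chrom)
            if rec.svtype == "INS":
                for s, e in ivals:
                    if abs(int(s) - rec.start) <= refdist:
                        elen = max(int(e) - int(s), 1)
                        if min(elen, rec.svlen) / max(elen, rec.svlen) >= frac:
                            matched = True
                            break
                    elif int(s) > rec.start + refdist:
                        break
            else:
                for s, e in ivals:
                    if int(s) >= rec.end:
                        break
                    ov = min(int(e), rec.end) - max(int(s), rec.start)
                    if ov <= 0:
                        continue
                    elen = int(e) - int(s)
                    if ov >= frac * elen and ov >= frac * (rec.end - rec.start):
                        matched = True
                        break
        flags.append(matched)
    return flags


def snv_set_compare(
    set_a: Sequence[SNVRecord], set_b: Sequence[SNVRecord]
) -> Tuple[List[SNVRecord], List[SNVRecord], List[SNVRecord]]:
    """Partition two SNV sets by site identity (chrom, pos, ref, alt).

    Returns (shared, only_a, only_b); shared holds the records from set A.
    """
    keys_a = {r.site_key for r in set_a}
    keys_b = {r.site_key for r in set_b}
    shared = [r for r in set_a if r.site_key in keys_b]
    only_a = [r for r in set_a if r.site_key not in keys_b]
    only_b = [r for r in set_b if r.site_key not in keys_a]
    return shared, only_a, only_b


def ti_tv_ratio(snvs: Sequence[SNVRecord]) -> float:
    """Transition/transversion ratio; NaN when undefined (no transversions)."""
    ti = sum(1 for r in snvs if r.is_transition)
    tv = len(snvs) - ti
    if tv == 0:
        return math.nan
    return ti / tv
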