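"""Coverage accessibility partitioning, fold-coverage summaries,
poorly-covered-gene classification, and GC-content comparison.

A :class:`CoverageTrack` is a per-contig step function of integer read
depth (mapping-quality filtering happens upstream of track construction;
the ``mapq_floor`` field is metadata). The accessibility partition splits
the genome per base into four mutually exclusive sets — covered by both
technologies, by long reads only, by short reads only, or by neither —
the digital analogue of an accessibility ideogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datamodel import GeneModel, RegionSet

logger = logging.getLogger("triosv")


class CoverageTrack:
    """Per-contig step intervals of read depth tiling each contig."""

    def __init__(
        self,
        steps: Dict[str, Tuple[np.ndarray, np.ndarray]],
        label: str = "",
        mapq_floor: int = 0,
    ):
        """``steps`` maps contig -> (edges, depth) with ``len(edges) ==
        len(depth) + 1``, ``edges[0] == 0``, strictly increasing edges."""
        self.label = label
        self.mapq_floor = mapq_floor
        self._steps: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (edges, depth) in steps.items():
            edges = np.asarray(edges, dtype=np.int64)
            depth = np.asarray(depth, dtype=np.int64)
            if len(edges) != len(depth) + 1 or edges[0] != 0 or np.any(np.diff(edges) <= 0):
                raise ValueError(f"{chrom}: step intervals must tile the contig from 0")
            if np.any(depth < 0):
                raise ValueError(f"{chrom}: negative depth")
            self._steps[chrom] = (edges, depth)

    @property
    def contigs(self) -> List[str]:
        return sorted(self._steps)

    def contig_length(self, chrom: str) -> int:
        return int(self._steps[chrom][0][-1])

    @property
    def genome_length(self) -> int:
        return sum(self.contig_length(c) for c in self._steps)

    def steps(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        return self._steps[chrom]

    def depth_at(self, chrom: str, pos: int) -> int:
        edges, depth = self._steps[chrom]
        return int(depth[np.searchsorted(edges, pos, side="right") - 1])

    def regions_where(self, predicate) -> RegionSet:
        """RegionSet of bases whose depth satisfies a vectorized predicate."""
        intervals: List[Tuple[str, int, int]] = []
        for chrom, (edges, depth) in self._steps.items():
            mask = predicate(depth)
            for i in np.nonzero(mask)[0]:
                intervals.append((chrom, int(edges[i]), int(edges[i + 1])))
        return RegionSet(intervals)

    def zero_regions(self) -> RegionSet:
        return self.regions_where(lambda d: d == 0)

    def covered_regions(self, min_depth: int = 1) -> RegionSet:
        return self.regions_where(lambda d: d >= min_depth)

    @classmethod
    def from_bedgraph(
        cls,
        path,
        label: str = "",
        mapq_floor: int = 0,
        contig_lengths: Optional[Dict[str, int]] = None,
    ) -> "CoverageTrack":
        """Read a 4-column BEDGRAPH; gaps are filled with depth 0."""
        per: Dict[str, List[Tuple[int, int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, s, e, d = line.split("\t")[:4]
                per.setdefault(chrom, []).append((int(s), int(e), int(float(d))))
        steps: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, rows in per.items():
            rows.sort()
            length = (contig_lengths or {}).get(chrom, rows[-1][1])
            edges, depths = [0], []
            for s, e, d in rows:
                if s > edges[-1]:
                    depths.append(0)
                    edges.append(s)
                depths.append(d)
                edges.append(e)
            if length > edges[-1]:
                depths.append(0)
                edges.append(length)
            steps[chrom] = (np.asarray(edges), np.asarray(depths))
        return cls(steps, label=label, mapq_floor=mapq_floor)

    def to_bedgraph(self, path, omit_zero: bool = False) -> None:
        with open(path, "w") as fh:
            for chrom in self.contigs:
                edges, depth = self._steps[chrom]
                for i in range(len(depth)):
                    if omit_zero and depth[i] == 0:
                        continue
                    fh.write(f"{chrom}\t{edges[i]}\t{edges[i + 1]}\t{depth[i]}\n")


@dataclass
class AccessibilityPartition:
    """Four disjoint accessibility sets whose union tiles the genome."""

    both: RegionSet
    lrs_only: RegionSet
    srs_only: RegionSet
    neither: RegionSet
    min_report_length: int = 1000

    def reported(self, which: str) -> RegionSet:
        """Intervals of a set at or above the reporting length threshold."""
        rs: RegionSet = getattr(self, which)
        return RegionSet(
            (c, s, e) for c, s, e in rs if e - s >= self.min_report_length
        )

    def sub_threshold(self, which: str) -> RegionSet:
        rs: RegionSet = getattr(self, which)
        return RegionSet((c, s, e) for c, s, e in rs if e - s < self.min_report_length)

    def summary(self) -> Dict[str, Dict[str, int]]:
        out = {}
        for which in ("both", "lrs_only", "srs_only", "neither"):
            rs: RegionSet = getattr(self, which)
            rep = self.reported(which)
            out[which] = {
                "total_bp": rs.total_length,
                "n_intervals": len(rs),
                "reported_bp": rep.total_length,
                "n_reported": len(rep),
                "sub_threshold_bp": rs.total_length - rep.total_length,
            }
        return out


def partition_coverage(
    lrs: CoverageTrack,
    srs: CoverageTrack,
    min_report_length: int = 1000,
    min_depth: int = 1,
) -> AccessibilityPartition:
    """Partition the genome by per-base accessibility in two tracks.

    A base is covered in a track when its depth is at least ``min_depth``
    (default 1, i.e. the sets are defined by absence of coverage).
    """
    if set(lrs.contigs) != set(srs.contigs):
        odd = set(lrs.contigs) ^ set(srs.contigs)
        raise ValueError(f"contigs present in only one track: {sorted(odd)}")
    sets: Dict[str, List[Tuple[str, int, int]]] = {
        "both": [], "lrs_only": [], "srs_only": [], "neither": []
    }
    for chrom in lrs.contigs:
        e1, d1 = lrs.steps(chrom)
        e2, d2 = srs.steps(chrom)
        if e1[-1] != e2[-1]:
            raise ValueError(f"{chrom}: track lengths differ ({e1[-1]} vs {e2[-1]})")
        edges = np.union1d(e1, e2)
        mids = (edges[:-1] + edges[1:]) // 2
        lv = d1[np.searchsorted(e1, mids, side="right") - 1] >= min_depth
        sv = d2[np.searchsorted(e2, mids, side="right") - 1] >= min_depth
        cls = np.where(lv & sv, 0, np.where(lv, 1, np.where(sv, 2, 3)))
        names = ("both", "lrs_only", "srs_only", "neither")
        for i in range(len(cls)):
            sets[names[cls[i]]].append((chrom, int(edges[i]), int(edges[i + 1])))
    return AccessibilityPartition(
        both=RegionSet(sets["both"]),
        lrs_only=RegionSet(sets["lrs_only"]),
        srs_only=RegionSet(sets["srs_only"]),
        neither=RegionSet(sets["neither"]),
        min_report_length=min_report_length,
    )


def _auto_difficult(track: CoverageTrack, difficult: RegionSet) -> RegionSet:
    """Append whole chrY contigs to the difficult set."""
    extra = [
        (c, 0, track.contig_length(c))
        for c in track.contigs
        if c.lower() in ("chry", "y")
    ]
    return difficult.union(RegionSet(extra)) if extra else difficult


def fold_coverage_summary(
    track: CoverageTrack,
    difficult: RegionSet,
    thresholds: Sequence[int] = (5, 10, 15, 20),
) -> Dict[str, Dict[int, float]]:
    """Fraction of the genome at or above each fold-coverage threshold.

    ``restricted`` excludes the difficult regions (chrY auto-appended);
    ``unrestricted`` is the whole-genome fraction.
    """
    difficult = _auto_difficult(track, difficult)
    genome = RegionSet((c, 0, track.contig_length(c)) for c in track.contigs)
    accessible = genome.subtract(difficult)
    out: Dict[str, Dict[int, float]] = {"restricted": {}, "unrestricted": {}}
    for t in thresholds:
        cov = track.covered_regions(min_depth=t)
        out["unrestricted"][t] = (
            cov.total_length / genome.total_length if genome.total_length else 0.0
        )
        out["restricted"][t] = (
            cov.intersection(accessible).total_length / accessible.total_length
            if accessible.total_length
            else 0.0
        )
    return out


def gene_coverage_classify(
    genes: Sequence[GeneModel],
    srs: CoverageTrack,
    uncovered_frac: float = 0.10,
) -> Dict[str, str]:
    """Label each gene well/poorly covered by the short-read track.

    Poorly covered: at least ``uncovered_frac`` of the gene's length has
    zero depth (inclusive at the threshold).
    """
    zero = srs.zero_regions()
    labels: Dict[str, str] = {}
    for g in genes:
        uncovered = sum(
            zero.overlap_length(g.chrom, int(s), int(e))
            for s, e in g.intervals.intervals(g.chrom)
        )
        frac = uncovered / g.length
        labels[g.gene] = "poorly_covered" if frac >= uncovered_frac else "well_covered"
    return labels


@dataclass
class GcComparison:
    mean_poor: float
    mean_control: float
    t_statistic: float
    p_value: float
    controls: List[GeneModel] = field(default_factory=list)


def gc_comparison(
    poor_genes: Sequence[GeneModel],
    well_covered_genes: Sequence[GeneModel],
    seed: int = 0,
    length_window: float = 0.2,
) -> GcComparison:
    """Welch's t-test of GC content: poor genes vs length-matched controls.

    One control is drawn (seeded, without replacement) per poor gene from
    well-covered genes within a ±``length_window`` relative length window;
    an empty window is widened with a warning until a control is found.
    """
    rng = np.random.default_rng(seed)
    available = list(well_covered_genes)
    controls: List[GeneModel] = []
    order = rng.permutation(len(poor_genes))
    for idx in order:
        g = poor_genes[idx]
        window = length_window
        while True:
            cand = [
                i for i, w in enumerate(available)
                if abs(w.length - g.length) <= window * g.length
            ]
            if cand:
                break
            window *= 2.0
            logger.warning(
                "gc_comparison: no control within ±%.0f%% of %d bp for %s; widening",
                100 * window / 2, g.length, g.gene,
            )
            if window > 100:  # degenerate pool; take anything left
                cand = list(range(len(available)))
                break
        if not cand:
            break
        pick = cand[rng.integers(len(cand))]
        controls.append(available.pop(pick))
        if not available:
            break
    poor_gc = np.array([g.gc_fraction for g in poor_genes], dtype=float)
    ctrl_gc = np.array([g.gc_fraction for g in controls], dtype=float)
    mean_poor = float(poor_gc.mean()) if len(poor_gc) else float("nan")
    mean_ctrl = float(ctrl_gc.mean()) if len(ctrl_gc) else float("nan")
    if (
        len(poor_gc)
        and len(ctrl_gc)
        and np.isclose(mean_poor, mean_ctrl)
        and poor_gc.std() == 0
        and ctrl_gc.std() == 0
    ):
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_ind(poor_gc, ctrl_gc, equal_var=False)
    return GcComparison(
        mean_poor=mean_poor,
        mean_control=mean_ctrl,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        controls=controls,
    )
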