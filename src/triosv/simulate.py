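"""Seeded simulator of joint-called trio cohorts with a truth ledger.

The generator emulates the statistical structure of a long-read trio
study: founder SVs drawn from a type mixture dominated by insertions
(63%) and deletions (37%) with a trace of inversions, sizes following a
truncated power-law decay with point-mass peaks at ~300 bp (Alu) and
~6.4 kb (LINE1); Mendelian transmission to each proband; rare de novo
events (0.2 per genome per generation by default); genotype-flip errors
and parental dropout (a true parental het called homozygous reference
while its supporting reads remain — the process that produces apparent
de novo calls in offspring); per-sample read support with depth Poisson
in coverage and allele-balanced het support; SNVs with a controlled
transition/transversion ratio; and paired coverage tracks where the
short-read track loses depth in GC-rich windows.

Every simulated variant is recorded in a :class:`TruthLedger` with its
true and called genotypes, injected error events, and read support, so
downstream operations can be checked against ledger-derived expectations.
All randomness flows from a single seed through named substreams.
"""

from __future__ import annotations

import bisect
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .datamodel import GeneModel, RegionSet, SampleCall, SNVRecord, SVRecord, TrioPedigree

_GT_FROM_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SimConfig:
    """Study conditions for the simulated cohort (desk scale by default:
    three 10 Mb contigs with counts scaled accordingly)."""

    contigs: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    )
    n_trios: int = 5
    # --- structural variants ---
    n_sv: int = 5_000
    sv_type_weights: Dict[str, float] = field(
        default_factory=lambda: {"INS": 0.63, "DEL": 0.37, "INV": 0.0005}
    )
    sv_size_bounds: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {"INS": (50, 5_000), "DEL": (50, 100_000), "INV": (200, 5_000)}
    )
    sv_size_alpha: float = 1.6  # power-law decay exponent
    sv_size_peaks: Dict[int, float] = field(
        default_factory=lambda: {300: 0.20, 6_400: 0.05}  # Alu, LINE1 point masses
    )
    af_beta: Tuple[float, float] = (0.3, 1.5)  # founder allele-frequency prior
    de_novo_rate: float = 0.2  # mean events per child genome per generation
    genotype_error_rate: float = 0.02
    parental_dropout_rate: float = 0.005
    # --- read support / detection ---
    coverage: float = 15.0  # fold coverage per sample
    min_supporting_reads: int = 3  # k reads to call a variant detected
    het_allele_read_prob: float = 0.5  # allelic bias knob, balanced by default
    # --- SNVs ---
    n_snv: int = 50_000
    ti_tv_target: float = 2.1
    snv_class_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "noncoding": 0.83, "synonymous": 0.05, "missense": 0.08, "lof": 0.01, "other": 0.03
        }
    )
    snv_qual_mean: float = 55.0
    snv_qual_sd: float = 20.0
    # --- genes and coverage tracks ---
    n_genes: int = 200
    gene_length_log_mean: float = 9.9  # exp(9.9) ~ 20 kb
    gene_length_log_sd: float = 0.6
    gene_gc_mean: float = 0.46
    gene_gc_sd: float = 0.07
    coverage_window: int = 1_000
    lrs_track_coverage: float = 30.0
    srs_track_coverage: float = 30.0
    gc_bias_strength: float = 8.0
    gc_knee: float = 0.55
    seed: int = 0

    def sample_names(self) -> List[str]:
        out = []
        for i in range(1, self.n_trios + 1):
            out += [f"T{i}P", f"T{i}F", f"T{i}M"]
        return out

    def pedigree(self) -> TrioPedigree:
        samples = self.sample_names()
        trios = [tuple(samples[3 * i : 3 * i + 3]) for i in range(self.n_trios)]
        return TrioPedigree(trios=trios, all_samples=samples)


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child RNG of the global seed."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class TruthEntry:
    """Ledger row: one simulated variant with per-sample truth and calls."""

    id: str
    chrom: str
    start: int
    end: int
    kind: str  # "sv" | "snv"
    svtype: Optional[str]
    svlen: Optional[int]
    origin: str  # "founder" | "de_novo"
    de_novo_child: Optional[str]
    true_gt: Dict[str, int]  # dosage 0/1/2
    called_gt: Dict[str, int]
    depth: Dict[str, int]
    alt_support: Dict[str, int]
    errors: Dict[str, str]  # sample -> "flip" | "dropout"


@dataclass
class TruthLedger:
    sv_entries: List[TruthEntry] = field(default_factory=list)
    snv_entries: List[TruthEntry] = field(default_factory=list)
    skipped_placements: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for entry in self.sv_entries + self.snv_entries:
            row = {
                "id": entry.id, "chrom": entry.chrom, "start": entry.start,
                "end": entry.end, "kind": entry.kind, "svtype": entry.svtype,
                "svlen": entry.svlen, "origin": entry.origin,
                "de_novo_child": entry.de_novo_child or "",
            }
            for s, d in entry.true_gt.items():
                row[f"true_gt_{s}"] = d
                row[f"called_gt_{s}"] = entry.called_gt[s]
                row[f"dp_{s}"] = entry.depth[s]
                row[f"alt_{s}"] = entry.alt_support[s]
                row[f"err_{s}"] = entry.errors.get(s, "")
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SimResult:
    config: SimConfig
    pedigree: TrioPedigree
    sv_records: List[SVRecord]
    snv_records: List[SNVRecord]
    ledger: TruthLedger


# ---------------------------------------------------------------------------
# SV site generation
# ---------------------------------------------------------------------------

def _draw_sizes(rng: np.random.Generator, svtypes: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Mixture of truncated power law and repeat-peak point masses, within
    per-type size bounds."""
    sizes = np.zeros(len(svtypes), dtype=np.int64)
    alpha = cfg.sv_size_alpha
    for i, t in enumerate(svtypes):
        lo, hi = cfg.sv_size_bounds[t]
        peaks = {p: w for p, w in cfg.sv_size_peaks.items() if lo <= p <= hi}
        total_peak = sum(peaks.values())
        u = rng.random()
        if u < total_peak:
            acc = 0.0
            for p, w in peaks.items():
                acc += w
                if u < acc:
                    sizes[i] = p
                    break
        else:
            # inverse CDF of a Pareto-like density ~ x^-alpha truncated to [lo, hi]
            v = rng.random()
            a1 = 1.0 - alpha
            sizes[i] = int((lo ** a1 + v * (hi ** a1 - lo ** a1)) ** (1.0 / a1))
            sizes[i] = min(max(sizes[i], lo), hi)
    return sizes


def _place_sites(
    rng: np.random.Generator,
    cfg: SimConfig,
    svtypes: np.ndarray,
    sizes: np.ndarray,
    max_retries: int = 20,
) -> Tuple[List[Tuple[str, int]], int]:
    """Assign non-overlapping positions (DEL/INV by footprint, INS by
    anchor); colliding placements are retried and finally skipped."""
    contigs = list(cfg.contigs)
    lengths = np.array([cfg.contigs[c] for c in contigs], dtype=float)
    probs = lengths / lengths.sum()
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contigs}
    positions: List[Optional[Tuple[str, int]]] = []
    skipped = 0
    for i in range(len(svtypes)):
        foot = 1 if svtypes[i] == "INS" else int(sizes[i])
        placed = None
        for _ in range(max_retries):
            ci = rng.choice(len(contigs), p=probs)
            chrom = contigs[ci]
            limit = cfg.contigs[chrom] - foot
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + foot
            ivals = occupied[chrom]
            j = bisect.bisect_left(ivals, (start, end))
            if j > 0 and ivals[j - 1][1] > start:
                continue
            if j < len(ivals) and ivals[j][0] < end:
                continue
            ivals.insert(j, (start, end))
            placed = (chrom, start)
            break
        if placed is None:
            skipped += 1
        positions.append(placed)
    return positions, skipped


# ---------------------------------------------------------------------------
# Genotypes: founders, transmission, errors
# ---------------------------------------------------------------------------

def _founder_and_child_dosages(
    rng: np.random.Generator, af: np.ndarray, n_trios: int
) -> np.ndarray:
    """Cohort dosage matrix (n_sites x 3*n_trios) ordered P, F, M per trio.

    Founder genotypes are Hardy-Weinberg draws at each site's allele
    frequency; each child receives one transmitted allele per parent.
    """
    n = len(af)
    out = np.zeros((n, 3 * n_trios), dtype=np.int8)
    for t in range(n_trios):
        father = (rng.random((n, 2)) < af[:, None]).sum(axis=1).astype(np.int8)
        mother = (rng.random((n, 2)) < af[:, None]).sum(axis=1).astype(np.int8)
        # transmitted allele: P(alt) = dosage / 2
        from_f = (rng.random(n) < father / 2.0).astype(np.int8)
        from_m = (rng.random(n) < mother / 2.0).astype(np.int8)
        out[:, 3 * t + 0] = from_f + from_m
        out[:, 3 * t + 1] = father
        out[:, 3 * t + 2] = mother
    return out


def _inject_call_errors(
    rng: np.random.Generator,
    true_dosage: np.ndarray,
    cfg: SimConfig,
    parent_cols: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Return (called dosage, error codes) — 0 none, 1 flip, 2 dropout."""
    called = true_dosage.copy()
    err = np.zeros_like(true_dosage)
    # parental dropout: true het parent called hom-ref, reads untouched
    if cfg.parental_dropout_rate > 0:
        drop = np.zeros(true_dosage.shape, dtype=bool)
        drop[:, parent_cols] = rng.random((true_dosage.shape[0], len(parent_cols))) < cfg.parental_dropout_rate
        drop &= true_dosage == 1
        called[drop] = 0
        err[drop] = 2
    # genotype flips: replace with one of the two other genotypes
    if cfg.genotype_error_rate > 0:
        flip = (rng.random(true_dosage.shape) < cfg.genotype_error_rate) & (err == 0)
        shift = rng.integers(1, 3, size=true_dosage.shape).astype(np.int8)
        called[flip] = (true_dosage[flip] + shift[flip]) % 3
        err[flip] = 1
    return called, err


def _read_support(
    rng: np.random.Generator, true_dosage: np.ndarray, coverage: float, het_p: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Depth ~ Poisson(coverage); alt ~ Binomial(depth, p_genotype)."""
    depth = rng.poisson(coverage, size=true_dosage.shape)
    p = np.choose(true_dosage, [0.0, het_p, 1.0])
    alt = rng.binomial(depth, p)
    return depth, alt


_ERR_NAMES = {0: "", 1: "flip", 2: "dropout"}


def _build_entries(
    ids, chroms, starts, ends, kind, svtypes, svlens, origins, dn_children,
    samples, true_d, called_d, depth, alt,
    err,
) -> List[TruthEntry]:
    entries = []
    for i in range(len(ids)):
        entries.append(
            TruthEntry(
                id=ids[i], chrom=chroms[i], start=int(starts[i]), end=int(ends[i]),
                kind=kind,
                svtype=None if svtypes is None else svtypes[i],
                svlen=None if svlens is None else int(svlens[i]),
                origin=origins[i], de_novo_child=dn_children[i],
                true_gt={s: int(true_d[i, j]) for j, s in enumerate(samples)},
                called_gt={s: int(called_d[i, j]) for j, s in enumerate(samples)},
                depth={s: int(depth[i, j]) for j, s in enumerate(samples)},
                alt_support={s: int(alt[i, j]) for j, s in enumerate(samples)},
                errors={
                    s: _ERR_NAMES[int(err[i, j])]
                    for j, s in enumerate(samples)
                    if err[i, j]
                },
            )
        )
    return entries


def _entry_to_sv_record(entry: TruthEntry, samples: Sequence[str]) -> SVRecord:
    calls = {}
    for s in samples:
        dp, a = entry.depth[s], entry.alt_support[s]
        calls[s] = SampleCall(
            genotype=_GT_FROM_DOSAGE[entry.called_gt[s]],
            depth=dp, alt_support=a, ref_support=dp - a,
        )
    return SVRecord(
        chrom=entry.chrom, start=entry.start, end=entry.end,
        svtype=entry.svtype, svlen=entry.svlen, id=entry.id, calls=calls,
    )


def simulate_trio_cohort(config: SimConfig) -> SimResult:
    """Simulate the full cohort: SVs, SNVs, pedigree, and truth ledger.

    Identical configs (including seed) produce identical outputs.
    """
    ped = config.pedigree()
    samples = ped.all_samples
    parent_cols = np.array(
        [j for j in range(len(samples)) if j % 3 != 0], dtype=int
    )
    ledger = TruthLedger()

    # ---- SV sites -------------------------------------------------------
    rng_sites = substream(config.seed, "sv_sites")
    type_names = list(config.sv_type_weights)
    w = np.array([config.sv_type_weights[t] for t in type_names], dtype=float)
    svtypes = np.array(
        [type_names[i] for i in rng_sites.choice(len(type_names), size=config.n_sv, p=w / w.sum())]
    )
    sizes = _draw_sizes(rng_sites, svtypes, config)
    positions, skipped = _place_sites(rng_sites, config, svtypes, sizes)
    ledger.skipped_placements = skipped
    keep = [i for i, p in enumerate(positions) if p is not None]
    svtypes, sizes = svtypes[keep], sizes[keep]
    chroms = np.array([positions[i][0] for i in keep])
    starts = np.array([positions[i][1] for i in keep], dtype=np.int64)
    ends = np.where(svtypes == "INS", starts, starts + sizes)

    # ---- genotypes ------------------------------------------------------
    rng_gt = substream(config.seed, "sv_genotypes")
    af = rng_gt.beta(*config.af_beta, size=len(starts))
    true_d = _founder_and_child_dosages(rng_gt, af, config.n_trios)

    # ---- de novo events -------------------------------------------------
    rng_dn = substream(config.seed, "sv_denovo")
    dn_rows = []
    for t in range(config.n_trios):
        n_dn = rng_dn.poisson(config.de_novo_rate)
        for _ in range(n_dn):
            dn_rows.append(t)
    if dn_rows:
        dn_types = np.array(
            [type_names[i] for i in rng_dn.choice(len(type_names), size=len(dn_rows), p=w / w.sum())]
        )
        dn_sizes = _draw_sizes(rng_dn, dn_types, config)
        dn_pos, dn_skip = _place_sites(rng_dn, config, dn_types, dn_sizes)
        ledger.skipped_placements += dn_skip
        dn_keep = [i for i, p in enumerate(dn_pos) if p is not None]
        dn_d = np.zeros((len(dn_keep), len(samples)), dtype=np.int8)
        kept_rows = [dn_rows[i] for i in dn_keep]
        for r, t in enumerate(kept_rows):
            dn_d[r, 3 * t] = 1  # het in the proband only
        svtypes = np.concatenate([svtypes, dn_types[dn_keep]])
        sizes = np.concatenate([sizes, dn_sizes[dn_keep]])
        chroms = np.concatenate([chroms, [dn_pos[i][0] for i in dn_keep]])
        dn_starts = np.array([dn_pos[i][1] for i in dn_keep], dtype=np.int64)
        starts = np.concatenate([starts, dn_starts])
        ends = np.concatenate(
            [ends, np.where(dn_types[dn_keep] == "INS", dn_starts, dn_starts + dn_sizes[dn_keep])]
        )
        true_d = np.vstack([true_d, dn_d])
        origins = ["founder"] * (len(starts) - len(dn_keep)) + ["de_novo"] * len(dn_keep)
        dn_children = [None] * (len(starts) - len(dn_keep)) + [samples[3 * t] for t in kept_rows]
    else:
        origins = ["founder"] * len(starts)
        dn_children = [None] * len(starts)

    # ---- errors and reads ----------------------------------------------
    rng_err = substream(config.seed, "sv_errors")
    called_d, err = _inject_call_errors(rng_err, true_d, config, parent_cols)
    rng_reads = substream(config.seed, "sv_reads")
    depth, alt = _read_support(rng_reads, true_d, config.coverage, config.het_allele_read_prob)

    # keep sites carried (in truth or call) by at least one sample
    poly = (true_d.max(axis=1) > 0) | (called_d.max(axis=1) > 0)
    order = np.lexsort((starts, chroms))
    order = order[poly[order]]
    ids = [f"sv_{i}" for i in range(len(order))]
    ledger.sv_entries = _build_entries(
        ids, chroms[order], starts[order], ends[order], "sv",
        svtypes[order], sizes[order],
        [origins[i] for i in order], [dn_children[i] for i in order],
        samples, true_d[order], called_d[order], depth[order], alt[order], err[order],
    )
    sv_records = [_entry_to_sv_record(entry, samples) for entry in ledger.sv_entries]

    # ---- SNVs -----------------------------------------------------------
    snv_records = simulate_snvs(config, genes=None, ledger=ledger)
    return SimResult(
        config=config, pedigree=ped, sv_records=sv_records,
        snv_records=snv_records, ledger=ledger,
    )


# ---------------------------------------------------------------------------
# SNVs
# ---------------------------------------------------------------------------

def simulate_snvs(
    config: SimConfig,
    genes: Optional[Sequence[GeneModel]] = None,
    ledger: Optional[TruthLedger] = None,
) -> List[SNVRecord]:
    """Simulate cohort SNVs with the configured Ti/Tv ratio.

    Transitions are chosen with probability ti_tv/(1 + ti_tv). Coding-class
    sites are placed inside gene intervals when gene models are supplied
    (and inherit the gene symbol); otherwise positions are uniform.
    """
    ped = config.pedigree()
    samples = ped.all_samples
    parent_cols = np.array([j for j in range(len(samples)) if j % 3 != 0], dtype=int)
    rng = substream(config.seed, "snv_sites")
    n = config.n_snv

    classes = list(config.snv_class_weights)
    cw = np.array([config.snv_class_weights[c] for c in classes], dtype=float)
    func = np.array([classes[i] for i in rng.choice(len(classes), size=n, p=cw / cw.sum())])

    contigs = list(config.contigs)
    lengths = np.array([config.contigs[c] for c in contigs], dtype=float)
    ci = rng.choice(len(contigs), size=n, p=lengths / lengths.sum())
    pos = np.array([rng.integers(0, config.contigs[contigs[c]]) for c in ci], dtype=np.int64)
    chrom_arr = np.array([contigs[c] for c in ci])
    gene_arr: List[Optional[str]] = [None] * n
    if genes:
        coding = np.isin(func, ("missense", "lof", "synonymous"))
        gidx = rng.choice(len(genes), size=int(coding.sum()))
        for slot, gi in zip(np.nonzero(coding)[0], gidx):
            g = genes[gi]
            span = g.span
            chrom_arr[slot] = g.chrom
            pos[slot] = rng.integers(span[0], span[1])
            gene_arr[slot] = g.gene

    # unique site positions per contig
    seen = set()
    for i in range(n):
        while (chrom_arr[i], int(pos[i])) in seen:
            pos[i] = rng.integers(0, config.contigs[chrom_arr[i]])
        seen.add((chrom_arr[i], int(pos[i])))

    refs = np.array(list("ACGT"))[rng.integers(0, 4, size=n)]
    is_ti = rng.random(n) < config.ti_tv_target / (1.0 + config.ti_tv_target)
    alts = np.empty(n, dtype="<U1")
    tv_pick = rng.integers(0, 2, size=n)
    for i in range(n):
        alts[i] = _TRANSITION[refs[i]] if is_ti[i] else _TRANSVERSIONS[refs[i]][tv_pick[i]]
    qual = np.clip(rng.normal(config.snv_qual_mean, config.snv_qual_sd, size=n), 1.0, 100.0)

    rng_gt = substream(config.seed, "snv_genotypes")
    af = rng_gt.beta(*config.af_beta, size=n)
    true_d = _founder_and_child_dosages(rng_gt, af, config.n_trios)
    rng_err = substream(config.seed, "snv_errors")
    called_d, err = _inject_call_errors(rng_err, true_d, config, parent_cols)
    rng_reads = substream(config.seed, "snv_reads")
    depth, alt_sup = _read_support(
        rng_reads, true_d, config.coverage, config.het_allele_read_prob
    )

    poly = (true_d.max(axis=1) > 0) | (called_d.max(axis=1) > 0)
    order = np.lexsort((pos, chrom_arr))
    order = order[poly[order]]
    ids = [f"snv_{i}" for i in range(len(order))]
    entries = _build_entries(
        ids, chrom_arr[order], pos[order], pos[order] + 1, "snv",
        None, None, ["founder"] * len(order), [None] * len(order),
        samples, true_d[order], called_d[order], depth[order], alt_sup[order], err[order],
    )
    if ledger is not None:
        ledger.snv_entries = entries
    records = []
    for rank, i in enumerate(order):
        entry = entries[rank]
        calls = {}
        for j, s in enumerate(samples):
            dp, a = int(depth[i, j]), int(alt_sup[i, j])
            calls[s] = SampleCall(
                genotype=_GT_FROM_DOSAGE[int(called_d[i, j])],
                depth=dp, alt_support=a, ref_support=dp - a,
            )
        records.append(
            SNVRecord(
                chrom=str(chrom_arr[i]), pos=int(pos[i]),
                ref_allele=str(refs[i]), alt_allele=str(alts[i]),
                quality=float(qual[i]), func_class=str(func[i]),
                gene=gene_arr[i], id=entry.id, calls=calls,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Read support / detection at arbitrary coverage (titration inputs)
# ---------------------------------------------------------------------------

def simulate_read_support(
    ledger: TruthLedger,
    coverage: float,
    k: int,
    seed: int,
    het_p: float = 0.5,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Redraw per-sample read support for every ledger SV at a coverage.

    Depth is Poisson(coverage); alternative support Binomial(depth, 0.5)
    for hets and Binomial(depth, 1) for homozygous carriers. A variant is
    detected in a sample when its alternative support reaches ``k`` reads.
    Returns {sample: {"depth", "alt_support", "detected"}} arrays aligned
    with ``ledger.sv_entries``.
    """
    if coverage <= 0 or k < 1:
        raise ValueError("coverage must be > 0 and k >= 1")
    rng = substream(seed, f"read_support_{coverage:g}")
    entries = ledger.sv_entries
    samples = list(entries[0].true_gt) if entries else []
    true_d = np.array([[e.true_gt[s] for s in samples] for e in entries], dtype=np.int8)
    depth, alt = _read_support(rng, true_d, coverage, het_p)
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for j, s in enumerate(samples):
        out[s] = {
            "depth": depth[:, j],
            "alt_support": alt[:, j],
            "detected": (alt[:, j] >= k) & (true_d[:, j] > 0),
        }
    return out


def titration_callsets(
    ledger: TruthLedger,
    sample: str,
    coverages: Sequence[float],
    k: int,
    seed: int,
    het_p: float = 0.5,
) -> Tuple[List[SVRecord], Dict[float, List[SVRecord]]]:
    """Truth call set (variants carried by ``sample``) and the detected
    subset at each coverage, as SV records ready for matching."""
    entries = ledger.sv_entries
    carried = [e for e in entries if e.true_gt[sample] > 0]
    samples = list(entries[0].true_gt) if entries else []
    truth = [_entry_to_sv_record(e, samples) for e in carried]
    callsets: Dict[float, List[SVRecord]] = {}
    for cov in coverages:
        support = simulate_read_support(ledger, cov, k, seed, het_p)[sample]
        detected_ids = {
            entries[i].id for i in np.nonzero(support["detected"])[0]
        }
        callsets[cov] = [r for r in truth if r.id in detected_ids]
    return truth, callsets


# ---------------------------------------------------------------------------
# Genes and coverage tracks
# ---------------------------------------------------------------------------

def simulate_genes(config: SimConfig) -> List[GeneModel]:
    """Non-overlapping gene models with lognormal lengths and normal GC."""
    rng = substream(config.seed, "genes")
    contigs = list(config.contigs)
    lengths = np.array([config.contigs[c] for c in contigs], dtype=float)
    probs = lengths / lengths.sum()
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contigs}
    genes: List[GeneModel] = []
    for i in range(config.n_genes):
        size = int(
            np.clip(
                rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd),
                2_000, 500_000,
            )
        )
        gc = float(np.clip(rng.normal(config.gene_gc_mean, config.gene_gc_sd), 0.30, 0.72))
        for _ in range(30):
            ci = rng.choice(len(contigs), p=probs)
            chrom = contigs[ci]
            if config.contigs[chrom] <= size:
                continue
            start = int(rng.integers(0, config.contigs[chrom] - size))
            end = start + size
            ivals = occupied[chrom]
            j = bisect.bisect_left(ivals, (start, end))
            if j > 0 and ivals[j - 1][1] > start:
                continue
            if j < len(ivals) and ivals[j][0] < end:
                continue
            ivals.insert(j, (start, end))
            genes.append(
                GeneModel(
                    gene=f"GENE{i + 1}", chrom=chrom,
                    intervals=RegionSet([(chrom, start, end)]), gc_fraction=gc,
                )
            )
            break
    return genes


def simulate_coverage_tracks(
    config: SimConfig, genes: Sequence[GeneModel]
) -> Tuple[CoverageTrack, CoverageTrack]:
    """Paired LRS/SRS depth tracks in fixed windows.

    The long-read track is uniform Poisson. The short-read track's mean is
    scaled by exp(-gc_bias_strength * max(0, gc - 0.5)) per window, and
    windows beyond the GC knee drop to zero coverage with probability
    rising to 1 — so GC-rich genes lose short-read coverage.
    """
    rng = substream(config.seed, "coverage_tracks")
    wsize = config.coverage_window
    lrs_steps: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    srs_steps: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    gene_by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, length in config.contigs.items():
        n_win = max(1, length // wsize)
        edges = np.arange(n_win + 1, dtype=np.int64) * wsize
        edges[-1] = length
        gc = np.clip(rng.normal(0.42, 0.02, size=n_win), 0.25, 0.75)
        for g in gene_by_chrom.get(chrom, []):
            s, e = g.span
            w0, w1 = s // wsize, min(n_win, (e + wsize - 1) // wsize)
            gc[w0:w1] = np.clip(
                rng.normal(g.gc_fraction, 0.01, size=max(0, w1 - w0)), 0.25, 0.80
            )
        lrs_depth = rng.poisson(config.lrs_track_coverage, size=n_win)
        scale = np.exp(-config.gc_bias_strength * np.maximum(0.0, gc - 0.5))
        srs_depth = rng.poisson(config.srs_track_coverage * scale)
        if config.gc_bias_strength > 0:
            p_drop = np.clip((gc - config.gc_knee) / 0.05, 0.0, 1.0)
            srs_depth = np.where(rng.random(n_win) < p_drop, 0, srs_depth)
        lrs_steps[chrom] = (edges, lrs_depth)
        srs_steps[chrom] = (edges, srs_depth)
    return (
        CoverageTrack(lrs_steps, label="LRS", mapq_floor=10),
        CoverageTrack(srs_steps, label="SRS", mapq_floor=10),
    )


def simulate_difficult_regions(config: SimConfig, frac: float = 0.02) -> RegionSet:
    """A centromere-like difficult block in the middle of each contig."""
    out = []
    for chrom, length in config.contigs.items():
        half = int(length * frac / 2)
        mid = length // 2
        out.append((chrom, mid - half, mid + half))
    return RegionSet(out)


def write_outputs(sim: SimResult, outdir) -> Dict[str, Path]:
    """Write the simulated cohort to disk (VCFs, PED, BEDs, tracks, ledger)."""
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = sim.config
    genes = simulate_genes(cfg)
    lrs, srs = simulate_coverage_tracks(cfg, genes)
    paths = {
        "sv_vcf": outdir / "sv.vcf",
        "snv_vcf": outdir / "snv.vcf",
        "ped": outdir / "trios.ped",
        "genes_bed": outdir / "genes.bed",
        "genes_gc": outdir / "genes_gc.tsv",
        "difficult_bed": outdir / "difficult.bed",
        "lrs_bedgraph": outdir / "lrs.bedgraph",
        "srs_bedgraph": outdir / "srs.bedgraph",
        "ledger": outdir / "ledger.tsv",
    }
    tio.write_cohort_vcf(paths["sv_vcf"], sim.sv_records, sim.pedigree.all_samples, cfg.contigs)
    tio.write_cohort_vcf(paths["snv_vcf"], sim.snv_records, sim.pedigree.all_samples, cfg.contigs)
    tio.write_pedigree(paths["ped"], sim.pedigree)
    tio.write_gene_models(paths["genes_bed"], genes, paths["genes_gc"])
    tio.write_regions(paths["difficult_bed"], simulate_difficult_regions(cfg))
    lrs.to_bedgraph(paths["lrs_bedgraph"])
    srs.to_bedgraph(paths["srs_bedgraph"])
    sim.ledger.to_dataframe().to_csv(paths["ledger"], sep="\t", index=False)
    return paths
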