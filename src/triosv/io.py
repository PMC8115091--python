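"""Readers and writers for VCF, BED, BEDGRAPH, and pedigree files.

VCF parsing and writing go through :mod:`pysam`. All coordinates are
converted to 0-based half-open on read and restored to VCF conventions on
write (POS 1-based; SVLEN negative for deletions; END == POS for
insertions).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pysam

from .datamodel import (
    GeneModel,
    RegionSet,
    SampleCall,
    SNVRecord,
    SVRecord,
    TrioPedigree,
)

logger = logging.getLogger("triosv")

PathLike = Union[str, Path]


class InputError(ValueError):
    """A malformed input file."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _parse_call(sample) -> SampleCall:
    gt = sample.get("GT")
    if gt is not None and (len(gt) != 2 or any(a is None for a in gt)):
        gt = None
    ad = sample.get("AD")
    dp = sample.get("DP")
    ref_sup = alt_sup = None
    if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
        ref_sup, alt_sup = int(ad[0]), int(ad[1])
    return SampleCall(
        genotype=tuple(gt) if gt is not None else None,
        depth=int(dp) if dp is not None else None,
        alt_support=alt_sup,
        ref_support=ref_sup,
    )


def _record_filter_pass(rec) -> bool:
    keys = list(rec.filter.keys())
    return not keys or keys == ["PASS"]


def read_cohort_vcf(
    path: PathLike,
    kind: str,
    passonly: bool = True,
) -> Union[List[SVRecord], List[SNVRecord]]:
    """Read a multi-sample VCF into SV or SNV records.

    Parameters
    ----------
    kind
        ``"sv"`` or ``"snv"``.
    passonly
        Drop records whose FILTER is anything other than PASS or ``.``
        (default on).

    SV records lacking an SVTYPE are skipped with a warning; malformed
    headers or missing GT FORMAT raise :class:`InputError` naming the line.
    """
    if kind not in ("sv", "snv"):
        raise ValueError(f"kind must be 'sv' or 'snv', got {kind!r}")
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise InputError(f"{path}: malformed VCF header: {exc}") from exc
    if "GT" not in vcf.header.formats:
        raise InputError(f"{path}: required FORMAT field GT missing from header")
    n_header = str(vcf.header).count("\n")

    records: List[Union[SVRecord, SNVRecord]] = []
    for i, rec in enumerate(vcf):
        line_no = n_header + i + 1
        fpass = _record_filter_pass(rec)
        if passonly and not fpass:
            continue
        try:
            calls = {s: _parse_call(rec.samples[s]) for s in rec.samples}
            if kind == "sv":
                svtype = rec.info.get("SVTYPE")
                if svtype is None:
                    logger.warning(
                        "%s line %d: SV record without SVTYPE skipped", path, line_no
                    )
                    continue
                svlen = rec.info.get("SVLEN")
                if isinstance(svlen, (tuple, list)):
                    svlen = svlen[0]
                start = rec.start
                if svtype == "INS":
                    end = start
                elif svlen is not None:
                    # htslib pads symbolic-allele END when SVLEN is present;
                    # the affected interval is [start, start + |SVLEN|)
                    end = start + abs(int(svlen))
                else:
                    end = rec.stop
                if svlen is None:
                    svlen = end - start
                records.append(
                    SVRecord(
                        chrom=rec.chrom,
                        start=start,
                        end=end,
                        svtype=str(svtype),
                        svlen=abs(int(svlen)),
                        id=rec.id or ".",
                        filter_pass=fpass,
                        calls=calls,
                    )
                )
            else:
                alt = rec.alts[0] if rec.alts else None
                if alt is None or len(rec.ref) != 1 or len(alt) != 1:
                    logger.warning(
                        "%s line %d: non-SNV record skipped", path, line_no
                    )
                    continue
                gene = rec.info.get("GENE")
                records.append(
                    SNVRecord(
                        chrom=rec.chrom,
                        pos=rec.start,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        quality=float(rec.qual) if rec.qual is not None else None,
                        func_class=str(rec.info.get("FUNC_CLASS", "other")),
                        gene=str(gene) if gene is not None else None,
                        id=rec.id or ".",
                        filter_pass=fpass,
                        calls=calls,
                    )
                )
        except (KeyError, ValueError) as exc:
            raise InputError(f"{path} line {line_no}: {exc}") from exc
    vcf.close()
    return records


def _vcf_header(
    samples: Sequence[str], contigs: Optional[Dict[str, int]], kind: str
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in (contigs or {}).items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    if kind == "sv":
        header.add_line(
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">'
        )
        header.add_line(
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of structural variant">'
        )
        header.add_line(
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">'
        )
    else:
        header.add_line(
            '##INFO=<ID=FUNC_CLASS,Number=1,Type=String,Description="Functional class">'
        )
        header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for s in samples:
        header.add_sample(s)
    return header


def _fill_calls(vrec, samples: Sequence[str], calls: Dict[str, SampleCall]) -> None:
    for s in samples:
        call = calls.get(s, SampleCall())
        vrec.samples[s]["GT"] = call.genotype if call.genotype is not None else (None, None)
        if call.ref_support is not None and call.alt_support is not None:
            vrec.samples[s]["AD"] = (call.ref_support, call.alt_support)
        if call.depth is not None:
            vrec.samples[s]["DP"] = call.depth


def write_cohort_vcf(
    path: PathLike,
    records: Sequence[Union[SVRecord, SNVRecord]],
    samples: Sequence[str],
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write SV or SNV records as an uncompressed multi-sample VCF."""
    kind = "sv" if (not records or isinstance(records[0], SVRecord)) else "snv"
    header = _vcf_header(samples, contigs, kind)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            if isinstance(rec, SVRecord):
                signed_len = -rec.svlen if rec.svtype == "DEL" else rec.svlen
                stop = rec.start + 1 if rec.svtype == "INS" else rec.end
                vrec = out.new_record(
                    contig=rec.chrom,
                    start=rec.start,
                    stop=stop,
                    alleles=("N", f"<{rec.svtype}>"),
                    id=None if rec.id == "." else rec.id,
                    filter="PASS" if rec.filter_pass else "LowQual",
                )
                vrec.info["SVTYPE"] = rec.svtype
                vrec.info["SVLEN"] = signed_len
            else:
                vrec = out.new_record(
                    contig=rec.chrom,
                    start=rec.pos,
                    stop=rec.pos + 1,
                    alleles=(rec.ref_allele, rec.alt_allele),
                    id=None if rec.id == "." else rec.id,
                    qual=rec.quality,
                    filter="PASS" if rec.filter_pass else "LowQual",
                )
                vrec.info["FUNC_CLASS"] = rec.func_class
                if rec.gene is not None:
                    vrec.info["GENE"] = rec.gene
            _fill_calls(vrec, samples, rec.calls)
            out.write(vrec)


# ---------------------------------------------------------------------------
# SV size filter
# ---------------------------------------------------------------------------

def filter_min_sv_size(records: Iterable[SVRecord], min_size: int = 50) -> List[SVRecord]:
    """Keep SVs of ``min_size`` bp and above (inclusive); order preserved."""
    return [r for r in records if r.svlen >= min_size]


# ---------------------------------------------------------------------------
# BED / BEDGRAPH
# ---------------------------------------------------------------------------

def read_regions(path: PathLike) -> RegionSet:
    """Read a BED3+ file (0-based half-open) into a merged RegionSet."""
    intervals: List[Tuple[str, int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path} line {line_no}: expected >= 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(f"{path} line {line_no}: {exc}") from exc
            if start > end:
                raise InputError(
                    f"{path} line {line_no}: start {start} > end {end}"
                )
            intervals.append((chrom, start, end))
    return RegionSet(intervals)


def write_regions(path: PathLike, regions: RegionSet, name: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            if name is None:
                fh.write(f"{chrom}\t{start}\t{end}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(
    bed_path: PathLike, gc_tsv: Optional[PathLike] = None
) -> List[GeneModel]:
    """Read genes from BED6 (name in column 4); GC fractions from a side TSV.

    Lines sharing a gene name are unioned into one model (exon BED support).
    Genes absent from the GC table default to gc_fraction 0.5.
    """
    gc: Dict[str, float] = {}
    if gc_tsv is not None:
        with open(gc_tsv) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                gene, frac = line.split("\t")[:2]
                gc[gene] = float(frac)
    spans: Dict[Tuple[str, str], List[Tuple[str, int, int]]] = {}
    order: List[Tuple[str, str]] = []
    with open(bed_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise InputError(f"{bed_path} line {line_no}: gene BED needs a name column")
            chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            key = (gene, chrom)
            if key not in spans:
                spans[key] = []
                order.append(key)
            spans[key].append((chrom, start, end))
    return [
        GeneModel(
            gene=gene,
            chrom=chrom,
            intervals=RegionSet(spans[(gene, chrom)]),
            gc_fraction=gc.get(gene, 0.5),
        )
        for gene, chrom in order
    ]


def write_gene_models(
    bed_path: PathLike, genes: Sequence[GeneModel], gc_tsv: Optional[PathLike] = None
) -> None:
    with open(bed_path, "w") as fh:
        for g in genes:
            for chrom, start, end in g.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{g.gene}\t0\t+\n")
    if gc_tsv is not None:
        with open(gc_tsv, "w") as fh:
            for g in genes:
                fh.write(f"{g.gene}\t{g.gc_fraction:.4f}\n")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def read_pedigree(path: PathLike) -> TrioPedigree:
    """Read a tab-separated pedigree (family, proband, father, mother)."""
    trios: List[Tuple[str, str, str]] = []
    all_samples: List[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise InputError(
                    f"{path} line {line_no}: expected family, proband, father, mother"
                )
            _, proband, father, mother = fields[:4]
            trios.append((proband, father, mother))
            for s in (proband, father, mother):
                if s not in all_samples:
                    all_samples.append(s)
    return TrioPedigree(trios=trios, all_samples=all_samples)


def write_pedigree(path: PathLike, ped: TrioPedigree) -> None:
    with open(path, "w") as fh:
        fh.write("#family\tproband\tfather\tmother\n")
        for i, (p, f, m) in enumerate(ped.trios, 1):
            fh.write(f"trio{i}\t{p}\t{f}\t{m}\n")
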