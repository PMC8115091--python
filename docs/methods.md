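# Methods

## Coordinates and records

All intervals are 0-based, half-open. VCF POS is converted on read and
restored on write. Deletions and inversions occupy their reference
footprint (`svlen == end − start`); insertions have no reference
footprint, carry the inserted length in `svlen`, and sit on a zero-length
anchor (`end == start`) that is treated as the 1 bp point
`[start, start+1)` for any interval query. Genotypes are unordered allele
pairs (long-read SV and SNV callers emit unphased genotypes); a genotype
with any missing allele is missing as a whole. When an SV record carries
SVLEN, the affected interval is taken as `[start, start + |SVLEN|)` —
this reads both the plain `END = POS + len − 1` convention and htslib's
padded symbolic-allele END identically, and makes write→read a strict
identity.

`RegionSet` merges overlapping *and* bookended intervals at construction,
the same semantics as `bedtools merge`, so interval bookkeeping matches
what a genomecov-based workflow produces. Its union / intersection /
subtraction are verified against a per-base bitmap oracle in the tests.

## SV call-set matching

Two SVs match when (i) they are on the same contig and, if required, of
the same type; (ii) |Δstart| ≤ refdist and |Δend| ≤ refdist (default
1,000 bp); (iii) the size ratio smaller/larger ≥ 0.7. All three
boundaries are inclusive ("at least" semantics). Sequence similarity is
never computed: the calls this matcher is designed for are not
sequence-resolved, so comparison is by coordinates, type, and size only.

Assignment is greedy nearest-first 1:1: candidate pairs are ordered by
start distance, then |1 − size ratio|, then input order, and consumed
while both members are unused. This is deterministic and, whenever
matchable records form clusters separated by more than the match radius,
provably equal to the maximum bipartite matching (verified against an
exhaustive matcher on hundreds of random instances). On adversarial
overlapping clusters the greedy result may be smaller; the greedy result
is the contract. With `multimatch` enabled every satisfying pair is
kept; recall then counts each truth record once and precision each
query record once. Precision/recall with a zero denominator are reported
as undefined (`None`), never as 0. Records outside `[sizemin, sizemax]`
(defaults 50 and 1,000,000 bp) are removed before matching; the external
reciprocal-overlap comparison instead requires ≥ 50 % overlap of *both*
interval lengths, with insertions matched by anchor distance ≤ refdist
and size ratio ≥ the overlap fraction, since a zero-footprint call cannot
reciprocally overlap anything.

## Mendelian inheritance errors

`mendelian_consistent` asks whether the child's alleles can be
partitioned into one paternal and one maternal transmission. Sites with
any missing trio genotype are *uncounted* — excluded from numerator and
denominator — so rates are per fully genotyped site, mirroring the
behaviour of the standard trio-checking VCF plugins. Genuine de novo
events score as violations under this definition; at SV scale (≈0.2
events per genome per generation) their contribution is negligible.
Autosome filtering accepts chr1–chr22 with or without the `chr` prefix.
A variant is *unique* to a sample only if every other cohort sample is
homozygous reference — a missing genotype cannot certify absence, so it
disqualifies the site.

## De novo filtering and classification

The SV filter applies the five criteria listed in the README, all
boundaries inclusive. "Every sample" means the full joint-called cohort
when one is supplied, else the trio. Records with missing AD/DP in a
required sample are excluded with a logged reason rather than guessed.

Candidate classification replaces manual inspection of read alignments
with explicit evidence rules: *inherited* if either parent shows ≥ 1
alternative-supporting read (the call, not the variant, was missing in
the parent); *false positive* if proband support is grossly unbalanced
(outside a relaxed [0.2, 0.8] band) or depth is below the minimum;
otherwise *putative de novo*. The relaxed band is an implementation
choice standing in for a judgement call that is otherwise made by eye;
it is deliberately wider than the candidate band so that classification
never contradicts the filter.

The SNV filter keeps Mendelian-violating sites that are loss-of-function
(any quality) or missense with quality ≥ 30 (inclusive).

## Recessive pairing

Variants are assigned to genes by annotation or by intersection with
gene intervals (insertions by anchor point). Mechanisms: homozygous
coding SV; homozygous LoF SNV with quality strictly > 30; compound
heterozygous coding SV + LoF SNV (quality > 30) in one gene. The LoF
threshold is strict ("higher than 30") and thus intentionally different
from the de novo missense cutoff (≥ 30). Parental origin is inferred
from trio genotypes where exactly one parent carries the allele; a pair
is emitted unless both origins are known and identical (provably cis).
`use_phase=False` disables this and pairs naively, reproducing an
unphased analysis.

## Coverage

Coverage tracks are per-contig step functions of integer depth; mapping
-quality filtering (≥ 10) happens upstream of track construction and is
carried as metadata only. The accessibility partition classifies every
base by presence/absence of coverage (depth ≥ 1 by default; a
`min_depth` option allows stricter definitions) into four mutually
exclusive sets whose lengths always sum to the genome length — a
conservation property the tests enforce on random tracks. Intervals
shorter than the 1 kb reporting threshold stay in the partition but are
flagged sub-threshold, and totals are reported both ways.

Fold-coverage fractions are computed twice: over the whole genome and
over the genome minus "difficult" regions, with chrY automatically added
to the difficult set so samples of different sex remain comparable. A
gene is poorly covered when ≥ 10 % of its length (inclusive) has zero
depth in the short-read track. The GC comparison draws one control per
poorly covered gene from the well-covered pool, seeded and without
replacement, within a ±20 % relative length window (widened with a
warning when empty — "comparable length" has no canonical width, ±20 %
is this package's choice), then applies Welch's two-sample *t*-test; the
degenerate all-identical case returns t = 0, p = 1, and the null
distribution of p-values is checked for uniformity in the tests.

## Titration

Reduced-coverage call sets are compared against the full-coverage call
set as truth using the matcher with multimatch on, refdist 1,000, and
sizes restricted to [50, 1e6]. Subsampling operates on call sets
produced by the simulator's detection model, not on reads: the contract
is the precision/recall computation, and the detection model makes the
expected recall analytic (below). SNV titration reuses exact site
comparison through the same driver.

## The simulator

The generator reproduces the statistical structure of a long-read trio
study, not its sequences:

- **Sites.** Founder SV sites draw type from weights INS 0.63 : DEL 0.37
  : INV 0.0005 (the observed cohort composition scale), size from a
  truncated power-law decay (exponent 1.6) mixed with point masses at
  300 bp (Alu) and 6.4 kb (LINE1) at weights 0.20/0.05, bounded per type
  (INS 50–5,000; DEL 50–100,000; INV 200–5,000 bp). Placement retries up
  to 20 positions to keep DEL/INV footprints disjoint; a site that still
  collides is skipped and counted in the ledger.
- **Genotypes.** Each site gets an allele frequency from Beta(0.3, 1.5)
  (rare-shifted, so cohort-unique variants exist); founders are
  Hardy–Weinberg draws and each child receives one transmitted allele
  per parent, so truth genotypes are Mendelian-consistent by
  construction at all non-de-novo sites. De novo counts per child are
  Poisson(0.2) by default. This allele-frequency formulation subsumes a
  fixed het/hom placement ratio: the het/hom balance is the
  Hardy–Weinberg consequence of the frequency prior.
- **Errors.** Genotype flips replace the called genotype with one of the
  two alternatives at rate 0.02 (default; chosen to put trio MIE rates
  in the upper-single-digit percent range typical of long-read SV
  calling). Parental dropout converts a true parental het call to
  homozygous reference at rate 0.005 while leaving its simulated reads
  untouched — exactly the process that manufactures apparent de novo
  calls in offspring. Read support is depth ~ Poisson(coverage) with
  alternative support Binomial(depth, 0.5) for hets (an allelic-bias
  knob exists, off by default) and Binomial(depth, 1) for homozygotes;
  a variant is detected at ≥ k = 3 supporting reads. Hence the analytic
  detection probability used as the titration oracle:
  P(detect | het) = P(Poisson(c/2) ≥ k), P(detect | hom) = P(Poisson(c) ≥ k).
- **SNVs.** Transitions are chosen with probability t/(1+t) for the
  target Ti/Tv t = 2.1; functional classes follow configured
  proportions, and site quality is Normal(55, 20) clipped to [1, 100] so
  both sides of every quality threshold are populated. Coding sites are
  placed inside gene models when supplied.
- **Coverage tracks.** The long-read track is uniform Poisson(30); the
  short-read track's mean is scaled by exp(−8·max(0, GC − 0.5)) per 1 kb
  window with hard dropout ramping in above GC 0.55, so GC-rich genes
  lose short-read coverage and the GC comparison has a known direction.
- **Scale and determinism.** Default conditions are three 10 Mb contigs,
  five trios, 5,000 SV sites, and 50,000 SNV sites — a desk scale at
  which every contract is testable in seconds; whole-genome scale adds
  nothing to contract verification. All randomness flows from one seed
  through named substreams (stage isolation: changing the SNV count
  cannot perturb the SV draw), and identical configs produce
  byte-identical output files.

The simulator emulates joint genotyping statistics only. It does not
model read sequences, alignment artifacts, caller-specific biases,
breakpoint uncertainty correlated with repeat content, or linkage
between sites. Passing tests therefore demonstrate that the *analysis
operations* are correct under the stated statistical assumptions, not
that any particular caller meets these error rates on real data.

## Numerical and design notes

- Thresholds: size ratio ≥ 0.7, distances ≤ 1 kb, reciprocal overlap
  ≥ 0.5, SV size ≥ 50 bp, de novo ratio ∈ [0.3, 0.7], missense quality
  ≥ 30 and gene-uncovered fraction ≥ 10 % are inclusive; recessive LoF
  quality > 30 is strict.
- Matching ties are broken by size-ratio closeness, then input order —
  results are order-stable and platform-independent.
- Undefined statistics (MIE with zero evaluated sites, precision/recall
  with empty denominators, Ti/Tv without transversions) are `None`/NaN,
  never silently 0.
- The per-sample "affected bp" column counts each SV's `svlen` once per
  sample with a non-reference genotype; multi-allelic records are out of
  scope throughout (the callers this models emit biallelic SV records).
- `triosv` subcommands are thin wrappers; all logic is importable and the
  CLI smoke tests run every subcommand end-to-end on a 1 Mb simulation.
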