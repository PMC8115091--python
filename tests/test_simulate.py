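import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from triosv.coverage import gc_comparison, gene_coverage_classify, partition_coverage
from triosv.mendelian import mie_summary
from triosv.simulate import (
    SimConfig,
    TruthEntry,
    TruthLedger,
    simulate_coverage_tracks,
    simulate_genes,
    simulate_read_support,
    simulate_snvs,
    simulate_trio_cohort,
    write_outputs,
)

from conftest import transmission_oracle


class TestDeterminism:
    def test_same_seed_same_vcf_bytes(self, tmp_path):
        cfg = SimConfig(seed=42, n_sv=200, n_snv=500)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_outputs(simulate_trio_cohort(cfg), d1)
        write_outputs(simulate_trio_cohort(cfg), d2)
        for name in ("sv.vcf", "snv.vcf", "lrs.bedgraph", "srs.bedgraph", "ledger.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_trio_cohort(SimConfig(seed=1, n_sv=200, n_snv=50))
        b = simulate_trio_cohort(SimConfig(seed=2, n_sv=200, n_snv=50))
        assert [r.start for r in a.sv_records] != [r.start for r in b.sv_records]


class TestTruthStructure:
    def test_clean_config_zero_mie(self, clean_sim):
        for trio in clean_sim.pedigree.trios:
            assert mie_summary(clean_sim.sv_records, trio).mie_rate == 0.0

    def test_truth_genotypes_mendelian_at_non_denovo_sites(self, noisy_sim):
        """Before error injection the ledger transmits cleanly everywhere."""
        gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        for entry in noisy_sim.ledger.sv_entries:
            if entry.origin == "de_novo":
                continue
            for p, f, m in noisy_sim.pedigree.trios:
                assert (
                    transmission_oracle(gt[entry.true_gt[p]], gt[entry.true_gt[f]], gt[entry.true_gt[m]])
                    == "consistent"
                )

    def test_no_overlapping_del_inv_footprints(self, full_sim):
        by_chrom = {}
        for entry in full_sim.ledger.sv_entries:
            if entry.svtype in ("DEL", "INV"):
                by_chrom.setdefault(entry.chrom, []).append((entry.start, entry.end))
        for ivals in by_chrom.values():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                assert e1 <= s2

    def test_every_record_maps_to_one_ledger_entry(self, clean_sim):
        ids_rec = [r.id for r in clean_sim.sv_records]
        ids_led = [e.id for e in clean_sim.ledger.sv_entries]
        assert ids_rec == ids_led and len(set(ids_rec)) == len(ids_rec)

    def test_ins_fraction_near_configured_weight(self):
        cfg = SimConfig(seed=13, n_sv=10_000, n_snv=10,
                        genotype_error_rate=0.0, parental_dropout_rate=0.0)
        sim = simulate_trio_cohort(cfg)
        types = Counter(e.svtype for e in sim.ledger.sv_entries)
        n = sum(types.values())
        w = cfg.sv_type_weights
        expect = w["INS"] / sum(w.values())
        se = math.sqrt(expect * (1 - expect) / n)
        assert types["INS"] / n == pytest.approx(expect, abs=3 * se)

    def test_size_bounds_respected(self, full_sim):
        bounds = full_sim.config.sv_size_bounds
        for entry in full_sim.ledger.sv_entries:
            lo, hi = bounds[entry.svtype]
            assert lo <= entry.svlen <= hi

    def test_dropout_keeps_alt_reads(self, noisy_sim):
        found = 0
        for entry in noisy_sim.ledger.sv_entries:
            for sample, kind in entry.errors.items():
                if kind == "dropout":
                    assert entry.called_gt[sample] == 0
                    assert entry.true_gt[sample] == 1
                    found += 1
        assert found > 0


def constant_ledger(genotype, n=10_000):
    samples = {"S": genotype}
    entries = [
        TruthEntry(
            id=f"v{i}", chrom="chr1", start=100 * i, end=100 * i + 50, kind="sv",
            svtype="DEL", svlen=50, origin="founder", de_novo_child=None,
            true_gt={"S": genotype}, called_gt={"S": genotype},
            depth={"S": 0}, alt_support={"S": 0}, errors={},
        )
        for i in range(n)
    ]
    return TruthLedger(sv_entries=entries)


class TestReadSupportModel:
    def test_het_detection_matches_binomial_mixture_oracle(self):
        """Empirical detection over 10,000 draws vs direct summation of
        P(Binomial(d, 0.5) >= k) weighted by Poisson(coverage) depths."""
        cov, k = 40.0, 3
        ledger = constant_ledger(1)
        out = simulate_read_support(ledger, cov, k, seed=5)["S"]
        depths = np.arange(0, 200)
        oracle = float(
            np.sum(stats.poisson.pmf(depths, cov) * stats.binom.sf(k - 1, depths, 0.5))
        )
        frac = out["detected"].mean()
        se = math.sqrt(oracle * (1 - oracle) / len(out["detected"]))
        assert frac == pytest.approx(oracle, abs=3 * se)

    def test_hom_alt_k1_poisson_zero_class(self):
        cov = 10.0
        ledger = constant_ledger(2)
        out = simulate_read_support(ledger, cov, 1, seed=6)["S"]
        oracle = 1.0 - math.exp(-cov)
        se = math.sqrt(oracle * (1 - oracle) / 10_000)
        assert out["detected"].mean() == pytest.approx(oracle, abs=max(3 * se, 1e-3))

    def test_saturating_coverage_detects_everything(self):
        ledger = constant_ledger(1, n=2_000)
        out = simulate_read_support(ledger, 1_000.0, 3, seed=7)["S"]
        assert out["detected"].mean() >= 0.999

    def test_hom_ref_never_detected(self):
        ledger = constant_ledger(0, n=1_000)
        out = simulate_read_support(ledger, 30.0, 1, seed=8)["S"]
        assert out["detected"].sum() == 0

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_read_support(constant_ledger(1, n=1), 0.0, 3, seed=1)


class TestSnvs:
    def test_ti_tv_symmetric_config(self):
        cfg = SimConfig(seed=9, n_snv=30_000, n_sv=10, ti_tv_target=1.0)
        snvs = simulate_snvs(cfg)
        ti = sum(r.is_transition for r in snvs)
        assert ti / max(len(snvs) - ti, 1) == pytest.approx(1.0, abs=0.06)

    def test_quality_straddles_filter_cutoff(self, full_sim):
        quals = [r.quality for r in full_sim.snv_records]
        assert any(q < 30 for q in quals) and any(q >= 30 for q in quals)

    def test_coding_snvs_placed_in_genes(self):
        cfg = SimConfig(seed=10, n_snv=2_000, n_sv=10)
        genes = simulate_genes(cfg)
        snvs = simulate_snvs(cfg, genes=genes)
        by_name = {g.gene: g for g in genes}
        coding = [r for r in snvs if r.func_class in ("missense", "lof", "synonymous")]
        assert coding
        for rec in coding:
            g = by_name[rec.gene]
            span = g.span
            assert g.chrom == rec.chrom and span[0] <= rec.pos < span[1]


class TestCoverageTracks:
    def test_no_bias_no_lrs_only_excess(self):
        cfg = SimConfig(seed=15, gc_bias_strength=0.0, n_genes=40)
        genes = simulate_genes(cfg)
        lrs, srs = simulate_coverage_tracks(cfg, genes)
        part = partition_coverage(lrs, srs)
        assert part.lrs_only.total_length / lrs.genome_length < 1e-3
        assert part.srs_only.total_length / lrs.genome_length < 1e-3

    def test_strong_bias_marks_high_gc_genes_poor(self):
        cfg = SimConfig(seed=16, n_genes=120)
        genes = simulate_genes(cfg)
        _, srs = simulate_coverage_tracks(cfg, genes)
        labels = gene_coverage_classify(genes, srs)
        poor = [g for g in genes if labels[g.gene] == "poorly_covered"]
        well = [g for g in genes if labels[g.gene] == "well_covered"]
        assert poor and well
        res = gc_comparison(poor, well, seed=1)
        assert res.mean_poor > res.mean_control

    def test_seeded_track_determinism(self):
        cfg = SimConfig(seed=17, n_genes=10)
        genes = simulate_genes(cfg)
        a_lrs, a_srs = simulate_coverage_tracks(cfg, genes)
        b_lrs, b_srs = simulate_coverage_tracks(cfg, genes)
        for chrom in a_lrs.contigs:
            assert np.array_equal(a_lrs.steps(chrom)[1], b_lrs.steps(chrom)[1])
            assert np.array_equal(a_srs.steps(chrom)[1], b_srs.steps(chrom)[1])
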