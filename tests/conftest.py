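import numpy as np
import pytest

from triosv.datamodel import SampleCall, SVRecord
from triosv.simulate import SimConfig, simulate_trio_cohort


def transmission_oracle(child, father, mother):
    """Brute-force allele-transmission check, independent of the package's
    Mendelian predicate: try every (paternal, maternal) allele pair."""
    if child is None or father is None or mother is None:
        return "uncounted"
    for fa in father:
        for ma in mother:
            if tuple(sorted((fa, ma))) == tuple(sorted(child)):
                return "consistent"
    return "violation"


def make_sv(
    chrom="chr1",
    start=1000,
    svtype="DEL",
    svlen=100,
    id=".",
    calls=None,
):
    end = start if svtype == "INS" else start + svlen
    return SVRecord(
        chrom=chrom, start=start, end=end, svtype=svtype, svlen=svlen,
        id=id, calls=calls or {},
    )


def make_call(gt, depth=None, alt=None):
    ref = None if depth is None or alt is None else depth - alt
    return SampleCall(genotype=gt, depth=depth, alt_support=alt, ref_support=ref)


@pytest.fixture(scope="session")
def clean_sim():
    """Cohort with no injected errors, dropout, or de novo events."""
    cfg = SimConfig(
        seed=11, n_sv=800, n_snv=3000,
        genotype_error_rate=0.0, parental_dropout_rate=0.0, de_novo_rate=0.0,
    )
    return simulate_trio_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Cohort with default error/dropout processes switched on."""
    cfg = SimConfig(seed=7, n_sv=800, n_snv=4000)
    return simulate_trio_cohort(cfg)


@pytest.fixture(scope="session")
def full_sim():
    """Desk-scale cohort at the default study conditions."""
    return simulate_trio_cohort(SimConfig(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
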