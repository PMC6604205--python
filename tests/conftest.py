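import pandas as pd
import pytest

from pdxsoma import simulate, somatic


@pytest.fixture(scope="session")
def small_refs():
    cfg = simulate.SimConfig(seed=7, ref_length=2000, read_length=100, coverage=40)
    graft, host = simulate.gen_reference_pair(cfg)
    return cfg, graft, host


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the default study conditions, with loci counts scaled for
    test runtime (20 samples, germline/somatic/artifact loci planted)."""
    cfg = simulate.SimConfig(seed=11)
    vc = simulate.gen_variant_cohort(
        cfg, n_germline_loci=40, n_somatic_per_sample=10, n_artifact_loci=5
    )
    return cfg, vc


@pytest.fixture(scope="session")
def default_pipeline(default_cohort):
    _, vc = default_cohort
    result = somatic.run_somatic_pipeline(vc.calls, vc.resource)
    return vc, result


@pytest.fixture(scope="session")
def expression_cohort():
    """The classifier-derivation study conditions: 20 EBV vs 100 non-EBV,
    48 planted genes at log2 effect 2."""
    return simulate.gen_expression_cohort(
        n_ebv=20, n_other=100, signature_size=48, effect=2.0, seed=5
    )


def make_call(**kwargs) -> somatic.VariantCall:
    base = dict(sample_id="S1", chrom="chr1", pos=100, ref="A", alt="T",
                vtype="snv", caller="gatk", DP=500, ALT_AF=0.3,
                QD=20.0, FS=1.0, MQ=55.0, MQRankSum=0.0, ReadPosRankSum=0.0,
                effect="non_silent_coding", gene="GENE001")
    base.update(kwargs)
    return somatic.VariantCall(**base)


@pytest.fixture
def clean_call():
    return make_call


def truth_universe(vc, predicted: pd.DataFrame) -> set:
    """Assessable loci: every planted locus plus everything predicted."""
    uni = {(r.chrom, r.pos, r.alt) for r in vc.truth.itertuples(index=False)}
    uni |= {(r.chrom, r.pos, r.alt) for r in predicted.itertuples(index=False)}
    return uni
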