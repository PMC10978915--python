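import pytest

from snvguide import (PipelineConfig, SomaticSNV, SyntheticCohortSpec,
                      VariantClass, Zygosity, generate, run_pipeline)

# Desk-scale cohort reused across tests: 3 x 20 kb contigs, 12 genes,
# 8 samples, two planted eligible samples (one essential/seed design on the
# plus strand, one haploinsufficient/PAM-creating design on the minus strand).
SMALL_SPEC = dict(
    seed=11, n_contigs=3, contig_length=20_000, n_genes=12, n_samples=8,
    muts_per_sample=40,
    planted_guides=(
        (0, "essential", "snv_in_seed", "+"),
        (1, "haploinsufficient", "snv_in_pam", "-"),
    ),
    planted_hotspot_carriers=(1, 4, 6),
)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    return generate(SyntheticCohortSpec(**SMALL_SPEC),
                    tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def small_result(small_bundle, tmp_path_factory):
    return run_pipeline(
        small_bundle.maf, small_bundle.genome_fa,
        [small_bundle.gene_catalog_tsv], small_bundle.expression_tsv,
        hotspot_path=small_bundle.hotspots_tsv,
        outdir=tmp_path_factory.mktemp("reports"))


def make_snv(sample_id="S01", chrom="chr1", pos=100, ref="G", alt="A",
             af=0.5, alt_reads=50, gene="GENE1", zygosity=Zygosity.unknown,
             flags=(), variant_class=VariantClass.missense, cancer_type=None):
    return SomaticSNV(
        sample_id=sample_id, chrom=chrom, pos=pos, ref_allele=ref,
        alt_allele=alt, allele_frequency=af, alt_read_count=alt_reads,
        gene_symbol=gene, zygosity=zygosity, flags=frozenset(flags),
        variant_class=variant_class, cancer_type=cancer_type)


@pytest.fixture
def snv_factory():
    return make_snv
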