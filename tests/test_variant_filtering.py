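import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snvguide import GeneClass, HotspotEntry, PipelineConfig, Zygosity
from snvguide.io_formats import GeneCatalog
from snvguide.records import GeneClassEntry
from snvguide.variant_filtering import (ThresholdUndefinedError,
                                        annotate_hotspot_carrier,
                                        call_zygosity, compute_af_cut,
                                        filter_by_af, filter_by_expression,
                                        filter_by_gene_class, qc_filter,
                                        recurrence_filter)

from conftest import make_snv
from oracles import af_cut_oracle


class DictExpr:
    def __init__(self, d):
        self.d = d

    def get(self, s, g):
        return self.d.get((s, g))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_boundaries_are_inclusive(config):
    """'At least 5 reads' and 'at least 20% AF' keep the exact boundary."""
    keep = make_snv(af=0.20, alt_reads=5)
    low_reads = make_snv(af=0.20, alt_reads=4)
    flagged = make_snv(af=0.50, alt_reads=50, flags={"segdup"})
    out = qc_filter([keep, low_reads, flagged], config)
    assert out == [keep]


def test_qc_missing_read_count_passes_vacuously(config):
    snv = make_snv(af=0.5, alt_reads=None)
    assert qc_filter([snv], config) == [snv]


def test_recurrence_filter_is_exact_intersection(config):
    inside = make_snv(pos=100)
    outside = make_snv(pos=200)
    catalog = {inside.key}
    assert recurrence_filter([inside, outside], catalog) == [inside]
    assert recurrence_filter([inside, outside], set()) == []


# ---------------------------------------------------------------------------
# Zygosity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("af,expected", [
    (0.95, Zygosity.homozygous),
    (0.90, Zygosity.homozygous),     # boundary inclusive
    (0.58, Zygosity.heterozygous),   # the known heterozygous SMG6-style AF
    (0.89, Zygosity.heterozygous),
])
def test_af_rule_calls_zygosity_when_unknown(config, af, expected):
    out = call_zygosity(make_snv(af=af), config)
    assert out.zygosity is expected
    assert out.zygosity_source == "af_rule"


def test_genotype_derived_zygosity_takes_precedence(config):
    snv = make_snv(af=0.6, zygosity=Zygosity.homozygous)
    assert call_zygosity(snv, config).zygosity is Zygosity.homozygous


# ---------------------------------------------------------------------------
# Gene class
# ---------------------------------------------------------------------------

def _catalog():
    return GeneCatalog([
        GeneClassEntry("ESS", GeneClass.essential),
        GeneClassEntry("HAP", GeneClass.haploinsufficient),
        GeneClassEntry("ONC", GeneClass.oncogene),
        GeneClassEntry("OTH", GeneClass.other),
    ])


def test_gene_class_filter_retains_exactly_the_viable_combinations():
    """Retained = {haploinsufficient x any zygosity} u {essential x hom}."""
    cat = _catalog()
    combos = [(g, z) for g in ("ESS", "HAP", "ONC", "OTH", "NONE")
              for z in (Zygosity.heterozygous, Zygosity.homozygous)]
    snvs = [make_snv(pos=i + 1, gene=g, zygosity=z)
            for i, (g, z) in enumerate(combos)]
    kept = filter_by_gene_class(snvs, cat)
    kept_combos = {(s.gene_symbol, s.zygosity) for s in kept}
    assert kept_combos == {
        ("HAP", Zygosity.heterozygous), ("HAP", Zygosity.homozygous),
        ("ESS", Zygosity.homozygous)}
    assert all(s.gene_class is not None for s in kept)


# ---------------------------------------------------------------------------
# AF_cut
# ---------------------------------------------------------------------------

def _het_snvs(afs, sample="S1"):
    return [make_snv(sample_id=sample, pos=i + 1, af=a,
                     zygosity=Zygosity.heterozygous)
            for i, a in enumerate(afs)]


def test_af_cut_hand_computed_cases(config):
    t = compute_af_cut(_het_snvs([0.10, 0.20, 0.30, 0.40, 0.50]), config)
    assert t.af_median == pytest.approx(0.30)
    assert t.mad_het == pytest.approx(0.10)
    assert t.af_cut == pytest.approx(0.40)

    t = compute_af_cut(_het_snvs([0.5, 0.5, 0.5]), config)
    assert t.af_cut == pytest.approx(0.5) and t.mad_het == 0.0

    t = compute_af_cut(_het_snvs([0.37]), config)
    assert t.af_cut == pytest.approx(0.37)   # MAD of a singleton is 0


def test_af_cut_identity_is_exact(config):
    t = compute_af_cut(_het_snvs([0.11, 0.31, 0.47, 0.52]), config)
    assert t.af_cut == t.af_median + t.mad_het


def test_af_cut_requires_heterozygous_snvs(config):
    hom_only = [make_snv(af=0.95, zygosity=Zygosity.homozygous)]
    with pytest.raises(ThresholdUndefinedError):
        compute_af_cut(hom_only, config)


def test_af_cut_matches_sort_based_oracle_on_random_vectors(config):
    rng = np.random.default_rng(42)
    for _ in range(300):
        n = int(rng.integers(1, 40))
        afs = np.round(rng.uniform(0.05, 0.95, size=n), 4).tolist()
        t = compute_af_cut(_het_snvs(afs), config)
        assert t.af_cut == pytest.approx(af_cut_oracle(afs), abs=1e-12)


def test_af_cut_population_switch_and_mad_scaling():
    """'all' population medians over every SNV; MAD stays het-only and
    scales with the configured constant."""
    snvs = _het_snvs([0.4, 0.5, 0.6]) + [
        make_snv(pos=10, af=0.95, zygosity=Zygosity.homozygous)]
    het_cfg = PipelineConfig(af_median_population="het")
    all_cfg = PipelineConfig(af_median_population="all")
    assert compute_af_cut(snvs, het_cfg).af_median == pytest.approx(0.5)
    assert compute_af_cut(snvs, all_cfg).af_median == pytest.approx(0.55)
    r_cfg = PipelineConfig(mad_constant=1.4826)
    assert compute_af_cut(_het_snvs([0.3, 0.4, 0.6]), r_cfg).mad_het == \
        pytest.approx(1.4826 * 0.1)


def test_filter_by_af_strict_and_tie_behaviour(config):
    t = compute_af_cut(_het_snvs([0.40]), config)  # af_cut = 0.40
    above = make_snv(pos=1, af=0.41)
    tie = make_snv(pos=2, af=0.40)
    below = make_snv(pos=3, af=0.10)
    assert filter_by_af([above, tie, below], t, config) == [above]
    lax = PipelineConfig(af_strict=False)
    assert filter_by_af([above, tie, below], t, lax) == [above, tie]


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def test_expression_filter_strictly_above_cutoff(config):
    expr = DictExpr({("S01", "HI"): 1.5, ("S01", "AT"): 1.0})
    hi = make_snv(gene="HI")
    at = make_snv(gene="AT")
    missing = make_snv(gene="MISSING")
    assert filter_by_expression([hi, at, missing], expr, config) == [hi]
    keep_cfg = PipelineConfig(keep_missing_expression=True)
    assert filter_by_expression([missing], expr, keep_cfg) == [missing]


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------

def test_hotspot_carrier_matching_rules():
    hs = [HotspotEntry("ONC", "chr1", 500),
          HotspotEntry("ONC2", "chr2", 900, ref_allele="G", alt_allele="A")]
    at_hotspot = [make_snv(gene="ONC", pos=500)]
    elsewhere = [make_snv(gene="ONC", pos=501)]
    allele_match = [make_snv(gene="ONC2", chrom="chr2", pos=900, ref="G", alt="A")]
    allele_mismatch = [make_snv(gene="ONC2", chrom="chr2", pos=900, ref="G", alt="T")]
    assert annotate_hotspot_carrier(at_hotspot, hs)
    assert not annotate_hotspot_carrier(elsewhere, hs)
    assert annotate_hotspot_carrier(allele_match, hs)
    assert not annotate_hotspot_carrier(allele_mismatch, hs)


# ---------------------------------------------------------------------------
# Permutation invariance
# ---------------------------------------------------------------------------

@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.2, max_value=0.89), min_size=1,
                max_size=30),
       st.randoms(use_true_random=False))
def test_threshold_and_filters_invariant_under_input_order(afs, rnd):
    """Shuffling the SNV stream changes no threshold and no retained set."""
    config = PipelineConfig()
    snvs = _het_snvs([round(a, 3) for a in afs])
    shuffled = list(snvs)
    rnd.shuffle(shuffled)
    t1 = compute_af_cut(snvs, config)
    t2 = compute_af_cut(shuffled, config)
    assert t1.af_cut == t2.af_cut
    kept1 = {s.pos for s in filter_by_af(snvs, t1, config)}
    kept2 = {s.pos for s in filter_by_af(shuffled, t2, config)}
    assert kept1 == kept2
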