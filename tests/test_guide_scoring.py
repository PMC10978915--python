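import numpy as np
import pytest

from snvguide import PipelineConfig
from snvguide._sequence import revcomp
from snvguide.guide_design import GuideCandidate, ProtospacerSite
from snvguide.guide_scoring import (CFDModel, CFDModelError, ScoringError,
                                    attach_off_target_scores, cfd_score,
                                    default_cfd_model, enumerate_off_targets,
                                    get_scorer, load_cfd_model, qualify_guide,
                                    score_on_target, score_wt_allele)

from conftest import make_snv
from oracles import cfd_oracle, off_targets_oracle


def _random_genome(rng, n=2000):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _random_spacer(rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=20))


def _hits_as_set(hits):
    return {(h.chrom, h.start, h.end, h.strand, h.n_mismatches) for h in hits}


def _make_candidate(design_class="snv_in_seed", spacer_wt=None):
    spacer = "ACGTACGTACGTACGTACGT"
    if design_class == "snv_in_pam":
        site = ProtospacerSite(
            chrom="chr1", protospacer_start=101, protospacer_end=120,
            strand="+", spacer_mut=spacer, spacer_wt=spacer,
            pam_seq_mut="TGG", pam_seq_wt="TGC",
            snv_position_in_spacer=0, design_class="snv_in_pam")
    else:
        wt = spacer_wt or spacer[:14] + "A" + spacer[15:]   # mismatch at pos 15
        site = ProtospacerSite(
            chrom="chr1", protospacer_start=101, protospacer_end=120,
            strand="+", spacer_mut=spacer, spacer_wt=wt,
            pam_seq_mut="TGG", pam_seq_wt="TGG",
            snv_position_in_spacer=15, design_class="snv_in_seed")
    return GuideCandidate(site=site, source_snv=make_snv(),
                          context30_mut="AAAA" + spacer + site.pam_seq_mut + "CCC")


# ---------------------------------------------------------------------------
# On-target surrogate
# ---------------------------------------------------------------------------

def test_gc_surrogate_peaks_at_55_percent_and_clamps(config):
    scorer = get_scorer("gc_surrogate")
    eleven_gc = "G" * 6 + "C" * 5 + "A" * 9          # GC20 = 0.55
    assert scorer.score("AAAA" + eleven_gc + "TGGAAA") == pytest.approx(1.0)
    one_gc = "G" + "A" * 19                           # GC20 = 0.05 -> clamp
    assert scorer.score("AAAA" + one_gc + "TGGAAA") == 0.0
    c = _make_candidate()
    s1 = score_on_target(c, scorer).on_target_score
    s2 = score_on_target(c, scorer).on_target_score
    assert s1 == s2


def test_scorer_rejects_non_acgt_context():
    with pytest.raises(ScoringError):
        get_scorer("gc_surrogate").score("N" * 30)


# ---------------------------------------------------------------------------
# Off-target enumeration
# ---------------------------------------------------------------------------

def test_planted_verbatim_copy_found_with_zero_mismatches(config):
    rng = np.random.default_rng(5)
    spacer = _random_spacer(rng)
    bg = _random_genome(rng, 3000)
    genome = {"chr1": bg[:1000] + spacer + "TGG" + bg[1000:]}
    hits = [h for h in enumerate_off_targets(spacer, genome, config)
            if h.n_mismatches == 0]
    assert any(h.start == 1001 and h.strand == "+" for h in hits)


def test_non_ngg_pam_gates_the_hit(config):
    spacer = "ATTATATTATAATATTATAT"
    genome = {"chr1": "C" * 500 + spacer + "TGA" + "C" * 500}
    assert enumerate_off_targets(spacer, genome, config) == []
    genome2 = {"chr1": "C" * 500 + spacer + "TGG" + "C" * 500}
    assert len(enumerate_off_targets(spacer, genome2, config)) == 1


def test_ambiguous_bases_never_match(config):
    spacer = "ATTATATTATAATATTATAT"
    site = spacer[:10] + "N" + spacer[11:]
    genome = {"chr1": "C" * 500 + site + "TGG" + "C" * 500}
    assert enumerate_off_targets(spacer, genome, config) == []


def test_off_target_scan_matches_full_scan_oracle(config):
    """150 random (spacer, genome) pairs, budgets 0-3: the vectorized scan
    equals the literal per-window oracle."""
    rng = np.random.default_rng(17)
    for trial in range(150):
        genome = {"chr1": _random_genome(rng, 1500)}
        spacer = _random_spacer(rng)
        mm = trial % 4
        cfg = PipelineConfig(max_mismatches=mm)
        got = _hits_as_set(enumerate_off_targets(spacer, genome, cfg))
        assert got == off_targets_oracle(spacer, genome, mm)


def test_raising_mismatch_budget_never_shrinks_hit_set(config):
    rng = np.random.default_rng(23)
    genome = {"chr1": _random_genome(rng, 5000)}
    spacer = _random_spacer(rng)
    prev = set()
    for mm in range(4):
        cfg = PipelineConfig(max_mismatches=mm)
        hits = _hits_as_set(enumerate_off_targets(spacer, genome, cfg))
        assert prev <= hits
        prev = hits


def test_off_target_hits_mirror_on_reverse_complemented_genome(config):
    rng = np.random.default_rng(29)
    seq = _random_genome(rng, 4000)
    spacer = _random_spacer(rng)
    L = len(seq)
    fwd = _hits_as_set(enumerate_off_targets(spacer, {"c": seq}, config))
    rev = _hits_as_set(enumerate_off_targets(spacer, {"c": revcomp(seq)}, config))
    mirrored = {(c, L + 1 - e, L + 1 - s, "+" if st == "-" else "-", mm)
                for c, s, e, st, mm in fwd}
    assert rev == mirrored


def test_exclude_interval_suppresses_own_locus(config):
    rng = np.random.default_rng(31)
    spacer = _random_spacer(rng)
    genome = {"chr1": "C" * 500 + spacer + "TGG" + "C" * 500}
    all_hits = enumerate_off_targets(spacer, genome, config)
    assert len(all_hits) == 1
    none = enumerate_off_targets(spacer, genome, config,
                                 exclude=("chr1", 501, 520))
    assert none == []


# ---------------------------------------------------------------------------
# CFD
# ---------------------------------------------------------------------------

def _toy_model():
    # keyed to the actual bases of spacer "ACGTACGTACGTACGTACGT"
    mm = {(12, "T", "G"): 0.6, (3, "G", "A"): 0.5, (18, "C", "G"): 0.4,
          (15, "G", "A"): 0.2}
    pam = {"GG": 1.0, "AG": 0.25}
    return CFDModel(mismatch_penalty=mm, pam_penalty=pam, name="toy")


def test_cfd_perfect_match_with_ngg_is_exactly_one():
    m = _toy_model()
    s = "ACGTACGTACGTACGTACGT"
    assert cfd_score(s, s, "AGG", m) == 1.0


def test_cfd_single_and_double_mismatch_products():
    m = _toy_model()
    s = "ACGTACGTACGTACGTACGT"
    one = s[:11] + "G" + s[12:]            # A->G at position 12
    assert cfd_score(s, one, "CGG", m) == pytest.approx(0.6)
    two = s[:2] + "A" + s[3:17] + "G" + s[18:]  # pos 3 C->A and pos 18 T->G
    assert cfd_score(s, two, "TGG", m) == pytest.approx(0.5 * 0.4)


def test_cfd_missing_penalty_names_the_triple():
    m = _toy_model()
    s = "ACGTACGTACGTACGTACGT"
    bad = "T" + s[1:]
    with pytest.raises(CFDModelError, match="position 1"):
        cfd_score(s, bad, "AGG", m)


def test_cfd_bounds_and_perfect_match_iff_on_default_model():
    """On the bundled synthetic table: score in [0,1] always; equals 1 only
    for a perfect match with NGG; random cases agree with hand products."""
    model = default_cfd_model()
    rng = np.random.default_rng(37)
    for _ in range(200):
        spacer = _random_spacer(rng)
        site = list(spacer)
        n_mm = int(rng.integers(0, 4))
        for p in rng.choice(20, size=n_mm, replace=False):
            site[p] = "ACGT"[(("ACGT".index(site[p])) + 1 + int(rng.integers(3))) % 4]
        site = "".join(site)
        pam = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
        score = cfd_score(spacer, site, pam, model)
        assert 0.0 <= score <= 1.0
        assert score == pytest.approx(cfd_oracle(spacer, site, pam, model))
        if score == 1.0:
            assert site == spacer and pam[1:] == "GG"


def test_cfd_table_round_trip_with_rna_keys(tmp_path):
    p = tmp_path / "cfd.tsv"
    p.write_text("position\tspacer_base\tgenomic_base\tpenalty\n"
                 "5\tU\tG\t0.7\n"
                 "PAM\t\tAG\t0.3\n")
    m = load_cfd_model(p)
    assert m.mismatch_penalty[(5, "T", "G")] == 0.7     # U re-keyed to T
    assert m.pam_penalty["AG"] == 0.3
    assert m.pam_penalty["GG"] == 1.0


# ---------------------------------------------------------------------------
# Wild-type allele score and qualification
# ---------------------------------------------------------------------------

def test_wt_allele_score_zero_without_wildtype_pam():
    c = _make_candidate("snv_in_pam")
    assert score_wt_allele(c, default_cfd_model()).wt_allele_cfd == 0.0


def test_wt_allele_score_is_seed_mismatch_penalty():
    model = default_cfd_model()
    c = _make_candidate("snv_in_seed")
    score_wt_allele(c, model)
    # spacer A at position 15 vs wild-type A->? : mut G? spacer_mut[14]='A'?
    mut_b = c.site.spacer_mut[14]
    wt_b = c.site.spacer_wt[14]
    assert c.wt_allele_cfd == pytest.approx(
        model.mismatch_penalty[(15, mut_b, wt_b)])


@pytest.mark.parametrize("on,hit_cfds,expected", [
    (0.6, None, True),          # efficient, no off-target site
    (0.6, [0.175], True),       # tie at the CFD cutoff is kept
    (0.6, [0.30], False),       # off-target above cutoff
    (0.4, None, False),         # inefficient
    (0.4, [0.10], False),
    (0.4, [0.30], False),
    (0.5, None, False),         # tie at on-target cutoff is rejected
    (0.9, [0.10, 0.174], True),
])
def test_qualification_truth_table(config, on, hit_cfds, expected):
    """Only on-target > 0.5 AND (no hits OR max CFD <= 0.175) qualifies."""
    c = _make_candidate()
    c.on_target_score = on
    c.off_targets = []
    if hit_cfds:
        from snvguide.guide_scoring import OffTargetHit
        c.off_targets = [
            OffTargetHit(chrom="chr2", start=10 + i, end=29 + i, strand="+",
                         site_seq=c.site.spacer_mut, pam_seq="TGG",
                         n_mismatches=0, mismatch_positions=(), cfd=v)
            for i, v in enumerate(hit_cfds)]
    assert qualify_guide(c, config).qualified is expected


def test_qualification_invariant_to_hit_order(config):
    from snvguide.guide_scoring import OffTargetHit
    vals = [0.05, 0.3, 0.1]
    verdicts = []
    for order in (vals, vals[::-1]):
        c = _make_candidate()
        c.on_target_score = 0.9
        c.off_targets = [
            OffTargetHit(chrom="chr2", start=10 + i, end=29 + i, strand="+",
                         site_seq=c.site.spacer_mut, pam_seq="TGG",
                         n_mismatches=0, mismatch_positions=(), cfd=v)
            for i, v in enumerate(order)]
        verdicts.append(qualify_guide(c, config).qualified)
    assert verdicts[0] == verdicts[1] is False


def test_attach_off_target_scores_records_max(config):
    rng = np.random.default_rng(41)
    c = _make_candidate()
    spacer = c.site.spacer_mut
    genome = {"chrX": "C" * 300 + spacer + "TGG" + "C" * 300}
    hits = enumerate_off_targets(spacer, genome, config)
    attach_off_target_scores(c, hits, default_cfd_model())
    assert c.max_off_target_cfd == 1.0     # verbatim copy with NGG
    assert all(h.cfd is not None for h in c.off_targets)
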