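"""Allele-discriminating protospacer/PAM placement around a somatic SNV.

For SpCas9, a target is a 20-nt protospacer followed by an NGG PAM. A guide
discriminates the mutant from the wild-type allele in exactly two ways:

* ``snv_in_pam`` — the SNV creates the PAM itself (mutant triplet is NGG at
  position 2 or 3 where the wild-type triplet is not), so the wild-type
  allele is simply not cleavable;
* ``snv_in_seed`` — the SNV sits in the PAM-proximal "seed" of the spacer
  (positions 21−seed_window..20, default 9..20 with the 12-bp seed), where
  a single mismatch strongly suppresses Cas9 cleavage of the wild-type
  allele.

An SNV at PAM position 1 (the N) is rejected: any base satisfies N, so the
placement cannot distinguish alleles. Spacer positions are numbered 1
(PAM-distal) to 20 (PAM-proximal); 0 marks an SNV inside the PAM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from ._sequence import contig_length, fetch, revcomp
from .config import PipelineConfig
from .records import SomaticSNV

log = logging.getLogger(__name__)

SPACER_LEN = 20
PAM_LEN = 3
WINDOW = SPACER_LEN + PAM_LEN  # 23


class ReferenceMismatchError(ValueError):
    """The reference genome disagrees with an SNV's stated ref allele."""


@dataclass(frozen=True)
class ProtospacerSite:
    """One allele-discriminating placement of a 20-nt protospacer + PAM.

    ``protospacer_start/end`` are 1-based inclusive reference coordinates of
    the 20-nt protospacer span (min..max, strand-independent). Spacer
    strings read 5'->3' on the protospacer strand.
    """

    chrom: str
    protospacer_start: int
    protospacer_end: int
    strand: str
    spacer_mut: str
    spacer_wt: str
    pam_seq_mut: str
    pam_seq_wt: str
    snv_position_in_spacer: int   # 1..20, or 0 when the SNV is in the PAM
    design_class: str             # "snv_in_pam" | "snv_in_seed"

    def __post_init__(self):
        if len(self.spacer_mut) != SPACER_LEN or len(self.pam_seq_mut) != PAM_LEN:
            raise ValueError("spacer must be 20 nt and PAM 3 nt")
        if (self.design_class == "snv_in_pam") != (self.snv_position_in_spacer == 0):
            raise ValueError("design_class snv_in_pam <=> snv position 0")
        if self.spacer_mut == self.spacer_wt and self.pam_seq_mut == self.pam_seq_wt:
            raise ValueError("site does not discriminate alleles")


@dataclass
class GuideCandidate:
    """A protospacer site paired with its source SNV and scoring state.

    ``context30_mut`` is the 30-nt scoring context on the protospacer
    strand of the mutant haplotype: 4 nt upstream + 20-nt protospacer +
    3-nt PAM + 3 nt downstream (the layout Azimuth-style on-target scorers
    consume). Scores stay unset until the scoring stage fills them in.
    """

    site: ProtospacerSite
    source_snv: SomaticSNV
    context30_mut: str
    on_target_score: Optional[float] = None
    off_targets: Optional[list] = None
    max_off_target_cfd: Optional[float] = None
    wt_allele_cfd: Optional[float] = None
    qualified: Optional[bool] = None

    def __post_init__(self):
        if len(self.context30_mut) != 30:
            raise ValueError("scoring context must be 30 nt")
        if self.context30_mut[4:24] != self.site.spacer_mut:
            raise ValueError("context positions 5-24 must equal the spacer")
        if self.context30_mut[24:27] != self.site.pam_seq_mut:
            raise ValueError("context positions 25-27 must equal the PAM")


@dataclass
class ContextPair:
    """Wild-type and mutant sequence windows around an SNV."""

    chrom: str
    start: int            # 1-based genomic coordinate of the first window base
    wt: str
    mut: str
    snv_offset: int       # 0-based index of the SNV within the window
    truncated: bool = False


def extract_context(genome, snv: SomaticSNV, radius: int = 30) -> ContextPair:
    """Extract the +/- ``radius`` window around an SNV on both haplotypes.

    The wild-type window is the reference sequence; the mutant window
    substitutes the alt allele at the SNV. Windows hitting a contig end are
    truncated and flagged. A reference base that disagrees with the SNV's
    ref allele raises :class:`ReferenceMismatchError` (stale coordinates or
    the wrong assembly).
    """
    clen = contig_length(genome, snv.chrom)
    start = max(1, snv.pos - radius)
    end = min(clen, snv.pos + radius)
    truncated = (start != snv.pos - radius) or (end != snv.pos + radius)
    wt = fetch(genome, snv.chrom, start, end)
    offset = snv.pos - start
    if wt[offset] != snv.ref_allele:
        raise ReferenceMismatchError(
            f"reference has {wt[offset]!r} at {snv.chrom}:{snv.pos}, "
            f"SNV claims ref {snv.ref_allele!r}")
    mut = wt[:offset] + snv.alt_allele + wt[offset + 1:]
    return ContextPair(chrom=snv.chrom, start=start, wt=wt, mut=mut,
                       snv_offset=offset, truncated=truncated)


def _scan_oriented(wt: str, mut: str, k: int, seed_window: int):
    """Scan one strand orientation for discriminating placements.

    ``wt``/``mut`` are strand-oriented 5'->3' strings, ``k`` the 0-based SNV
    index in that orientation. Yields (i, spacer_pos, design_class) for each
    window start i whose placement discriminates alleles. Only windows
    containing the SNV can discriminate, so the scan is bounded to those.
    """
    lo = max(0, k - WINDOW + 1)
    hi = min(len(mut) - WINDOW, k)
    for i in range(lo, hi + 1):
        spacer = mut[i:i + SPACER_LEN]
        pam = mut[i + SPACER_LEN:i + WINDOW]
        if any(c not in "ACGT" for c in spacer) or any(c not in "ACGT" for c in pam):
            continue
        if not (pam[1] == "G" and pam[2] == "G"):
            continue
        rel = k - i
        if rel < SPACER_LEN:
            q = rel + 1  # spacer position, 1 = PAM-distal
            if q >= SPACER_LEN + 1 - seed_window:
                yield i, q, "snv_in_seed"
        elif rel == SPACER_LEN:
            continue  # PAM position 1 is N: never discriminating
        else:
            # SNV at PAM position 2 or 3: mutant NGG must be SNV-created
            wt_pam = wt[i + SPACER_LEN:i + WINDOW]
            if not (wt_pam[1] == "G" and wt_pam[2] == "G"):
                yield i, 0, "snv_in_pam"


def find_design_sites(wt_context: str, mut_context: str, snv_offset: int,
                      config: PipelineConfig, *, chrom: str = "",
                      context_start: int = 1) -> list[ProtospacerSite]:
    """Enumerate every allele-discriminating protospacer placement.

    Both strands of the mutant haplotype are scanned for 23-nt
    protospacer+PAM windows satisfying the seed or PAM-creation rule (see
    module docstring). ``context_start`` anchors the window to reference
    coordinates. Placements are deduplicated by (start, strand) and sorted.
    """
    if len(wt_context) != len(mut_context):
        raise ValueError("wild-type and mutant contexts must have equal length")
    L = len(mut_context)
    sites: dict[tuple, ProtospacerSite] = {}

    for strand in ("+", "-"):
        if strand == "+":
            w, m, k = wt_context, mut_context, snv_offset
        else:
            w, m, k = revcomp(wt_context), revcomp(mut_context), L - 1 - snv_offset
        for i, q, dclass in _scan_oriented(w, m, k, config.seed_window):
            if strand == "+":
                g_start = context_start + i
                g_end = g_start + SPACER_LEN - 1
            else:
                g_end = context_start + (L - 1 - i)
                g_start = g_end - SPACER_LEN + 1
            key = (g_start, strand)
            if key in sites:
                continue
            sites[key] = ProtospacerSite(
                chrom=chrom,
                protospacer_start=g_start,
                protospacer_end=g_end,
                strand=strand,
                spacer_mut=m[i:i + SPACER_LEN],
                spacer_wt=w[i:i + SPACER_LEN],
                pam_seq_mut=m[i + SPACER_LEN:i + WINDOW],
                pam_seq_wt=w[i + SPACER_LEN:i + WINDOW],
                snv_position_in_spacer=q,
                design_class=dclass,
            )
    return sorted(sites.values(),
                  key=lambda s: (s.protospacer_start, s.strand))


def build_candidates(genome, snv: SomaticSNV,
                     config: PipelineConfig) -> list[GuideCandidate]:
    """Design guide candidates for one SNV from an indexed genome.

    Extracts the mutant-haplotype context, finds discriminating placements
    on both strands, and assembles the 30-nt scoring context per candidate.
    Reverse-strand candidates are reported reverse-complemented so the
    spacer always reads 5'->3' with the PAM 3'. Placements too close to a
    contig end to supply the full 30-nt context are dropped (logged):
    Azimuth-style scorers require the complete window.
    """
    ctx = extract_context(genome, snv, radius=config.context_radius)
    sites = find_design_sites(ctx.wt, ctx.mut, ctx.snv_offset, config,
                              chrom=snv.chrom, context_start=ctx.start)
    L = len(ctx.mut)
    out = []
    for site in sites:
        if site.strand == "+":
            oriented = ctx.mut
            i = site.protospacer_start - ctx.start
        else:
            oriented = revcomp(ctx.mut)
            i = (ctx.start + L - 1) - site.protospacer_end
        if i < 4 or i + 26 > L:
            log.debug("dropping site %s:%d%s: incomplete 30-nt scoring context",
                      site.chrom, site.protospacer_start, site.strand)
            continue
        out.append(GuideCandidate(
            site=site, source_snv=snv,
            context30_mut=oriented[i - 4:i + 26]))
    return out
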