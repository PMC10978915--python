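"""Somatic SNV filtering: QC, zygosity, gene class, clonality, expression.

The selection logic targets passenger SNVs that (i) sit in genes whose
disruption kills the cell — essential genes (homozygous SNVs only, since a
heterozygous cut leaves a functional copy) or haploinsufficient genes (any
zygosity) — (ii) are clonal, i.e. their allele frequency exceeds a
per-sample threshold AF_cut = median(het AF) + MAD(het AF), and (iii) fall
in genes actually expressed in that sample (log2(FPKM+1) strictly above 1).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np

from .config import PipelineConfig
from .io_formats import GeneCatalog
from .records import AFThreshold, GeneClass, HotspotEntry, SomaticSNV, Zygosity

log = logging.getLogger(__name__)


class ThresholdUndefinedError(ValueError):
    """A sample has no heterozygous SNVs, so AF_cut cannot be computed."""


def qc_filter(snvs: Iterable[SomaticSNV], config: PipelineConfig) -> list[SomaticSNV]:
    """Read-support and context QC.

    Keeps SNVs with at least ``qc_min_alt_reads`` supporting reads, allele
    frequency at least ``qc_min_af`` (both bounds inclusive), and none of
    the excluded context flags (segmental duplication, tandem repeat, known
    germline variant). Records without an alt read count pass the
    read-count check vacuously (logged).
    """
    out = []
    for snv in snvs:
        if snv.alt_read_count is None:
            log.debug("SNV %s:%d lacks alt_read_count; read-count check skipped",
                      snv.chrom, snv.pos)
        elif snv.alt_read_count < config.qc_min_alt_reads:
            continue
        if snv.allele_frequency < config.qc_min_af:
            continue
        if snv.flags & config.exclude_flags:
            continue
        out.append(snv)
    return out


def recurrence_filter(snvs: Iterable[SomaticSNV], catalog: set) -> list[SomaticSNV]:
    """Keep only SNVs whose (chrom, pos, ref, alt) is a known somatic mutation.

    Optional stage: the pipeline skips it entirely when no catalog is given.
    """
    return [s for s in snvs if s.key in catalog]


def call_zygosity(snv: SomaticSNV, config: PipelineConfig) -> SomaticSNV:
    """Resolve unknown zygosity from allele frequency.

    An explicit genotype always wins. Otherwise the SNV is called homozygous
    when AF >= ``hom_af_min`` (default 0.9, tolerant of loss of
    heterozygosity and impure tumors), else heterozygous. The decision path
    is stamped into ``zygosity_source``.
    """
    if snv.zygosity is not Zygosity.unknown:
        if snv.zygosity_source is None:
            return snv.with_(zygosity_source="genotype")
        return snv
    zyg = (Zygosity.homozygous if snv.allele_frequency >= config.hom_af_min
           else Zygosity.heterozygous)
    return snv.with_(zygosity=zyg, zygosity_source="af_rule")


def filter_by_gene_class(snvs: Iterable[SomaticSNV],
                         catalog: GeneCatalog) -> list[SomaticSNV]:
    """Keep SNVs whose knockout is expected to kill the carrying cell.

    Haploinsufficient genes: any zygosity (one broken copy suffices).
    Essential genes: homozygous SNVs only. Everything else is dropped.
    Retained records are annotated with their gene class.
    """
    out = []
    for snv in snvs:
        cls = catalog.viability_class(snv.gene_symbol)
        if cls is GeneClass.haploinsufficient:
            out.append(snv.with_(gene_class=cls))
        elif cls is GeneClass.essential and snv.zygosity is Zygosity.homozygous:
            out.append(snv.with_(gene_class=cls))
    return out


def compute_af_cut(snvs_of_sample: list[SomaticSNV],
                   config: PipelineConfig,
                   sample_id: Optional[str] = None) -> AFThreshold:
    """Per-sample clonality threshold: AF_cut = median(AF) + MAD(het AF).

    Computed on the sample's full QC-passed SNV list, before gene-class
    filtering. The median population defaults to heterozygous SNVs
    (``af_median_population='het'``); the MAD is always over heterozygous
    AFs, scaled by ``mad_constant`` (1.0 = literal median absolute
    deviation; 1.4826 = the normal-consistency scaling R applies).
    """
    snvs = list(snvs_of_sample)
    if sample_id is None:
        sample_id = snvs[0].sample_id if snvs else ""
    het_afs = np.array([s.allele_frequency for s in snvs
                        if s.zygosity is Zygosity.heterozygous], dtype=float)
    if het_afs.size == 0:
        raise ThresholdUndefinedError(
            f"sample {sample_id}: no heterozygous SNVs, AF_cut undefined")
    if config.af_median_population == "het":
        pop = het_afs
    else:
        pop = np.array([s.allele_frequency for s in snvs], dtype=float)
    af_median = float(np.median(pop))
    mad = float(np.median(np.abs(het_afs - np.median(het_afs))))
    mad_het = config.mad_constant * mad
    return AFThreshold(
        sample_id=sample_id,
        af_median=af_median,
        mad_het=mad_het,
        af_cut=af_median + mad_het,
        n_snvs_used=int(pop.size),
        n_het_used=int(het_afs.size),
    )


def filter_by_af(snvs: Iterable[SomaticSNV], threshold: AFThreshold,
                 config: PipelineConfig = None) -> list[SomaticSNV]:
    """Keep SNVs surpassing the sample's AF_cut.

    "Surpassed" is read as strictly greater by default; set
    ``af_strict=False`` in the config for >=.
    """
    strict = True if config is None else config.af_strict
    if strict:
        return [s for s in snvs if s.allele_frequency > threshold.af_cut]
    return [s for s in snvs if s.allele_frequency >= threshold.af_cut]


def filter_by_expression(snvs: Iterable[SomaticSNV], expr,
                         config: PipelineConfig) -> list[SomaticSNV]:
    """Keep SNVs whose gene is expressed in the carrying sample.

    Expression must be strictly greater than ``expression_min``
    (log2(FPKM+1) > 1 by default). SNVs with no expression value for the
    (sample, gene) pair are dropped unless ``keep_missing_expression``.
    """
    out = []
    for snv in snvs:
        v = expr.get(snv.sample_id, snv.gene_symbol)
        if v is None:
            if config.keep_missing_expression:
                out.append(snv)
            continue
        if v > config.expression_min:
            out.append(snv)
    return out


def annotate_hotspot_carrier(snvs_of_sample: Iterable[SomaticSNV],
                             hotspots: Iterable[HotspotEntry]) -> bool:
    """True when the sample carries an SNV at a cataloged oncogene hotspot.

    Matching is on (gene, position); when the catalog entry specifies
    alleles, ref and alt must match as well.
    """
    index: dict[tuple, list[HotspotEntry]] = {}
    for h in hotspots:
        index.setdefault((h.gene_symbol, h.pos), []).append(h)
    for snv in snvs_of_sample:
        for h in index.get((snv.gene_symbol, snv.pos), []):
            if h.ref_allele is not None and h.ref_allele != snv.ref_allele:
                continue
            if h.alt_allele is not None and h.alt_allele != snv.alt_allele:
                continue
            return True
    return False
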