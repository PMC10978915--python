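"""Readers and writers for the external formats the pipeline touches.

Somatic variants arrive as GDC-style MAF (tab separated, one row per
variant call) or VCF 4.x; gene-class catalogs, hotspot catalogs and
expression tables are plain TSV/JSON. Everything is normalized into the
domain records in :mod:`snvguide.records`. Coordinates stay 1-based
inclusive at every interface.

Zygosity is only taken from explicit genotypes (VCF GT); MAF rows come out
``unknown`` and are resolved later by
:func:`snvguide.variant_filtering.call_zygosity`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .records import (
    ExpressionRecord,
    GeneClass,
    GeneClassEntry,
    HotspotEntry,
    SomaticSNV,
    VariantClass,
    Zygosity,
)

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

#: Minimal GDC MAF column set required by :func:`read_maf`.
MAF_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
    "Tumor_Sample_Barcode",
)

_MAF_CLASS_MAP = {
    "Missense_Mutation": VariantClass.missense,
    "Silent": VariantClass.synonymous,
    "Nonsense_Mutation": VariantClass.nonsense,
    "Splice_Site": VariantClass.splice,
    "Splice_Region": VariantClass.splice,
}


@dataclass
class ReadResult:
    """Records plus bookkeeping from a variant reader."""

    records: list
    n_skipped_non_snv: int = 0
    n_skipped_bad_rows: int = 0
    row_errors: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _maf_af(row) -> tuple[float, Optional[int]]:
    """Allele fraction and alt read count from a MAF row.

    Uses an explicit AF-like column when present, otherwise
    t_alt_count / t_depth.
    """
    alt_count = None
    if "t_alt_count" in row and not _is_na(row["t_alt_count"]):
        alt_count = int(row["t_alt_count"])
    for col in ("tumor_f", "AF", "i_TumorVAF_WU"):
        if col in row and not _is_na(row[col]):
            return float(row[col]), alt_count
    if alt_count is None or "t_depth" not in row or _is_na(row["t_depth"]):
        raise FormatError("no AF column and no t_alt_count/t_depth pair")
    depth = int(row["t_depth"])
    if depth <= 0:
        raise FormatError("t_depth must be positive")
    return alt_count / depth, alt_count


def _is_na(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and v.strip() in ("", ".", "NA")


def read_maf(path, dialect: str = "gdc", strict: bool = True) -> ReadResult:
    """Read somatic SNVs from a GDC-style MAF file.

    Non-SNP rows (InDels, MNPs) are skipped and counted, never errors.
    In ``strict`` mode an unparsable SNP row raises a :class:`FormatError`
    naming the line; in lenient mode it is skipped and logged.
    """
    if dialect != "gdc":
        raise ValueError(f"unsupported MAF dialect: {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"MAF is missing required column(s): {', '.join(missing)}")

    result = ReadResult(records=[])
    for idx, row in enumerate(df.to_dict("records")):
        if row["Variant_Type"].upper() != "SNP":
            result.n_skipped_non_snv += 1
            continue
        try:
            af, alt_count = _maf_af(row)
            flags = frozenset()
            if "Flags" in row and not _is_na(row["Flags"]):
                flags = frozenset(f for f in row["Flags"].split(";") if f)
            snv = SomaticSNV(
                sample_id=row["Tumor_Sample_Barcode"],
                cancer_type=(row.get("Cancer_Type") or None),
                chrom=row["Chromosome"],
                pos=int(row["Start_Position"]),
                ref_allele=row["Reference_Allele"].upper(),
                alt_allele=row["Tumor_Seq_Allele2"].upper(),
                allele_frequency=af,
                alt_read_count=alt_count,
                gene_symbol=row["Hugo_Symbol"],
                variant_class=_MAF_CLASS_MAP.get(
                    row.get("Variant_Classification", ""), VariantClass.other),
                zygosity=Zygosity.unknown,
                flags=flags,
            )
        except (ValueError, FormatError) as exc:
            if strict:
                raise FormatError(f"MAF row {idx + 2}: {exc}") from exc
            log.warning("skipping MAF row %d: %s", idx + 2, exc)
            result.n_skipped_bad_rows += 1
            result.row_errors.append((idx + 2, str(exc)))
            continue
        result.records.append(snv)
    return result


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> ReadResult:
    """Read biallelic somatic SNVs from a VCF 4.x file (single or multi sample).

    Multiallelic sites are decomposed into per-alt records. AF comes from the
    AF/VAF FORMAT field when present, else the AF INFO field, else allele
    depths (AD). A GT field sets zygosity (1/1 homozygous, 0/1 heterozygous);
    without GT the record stays ``unknown``. The custom INFO keys ``GENE``
    and ``VC`` carry gene symbol and variant class.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad input
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    result = ReadResult(records=[])
    for v in vcf:
        if len(v.REF) != 1 or v.REF not in "ACGT":
            result.n_skipped_non_snv += 1
            continue
        gene = v.INFO.get("GENE") or "Unknown"
        vclass = VariantClass(v.INFO.get("VC")) if v.INFO.get("VC") else VariantClass.other
        for ai, alt in enumerate(v.ALT):
            if len(alt) != 1 or alt not in "ACGT":
                result.n_skipped_non_snv += 1
                continue
            allele_idx = ai + 1
            if samples:
                for si, sample in enumerate(samples):
                    gt = v.genotypes[si][:-1]
                    if allele_idx not in gt:
                        continue
                    zyg = Zygosity.unknown
                    source = None
                    called = [a for a in gt if a >= 0]
                    if called:
                        if all(a == allele_idx for a in called) and len(called) > 1:
                            zyg, source = Zygosity.homozygous, "genotype"
                        else:
                            zyg, source = Zygosity.heterozygous, "genotype"
                    af, ad = _vcf_sample_af(v, si, allele_idx)
                    result.records.append(SomaticSNV(
                        sample_id=sample, chrom=v.CHROM, pos=v.POS,
                        ref_allele=v.REF, alt_allele=alt,
                        allele_frequency=af, alt_read_count=ad,
                        gene_symbol=gene, variant_class=vclass,
                        zygosity=zyg, zygosity_source=source,
                    ))
            else:
                info_af = v.INFO.get("AF")
                if info_af is None:
                    raise FormatError(
                        f"sites-only VCF record {v.CHROM}:{v.POS} lacks INFO AF")
                af = float(info_af[ai] if isinstance(info_af, tuple) else info_af)
                result.records.append(SomaticSNV(
                    sample_id="SAMPLE", chrom=v.CHROM, pos=v.POS,
                    ref_allele=v.REF, alt_allele=alt,
                    allele_frequency=af, gene_symbol=gene, variant_class=vclass,
                ))
    return result


def _fmt_field(v, key):
    try:
        return v.format(key)
    except KeyError:  # field not declared in the header
        return None


def _vcf_sample_af(v, si: int, allele_idx: int) -> tuple[float, Optional[int]]:
    ad = None
    fmt_ad = _fmt_field(v, "AD")
    if fmt_ad is not None:
        row = fmt_ad[si]
        if allele_idx < len(row) and row[allele_idx] >= 0:
            ad = int(row[allele_idx])
    for key in ("AF", "VAF"):
        fmt = _fmt_field(v, key)
        if fmt is not None:
            val = fmt[si]
            val = val[allele_idx - 1] if hasattr(val, "__len__") else val
            return float(val), ad
    info_af = v.INFO.get("AF")
    if info_af is not None:
        val = info_af[allele_idx - 1] if isinstance(info_af, tuple) else info_af
        return float(val), ad
    if ad is not None and fmt_ad is not None:
        depth = int(sum(x for x in fmt_ad[si] if x > 0))
        if depth > 0:
            return ad / depth, ad
    raise FormatError(f"no AF/VAF/AD information at {v.CHROM}:{v.POS}")


# ---------------------------------------------------------------------------
# Gene-class catalog
# ---------------------------------------------------------------------------

_ADMISSIBLE_CLASSES = tuple(c.value for c in GeneClass)


class GeneCatalog:
    """Merged gene-class catalog with deterministic conflict resolution.

    Viability classes (essential / haploinsufficient) are merged with
    haploinsufficient taking precedence on conflict — haploinsufficiency
    subsumes the essential-gene zygosity requirement at filtering time and
    retains more candidates. Oncogene labels are kept in a separate lookup
    and never merged into the viability classes.
    """

    def __init__(self, entries: Iterable[GeneClassEntry]):
        self._viability: dict[str, GeneClass] = {}
        self.oncogenes: set[str] = set()
        self.other: set[str] = set()
        self.conflicts: list[tuple[str, GeneClass, GeneClass]] = []
        for e in entries:
            if e.gene_class is GeneClass.oncogene:
                self.oncogenes.add(e.gene_symbol)
                continue
            if e.gene_class is GeneClass.other:
                self.other.add(e.gene_symbol)
                continue
            prev = self._viability.get(e.gene_symbol)
            if prev is None:
                self._viability[e.gene_symbol] = e.gene_class
            elif prev is not e.gene_class:
                self.conflicts.append((e.gene_symbol, prev, e.gene_class))
                self._viability[e.gene_symbol] = GeneClass.haploinsufficient
                log.info("gene %s listed as both essential and haploinsufficient; "
                         "resolved to haploinsufficient", e.gene_symbol)

    def viability_class(self, gene: str) -> Optional[GeneClass]:
        return self._viability.get(gene)

    def is_oncogene(self, gene: str) -> bool:
        return gene in self.oncogenes

    def __len__(self):
        return len(self._viability) + len(self.oncogenes) + len(self.other)


def read_gene_catalog(paths: Iterable, default_class: Optional[str] = None) -> GeneCatalog:
    """Read and merge gene-class catalogs from TSV/JSON files.

    TSV files need ``gene_symbol`` and ``gene_class`` columns (``source``
    optional). JSON files may map gene -> class, or class -> [genes], or be a
    plain list of genes (then ``default_class`` is required). An empty path
    list yields an empty catalog with a warning.
    """
    paths = list(paths)
    if not paths:
        log.warning("no gene catalog files given; catalog is empty")
        return GeneCatalog([])
    entries = []
    for path in paths:
        path = Path(path)
        if path.suffix.lower() == ".json":
            entries.extend(_gene_entries_from_json(path, default_class))
        else:
            df = pd.read_csv(path, sep="\t", dtype=str)
            if "gene_symbol" not in df.columns or "gene_class" not in df.columns:
                raise FormatError(
                    f"{path}: gene catalog TSV needs gene_symbol and gene_class columns")
            for row in df.itertuples(index=False):
                entries.append(GeneClassEntry(
                    row.gene_symbol, _parse_gene_class(row.gene_class),
                    getattr(row, "source", "") or str(path.name)))
    # collapse exact duplicates, keep first-seen order
    seen = set()
    unique = []
    for e in entries:
        k = (e.gene_symbol, e.gene_class)
        if k not in seen:
            seen.add(k)
            unique.append(e)
    return GeneCatalog(unique)


def _parse_gene_class(label: str) -> GeneClass:
    try:
        return GeneClass(label.strip().lower())
    except ValueError:
        raise FormatError(
            f"unknown gene class {label!r}; admissible: {', '.join(_ADMISSIBLE_CLASSES)}")


def _gene_entries_from_json(path: Path, default_class: Optional[str]):
    with open(path) as fh:
        data = json.load(fh)
    src = path.name
    if isinstance(data, list):
        if default_class is None:
            raise FormatError(f"{path}: raw gene list needs an explicit default_class")
        cls = _parse_gene_class(default_class)
        return [GeneClassEntry(g, cls, src) for g in data]
    entries = []
    for key, val in data.items():
        if isinstance(val, list):  # class -> [genes]
            cls = _parse_gene_class(key)
            entries.extend(GeneClassEntry(g, cls, src) for g in val)
        else:  # gene -> class
            entries.append(GeneClassEntry(key, _parse_gene_class(val), src))
    return entries


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

class ExpressionLookup:
    """(sample, gene) -> log2(FPKM+1); missing pairs are distinguishable from 0."""

    def __init__(self, values: dict):
        self._values = values

    def get(self, sample_id: str, gene_symbol: str) -> Optional[float]:
        return self._values.get((sample_id, gene_symbol))

    def __contains__(self, key) -> bool:
        return key in self._values

    def __len__(self):
        return len(self._values)


def read_expression(path) -> ExpressionLookup:
    """Read an expression table, auto-detecting long vs matrix layout.

    Long layout has columns ``sample_id``, ``gene_symbol``,
    ``log2_fpkm_plus1``; matrix layout has genes in the first column and one
    column per sample. Negative values are a format error.
    """
    df = pd.read_csv(path, sep="\t")
    values: dict = {}
    if {"sample_id", "gene_symbol", "log2_fpkm_plus1"}.issubset(df.columns):
        for row in df.itertuples(index=False):
            v = float(row.log2_fpkm_plus1)
            if v < 0:
                raise FormatError(f"negative expression value {v} for "
                                  f"({row.sample_id}, {row.gene_symbol})")
            values[(row.sample_id, row.gene_symbol)] = v
    else:
        gene_col = df.columns[0]
        for row in df.itertuples(index=False):
            gene = getattr(row, gene_col) if gene_col.isidentifier() else row[0]
            for sample, v in zip(df.columns[1:], row[1:]):
                v = float(v)
                if v < 0:
                    raise FormatError(f"negative expression value {v} for "
                                      f"({sample}, {gene})")
                values[(sample, gene)] = v
    return ExpressionLookup(values)


# ---------------------------------------------------------------------------
# Hotspot and recurrence catalogs
# ---------------------------------------------------------------------------

def read_hotspots(path) -> list[HotspotEntry]:
    """TSV hotspot catalog: gene_symbol, chrom, pos [, ref_allele, alt_allele]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene_symbol", "chrom", "pos"}
    if not need.issubset(df.columns):
        raise FormatError(f"hotspot TSV needs columns {sorted(need)}")
    out = []
    for row in df.to_dict("records"):
        out.append(HotspotEntry(
            gene_symbol=row["gene_symbol"], chrom=row["chrom"], pos=int(row["pos"]),
            ref_allele=None if _is_na(row.get("ref_allele")) else row["ref_allele"],
            alt_allele=None if _is_na(row.get("alt_allele")) else row["alt_allele"]))
    return out


def read_recurrence_catalog(path) -> set:
    """TSV of known somatic mutations: chrom, pos, ref_allele, alt_allele."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"chrom", "pos", "ref_allele", "alt_allele"}
    if not need.issubset(df.columns):
        raise FormatError(f"recurrence TSV needs columns {sorted(need)}")
    return {(r["chrom"], int(r["pos"]), r["ref_allele"], r["alt_allele"])
            for r in df.to_dict("records")}


# ---------------------------------------------------------------------------
# Guide report
# ---------------------------------------------------------------------------

#: Fixed column order of the guide report TSV.
GUIDE_REPORT_COLUMNS = (
    "sample_id", "cancer_type", "chrom", "pos", "ref_allele", "alt_allele",
    "gene_symbol", "gene_class", "zygosity", "allele_frequency",
    "spacer", "pam", "strand", "design_class", "snv_spacer_position",
    "on_target_score", "n_off_targets", "max_off_target_cfd",
    "wt_allele_cfd", "qualified",
)


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def write_guide_report(candidates, path) -> None:
    """Write the final guide table as TSV with a fixed, documented column order.

    Rows are sorted by (sample, chrom, pos, strand, spacer) so repeated runs
    on the same input produce byte-identical files.
    """
    rows = []
    for c in candidates:
        s = c.site
        snv = c.source_snv
        rows.append({
            "sample_id": snv.sample_id,
            "cancer_type": snv.cancer_type,
            "chrom": snv.chrom,
            "pos": snv.pos,
            "ref_allele": snv.ref_allele,
            "alt_allele": snv.alt_allele,
            "gene_symbol": snv.gene_symbol,
            "gene_class": snv.gene_class.value if snv.gene_class else None,
            "zygosity": snv.zygosity.value,
            "allele_frequency": snv.allele_frequency,
            "spacer": s.spacer_mut,
            "pam": s.pam_seq_mut,
            "strand": s.strand,
            "design_class": s.design_class,
            "snv_spacer_position": s.snv_position_in_spacer,
            "on_target_score": c.on_target_score,
            "n_off_targets": None if c.off_targets is None else len(c.off_targets),
            "max_off_target_cfd": c.max_off_target_cfd,
            "wt_allele_cfd": c.wt_allele_cfd,
            "qualified": c.qualified,
        })
    rows.sort(key=lambda r: (r["sample_id"], r["chrom"], r["pos"],
                             r["strand"], r["spacer"]))
    with open(path, "w") as fh:
        fh.write("\t".join(GUIDE_REPORT_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(_fmt(r[c]) for c in GUIDE_REPORT_COLUMNS) + "\n")


def read_guide_report(path) -> pd.DataFrame:
    """Read a guide report TSV back into a DataFrame (NA-aware)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GUIDE_REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"guide report missing column(s): {missing}")
    return df
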