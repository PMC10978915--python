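"""Domain record types flowing through the pipeline.

The unit of flow is the :class:`SomaticSNV`: one somatic single-nucleotide
variant in one sample, carrying allele frequency, read support, gene
annotation and (once resolved) zygosity. Catalog entries, expression values
and the per-sample allele-frequency threshold are small companion records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class VariantClass(str, Enum):
    missense = "missense"
    synonymous = "synonymous"
    nonsense = "nonsense"
    splice = "splice"
    other = "other"


class Zygosity(str, Enum):
    heterozygous = "heterozygous"
    homozygous = "homozygous"
    unknown = "unknown"


class GeneClass(str, Enum):
    essential = "essential"
    haploinsufficient = "haploinsufficient"
    oncogene = "oncogene"
    other = "other"


_VALID_BASES = frozenset("ACGT")


@dataclass
class SomaticSNV:
    """One somatic single-nucleotide variant in one sample.

    Coordinates are 1-based reference coordinates. ``allele_frequency`` is
    the variant allele fraction in [0, 1]. ``zygosity`` starts ``unknown``
    when the input format carries no genotype; readers never guess it.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    allele_frequency: float
    gene_symbol: str
    cancer_type: Optional[str] = None
    alt_read_count: Optional[int] = None
    base_quality_ok: Optional[bool] = None
    variant_class: VariantClass = VariantClass.other
    zygosity: Zygosity = Zygosity.unknown
    flags: frozenset = field(default_factory=frozenset)
    gene_class: Optional[GeneClass] = None       # annotated by filter_by_gene_class
    zygosity_source: Optional[str] = None        # "genotype" | "af_rule" provenance

    def __post_init__(self):
        if self.ref_allele not in _VALID_BASES or self.alt_allele not in _VALID_BASES:
            raise ValueError(
                f"alleles must be single A/C/G/T bases, got "
                f"{self.ref_allele!r}>{self.alt_allele!r} at {self.chrom}:{self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(f"allele_frequency {self.allele_frequency} outside [0,1]")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt_read_count is not None and self.alt_read_count < 0:
            raise ValueError("alt_read_count must be non-negative")
        self.flags = frozenset(self.flags)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def with_(self, **kw) -> "SomaticSNV":
        return replace(self, **kw)


@dataclass(frozen=True)
class GeneClassEntry:
    gene_symbol: str
    gene_class: GeneClass
    source: str = ""


@dataclass(frozen=True)
class HotspotEntry:
    gene_symbol: str
    chrom: str
    pos: int
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("hotspot pos must be >= 1")


@dataclass(frozen=True)
class ExpressionRecord:
    sample_id: str
    gene_symbol: str
    log2_fpkm_plus1: float

    def __post_init__(self):
        if self.log2_fpkm_plus1 < 0:
            raise ValueError("log2(FPKM+1) cannot be negative")


@dataclass(frozen=True)
class AFThreshold:
    """Per-sample clonality threshold AF_cut = median(AF) + MAD(het AF).

    ``af_median`` is the median over the configured AF population (default:
    heterozygous SNVs); ``mad_het`` is the (scaled) median absolute deviation
    of heterozygous AFs. The sum identity is exact by construction.
    """

    sample_id: str
    af_median: float
    mad_het: float
    af_cut: float
    n_snvs_used: int
    n_het_used: int

    def __post_init__(self):
        if self.mad_het < 0:
            raise ValueError("MAD cannot be negative")
        if self.af_cut != self.af_median + self.mad_het:
            raise ValueError("af_cut must equal af_median + mad_het exactly")


# Ordered pipeline stages recorded in a FilterTrace.
TRACE_STEPS = (
    "input",
    "after_gene_class",
    "after_af",
    "after_expression",
    "after_design",
    "after_on_target",
    "after_off_target",
)


@dataclass
class FilterTrace:
    """Per-sample SNV counts surviving each pipeline step (non-increasing)."""

    sample_id: str
    counts: dict

    def __post_init__(self):
        vals = [self.counts[s] for s in TRACE_STEPS if s in self.counts]
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"attrition counts must be non-increasing: {self.counts}")

    def as_row(self) -> list:
        return [self.counts.get(s, 0) for s in TRACE_STEPS]
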