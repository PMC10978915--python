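"""Pipeline configuration: every tunable cutoff in one dataclass.

Defaults reproduce the published workflow: homozygosity called at AF >= 0.9
when no genotype is available, gene expression required strictly above
log2(FPKM+1) = 1, on-target score strictly above 0.5, off-target CFD at most
0.175, off-target search within 3 mismatches of the spacer, allele
discrimination restricted to the 12 PAM-proximal spacer positions, NGG PAMs,
and QC at >= 5 alt reads with >= 20% allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    hom_af_min: float = 0.9
    expression_min: float = 1.0
    mad_constant: float = 1.0
    on_target_min: float = 0.5
    off_target_max_cfd: float = 0.175
    max_mismatches: int = 3
    seed_window: int = 12
    pam_motifs: tuple = ("NGG",)
    exclude_flags: frozenset = field(
        default_factory=lambda: frozenset({"segdup", "tandem_repeat", "germline_db"}))
    qc_min_alt_reads: int = 5
    qc_min_af: float = 0.20

    # documented switches for points the source workflow leaves open
    af_median_population: str = "het"        # "het" | "all"
    af_strict: bool = True                   # AF must strictly exceed AF_cut
    keep_missing_expression: bool = False
    count_wt_as_offtarget: bool = False
    allow_nag_offtarget: bool = False        # relax off-target PAM to NGG+NAG
    scorer: str = "gc_surrogate"
    context_radius: int = 30

    def __post_init__(self):
        for name in ("hom_af_min", "on_target_min", "off_target_max_cfd", "qc_min_af"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not 1 <= self.seed_window <= 20:
            raise ValueError("seed_window must be in [1,20]")
        if self.mad_constant <= 0:
            raise ValueError("mad_constant must be positive")
        if self.af_median_population not in ("het", "all"):
            raise ValueError("af_median_population must be 'het' or 'all'")
        self.pam_motifs = tuple(m.upper() for m in self.pam_motifs)
        self.exclude_flags = frozenset(self.exclude_flags)

    @property
    def off_target_pam_motifs(self) -> tuple:
        if self.allow_nag_offtarget:
            return tuple(dict.fromkeys(self.pam_motifs + ("NAG",)))
        return self.pam_motifs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pam_motifs"] = list(self.pam_motifs)
        d["exclude_flags"] = sorted(self.exclude_flags)
        return d

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


DEFAULT_CONFIG = PipelineConfig()
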