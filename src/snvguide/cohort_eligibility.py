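"""Cohort-level aggregation: patient eligibility and hotspot comparison.

A patient is "applicable" when at least one qualified sgRNA exists for at
least one of their passenger SNVs. Eligibility is summarized per sample,
per cancer type (with both a pooled and a type-averaged percentage) and
compared against the conventional oncogene-hotspot strategy via Venn-style
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .records import FilterTrace, SomaticSNV, TRACE_STEPS

log = logging.getLogger(__name__)


class CohortIntegrityError(ValueError):
    """A candidate references a sample absent from the sample table."""


@dataclass
class EligibilitySummary:
    """Per-sample, per-cancer-type and overall eligibility statistics.

    ``per_sample`` maps sample_id to a dict with cancer_type,
    n_qualified_guides, eligible, hotspot_carrier. Percentages are stored
    at full precision; rounding happens only at presentation.
    """

    per_sample: dict
    per_type: dict
    overall: dict

    def to_json_dict(self) -> dict:
        return {"per_sample": self.per_sample, "per_type": self.per_type,
                "overall": self.overall}


def summarize(candidates: Iterable, samples: Iterable[tuple],
              hotspot_flags: Optional[Mapping[str, bool]] = None) -> EligibilitySummary:
    """Aggregate qualified guides into patient-eligibility statistics.

    ``samples`` is an iterable of (sample_id, cancer_type) covering every
    analyzed patient — samples with zero candidates count as ineligible,
    not missing, so they stay in every denominator. ``hotspot_flags`` marks
    carriers of cataloged oncogene hotspot mutations for the
    strategy-comparison counts.
    """
    hotspot_flags = hotspot_flags or {}
    sample_types = dict(samples)
    n_qualified: dict[str, int] = {s: 0 for s in sample_types}
    for c in candidates:
        sid = c.source_snv.sample_id
        if sid not in sample_types:
            raise CohortIntegrityError(
                f"candidate references sample {sid!r} absent from the sample table")
        if c.qualified:
            n_qualified[sid] += 1

    per_sample = {}
    for sid in sorted(sample_types):
        per_sample[sid] = {
            "cancer_type": sample_types[sid],
            "n_qualified_guides": n_qualified[sid],
            "eligible": n_qualified[sid] >= 1,
            "hotspot_carrier": bool(hotspot_flags.get(sid, False)),
        }

    per_type = {}
    for ctype in sorted({t for t in sample_types.values() if t is not None} |
                        ({None} if any(t is None for t in sample_types.values()) else set())):
        rows = [v for v in per_sample.values() if v["cancer_type"] == ctype]
        n = len(rows)
        n_elig = sum(r["eligible"] for r in rows)
        n_hot = sum(r["hotspot_carrier"] for r in rows)
        per_type[ctype if ctype is not None else "NA"] = {
            "n_samples": n,
            "n_eligible": n_elig,
            "pct_eligible": 100.0 * n_elig / n if n else 0.0,
            "n_hotspot": n_hot,
            "pct_hotspot": 100.0 * n_hot / n if n else 0.0,
        }

    n = len(per_sample)
    n_elig = sum(r["eligible"] for r in per_sample.values())
    n_hot = sum(r["hotspot_carrier"] for r in per_sample.values())
    n_both = sum(r["eligible"] and r["hotspot_carrier"] for r in per_sample.values())
    type_pcts = [v["pct_eligible"] for v in per_type.values()]
    overall = {
        "n_samples": n,
        "n_eligible": n_elig,
        "pct_eligible": 100.0 * n_elig / n if n else 0.0,
        "pct_eligible_type_averaged": float(np.mean(type_pcts)) if type_pcts else 0.0,
        "n_hotspot": n_hot,
        "pct_hotspot": 100.0 * n_hot / n if n else 0.0,
        "n_both": n_both,
        "n_only_passenger": n_elig - n_both,
        "n_only_hotspot": n_hot - n_both,
        "n_neither": n - n_elig - n_hot + n_both,
    }
    return EligibilitySummary(per_sample=per_sample, per_type=per_type,
                              overall=overall)


def step_attrition_table(traces: Iterable[FilterTrace],
                         group_by: str = "sample",
                         cancer_types: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Summed per-step SNV counts per sample or per cancer type.

    Rows are non-increasing left to right by construction (each trace
    already is, and sums of non-increasing sequences stay non-increasing).
    """
    if group_by not in ("sample", "cancer_type"):
        raise ValueError("group_by must be 'sample' or 'cancer_type'")
    rows = {}
    for t in traces:
        if group_by == "sample":
            key = t.sample_id
        else:
            key = (cancer_types or {}).get(t.sample_id, "NA")
        acc = rows.setdefault(key, [0] * len(TRACE_STEPS))
        for i, v in enumerate(t.as_row()):
            acc[i] += v
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(TRACE_STEPS))
    df.index.name = group_by
    return df.sort_index()


def compare_af_distributions(selected: list[SomaticSNV],
                             hotspot_snvs: list[SomaticSNV],
                             all_snvs: list[SomaticSNV]) -> dict:
    """Descriptive AF statistics per group, plus a rank test.

    Groups: selected passenger SNVs, oncogene hotspot SNVs, and the full
    pre-selection SNV set. Empty groups are omitted with a warning. When
    both the selected and pre-selection groups are non-empty, a two-sided
    Mann-Whitney U test between them is reported (descriptive only — no
    filtering decision depends on it).
    """
    groups = {"selected": selected, "hotspot": hotspot_snvs, "all": all_snvs}
    out: dict = {}
    for name, snvs in groups.items():
        if not snvs:
            log.warning("AF comparison: group %r is empty, omitted", name)
            continue
        afs = np.array([s.allele_frequency for s in snvs], dtype=float)
        out[name] = {
            "n": int(afs.size),
            "median": float(np.median(afs)),
            "q1": float(np.percentile(afs, 25)),
            "q3": float(np.percentile(afs, 75)),
        }
    if "selected" in out and "all" in out:
        u = stats.mannwhitneyu(
            [s.allele_frequency for s in selected],
            [s.allele_frequency for s in all_snvs],
            alternative="two-sided")
        out["rank_test"] = {"name": "Mann-Whitney U", "statistic": float(u.statistic),
                            "p_value": float(u.pvalue)}
    return out
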