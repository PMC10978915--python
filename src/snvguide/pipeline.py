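"""End-to-end orchestration: MAF/VCF in, guide + eligibility reports out.

Stage order: QC -> zygosity -> (optional recurrence) -> per-sample AF_cut
(computed on the full QC-passed list) -> gene class -> AF threshold ->
expression -> guide design -> on-target -> off-target/CFD -> qualification
-> cohort summary. Each stage is a pure function of its inputs, so the
pipeline output is invariant to input record order and repeated runs
produce byte-identical reports.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pyfaidx

from . import __version__
from .config import PipelineConfig
from .records import FilterTrace, SomaticSNV, Zygosity
from . import io_formats, variant_filtering as vf
from .guide_design import build_candidates
from .guide_scoring import (CFDModel, attach_off_target_scores, default_cfd_model,
                            enumerate_off_targets, get_scorer, load_cfd_model,
                            qualify_guide, score_on_target, score_wt_allele)
from .cohort_eligibility import step_attrition_table, summarize

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


@dataclass
class PipelineResult:
    candidates: list
    summary: object                  # EligibilitySummary
    traces: list
    thresholds: dict
    skipped_samples: list
    guide_report: Optional[Path] = None
    eligibility_json: Optional[Path] = None
    attrition_tsv: Optional[Path] = None
    manifest_json: Optional[Path] = None


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(maf_path, genome_path, gene_catalog_paths, expression_path,
                 config: Optional[PipelineConfig] = None,
                 hotspot_path=None, recurrence_path=None,
                 cfd_model: Optional[CFDModel] = None,
                 cfd_model_path=None,
                 outdir=None) -> PipelineResult:
    """Run the full selection workflow over a cohort MAF.

    When ``outdir`` is given, writes guide_report.tsv, eligibility.json,
    attrition.tsv and manifest.json there. Samples without heterozygous
    SNVs (AF_cut undefined) are skipped with a log entry and reported in
    ``skipped_samples``; they stay in eligibility denominators.
    """
    config = config or PipelineConfig()
    if cfd_model is None:
        cfd_model = load_cfd_model(cfd_model_path) if cfd_model_path \
            else default_cfd_model()
    scorer = get_scorer(config.scorer)

    maf = io_formats.read_maf(maf_path)
    genome = pyfaidx.Fasta(str(genome_path))
    catalog = io_formats.read_gene_catalog(gene_catalog_paths)
    expr = io_formats.read_expression(expression_path)
    hotspots = io_formats.read_hotspots(hotspot_path) if hotspot_path else []
    recurrence = (io_formats.read_recurrence_catalog(recurrence_path)
                  if recurrence_path else None)

    by_sample: dict[str, list[SomaticSNV]] = {}
    sample_types: dict[str, Optional[str]] = {}
    for snv in maf.records:
        by_sample.setdefault(snv.sample_id, []).append(snv)
        sample_types.setdefault(snv.sample_id, snv.cancer_type)

    candidates = []
    traces = []
    thresholds = {}
    hotspot_flags = {}
    skipped = []

    for sid in sorted(by_sample):
        snvs = sorted(by_sample[sid], key=lambda s: (s.chrom, s.pos, s.alt_allele))
        n_input = len(snvs)

        snvs = vf.qc_filter(snvs, config)
        snvs = [vf.call_zygosity(s, config) for s in snvs]
        if recurrence is not None:
            snvs = vf.recurrence_filter(snvs, recurrence)
        hotspot_flags[sid] = vf.annotate_hotspot_carrier(snvs, hotspots)

        try:
            threshold = vf.compute_af_cut(snvs, config, sample_id=sid)
        except vf.ThresholdUndefinedError as exc:
            log.warning("skipping sample %s: %s", sid, exc)
            skipped.append(sid)
            traces.append(FilterTrace(sample_id=sid, counts={
                s: (n_input if s == "input" else 0)
                for s in ("input", "after_gene_class", "after_af",
                          "after_expression", "after_design",
                          "after_on_target", "after_off_target")}))
            continue
        thresholds[sid] = threshold

        kept = vf.filter_by_gene_class(snvs, catalog)
        n_gene_class = len(kept)
        kept = vf.filter_by_af(kept, threshold, config)
        n_af = len(kept)
        kept = vf.filter_by_expression(kept, expr, config)
        n_expr = len(kept)

        n_design = n_on = n_off = 0
        for snv in kept:
            try:
                snv_cands = build_candidates(genome, snv, config)
            except Exception as exc:
                raise StageError("design", f"{sid} {snv.chrom}:{snv.pos}: {exc}")
            if not snv_cands:
                continue
            n_design += 1
            snv_on = snv_qualified = 0
            for cand in snv_cands:
                score_on_target(cand, scorer)
                if cand.on_target_score > config.on_target_min:
                    snv_on += 1
                site = cand.site
                hits = enumerate_off_targets(
                    site.spacer_mut, genome, config,
                    exclude=(site.chrom, site.protospacer_start,
                             site.protospacer_end))
                attach_off_target_scores(cand, hits, cfd_model)
                score_wt_allele(cand, cfd_model)
                qualify_guide(cand, config)
                if cand.qualified:
                    snv_qualified += 1
                candidates.append(cand)
            n_on += snv_on > 0
            n_off += snv_qualified > 0

        traces.append(FilterTrace(sample_id=sid, counts={
            "input": n_input, "after_gene_class": n_gene_class,
            "after_af": n_af, "after_expression": n_expr,
            "after_design": n_design, "after_on_target": n_on,
            "after_off_target": n_off}))

    summary = summarize(candidates,
                        [(sid, sample_types.get(sid)) for sid in sorted(by_sample)],
                        hotspot_flags)
    result = PipelineResult(candidates=candidates, summary=summary,
                            traces=traces, thresholds=thresholds,
                            skipped_samples=skipped)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.guide_report = outdir / "guide_report.tsv"
        io_formats.write_guide_report(candidates, result.guide_report)

        result.eligibility_json = outdir / "eligibility.json"
        payload = summary.to_json_dict()
        payload["af_thresholds"] = {
            sid: {"af_median": t.af_median, "mad_het": t.mad_het,
                  "af_cut": t.af_cut, "n_het_used": t.n_het_used}
            for sid, t in sorted(thresholds.items())}
        with open(result.eligibility_json, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

        result.attrition_tsv = outdir / "attrition.tsv"
        step_attrition_table(traces).to_csv(result.attrition_tsv, sep="\t")

        inputs = {"maf": str(maf_path), "genome": str(genome_path),
                  "expression": str(expression_path)}
        manifest = {
            "tool": "snvguide", "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "config": config.to_dict(),
            "cfd_model": cfd_model.name,
            "inputs": {k: {"path": v, "sha256": _sha256(v)}
                       for k, v in inputs.items()},
            "outputs": {p.name: {"sha256": _sha256(p)} for p in
                        (result.guide_report, result.eligibility_json,
                         result.attrition_tsv)},
            "per_sample_counts": {t.sample_id: t.counts for t in traces},
            "skipped_samples": skipped,
        }
        result.manifest_json = outdir / "manifest.json"
        with open(result.manifest_json, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result
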