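"""Deterministic synthetic genomes and tumor cohorts with planted structure.

The generator emulates the pipeline's real-world inputs at desk scale: a
small multi-contig reference genome with gene models, a per-sample somatic
SNV cohort (MAF) with controlled zygosity and allele-frequency structure,
an expression matrix, gene-class / hotspot catalogs, and a truth JSON
recording every planted fact. Every stochastic draw goes through one
seeded generator, so the same spec yields byte-identical files.

Allele-frequency model: heterozygous clonal AFs concentrate near
purity / 2, homozygous clonal AFs near purity, subclonal AFs near 0.2.
Default purity is 0.95 so that homozygous clonal AFs clear the AF >= 0.9
homozygosity heuristic used when the MAF carries no genotype.

Planted eligibility is guaranteed by construction, not by simulation luck:
planted guide SNVs get spacers at 55% GC (maximal surrogate on-target
score), AF margins above the sample's AF_cut, expression above the cutoff,
and the genome is scrubbed of accidental near-matches to planted spacers.
Background SNVs are constructed to fail a specific step (wrong gene class,
heterozygous in an essential gene, subclonal AF, or low expression), so
non-planted samples are ineligible by construction.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._sequence import revcomp
from .config import PipelineConfig
from .records import SomaticSNV, VariantClass, Zygosity
from .guide_scoring import enumerate_off_targets

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class GenerationError(RuntimeError):
    """Planting is infeasible for the requested cohort geometry."""


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    contig: str
    start: int    # 1-based inclusive
    end: int
    gene_class: str


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort; defaults are the study conditions.

    ``planted_guides`` lists (sample_index, gene_class, design_class,
    strand) tuples that must survive the full pipeline; the planted gene
    class decides zygosity (essential -> homozygous, haploinsufficient ->
    heterozygous) so the zygosity rule holds by construction.
    """

    seed: int = 0
    n_contigs: int = 5
    contig_length: int = 50_000
    n_genes: int = 30
    n_samples: int = 20
    cancer_type_labels: tuple = ("COAD", "LUAD")
    muts_per_sample: int = 60
    purity: float = 0.95
    subclonal_fraction: float = 0.15
    hom_background_fraction: float = 0.10
    flag_fraction: float = 0.05
    planted_guides: tuple = (
        (0, "essential", "snv_in_seed", "+"),
        (1, "haploinsufficient", "snv_in_pam", "+"),
        (2, "haploinsufficient", "snv_in_seed", "-"),
    )
    planted_hotspot_carriers: tuple = (2, 7, 8, 12, 19)

    def __post_init__(self):
        for si, gclass, dclass, strand in self.planted_guides:
            if si >= self.n_samples:
                raise GenerationError(f"planted sample index {si} out of range")
            if gclass not in ("essential", "haploinsufficient"):
                raise GenerationError(f"planted gene class must be viable, got {gclass}")
            if dclass not in ("snv_in_pam", "snv_in_seed"):
                raise GenerationError(f"unknown design class {dclass}")
            if strand not in "+-":
                raise GenerationError("strand must be + or -")
        if any(i >= self.n_samples for i in self.planted_hotspot_carriers):
            raise GenerationError("hotspot carrier index out of range")
        if not 0.5 < self.purity <= 1.0:
            raise GenerationError("purity must be in (0.5, 1]")

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def cancer_type(self, i: int) -> str:
        return self.cancer_type_labels[i % len(self.cancer_type_labels)]


@dataclass
class Bundle:
    """Paths of a generated fixture bundle plus its truth record."""

    directory: Path
    genome_fa: Path
    maf: Path
    expression_tsv: Path
    gene_catalog_tsv: Path
    hotspots_tsv: Path
    truth_json: Path
    truth: dict
    sequences: dict = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# Low-level pieces
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])

_GENE_CLASS_CYCLE = ("essential", "haploinsufficient", "other",
                     "essential", "haploinsufficient", "oncogene")


def _lay_out_genes(spec: SyntheticCohortSpec) -> list[GeneModel]:
    per_contig = math.ceil(spec.n_genes / spec.n_contigs)
    gene_len = 2500
    pitch = (spec.contig_length - 4000) // per_contig
    if pitch < gene_len + 500:
        raise GenerationError("contigs too short for the requested gene count")
    genes = []
    g = 0
    for c in range(spec.n_contigs):
        for k in range(per_contig):
            if g >= spec.n_genes:
                break
            start = 2001 + k * pitch
            genes.append(GeneModel(
                symbol=f"GENE{g:03d}", contig=f"chr{c + 1}",
                start=start, end=start + gene_len - 1,
                gene_class=_GENE_CLASS_CYCLE[g % len(_GENE_CLASS_CYCLE)]))
            g += 1
    return genes


def _make_template(rng, design_class: str):
    """Build a 27-nt WT template (4 up + 20 spacer + 3 PAM) around one SNV.

    The mutant spacer carries exactly 11 G/C of 20 (GC 0.55, the surrogate
    on-target optimum). Returns (template_wt, snv_rel, ref, alt, spacer_mut)
    with snv_rel the 0-based SNV index inside the template.
    """
    gc_pos = set(rng.choice(20, size=11, replace=False).tolist())
    spacer_mut = "".join(
        "GC"[rng.integers(2)] if p in gc_pos else "AT"[rng.integers(2)]
        for p in range(20))
    left = _random_seq(rng, 4)
    if design_class == "snv_in_seed":
        idx = 14  # spacer position 15, inside the 12-bp seed
        alt = spacer_mut[idx]
        ref = [b for b in "ACGT" if b != alt][rng.integers(3)]
        spacer_wt = spacer_mut[:idx] + ref + spacer_mut[idx + 1:]
        return left + spacer_wt + "TGG", 4 + idx, ref, alt, spacer_mut
    # snv_in_pam: SNV completes TGG at PAM position 3; wild type TGC is no PAM
    return left + spacer_mut + "TGC", 4 + 22, "C", "G", spacer_mut


def _overlaps(a_start, a_end, intervals) -> bool:
    return any(s <= a_end and e >= a_start for s, e in intervals)


def _scrub_near_matches(seqs: dict, spacers: list[str], reserved: dict,
                        max_mismatches: int = 3) -> dict:
    """Destroy accidental near-matches (<=max_mismatches, NGG or NAG PAM)
    to planted spacers by breaking the invariant PAM G, so the truth JSON's
    "no off-targets" claim is exhaustive. Iterates to a fixed point."""
    scan_cfg = PipelineConfig(max_mismatches=max_mismatches, allow_nag_offtarget=True)
    for _round in range(20):
        dirty = False
        for spacer in spacers:
            for hit in enumerate_off_targets(spacer, seqs, scan_cfg):
                if _is_own_locus(hit, spacer, reserved):
                    continue
                if _overlaps(hit.start, hit.end, reserved.get(hit.chrom, [])):
                    # a planted window near-matching ANOTHER planted spacer
                    # cannot be scrubbed without destroying the plant
                    raise GenerationError("planted spacers collide; change the seed")
                seq = seqs[hit.chrom]
                if hit.strand == "+":
                    g_pos = hit.end + 3          # PAM position 3 (1-based)
                    new = "C" if seq[g_pos - 1] != "C" else "T"
                else:
                    g_pos = hit.start - 3        # complements PAM position 3
                    new = "A" if seq[g_pos - 1] != "A" else "T"
                if _overlaps(g_pos, g_pos, reserved.get(hit.chrom, [])):
                    raise GenerationError(
                        "near-match PAM inside a planted window; change the seed")
                seqs[hit.chrom] = seq[:g_pos - 1] + new + seq[g_pos:]
                dirty = True
        if not dirty:
            return seqs
    raise GenerationError("could not scrub accidental near-matches in 20 rounds")


def _is_own_locus(hit, spacer, reserved) -> bool:
    # own-plant near-match: the reserved window was created for this spacer
    return reserved.get((hit.chrom, "spacer_at"), {}).get((hit.start, hit.end)) == spacer


def plant_off_target_copy(seqs: dict, spacer: str, n_mismatches: int,
                          rng, pam: str = "TGG",
                          avoid: Optional[dict] = None,
                          max_tries: int = 200) -> tuple[dict, dict]:
    """Insert a site matching ``spacer`` at exactly ``n_mismatches`` mismatches.

    Writes the site plus a concrete PAM into a random location outside
    ``avoid`` intervals and returns (modified sequences, locus record).
    """
    if len(spacer) != 20:
        raise ValueError("spacer must be 20 nt")
    avoid = avoid or {}
    site = list(spacer)
    if n_mismatches:
        for p in rng.choice(20, size=n_mismatches, replace=False):
            site[p] = [b for b in "ACGT" if b != spacer[p]][rng.integers(3)]
    site_seq = "".join(site)
    chroms = sorted(seqs)
    for _ in range(max_tries):
        chrom = chroms[rng.integers(len(chroms))]
        L = len(seqs[chrom])
        if L < 2100:
            continue
        start = int(rng.integers(1000, L - 1000))  # 1-based protospacer start
        if _overlaps(start - 5, start + 27, avoid.get(chrom, [])):
            continue
        seq = seqs[chrom]
        seqs = dict(seqs)
        seqs[chrom] = seq[:start - 1] + site_seq + pam + seq[start + 22:]
        record = {"chrom": chrom, "start": start, "end": start + 19,
                  "strand": "+", "site_seq": site_seq, "pam_seq": pam,
                  "n_mismatches": int(n_mismatches)}
        return seqs, record
    raise GenerationError("could not place the off-target copy without collision")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_MAF_CLASS_OUT = {
    VariantClass.missense: "Missense_Mutation",
    VariantClass.synonymous: "Silent",
    VariantClass.nonsense: "Nonsense_Mutation",
    VariantClass.splice: "Splice_Site",
    VariantClass.other: "Other",
}

MAF_COLUMNS = (
    "Hugo_Symbol", "Chromosome", "Start_Position", "End_Position",
    "Reference_Allele", "Tumor_Seq_Allele1", "Tumor_Seq_Allele2",
    "Variant_Classification", "Variant_Type", "Tumor_Sample_Barcode",
    "Cancer_Type", "t_depth", "t_alt_count", "tumor_f", "Flags",
)


def write_cohort(records: list, path, depths: Optional[dict] = None) -> None:
    """Write SomaticSNV records as a GDC-style MAF (sorted, deterministic).

    ``depths`` optionally maps record key -> t_depth; alt counts are
    reconstructed from AF x depth. An explicit ``tumor_f`` column preserves
    the exact allele fraction across the round trip.
    """
    rows = []
    for s in records:
        depth = (depths or {}).get((s.sample_id,) + s.key, 100)
        alt = s.alt_read_count if s.alt_read_count is not None \
            else int(round(s.allele_frequency * depth))
        rows.append((
            s.gene_symbol, s.chrom, str(s.pos), str(s.pos),
            s.ref_allele, s.ref_allele, s.alt_allele,
            _MAF_CLASS_OUT[s.variant_class], "SNP", s.sample_id,
            s.cancer_type or "", str(depth), str(alt),
            format(s.allele_frequency, ".17g"), ";".join(sorted(s.flags))))
    rows.sort(key=lambda r: (r[9], r[1], int(r[2]), r[6]))
    with open(path, "w") as fh:
        fh.write("\t".join(MAF_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


def _write_fasta(seqs: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def generate(spec: SyntheticCohortSpec, outdir) -> Bundle:
    """Generate a complete fixture bundle; fully reproducible from the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    sample_ids = spec.sample_ids()

    # 1. genome and gene models
    seqs = {f"chr{c + 1}": _random_seq(rng, spec.contig_length)
            for c in range(spec.n_contigs)}
    genes = _lay_out_genes(spec)
    by_class: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_class.setdefault(g.gene_class, []).append(g)

    # 2. plant guide loci
    planted = []
    reserved: dict = {}
    used_genes: set[str] = set()
    for si, gclass, dclass, strand in spec.planted_guides:
        pool = [g for g in by_class.get(gclass, []) if g.symbol not in used_genes]
        if not pool:
            raise GenerationError(f"no free {gclass} gene left to plant in")
        gene = pool[0]
        used_genes.add(gene.symbol)
        template_wt, snv_rel, ref, alt, spacer_mut = _make_template(rng, dclass)
        site_start = gene.start + 400
        seq = seqs[gene.contig]
        if strand == "+":
            written = template_wt
            snv_pos = site_start + snv_rel
            ref_g, alt_g = ref, alt
            ps, pe = site_start + 4, site_start + 23
        else:
            written = revcomp(template_wt)
            snv_pos = site_start + (len(template_wt) - 1 - snv_rel)
            ref_g, alt_g = _COMP[ref], _COMP[alt]
            ps, pe = site_start + 3, site_start + 22
        seqs[gene.contig] = (seq[:site_start - 1] + written
                             + seq[site_start - 1 + len(written):])
        reserved.setdefault(gene.contig, []).append(
            (site_start - 5, site_start + len(written) + 5))
        reserved.setdefault((gene.contig, "spacer_at"), {})[(ps, pe)] = spacer_mut
        planted.append({
            "sample_id": sample_ids[si], "gene": gene.symbol,
            "gene_class": gclass, "design_class": dclass, "strand": strand,
            "chrom": gene.contig, "pos": snv_pos,
            "ref": ref_g, "alt": alt_g, "spacer_mut": spacer_mut,
            "protospacer_start": ps, "protospacer_end": pe,
        })

    # 3. scrub accidental near-matches to planted spacers
    seqs = _scrub_near_matches(seqs, [p["spacer_mut"] for p in planted], reserved)

    # 4. hotspot catalog on oncogenes
    hotspots = []
    for g in by_class.get("oncogene", [])[:3]:
        hotspots.append({"gene_symbol": g.symbol, "chrom": g.contig,
                         "pos": g.start + 500})
    if spec.planted_hotspot_carriers and not hotspots:
        raise GenerationError("hotspot carriers requested but no oncogene present")

    # 5. somatic records
    records: list[SomaticSNV] = []
    gene_index = {c: [g for g in genes if g.contig == c] for c in seqs}
    planted_by_sample: dict[str, list] = {}
    for p in planted:
        planted_by_sample.setdefault(p["sample_id"], []).append(p)

    essential_pool = [g for g in by_class.get("essential", [])
                      if g.symbol not in used_genes]
    decoy_cells = {}   # (sample, gene) -> low expression
    planted_cells = {}

    for i, sid in enumerate(sample_ids):
        ctype = spec.cancer_type(i)
        taken = set()

        def add(chrom, pos, ref, alt, af, zyg, gene_symbol, vclass, flags=frozenset()):
            depth = int(rng.integers(60, 201))
            if zyg == "homozygous":
                alt_n = min(depth, math.ceil(max(af, 0.92) * depth))
            else:
                alt_n = max(1, int(round(af * depth)))
            real_af = alt_n / depth
            records.append(SomaticSNV(
                sample_id=sid, cancer_type=ctype, chrom=chrom, pos=pos,
                ref_allele=ref, alt_allele=alt, allele_frequency=real_af,
                alt_read_count=alt_n, gene_symbol=gene_symbol,
                variant_class=vclass, zygosity=Zygosity.unknown, flags=flags))
            taken.add((chrom, pos))
            return real_af

        # planted guide SNVs
        for p in planted_by_sample.get(sid, []):
            if p["gene_class"] == "essential":
                af, zyg = float(np.clip(rng.normal(spec.purity, 0.015), 0.92, 0.995)), "homozygous"
            else:
                af, zyg = 0.78, "heterozygous"
            real = add(p["chrom"], p["pos"], p["ref"], p["alt"], af, zyg,
                       p["gene"], VariantClass.missense)
            p["allele_frequency"] = real
            planted_cells[(sid, p["gene"])] = 4.0

        # decoy: homozygous SNV in an essential gene silenced by expression
        if essential_pool:
            dg = essential_pool[i % len(essential_pool)]
            pos = dg.start + 100 + 17 * i
            ref = seqs[dg.contig][pos - 1]
            alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(3))) % 4]
            add(dg.contig, pos, ref, alt,
                float(np.clip(rng.normal(spec.purity, 0.015), 0.92, 0.995)),
                "homozygous", dg.symbol, VariantClass.missense)
            decoy_cells[(sid, dg.symbol)] = 0.3

        # hotspot carrier SNV (oncogene: dropped at the gene-class step)
        if i in spec.planted_hotspot_carriers:
            h = hotspots[i % len(hotspots)]
            ref = seqs[h["chrom"]][h["pos"] - 1]
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
            add(h["chrom"], h["pos"], ref, alt,
                float(np.clip(rng.beta(19, 21), 0.25, 0.85)),
                "heterozygous", h["gene_symbol"], VariantClass.missense)

        # background SNVs
        n_bg = spec.muts_per_sample
        placed = 0
        guard = 0
        while placed < n_bg:
            guard += 1
            if guard > 50 * n_bg:
                raise GenerationError("cannot place background SNVs without collision")
            chrom = f"chr{int(rng.integers(spec.n_contigs)) + 1}"
            pos = int(rng.integers(100, len(seqs[chrom]) - 100))
            if (chrom, pos) in taken or _overlaps(pos, pos, reserved.get(chrom, [])):
                continue
            if any(h["chrom"] == chrom and h["pos"] == pos for h in hotspots):
                continue  # hotspot positions are reserved for planted carriers
            gene = next((g for g in gene_index[chrom] if g.start <= pos <= g.end), None)
            gclass = gene.gene_class if gene else None
            symbol = gene.symbol if gene else "INTERGENIC"
            if gclass == "essential":
                af, zyg = float(np.clip(rng.beta(19, 21), 0.25, 0.85)), "heterozygous"
            elif gclass == "haploinsufficient":
                af, zyg = float(np.clip(rng.beta(4, 16), 0.05, 0.25)), "heterozygous"
            else:
                u = rng.random()
                if u < spec.hom_background_fraction:
                    af, zyg = float(np.clip(rng.normal(spec.purity, 0.015), 0.92, 0.995)), "homozygous"
                elif u < spec.hom_background_fraction + spec.subclonal_fraction:
                    af, zyg = float(np.clip(rng.beta(4, 16), 0.05, 0.25)), "heterozygous"
                else:
                    af, zyg = float(np.clip(rng.beta(19, 21), 0.25, 0.85)), "heterozygous"
            ref = seqs[chrom][pos - 1]
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
            flags = frozenset()
            if rng.random() < spec.flag_fraction:
                flags = frozenset({sorted(PipelineConfig().exclude_flags)[int(rng.integers(3))]})
            vclass = [VariantClass.missense, VariantClass.synonymous,
                      VariantClass.nonsense, VariantClass.other][int(rng.integers(4))]
            add(chrom, pos, ref, alt, af, zyg, symbol, vclass, flags)
            placed += 1

    # 6. verify AF margins against each sample's realized AF_cut
    af_cuts = _verify_af_margins(records, planted, spec)

    # 7. expression matrix
    expr_rows = []
    gene_syms = sorted(g.symbol for g in genes)
    for gsym in gene_syms:
        row = [gsym]
        for sid in sample_ids:
            if (sid, gsym) in planted_cells:
                v = planted_cells[(sid, gsym)]
            elif (sid, gsym) in decoy_cells:
                v = decoy_cells[(sid, gsym)]
            elif rng.random() < 0.15:
                v = float(rng.uniform(0.0, 0.9))
            else:
                v = float(rng.uniform(1.2, 6.0))
            row.append(format(v, ".4f"))
        expr_rows.append(row)

    # 8. write files
    genome_fa = outdir / "genome.fa"
    maf = outdir / "cohort.maf"
    expression_tsv = outdir / "expression.tsv"
    gene_catalog_tsv = outdir / "gene_catalog.tsv"
    hotspots_tsv = outdir / "hotspots.tsv"
    truth_json = outdir / "truth.json"

    _write_fasta(seqs, genome_fa)
    write_cohort(records, maf)
    with open(expression_tsv, "w") as fh:
        fh.write("\t".join(["gene_symbol"] + sample_ids) + "\n")
        for row in expr_rows:
            fh.write("\t".join(row) + "\n")
    with open(gene_catalog_tsv, "w") as fh:
        fh.write("gene_symbol\tgene_class\tsource\n")
        for g in sorted(genes, key=lambda g: g.symbol):
            fh.write(f"{g.symbol}\t{g.gene_class}\tsynthetic\n")
    with open(hotspots_tsv, "w") as fh:
        fh.write("gene_symbol\tchrom\tpos\tref_allele\talt_allele\n")
        for h in hotspots:
            fh.write(f"{h['gene_symbol']}\t{h['chrom']}\t{h['pos']}\t\t\n")

    eligible = sorted({p["sample_id"] for p in planted})
    carriers = sorted(sample_ids[i] for i in spec.planted_hotspot_carriers)
    truth = {
        "seed": spec.seed,
        "n_samples": spec.n_samples,
        "samples": {
            sid: {
                "cancer_type": spec.cancer_type(i),
                "eligible": sid in eligible,
                "hotspot_carrier": sid in carriers,
                "af_cut": af_cuts[sid],
            } for i, sid in enumerate(sample_ids)
        },
        "eligible_samples": eligible,
        "hotspot_carriers": carriers,
        "planted_guides": sorted(planted, key=lambda p: p["sample_id"]),
        "genes": [{"symbol": g.symbol, "contig": g.contig, "start": g.start,
                   "end": g.end, "gene_class": g.gene_class} for g in genes],
    }
    with open(truth_json, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return Bundle(directory=outdir, genome_fa=genome_fa, maf=maf,
                  expression_tsv=expression_tsv,
                  gene_catalog_tsv=gene_catalog_tsv,
                  hotspots_tsv=hotspots_tsv, truth_json=truth_json,
                  truth=truth, sequences=seqs)


def _verify_af_margins(records, planted, spec) -> dict:
    """Recompute each sample's AF_cut on QC-passed records and check that
    every planted SNV clears it with margin while haploinsufficient
    background stays below; raises GenerationError otherwise."""
    cfg = PipelineConfig()
    by_sample: dict[str, list] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    planted_keys = {(p["sample_id"], p["chrom"], p["pos"]): p for p in planted}
    af_cuts = {}
    for sid, snvs in by_sample.items():
        qc = [s for s in snvs
              if s.alt_read_count >= cfg.qc_min_alt_reads
              and s.allele_frequency >= cfg.qc_min_af
              and not (s.flags & cfg.exclude_flags)]
        het = np.array([s.allele_frequency for s in qc
                        if s.allele_frequency < cfg.hom_af_min])
        if het.size == 0:
            raise GenerationError(f"sample {sid} has no heterozygous QC-passed SNV")
        cut = float(np.median(het) + np.median(np.abs(het - np.median(het))))
        af_cuts[sid] = cut
        if not 0.30 <= cut <= 0.70:
            raise GenerationError(f"sample {sid}: AF_cut {cut:.3f} outside the "
                                  "designed margin band")
        for s in qc:
            p = planted_keys.get((sid, s.chrom, s.pos))
            if p is not None and s.allele_frequency <= cut + 0.02:
                raise GenerationError(
                    f"planted SNV for {sid} (AF {s.allele_frequency:.3f}) does not "
                    f"clear AF_cut {cut:.3f}")
    return af_cuts
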