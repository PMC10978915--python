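# Methods

`snvguide` implements a selection workflow for allele-specific CRISPR/Cas9
cancer targeting: from per-sample somatic SNV lists it identifies passenger
variants in essential or haploinsufficient genes that admit a
mutant-allele-discriminating, efficient, low-off-target SpCas9 guide, and
summarizes how many patients in a cohort are eligible. This note documents
the model, every tunable that matters, the synthetic-data generator, and
the numerical choices made where the design was genuinely open.

## Selection model

A candidate SNV must pass, in order:

1. **Read-support QC.** At least `qc_min_alt_reads = 5` supporting reads
   and allele frequency at least `qc_min_af = 0.20` (both inclusive);
   variants flagged as segmental duplication, tandem repeat, or known
   germline (`exclude_flags`) are removed. Records without a read count
   pass the count check vacuously and are logged.
2. **Zygosity.** An explicit genotype (VCF GT) always wins. Otherwise the
   variant is called homozygous when AF ≥ `hom_af_min = 0.9`, else
   heterozygous. 0.9 is a deliberately tolerant threshold: tumor impurity
   and loss of heterozygosity depress homozygous AFs below 1. The decision
   path is stamped into the record (`zygosity_source`).
3. **Gene class.** Keep SNVs in haploinsufficient genes at any zygosity
   (one broken copy suffices to kill the cell) and homozygous SNVs in
   essential genes (a heterozygous cut leaves a functional copy). When
   catalogs disagree on a gene, haploinsufficient wins: it subsumes the
   essential-gene zygosity requirement and retains more candidates.
   Oncogene labels live in a separate lookup used only for the
   hotspot-strategy comparison.
4. **Clonality.** Per sample, AF_cut = median(AF) + MAD(het AF), both
   statistics over the heterozygous SNVs of the sample's full QC-passed
   list (before gene-class filtering); an SNV survives when its AF
   strictly exceeds AF_cut. Early, clonal mutations sit above this
   threshold; subclonal ones fall below. The median population is
   switchable to all SNVs (`af_median_population`), the MAD scale constant
   defaults to 1.0 (literal MAD) and can be set to 1.4826 (the
   normal-consistency factor R applies by default), and the strict
   inequality can be relaxed to ≥ (`af_strict`). Samples with no
   heterozygous SNV have no threshold: they are skipped with a log entry
   and remain ineligible in denominators.
5. **Expression.** The gene must be expressed in that sample:
   log2(FPKM+1) strictly greater than `expression_min = 1.0`. Missing
   (sample, gene) values are distinguishable from zero and are dropped by
   default (`keep_missing_expression` reverses this).
6. **Guide design.** See below; at least one allele-discriminating
   protospacer placement must exist.
7. **On-target efficiency** strictly above `on_target_min = 0.5`.
8. **Off-target safety.** Genome-wide scan at ≤ `max_mismatches = 3`
   mismatches with an NGG PAM; if any hit's CFD exceeds
   `off_target_max_cfd = 0.175` the guide is discarded (a tie at 0.175 is
   kept; only strictly greater scores disqualify).

A patient is *eligible* when at least one guide survives all steps.

## Allele-discriminating design

SpCas9 needs a 20-nt protospacer followed 3' by an NGG PAM. Two placements
discriminate the mutant from the wild-type allele:

* **snv_in_pam** — the SNV creates the PAM: the mutant triplet is NGG with
  the substitution at PAM position 2 or 3 and the wild-type triplet is not
  NGG. The wild-type allele is simply not cleavable, so its reported CFD
  is 0.
* **snv_in_seed** — the SNV sits in the PAM-proximal seed of the spacer,
  positions `21 − seed_window … 20` (default 9–20 with the 12-bp seed,
  numbering position 1 PAM-distal). A seed mismatch strongly suppresses
  cleavage of the wild-type allele.

An SNV at PAM position 1 (the N) is rejected: any base satisfies N, so the
placement cannot distinguish alleles. SNVs that *destroy* a wild-type PAM
would make the wild-type allele the targetable one and are out of scope.
Both strands are scanned; reverse-strand spacers are reported 5'→3' with
the PAM 3'. Placements too close to a contig end to supply the 30-nt
scoring context (4 nt + spacer + PAM + 3 nt) are dropped with a logged
reason. Whether the original 12-bp window was meant as spacer positions
9–20 or as a symmetric window spanning the PAM is ambiguous; the
spacer-seed reading is implemented and the window width is configurable.

## Scoring

**On-target.** The workflow's interface is a pluggable scorer (a
deterministic map from the 30-nt context to [0, 1]); trained models such as
Azimuth 2.0 can be registered at runtime. The bundled default is a
documented surrogate, `clamp(1 − 2·|GC20 − 0.55|, 0, 1)` on the spacer's GC
fraction — a deliberately simple, deterministic stand-in that peaks at the
empirically favourable ~55 % GC. It is adequate for testing the pipeline's
plumbing and thresholds; it is not a validated efficiency predictor.

**Off-target.** The scan is exact and exhaustive: every 23-nt window on
both strands of every contig, hit when ≤ `max_mismatches` spacer
mismatches and the PAM matches a configured IUPAC motif (NGG by default;
NAG tolerance behind `allow_nag_offtarget`). Desk-scale genomes make the
vectorized naive scan sufficient and keep it trivially comparable to a
brute-force oracle; no heuristic index pruning is used. Windows containing
ambiguous bases (N) never match. The candidate's own locus is excluded —
otherwise every guide would disqualify itself. The wild-type allele at
that same locus is likewise excluded from the disqualifying set and
reported separately as `wt_allele_cfd`: for seed designs it is an
unavoidable 1-mismatch site whose CFD often exceeds 0.175, and counting it
would void exactly the guides the strategy depends on. The flag
`count_wt_as_offtarget` reverses this choice.

**CFD.** The cutting-frequency-determination score is the product of
position- and substitution-specific mismatch penalties times a
PAM-dinucleotide penalty; a perfect match with NGG scores exactly 1.
Penalty tables load from a documented TSV (position, spacer base, genomic
base, penalty; PAM rows keyed by dinucleotide), with RNA-alphabet tables
re-keyed U→T at load. The bundled `default_cfd_model()` is a synthetic
surrogate with the published matrix's qualitative structure (penalties
shrink toward the seed; transitions more tolerated than transversions;
non-NGG PAMs heavily penalized) and full coverage of all 1,200 triples; it
is clearly labelled and should be replaced by a published table for any
biological use.

## Cohort summary

Eligibility percentages are reported both pooled over patients and
averaged over cancer types (the two aggregations differ whenever type
sizes differ; both are labelled in the JSON). Samples with zero surviving
SNVs stay in denominators. The hotspot comparison marks samples carrying
an SNV at a cataloged oncogene hotspot, matched on (gene, position) and,
when the catalog specifies them, on alleles; Venn-style counts (both /
only passenger / only hotspot / neither) always partition the cohort. The
AF-distribution comparison (selected vs hotspot vs pre-selection) is
descriptive; its Mann-Whitney test drives no filtering decision.
Percentages are rounded to one decimal only at presentation; JSON carries
full precision.

## T7E1 arithmetic

From band densitometry, fraction cleaved = digested / (digested + parent)
and NHEJ(%) = 100 × [1 − (1 − fraction cleaved)^(1/2)] — the square root
reflects that a heteroduplex requires pairing one edited with one unedited
strand. The function is strictly increasing on (0, 1), maps 0 → 0 % and
1 → 100 %, and is invariant to rescaling both densities. Densitometry
itself is out of scope; densities are plain numbers.

## Synthetic cohort generator

The generator emulates the pipeline's inputs at desk scale with planted
ground truth. Defaults: 5 contigs × 50 kb, 30 gene models (10 essential,
10 haploinsufficient, 5 oncogene, 5 other), 20 samples, 60 somatic SNVs
per sample, tumor purity 0.95. Heterozygous clonal AFs draw from a Beta
centered at purity/2 (≈ 0.475, clipped to [0.25, 0.85]), homozygous clonal
AFs near purity (clipped to ≥ 0.92 so they clear the 0.9 homozygosity
heuristic — purity defaults to 0.95 precisely so zygosity is recoverable
from a MAF that carries no genotype), subclonal AFs from a Beta centered
near 0.2 (clipped to ≤ 0.25). Read depths are 60–200×; the AF written to
the MAF is the realized alt/depth ratio.

Planting is constructive, not statistical: planted guide SNVs get spacers
with exactly 11/20 GC (the surrogate optimum), a TGG PAM (or a TGC→TGG
PAM-creating substitution), AF margins verified against the sample's
realized AF_cut, and expression fixed at 4.0. The genome is scrubbed of
accidental ≤3-mismatch NGG/NAG near-matches to planted spacers, so the
truth file's "no off-target" claim is exhaustive. Every background SNV is
constructed to fail a specific step — unclassed gene, heterozygous in an
essential gene, subclonal AF in a haploinsufficient gene, or (for one
homozygous essential-gene decoy per sample) expression below the cutoff —
so the eligible set equals the planted set by construction, and the
generator raises rather than emit a bundle whose margins did not
materialize. A single seeded generator drives every draw: the same spec
yields byte-identical files.

What the generator does *not* emulate: mutational signatures, germline
variation, copy-number change, tumor-purity heterogeneity within a sample,
and realistic gene/exon structure. Passing end-to-end tests therefore
demonstrates that the machinery is correct under controlled conditions,
not that real-cohort eligibility rates would be reproduced; published
cohort-scale percentages require protected cohort MAFs and full catalogs,
which are inputs, not package contents.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive at every interface (MAF/VCF
  convention); BED-style half-open conversion happens only at export.
* Medians use the midpoint rule for even counts; the AF_cut identity
  af_cut = af_median + mad_het holds exactly as stored.
* Ties: AF at exactly AF_cut is dropped (strict >), on-target at exactly
  0.5 is rejected, off-target CFD at exactly 0.175 is kept — each
  configurable, all documented above.
* Guide-report rows sort by (sample, chrom, pos, strand, spacer) and
  floats print via a fixed format, so repeated runs are byte-identical.
  The run manifest records input/output digests and a wall-clock
  timestamp; the timestamp makes the manifest itself the one
  intentionally non-identical output.
* Empty inputs are valid: an empty cohort yields a header-only report and
  0 % eligibility; an empty design result is an empty list, not an error.
* Reference-mismatch between an SNV and the genome raises immediately
  (stale coordinates or wrong assembly), as does a negative expression
  value or an unknown gene-class label.

## Problem sizes used in the test suite

Unit tests run on crafted strings and 1.5–5 kb random genomes; oracle
equivalence suites use 300–1,000 random instances per property; the
end-to-end test uses the full default cohort (20 samples, 250 kb genome),
which completes in a few seconds. These sizes give exhaustive coverage of
the combinatorial rules while keeping the whole suite near ten seconds.

## Known limitations

The bundled on-target and CFD models are documented surrogates, not the
published trained models. Off-target search has no DNA/RNA bulge
tolerance. Hotspot matching is genomic-position-based, not residue-based.
No tumor-purity or copy-number correction of AFs is attempted beyond the
AF_cut heuristic, and no InDel or MNP targets are supported (SNVs only).
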