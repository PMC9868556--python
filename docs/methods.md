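# Methods

This note documents the models and procedures `lncforge` implements, the
defaults it ships, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## Identification cascade

The cascade turns an assembled transcript catalog into a lncRNA set in six
ordered stages; a `FilterReport` records n_in / n_removed / n_retained and
the removed ids at every stage, and the package enforces count conservation
(`n_in = n_removed + n_retained`, each stage's input equal to the previous
stage's output).

* **Length ≥ 200 nt** (spliced length, sum of inclusive exon lengths).
  The boundary is inclusive: a transcript of exactly 200 nt passes.
* **Exon count ≥ 2.** Two-exon transcripts pass; in real catalogs they
  dominate the final lncRNA set (~70%), so a stricter ≥3 reading would be
  inconsistent with the observed class structure.
* **Coding-id exclusion (optional).** Protein-homology searches (BLAST
  against protein databases, profile-HMM scans) are not reimplemented;
  callers inject their hits as id lists. This is a deliberate fidelity
  limitation: the package treats those searches as external evidence.
* **Longest ORF ≤ 300 nt.** An ORF is ATG-initiated, in-frame
  stop-terminated, searched in all six frames; its length includes the
  stop codon, so it is always a multiple of 3. Codons containing `N`
  match neither ATG nor a stop. Removal is strict (`> 300 nt` removed).
* **Coding potential.** See below; transcripts with coding probability
  ≥ cutoff (default 0.5) are removed.
* **Known-ncRNA exclusion.** tRNA/rRNA/snoRNA-type hits are again injected
  as id or BED-interval lists rather than recomputed with covariance
  models.

Sequences are extracted only after the structural filters, so catalogs
dominated by short/single-exon noise never touch the genome FASTA.

## Coding-potential model

A logistic regression over four sequence-intrinsic features, trained on
user- or generator-supplied coding and noncoding sequence sets:

* **Fickett TESTCODE score** — the published position/content lookup
  tables; position parameters are `max/(min+1)` over the three codon-phase
  counts per base, content parameters are base fractions, each binned
  through the published thresholds and combined with the published
  weights. Bases other than A/C/G/T are ignored in the counts.
* **Hexamer usage log-ratio** — `log(f_coding/f_noncoding)` tables over
  all 4096 hexamers, estimated from the training sets with +1 smoothing
  (every entry finite), scored as the mean over frame-0, step-3 hexamers
  of the transcript.
* **Longest ORF length** and **ORF coverage** (ORF / transcript length).

Features are z-scaled with the training moments; the logistic fit is
unpenalized maximum likelihood (lbfgs). The decision cutoff defaults to
0.5. Predicted probabilities are clipped to (1e−12, 1−1e−12) so that a
cutoff of exactly 1.0 disables the filter, which gives the degenerate
"identity cascade" configuration a well-defined meaning.

## Positional classification

Rules in precedence order — the same order used when several genes
overlap a transcript:

1. **sense**: ≥1 bp overlap between a lncRNA exon and a same-strand
   coding-gene exon;
2. **intronic**: lncRNA span contained in a same-strand coding-gene span
   while touching only intronic sequence;
3. **antisense**: ≥1 bp overlap with an opposite-strand coding gene —
   span-level by default (a strict exon-only mode is a flag);
4. **lincRNA** otherwise.

Same-strand evidence outranks opposite-strand evidence; among several
supporting genes the one with maximal overlap bp is reported, ties broken
by lexicographically smaller gene id so results are deterministic. A
transcript on a chromosome absent from the annotation is classified
lincRNA with a warning. Exon-size histograms default to 200-bp bins from
0, isolating the sub-200-bp exon share that distinguishes coding exons
from lncRNA exons.

## Expression and differential calling

`FPKM = count · 10⁹ / (length_bp · library_size)`, with effective length
equal to the spliced transcript length (no fragment-length correction — a
documented simplification). Transcripts with FPKM exactly 0 in all
libraries are pruned before testing and reported separately. Fold change
is computed on condition-mean FPKM with a pseudocount of 0.1 in both
orientations (R vs S and S vs R) to avoid sign confusion between
reporting conventions.

Per-transcript tests run on log2(FPKM + 0.1). The default statistic is a
**variance-moderated t**: per-transcript pooled variances are shrunk
toward a prior estimated from all transcripts by fitting a scaled-F model
to the log variances (method of moments via digamma/trigamma, prior df by
trigamma inversion), and the statistic is referred to t with the
augmented df. The rationale is practical and important: with 3 replicates
per condition a per-transcript Welch test has ~2–4 df, which places a
floor of roughly 10⁻³ under attainable p-values; after
Benjamini–Hochberg adjustment across a few thousand transcripts *no*
transcript can reach q < .01, and the caller would return zero calls even
for four-fold planted effects. Sharing variance information across
transcripts is how every small-replicate RNA-seq tester works, and it
restores calibrated power: the null rejection rate at α = .01 measures
~0.010, and recall on planted |log2FC| = 2 at NB dispersion 0.05 exceeds
0.99. Plain Welch remains available (`call_de(method="welch")`) and is
itself slightly conservative at these sample sizes (null rate ≈ 0.005).

Calls require |log2FC| ≥ 1, p < .01 and q < .01 simultaneously; loosening
any threshold can only add calls (monotonicity is tested). A zero fold
change can be significant only in the degenerate lfc-threshold-0 limit
and is labeled toward the second condition by convention.

## Cis-neighbor mapping

Distance anchor: lncRNA gene-span midpoint (floor of the span mean) to
the coding gene's TSS, the strand-aware 5′ end of the gene span. A gene
is in the regulatory zone when that distance is ≤ 1000 kb (inclusive) on
the same chromosome; strand affects only TSS placement, never inclusion.
This midpoint-to-TSS convention is applied uniformly; published ad-hoc
"bp apart" figures may use other anchors, so distances are comparable in
convention, not necessarily in value. Queries run against a sorted
per-chromosome TSS index (binary search), which tests verify against an
exhaustive all-pairs filter.

## Validation statistics

2^−ΔΔCt uses the control-group mean ΔCt as baseline (Livak), reported per
replicate so error bars reflect biological replication; by construction
the control group's mean log2 fold is exactly 0. No amplification-
efficiency correction is applied. Mortality is the raw percentage
`100 · dead/treated` per replicate with group means over replicates — no
control-mortality (Abbott) correction. Two groups are compared with
Welch's t; three or more with one-way ANOVA plus Tukey HSD.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes and
plants complete ground truth:

* a multi-chromosome genome (6 chromosomes + 2 scaffold-named sequences,
  auto-sized) populated by collision-free slots separated by ≥1 kb, so
  the positional class of every planted lncRNA is unambiguous;
* 2,000 protein-coding genes with codon-biased CDS (strong G/C-ending
  codon preference), 2–8 exons, and ~50% carrying a truncated second
  catalog isoform whose CDS stays complete;
* 3,470 lncRNAs in the class proportions 1,879 lincRNA / 853 sense / 493
  antisense / 245 intronic, a two-exon share of ~70%, mean length
  ~1.0 kb; sense lncRNAs overlap a host coding exon by 40–180 bp,
  intronic/antisense ones sit in a deliberately inflated host intron;
  every lncRNA sequence is rejection-sampled until its longest ORF is
  ≤ 300 nt, so planted truth matches the cascade's definition exactly;
* catalog noise: 22 sub-200-nt fragments, 1,500 single-exon assemblies,
  150 long-ORF decoys (planted ≥420-nt ORFs), 150 hexamer-biased decoys
  (coding-like composition, ORFs broken below 300 nt), and 200 known
  ncRNAs that populate the exclusion list;
* negative-binomial counts (dispersion 0.05) for 2 conditions × 3
  replicates at library sizes of 40–55 million mapped fragments, base
  FPKM lognormal (median 10); 632 planted DE transcripts (297 up in S,
  335 up in R) at |log2FC| = 2 applied symmetrically, plus 116 all-zero
  rows. Library sizes are kept at the realistic tens-of-millions scale:
  count simulation cost does not depend on depth, and the realistic
  FPKM↔count relationship is what gives the DE thresholds their intended
  behavior;
* qPCR Ct tables (4 replicates, reference Ct ≈ 18, planted treatment
  fold 35.86, Ct noise sd 0.15) and bioassay tables (3 replicates × 25
  larvae; day-4 mortality probabilities 0.70 RNAi vs 0.39 control,
  day-8 0.39 vs 0.27);
* an optional ambiguous mode that plants precedence conflicts
  (simultaneous same-strand exon and opposite-strand overlap) to
  exercise the sense-first tie-break.

One seed fixes every output byte.

What the generator does **not** emulate: read-level errors and multi-
mapping, splice-isoform assembly noise, positionally clustered gene
families, GC or length biases in counting, and correlated biological
replicates. Passing tests therefore demonstrate correctness of the
implemented inference under its stated model, not robustness to every
artifact of real libraries — in particular, real catalogs can yield
lower cascade precision than the planted-decoy mix here.

## Problem sizes used by the test suite

The default generator scale (≈7,700 catalog transcripts over a ~25 Mb
genome) runs the full pipeline in a few seconds, and the calibration
simulations use 10,000 transcripts (DE null), 5,000 replicates (ANOVA
null) and 1,000 random instances (classifier oracle) — sizes chosen so
the whole suite completes in well under a minute while keeping Monte
Carlo error far below the asserted margins.

## Known limitations

* The coding-potential stage is a statistical classifier: a borderline
  planted lncRNA (~0.2–0.5% of cases) can fall on the coding side of the
  cutoff, and hexamer-biased decoys are caught only partially (~50%), so
  cascade recall/precision are asserted as ≥ 0.95, not 1.0.
* Homology- and covariance-model-based evidence enters only via exclusion
  lists.
* DE testing assumes a common mean–variance structure across transcripts
  for the moderation prior; strongly heteroskedastic designs should use
  `method="welch"` and more replicates.
* Neighbor distances use one fixed anchor convention (midpoint → TSS).
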