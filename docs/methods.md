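# Methods

This note documents the models and procedures implemented in
`lncweanflow`, the parameter defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the design
decisions made where more than one reasonable convention exists.

## Annotation model and coordinates

Transcripts are stranded exon chains on a chromosome; coordinates are
GTF-native (1-based, inclusive) everywhere inside the package, and
converted to 0-based half-open only at BED export. Mature transcript
length is the sum of exon lengths; introns are the gaps between
consecutive exons. Chromosome names are compared by exact string
match — no `chr`-prefix normalization — because silent renaming hides
input errors. Strand `.` is permitted for single-exon assemblies
(assemblers cannot orient them) and is treated as *unknown*: such
transcripts are compared in both orientations downstream and can never
be called antisense (`x`). Interval queries go through a per-chromosome
interval tree and are tested against a linear scan.

## Class codes

Each assembled transcript gets exactly one code relative to the
reference, the most specific of `=` (identical ordered intron chain,
same strand), `c` (exon chain contained in a reference transcript with
the query's introns forming a contiguous run of the reference chain),
`j` (shares at least one exact intron), `e`/`o` (same-strand exonic
overlap without a shared junction; single- vs multi-exon), `i` (span
entirely inside one reference intron), `x` (exonic overlap on the
opposite strand only), `u` (no span intersection). Conventions worth
stating explicitly:

- Two single-exon transcripts that overlap on the same strand compare
  as `=` (both intron chains are empty); a single-exon query inside a
  multi-exon reference exon is `c`.
- `c` is read at exon resolution, not span resolution: every query
  exon must lie inside a reference exon *and* the intron chains must
  be compatible.
- Intronic placements are called `i` on **either** strand; the strand
  relation (same/opposite/unknown) is recorded alongside, so the
  retention step keeps antisense-intronic transcripts while preserving
  the information. This is a deliberate convention; the alternative
  (a separate opposite-strand intronic code) changes nothing else.
- Ties across reference transcripts are broken by code precedence,
  then lexicographically by reference transcript id, making assignment
  deterministic and independent of reference ordering.

## Coding potential

The built-in scorer is an alignment-free logistic combiner over four
features: longest-ORF peptide length, ORF coverage (3·peptide/len),
the Fickett TESTCODE statistic from the published position/composition
lookup tables, and a hexamer log-likelihood ratio (mean over 6-mers of
log p_coding/p_noncoding, pseudocount 1e-9, step 1). ORFs are
ATG-initiated; ORFs without an in-frame stop are counted open-ended to
the sequence end — the permissive reading, so a transcript truncated
mid-ORF still counts as coding evidence. ORF scanning is sense-strand
for stranded transcripts, both strands (max) for unstranded ones.

The combiner is fit by maximum likelihood (IRLS, ≤100 iterations,
tolerance 1e-8). Under (near-)perfect separation the unpenalized MLE
does not exist; the fit then falls back to a light L2 penalty (C = 1)
and coefficients are capped at ±30, with a warning. When external
CNCI/CPAT score tables are supplied they govern the gate and the
combiner is bypassed.

The gate is a conjunction: retain only if CNCI < 0 (when present),
CPAT or combined probability < 0.5, no homology hit with
e-value < 1e-5, and peptide < 100 aa. It is monotone: strengthening
any piece of coding evidence can only move a transcript toward
discard.

## Positional classes

Eleven mutually exclusive genomic-location classes with stated
precedence: `containing_gene` (a coding gene wholly inside the
lncRNA), `sense_exonic`, `antisense_exonic`, `sense_intronic`,
`antisense_intronic`, then for disjoint placements split at a 1 kb
span-to-span gap: `bidirectional_promoter` (divergent head-to-head
under 1 kb), `intergenic_upstream_1kb` / `intergenic_downstream_1kb`
(side judged by the lncRNA's own strand), and beyond 1 kb
`intergenic_same` / `intergenic_divergent` / `intergenic_convergent`
by orientation relative to the nearest coding gene. Distances are
span-to-span on either strand (no TSS convention is assumed); a
chromosome with no coding gene defaults to `intergenic_same`. The rule
set is an explicit, reproducible interpretation — positional
taxonomies differ between studies and no single standard exists.

## Normalization, expression filter, differential expression

Size factors are median-of-ratios: s_j = median over features with a
positive geometric mean of k_ij / (∏_j k_ij)^{1/n}. Note the
estimator is invariant to scaling *all* counts and equivariant only in
the ratios between samples. Features with a zero in any sample drop
out of the reference set; if none remain the function refuses rather
than silently switching to a pseudo-reference.

A feature is *expressed* when its normalized count exceeds 5 in at
least ⌈0.10·n⌉ libraries, applied per tissue (tissues are analyzed
separately throughout).

The DE test, per feature: method-of-moments dispersion
α = max(0, (v − m)/m²) with v the within-group pooled variance and m
the grand mean of normalized counts; group means with pseudocount 0.5
when a group mean is zero; Wald statistic log2FC/SE with
SE² = ((1/m₁ + α)/n₁ + (1/m₂ + α)/n₂)/ln²2 from the NB variance
function. The two-sided p-value uses a **Student-t reference on
n₁+n₂−2 degrees of freedom** rather than a normal: with a
moment-estimated dispersion at n = 16 + 16 the normal reference is
measurably anti-conservative (null rejection ≈ 0.063 at the 0.05
level in simulation), while the t reference holds the level
(≈ 0.050–0.053). This is the package's deliberate finite-sample
choice. There is no dispersion shrinkage, no independent filtering and
no outlier handling — declared simplifications relative to full
DESeq2-style machinery; calibration is established by simulation, not
by replicating any particular study's gene lists.

BH adjustment is the standard step-up (delegated to statsmodels,
cross-checked against the definitional computation in tests). Signed
fold change is sign(log2FC)·2^|log2FC|, so down-regulation prints as a
negative fold change.

## Cis-target inference

Candidate pairs: coding-gene span intersects the lncRNA gene span
± 50 kb (boundary inclusive, either strand, same chromosome); the
distance recorded is the span gap (0 on overlap). The window anchors
on the gene span, not the TSS. Correlation uses Pearson r on
log2(normalized count + 1) across all samples of the tissue — pooling
both timepoints deliberately, since the timepoint contrast is itself a
source of shared variance that cis regulation would produce — with a
two-sided t test on n−2 df. The `raw` scale is available via
`--expr-scale`. BH is applied across all tested pairs of a tissue (one
family per tissue), and p.BH < 0.05 calls a target. Degree summaries
conserve edges by construction.

## Enrichment, qPCR

Over-representation uses the exact hypergeometric upper tail
P[X ≥ k]. The universe defaults to the tissue's expressed genes —
an explicit background, since database-internal backgrounds are not
reproducible. Two regimes: BH-corrected across sets, or raw p-values.

qPCR: ΔCt = Ct_target − Ct_housekeeper per sample, ΔΔCt centered on
the reference condition's mean ΔCt, RQ = 2^−ΔΔCt; the condition fold
change is the mean RQ of the test condition, and groups are compared
with a pooled-variance two-sample t-test. The housekeeper is a user
input (stability selection is out of scope).

## Synthetic data

The generator emulates the shape of a two-tissue weaning study:
group sizes 16/16 (rumen) and 8/8 (ileum); NB counts with dispersion
0.1 around log-normal means (log2 mean 7, sd 1.5); library-size
multipliers log-normal (sd 0.15); 10% of features DE with |log2FC| = 1
planted half up, half down — balanced so the planted shift is not
absorbed into the size factors; planted cis pairs share a latent
Gaussian factor on the log2-mean scale with signal sd 3 around a base
log2 mean of 8, scaled so the two log-mean profiles correlate at
ρ = 0.8 (the realized log-count correlation is mildly attenuated by
counting noise, ≈ 0.77–0.78 at these settings).

Annotation geometry places one construction per 40 kb slot, each slot
satisfying one class-code definition exactly, so intergenic
placements sit > 1 kb from, but within the 50 kb window of,
neighboring slots' genes (supplying null cis pairs). Noncoding
sequences are random-composition DNA post-processed to contain no ORF
over 60 aa (start-codon knockout with redraw on the rare
non-convergence); coding contaminants embed a GC-biased codon ORF of
≥ 100 aa. The combiner's training corpus overlaps the two classes in
ORF length (coding ORFs from 50 aa, noncoding up to 80 aa) so the fit
is exercised away from trivial separability.

What the generator does **not** emulate: positional biases of real
lncRNAs, shared exon structure between tissues, mean–dispersion trends
(dispersion is constant), batch effects, and GC/mappability biases.
Passing tests therefore demonstrate correctness of the algorithms at
the stated operating points, not performance on real libraries.

Problem sizes in the test and acceptance runs (10,000 null features,
20,000 features for effect recovery, 2,200 candidate pairs, ~50
planted transcripts) are the package's chosen benchmark sizes; all
randomness flows through seeded `numpy` generators and the full
pipeline is byte-reproducible under a fixed seed.

## Known limitations

- The class-code vocabulary covers the codes the cascade needs plus
  the generic overlap codes; assembler-specific codes (polymerase
  run-on, repeats) are out of scope.
- The DE model is two-group only; no covariates, no likelihood-ratio
  tests, no shrinkage. Features with moment dispersion truncated at 0
  get slightly optimistic standard errors; the t reference compensates
  on average.
- Cis-target calling is correlational; no causal claim is made, and
  trans-regulation is out of scope.
- The qPCR module assumes one housekeeper and equal amplification
  efficiencies.
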