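# Methods

## Scope and model

`circkit` implements the quantitative core of a circRNA profiling
workflow on synthetic data.  The object of study is the backsplice
junction (BSJ): the non-colinear exon–exon junction unique to a
circRNA.  Read pairs spanning the BSJ proxy circular abundance; the two
adjacent forward splice junctions (FSJs) proxy linear host-transcript
abundance.  Everything downstream — the circular-to-linear ratio,
cumulative circularization, differential expression, classification —
is built on those two fragment counts.

## Synthetic data

**Genome.** Chromosomes are i.i.d. uniform ACGT (GC ≈ 0.5) carrying
non-overlapping multi-exon genes laid left to right.  Defaults: 4–9
exons of 160–400 nt, introns 200–1200 nt, intergenic gaps 300–1500 nt
(the benchmark genome stretches introns to 500–3000 nt and gaps to
2000–8000 nt to reach ~2 Mb at 100 genes).  Canonical splice signals
are written into the genome at every exon flank (AG before each exon
start, GT after each exon end, complemented on minus-strand genes) so a
GT..AG-aware detector behaves as on real introns.  The 160 nt exon
floor keeps a 150 nt mate inside the two boundary exons of a junction,
which is what makes exact (non-split) placement a usable alignment
model at desk scale.

**Planted circRNAs.** Circles are contiguous runs of 1–3 *internal*
exons (never the first or last exon), so both adjacent FSJs exist and
both junction flanks are intronic.  The genomic span is constrained to
[50 nt, 100 kb].  Each circle carries a planted circular-to-linear
ratio drawn lognormally with median 2⁻³ (log2 sd 1): circRNAs are
typically a small fraction of their host's output, and this default
keeps circular fragments at a few percent of an untreated library,
which is what rRNA-depleted total-RNA libraries look like.  A per-state
copy-number map and a global `circ_scale` multiplier let experiments
impose stage-specific circularization programmes.

**Libraries.** Fragments (Normal length, mean 300 nt, sd 40, floored at
the 150 nt read length) are drawn multinomially over a pool of spliced
linear transcripts and circular sequences, with weights molar abundance
× length.  Gene abundances are lognormal and drawn from their own seed
so replicates and states share one expression programme.  Circular
fragments start uniformly around the circle and wrap across the BSJ; a
fragment longer than the circle is read from a tandem concatenation of
the circular sequence (documented behaviour, not an error).  Mates are
150 nt from either fragment end; the library is unstranded, which for
paired ends reduces to swapping the mates with probability ½.  Errors
are i.i.d. substitutions.  Untreated libraries contain exactly the
requested depth; RNase R treatment then thins linear fragments
binomially (survival 0.02) and leaves circles intact, so treated totals
are smaller by construction.  Read names carry the origin transcript
and whether the fragment wraps the BSJ, so recall and precision can be
scored without alignment.

**Depth compensation.** When a state multiplies circular output, the
pipeline scales that state's depth by the ratio of total pool weights,
holding absolute linear output constant.  Without this, fixed-depth
sampling is compositional: raising circular output necessarily lowers
linear output.  Residual compositional shrinkage remains in any
CPM-based between-state ratio (a planted 2.8-fold increase reads out
around 2.5–2.7 when circles are ~3–5% of the library); this is a
property of per-million normalization itself, not of the estimator.

**Cohorts.** Two-class count matrices are negative binomial
(`Var = μ + αμ²`) with log-uniform base means (~32–512 counts),
dispersion 0.1 by default, and a planted log2 fold change on a recorded
subset of features; effects may be scalar or per-feature (mixed signs).

## Discovery

Both detectors share one alignment primitive: a sorted-array index of
all 2-bit-encoded k-mers (k = anchor length, default 20) supporting
exact lookup on both strands, plus full-length mismatch verification
against the reference.

**Anchor detector.** For each mate (both orientations tried): place the
leading 20-mer; if the whole mate fits colinearly with ≤2 mismatches it
is not a backsplice.  Otherwise place the terminal 20-mer; a candidate
requires both anchors unique, on the same chromosome, with the terminal
anchor upstream — the backsplice signature.  Prefix and suffix
mismatch profiles give the total mismatch count for every breakpoint
position in O(read length); the minimal-mismatch breakpoint is chosen,
ties broken by annotated boundaries (when an annotation is supplied),
then GT..AG splice signal in either transcription orientation, then the
leftmost position, with residual ambiguity tallied in diagnostics.
Candidates without a GT..AG signal are rejected (configurable).  The
candidate's strand is the splice-signal orientation.

**Annotation-guided detector.** The same machinery, but final
breakpoints are snapped to the nearest annotated exon start/end within
±2 nt and unsnappable candidates are dropped; snapping replaces the
splice-signal requirement.

Support is counted per fragment (a pair supports a junction once).
The shared filter keeps candidates whose breakpoints lie inside exactly
one gene's span, whose genomic distance is within [50 nt, 100 kb], and
whose support is ≥2 fragments; entries take the host gene's strand.
Catalogs merge by set union on (chrom, strand, start, end), summing
support per detector — the union-of-callers strategy; the operation is
N-ary so further detectors can be added.

## Quantification

For each catalogued circle a junction contig concatenates the last
100 nt and first 100 nt of the circle's genomic interval (halves
truncated to ⌊span/2⌋ for circles under 200 nt, so no base is
duplicated).  For each FSJ adjacent to a catalogued circle an analogous
spliced contig joins the flanking exon sequences.  Mates are placed on
genome + contigs by seed-and-verify with three non-overlapping seeds
per orientation — which provably finds every ≤2-mismatch placement of a
150 nt mate — and all placements are kept (multimapped fragments count
toward every contig they hit).  A fragment is counted for a junction
when either mate covers ≥8 nt of the 10 nt window centred on the
junction (5 nt each side), once per junction.  The per-sample library
size is the number of fragments with at least one placement anywhere
(configurable at the call site by passing other sizes to
`compute_cpm`).

Full-length placement against a 200 nt contig means only mates whose
junction lies ~50–100 nt from the mate start fit; this loses a
constant fraction of junction-spanning mates uniformly across circles,
so ratios (CLR, between-state fold changes) are unaffected while
absolute counts are conservative.

`CLR = #BSJ / (mean(#FSJ) + 1)`, the mean over the FSJs that exist; a
terminal-exon circle's missing junction is excluded from the mean
rather than counted as zero, which would bias CLR upward.  Per
replicate, cumulative circularization is the sum of CPM-normalized BSJ
counts, diversity the number of species with raw count ≥1 (the
threshold is a parameter), and normalized load their ratio; stages are
summarized by replicate means.  The robust-expression filter keeps
features with ≥2 reads in ≥3 replicates of ≥1 time point.  Coherence
quadrants classify paired circular/linear log2 changes into
concordant/opposing quadrants, excluding pairs with a zero or undefined
member.

## Differential expression

Size factors are DESeq2-style median-of-ratios over features positive
in every sample (falling back to total-count ratios with a warning).
Dispersion is per-feature method of moments on normalized counts,
`α = max((Var − μ)/μ², 10⁻⁸)`, with the variance pooled within groups
when a group vector is available so planted effects do not masquerade
as overdispersion.  There is deliberately no dispersion shrinkage and
no independent filtering: the reproducible content here is the testing
logic and thresholds, not DESeq2's empirical-Bayes machinery.

The two-group Wald statistic is the log2 ratio of size-factor-corrected
group means (pseudocount 0.5 only when a group mean is exactly zero)
over its delta-method standard error from `Var(K) = μ + αμ²`.  Because
α is a per-feature plugin estimate, the statistic has Student-like
rather than normal tails at small n; p-values therefore use a t
reference with n₁+n₂−2 df, which restores nominal type-I control
(~0.05 at 5v5, where a normal reference gives ~0.085) at negligible
power cost.  Benjamini–Hochberg step-up adjustment is applied across
features, NAs excluded from m.

Differential CLR has no credible parametric model (a ratio of small
counts), so it is tested by label permutation on `log2(CLR + 0.01)`
group-mean differences: exact enumeration when the arrangement count is
≤10⁴, otherwise ≥1000 sampled permutations with the identity
permutation included; fewer than 20 arrangements yields NA.  The
observed statistic doubles as the reported log2 fold change.  Default
significance cuts: |log2FC| > 1 and adjusted P < 0.05 for abundance;
|log2FC| > 0.1 and adjusted P < 0.2 for CLR.

## Classification

Candidate features pass the DE cuts, then are ranked twice: by the best
single-threshold information gain (exhaustive over value midpoints —
deterministic, unlike MDL discretization) and by mean-decrease-in-
impurity importance from a seeded random forest (bootstrap, √p feature
subsampling).  The combined rank is the rank of the rank sum, ties
broken by information-gain rank then feature id — the simplest
deterministic combiner.  The SVM is grid-tuned over cost
{0.1, 1, 10, 100}, gamma {0.001, 0.01, 0.1, 1}, kernels
{linear, rbf, poly}, degree {2, 3} by inner-CV AUC, on z-scored
features with the scaler inside the pipeline; probabilities come from
sigmoid (Platt) calibration on inner-CV decision values.  AUC is
computed as pairwise concordance (ties ½), identical to the
Mann–Whitney statistic.  Cross-validation is stratified with a fixed
seed; out-of-fold probabilities are pooled into one ROC.  The learner
interface refits feature selection and scaling inside every training
fold, and a dedicated test shows that pooled (leaky) selection on null
data inflates CV AUC while the fold-internal path stays at chance.

## Pipeline

One YAML config drives simulate → discover → quantify → de → classify.
Stage sub-seeds are derived by hashing the stage name with the global
seed, so stage results are independent of execution order; a manifest
records outputs, hashes and seeds, and a stage reruns only when its
outputs are missing or an upstream stage was recomputed.  All
thresholds (50 nt/100 kb, 8-of-10, ≥2 reads/≥3 replicates, the DE and
CLR cuts) live in the config with the defaults above.  Internal
coordinates are 0-based half-open; all reports are 1-based inclusive
`chrN:start-end`, with a lossless converter in `circkit.coords`.

## What the simulations do and do not show

The simulator reproduces the statistical structure the methods assume —
junction-wrapping fragments, RNase R enrichment, NB counts, planted
effects — but not empirical error profiles, PCR duplicates, GC bias,
indels, repeat-induced multimapping beyond shared contig flanks, or
intronic/intergenic circles.  Passing benchmarks therefore validate the
logic and calibration of the implementation, not performance on real
sequencing data.  Benchmark problem sizes (a ~2 Mb genome with 100
genes and 60 circles at ~400k fragments for discovery; 6 samples at
~30k fragments for the global-increase experiment; cohorts of 40–100
samples) were chosen as the smallest at which the planted signals are
comfortably estimable on a single CPU.

## Known limitations

* The anchor detector requires unique anchors and ≥20 nt of clean
  sequence on both sides of the breakpoint; junctions near long repeats
  or read ends are invisible to it.
* Exact full-length placement undercounts junction mates relative to a
  split aligner; absolute BSJ counts are conservative (ratios are not).
* The NB test supports two-group contrasts only; no GLM designs.
* Permutation CLR p-values are resolution-limited by the arrangement
  count at small n.
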