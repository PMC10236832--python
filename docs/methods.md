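# Methods

`mavekit` processes multiplexed assay of variant effect (MAVE) sequencing
data from raw FASTQ files to per-variant statistical results.  This note
describes the models and procedures it implements, the parameters that
matter, the numerical choices behind them, and what the bundled synthetic
data can and cannot establish.

## Read model and digestion cascade

A read is modeled as a concatenation of five segment types — variable (V),
constant (C), skipped (S), primer (P) and UMI (U) — specified by an element
string and a parallel length vector; one length of −1 per read part marks a
"remainder" segment whose length is inferred.  A primer acts as an anchor:
it is located by exact string search rather than a fixed offset, so layouts
with a variable-length unknown prefix remain parseable.  Where the primer
occurs more than once, the leftmost occurrence compatible with the fixed
pre-primer segment lengths is used; this tie-break is a package decision
(deterministic, and consistent with a left-to-right search) rather than a
community convention.  Multiple regions of one segment type are
concatenated in read order, so downstream steps always see one variable,
one constant and one UMI string per read.  Qualities are Phred+33
throughout.

Each read (pair) passes through a fixed cascade, and the first failing step
claims it in the filter tally, so the tally always partitions the input
exactly (`nTotal == nRetained + Σ filters`):

1. **Adapter detection** — exact substring containment of the configured
   adapter in either mate; no mismatch model (partial terminal overlaps are
   not detections).
2. **Segmentation** — index arithmetic under the layout; incompatible read
   lengths and missing primers are filtered here.
3. **Reverse-complementing** of extracted variable/constant components when
   requested.
4. **Pair merging** (optional) — the reverse variable region is
   reverse-complemented once and overlaps are scanned from the longest
   allowed width down to the shortest; the first overlap whose mismatch
   fraction and merged length satisfy the configured bounds wins.  In the
   overlap, the higher-quality base wins discordant positions (tie: forward
   base) and concordant positions keep the maximum quality.  Longest-first
   scanning maximizes the use of sequence evidence and makes the procedure
   deterministic.
5. **Quality filters** — arithmetic mean of the variable-region Phred
   scores against `avg_qual_min` (the simplest reading of "average base
   quality"; not an error-probability average), then N-content limits for
   the variable region and UMI.  When merging is enabled these filters see
   the merged sequence; in paired non-merged mode, the concatenation of
   both variable regions.
6. **Wild-type matching** — Hamming distance to every same-length wild-type
   (unequal lengths are non-candidates; amplicons here are fixed-length, so
   no gapped or edit-distance mode is provided).  The unique nearest
   wild-type within the search budget wins; a tie between wild-types
   filters the read.  In base units the budget is `max_mutations` mutated
   bases; in codon units the base-space search budget is `3·max_mutations`
   and the mutated-codon count is checked separately.  Mutated bases below
   `min_mutation_quality` and observed mutated codons matching the
   forbidden IUPAC pattern (e.g. `NNW` = any codon ending in A/T) filter
   the read.  The forbidden test deliberately applies to the *observed*
   codon, not the position's design alphabet.
7. **Constant-region check** — nearest constant reference by Hamming
   distance; failure on distance above `max_constant_mismatch` or a
   reference tie.  Per-base-quality match/mismatch counts against the
   nearest reference accumulate into the error tally for every read that
   reaches this step, giving the stratified sequencing-error estimate
   `rate(q) = nMismatch(q) / (nMatch(q) + nMismatch(q))`.
8. **Accumulation** — the variant name and UMI are recorded.  Names are
   `WT.pos.ALT` terms (1-based positions; base or codon units) joined by
   `_`, with the bare wild-type name for exact matches; in paired
   non-merged designs the two sides' names are joined by `_`.  In paired
   non-merged mode the sub-checks of step 6 run in reason order across both
   sides so that first-failure accounting is by cascade stage, not read
   side.

Without wild-type sequences the package runs in sequence (barcode) mode:
variants are named by their observed sequence, and similar sequences can be
collapsed greedily — visiting sequences in decreasing count order (ties
lexicographic), each later sequence is absorbed by the first seed within
`max_distance` whose (original, pre-absorption) count passes the
`min_abundance` and `min_ratio` thresholds.  Absorption is single-pass and
non-transitive.  UMI deduplication inside one variant uses the same sweep
without the abundance thresholds.  Testing ratios against original counts
is a deliberate choice; updated-count semantics would make results depend
on absorption order in a less predictable way.

## Experiment container

Per-sample results merge into a variants × samples count matrix (reads
and, when present, UMIs as separate matrices) with the union-with-zeros
convention.  Row annotation records the closest wild-type, the canonical
variant and wild-type nucleotide sequences, mutated base/codon/amino-acid
counts and mutation types (silent / nonsynonymous / stop, standard genetic
code only).  Amino-acid collapsing groups rows by (wild-type, translated
sequence) and sums counts, conserving every column sum.  The container
serializes as a directory of TSV/JSON files and restores losslessly.

For paired two-locus designs the canonical sequence is the concatenation
of the two sides; amino-acid collapsing of such experiments assumes each
side's length is a multiple of 3 (true for codon-designed libraries).

## Statistical model

Counts for variant *g* in sample *s* are modeled as negative binomial with
mean `μ_gs = exp(x_sᵀ β_g + o_s)` and dispersion `φ_g`.  The offset `o_s`
carries the normalization:

* **TMM** ("absolute" scores): trimmed mean of M-values against a reference
  sample — log-ratio trim 0.30, abundance trim 0.05, precision weights from
  the delta method, zero counts excluded pairwise, factors rescaled to
  geometric mean 1; `o_s = log(lib_s · factor_s)`.
* **Wild-type offsets** ("relative" scores): `o_s = log` of the sum or
  geometric mean of the wild-type rows' counts in sample *s*.  With a
  single wild-type row and sum offsets the wild-type's own fit is exact and
  its log-fold change identically zero, which anchors the enrichment scale.

Two inference paths are provided, both testing a single contrast `cᵀβ = 0`
against the reduced model spanned by the null space of `c`:

**NB quasi-likelihood GLM.**  Dispersions are estimated by Cox–Reid
adjusted profile likelihood evaluated on a log-spaced grid
(18 points, 10⁻⁴…10) with the means refitted at every grid value;
the per-gene profiles are pooled within ~10 abundance bins and the binned
maxima (quadratically interpolated in log φ) are linearly interpolated into
an abundance trend (the pooled maximum serves as a common value for small
problems).  GLMs are fitted by IRLS vectorized across variants (shared
design matrix; linear predictor clipped to ±60 for overflow safety; a
1e-10 ridge on the normal equations guards degenerate weights).  The
quasi-dispersion `s²_g = deviance_g / df_res` is shrunk toward its lowess
abundance trend with a fixed prior of 10 df, and the contrast is tested
with `F = (dev_reduced − dev_full) / s²_post` on (1, 10 + df_res) df.  The
fixed prior df is a frozen, documented configuration: with the handful of
replicates typical of MAVE designs, per-variant quasi-dispersions are too
noisy to estimate a prior df stably, and 10 df gives moderate, symmetric
shrinkage.

**Precision weights + moderated t.**  Counts transform to
log2 CPM with a 0.5 pseudocount over effective library sizes (TMM-scaled,
or the wild-type aggregate).  The mean–variance trend — sqrt residual sd
against mean log2 count from an unweighted fit — is estimated by lowess
(span 0.5) and inverted into per-observation weights `1/trend⁴` evaluated
at fitted log-counts (constant extrapolation outside the fitted range;
trend floored at 10⁻⁴).  Weighted least squares per variant is followed by
empirical-Bayes variance moderation: the prior df and prior variance come
from a moment fit of a scaled F distribution to the residual variances
(log-variance mean/variance matched via digamma/trigamma, trigamma inverted
by Newton iteration), and the moderated t has `d0 + df_res` df.

Multiple testing uses Benjamini–Hochberg throughout.  Variants can be
pre-filtered to those with at least a minimum count (default 50) in every
designated input sample; low-count variants otherwise dominate the tails
without carrying information.

Per-replicate **PPI-style scores** are
`log2((out_v + p)/(in_v + p)) − log2((out_wt + p)/(in_wt + p))` with an
optional pseudocount `p` and an optional multiplicative constant for
growth-rate scaling; the wild-type scores exactly 0.  This simple
wild-type-normalized ratio is the package's frozen formula; assay-specific
rescalings (e.g. by generations of growth) enter only through the constant.

## Synthetic data

The generator assembles reads under the same layout grammar (random skip
bases and UMIs, configured constant and primer sequences, variant variable
regions drawn by frequency) and writes FASTQ plus the exact count table
expected from error-free digestion — the master round-trip oracle.
Contamination modes: per-quality substitution errors, uncalled-base (N)
conversion, and adapter replacement of a read prefix.  Quality strings are
constant per segment tier (e.g. all Q30) so that injected error rates are
analytically checkable against the stratified estimate.  All randomness
flows from one integer seed through integer-based draws, making output
byte-reproducible.

The count simulator draws NB counts with log-normal baseline abundances
(log2 sd 1 by default — a realistic abundance spread for variant
libraries) around a target depth, with per-variant group log2 fold changes;
dispersion 0 degenerates to Poisson, and an all-zero effect vector gives
the null design used for calibration checks.

What the synthetic data does *not* emulate: position- and cycle-dependent
error profiles, homopolymer artifacts, indels (reads are substitution-only,
matching the Hamming design), PCR amplification bias beyond duplicate UMIs,
and between-replicate technical variation beyond NB dispersion.  Passing
tests therefore establish the correctness of the bookkeeping, matching,
normalization and inference machinery under the stated model — not
robustness to instrument artifacts outside it.

## Validation problem sizes

The test-suite and reproduction script run at desk scale by design: 50,000
read pairs for the exact end-to-end round trip; 20 contaminated 500-read
libraries for filter accounting; 1,000 random instances for the matching
oracle and 200 tables for the collapsing oracle; 1,000 variants in a
3 vs 3 design (NB dispersion 0.1, median depth 300) for null calibration
of both inference paths; 100 spiked variants at depth 1,000 for effect
recovery; and 200,000 constant-region bases for error-rate estimation.

## Known limitations

* Hamming matching only; substitution-designed amplicon libraries are the
  target, and reads with indels fall into `fNoValidWildtype`.
* Exact-match adapters and primers (no mismatch tolerance).
* Fixed-effect designs only; no mixed models, and no feature-specific
  normalization beyond wild-type offsets.
* Single-threaded; the vectorized statistics are fast, and digestion
  throughput (~5k read pairs/s) is adequate for library-scale work but not
  for billion-read experiments.
* The standard genetic code only (translation table 1).
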