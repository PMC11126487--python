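# Methods

This note documents the models, conventions and design decisions behind
`btnmeth`, in the order data flows through the pipeline.

## Coordinates, formats and call semantics

All internal coordinates are 0-based half-open; VCF positions are shifted
on load, BED is taken as-is.  Per-CpG calls use a bedMethyl-style TSV with
one row per site per modification code (`m`/`h`) and a fraction column in
[0, 1]; both strands' evidence is assumed collapsed onto the plus-strand C
before the table is written (the calling tools can emit either convention;
one had to be fixed, and the simulator uses the same one).  A site's 5mC
and 5hmC fractions come from the same reads, so `mc + hmc <= 1` is
enforced.  Depth-0 sites have undefined fractions and are dropped on load
rather than imputed.  Fractions are serialised with `repr` so read/write
round trips are exact.

## Window profiling

Windows are 100-kb, non-overlapping, terminal windows truncated.  The
window mean is the *unweighted* mean of site fractions — sites are not
depth-weighted, because depth reflects sequencing chemistry, not biology;
windows without called CpGs stay undefined rather than being filled.  The
genome-level headline figure is the mean/sample-SD **over defined window
means** (this matches how karyogram-style window tracks are annotated);
site-level summaries are also exposed since the two differ when CpG
density varies.  GC content is computed over non-N bases; an all-N window
has undefined GC.

Feature-level distributions take one mean per interval with at least
`min_cpg = 3` called sites — one- and two-site intervals otherwise inject
0/1 spikes into the boxplot distributions.

Mann–Whitney comparisons are two-sided; exact enumeration is used when
`n_a * n_b <= 400` and the pooled sample is tie-free, otherwise the
tie-corrected normal approximation with continuity correction.  Stars
follow the conventional legend (`*` for 0.01 < p ≤ 0.05 down to `****`
for p ≤ 1e-4).

## CpG islands

Islands use the classical length / GC / observed-expected criterion: a
200-bp window qualifies when GC ≥ 0.5 and observed/expected CpG ≥ 0.6 with
expected = #C·#G/len; qualifying windows are unioned into maximal runs.
The thresholds are arguments, not constants, because island callers differ
and no exact equivalence with any specific tool is claimed.

## Stepwise AIC models

OLS with `AIC = n·ln(RSS/n) + 2(k+1)` (Gaussian likelihood with the error
variance profiled out; the additive constant is dropped since only
differences matter).  Search is greedy in both directions from the
intercept-only model: at each step the single add/drop move with the
lowest AIC is accepted while it strictly improves, ties broken by
candidate name order, so runs are deterministic.  Windows with undefined
means are excluded listwise.  Predictors are standardized internally for
the "strongest predictor" report; raw-scale coefficients are returned too.
Rank-deficient designs error out naming the collinear columns.

Note on null behaviour: with an AIC penalty of 2, a pure-noise candidate
enters whenever its chi-square(1) likelihood-ratio gain exceeds 2, which
happens for ~16% of independent noise predictors — an intended property
of AIC, not a defect; tests assert this calibrated rate.

## Differential methylation

Gene-level methylation is the unweighted site mean within the gene body;
genes with fewer than 3 called sites in a sample are missing for that
sample.  Group comparison uses Welch's unequal-variance t test (sample
sizes and variances differ strongly between 3 healthy tissues and 5
tumour samples of mixed purity).  Fold changes are
`log2((mean_t + ε)/(mean_h + ε))` with ε = 10⁻³, which keeps silent genes
(≈2.5% methylation) finite without drowning real effects.  A gene is
called differential when `p ≤ 0.05` **and** `|log2fc| ≥ 1`; the
fold-change gate is needed because purity dilution makes almost every
gene's mean shift slightly and nominally significant.  No multiple-testing
correction is applied by default (the volcano presentation uses a raw
p-value bar); Benjamini–Hochberg is available behind a flag.

Clustering is average-linkage (UPGMA) on Euclidean distances over genes
with complete values, samples and genes clustered separately, flat labels
cut at k = 3; SciPy's deterministic merge order is relied on.

### Dip test

Hartigan & Hartigan's dip — the sup-norm distance from the ECDF to the
nearest unimodal CDF — is computed with the iterative greatest-convex-
minorant / least-concave-majorant scan over a shrinking modal interval.
The statistic is floored at 1/(2n) (the value for a point mass).  The
implementation is verified exactly, over hundreds of random samples up to
n = 40, against a linear-programming oracle that minimises the band
half-width subject to convex-then-concave shape constraints with the mode
at a data point.  Ties at the optimal mode position can make the scan very
slightly conservative (it enforces continuity within each shape segment);
gene-level methylation means are effectively tie-free.  The p-value is
Monte-Carlo against uniform samples of the same size (the least
favourable unimodal null); a precomputed null table can be shared across
tests of equal n.

### Bimodal split

A two-component Gaussian mixture is fitted by EM on logit-transformed
fractions (10 seeded restarts, best likelihood kept).  Component means and
SDs are reported on the fraction scale as the empirical mean/SD of the
genes assigned to each component — this avoids the bias of inverting the
logit at the component mean, and makes the report independent of the exact
mixture parametrisation.  The split is flagged non-bimodal when the fitted
mixture density has no genuine valley between the component means (< 10%
dip below the lower peak), which correctly rejects splits of unimodal
samples.

## Expression coupling

Counts are TPM-normalised (`rate = count/length`, scaled to 10⁶).
"Transcription level" is log₁₀(TPM+1) — raw TPM spans four decades and
would let a handful of highly expressed genes dominate the correlation; a
raw-TPM mode exists behind a flag.  "Intragenic methylated-CpG proportion"
is the fraction of gene-body sites with 5mC ≥ 0.5; the threshold is an
argument, and a mean-methylation mode is available (the two agree on the
bimodal synthetic presets by construction).  Pearson's r with the
t-distribution p-value.

## Retroelement workflow

*Scanning.*  Exact 12-mers shared between consensus and genome are chained
by diagonal (≥3 seeds, ≥100-bp span, ≤500-bp gaps) and each candidate is
polished with an infix (edlib) alignment of the chained consensus span
plus a 25-bp flank; identity = 1 − edit distance / query length.  Copies
on either strand are reported; overlapping same-strand hits are merged.
Full-length means consensus coverage ≥ 0.90 at identity ≥ 0.80 — the
criteria are arguments with these defaults, chosen so fragments at half
coverage and decoys below 80% identity are excluded while copies up to
~10% divergence are always recovered (tested: recall 1.0 on planted
copies, zero hits on shuffled genomes).

*Divergence.*  Kimura two-parameter distance
`d = -½·ln((1-2P-Q)·sqrt(1-2Q))` over ungapped, unambiguous columns; plain
K2P without CpG adjustment.  Saturated pairs return infinity and land in
the last landscape bin.  Landscapes bin each copy's genomic footprint by
its distance to the consensus (1% bins, 0–50%), coverage as percent of
genome size.  Pairwise alignment (edlib, Needleman–Wunsch) replaces
multiple alignment for distance matrices; with the simulator's indel-free
copies the alignments are trivial and the downstream contract identical.

*Phylogeny.*  Saitou–Nei neighbour joining with the Studier–Keppler Q
criterion, lowest-index tie-break, negative branch lengths clamped to zero
with a warning.  Exact reconstruction of additive matrices is tested, and
topologies are cross-checked against scikit-bio's independent NJ.

*Insertions.*  The filter chain keeps INS records with support ≥ 4 reads
("more than 3"), PASS filter, PRECISE breakpoints, and a ≥200-bp consensus
match at ≥80% identity, in that documented precedence (non-INS records are
rejected first as `svtype`); every record is kept or carries exactly its
first failing reason.  `tandem_count` counts non-overlapping
same-orientation consensus matches inside the inserted sequence
(head-to-tail arrays); records over 5 kb are flagged for validation.

*Element methylation.*  Sites inside copy loci are pooled; positions
project to consensus coordinates by strand-aware offset within the matched
span (exact for indel-free copies, approximate otherwise).  Rolling
profiles use centred 20-bp windows, truncated at the edges, with 95%
confidence bands across copies (t-interval below 30 copies).  Per-read
matrices score a locus by the fraction of sites where ≥80% of observing
reads agree.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale (2 contigs × 2.5 Mb, 50 windows), with full determinism: the
same (preset, seed) gives byte-identical outputs.

**Layout.**  Per-window covariate patterns — GC (0.34–0.48), gene fraction
(0.10–0.45), CpG-island count (0–6), tandem fraction (0–0.08), N-block
count (0–5, 500-bp blocks), and a latent factor z — are fixed constants
shared by every preset and seed, rank-mapped onto QR-orthogonalised
scores so the covariates are mutually near-orthogonal and each regression
effect is attributable to its own covariate.  One 40-kb satellite array
sits in the least gene-dense window.  The user seed controls sequence
content, placements within windows, gene structure and all noise.

**Methylation model.**  Each CpG's regional mean comes from its feature:
satellite ≈ 0.4% (the modification desert), tandem repeats 4%, CpG islands
elevated, retroelement families at their lineage-specific levels, gene
bodies at their gene's mode value, and intergenic background at a
calibrated baseline modulated by the window's GC (−), N-block fraction
(−) and the latent factor (+, shared with 5hmC — this is what lets 5hmC
enter the 5mC predictor model with a positive sign).  5hmC adds boosts on
tandem repeats and islands and a deficit on gene bodies.  True site levels
are Beta around the regional mean (concentration 12 for 5mC, 30 for 5hmC),
depth is Poisson at the lineage's mean depth (14.72 / 7.54 / 13.02), and
reported fractions are joint binomial counts over that depth, so
`mc + hmc <= 1` holds read-wise.

**Gene modes.**  Gene bodies are bimodal: a silent mode (≈2.5%, SD 0.8 pp)
and a methylated mode (≈62%, SD 22.8 pp), mixing proportion 0.45 (the
density of the two modes is not separately documented; 0.45 keeps both
modes well populated).  Mode counts are stratified per window and mode
values are drawn as jittered quantiles of the (truncated-normal) mode
distributions, dealt across windows with a low-discrepancy stride — a
variance-control choice that pins genome-level summaries near their design
values across seeds without changing the marginal distributions.  The
tumour profile scales the methylated mode by 0.60 (global
hypomethylation) and flips 94 planted "down" genes (host-methylated,
silent in tumour; hosts drawn ≥ 28% so the fold-change gate is always
cleared after purity dilution) and 20 "up" genes (host-silent, methylated
in tumour).  Mixed-purity samples interpolate host and tumour site means
by the tumour-cell fraction; the cohort is 3 pure host tissues, 3 gills at
purity 0.35/0.45/0.55 and 2 haemolymphs at 0.92/0.96.

**Expression.**  log₁₀ expression = α + β·(true methylated proportion) +
ε, with ε drawn as stratified normal quantiles orthogonalised to the
signal in-sample and rescaled — the realised correlation then concentrates
on the design value instead of wandering ±0.05 with corr(signal, noise).
Counts are Poisson around length-scaled rates (2M reads).

**Retroelements.**  Two deterministic consensus sequences (a 7.5-kb
element with four ORFs and an internal 61-bp direct repeat; a 6.2-kb
LINE-like element) are fixed by an internal seed.  Copies are planted as
point-substituted consensus spans (transition:transversion 2:1, no
indels): the healthy genome carries six full-length copies of the first
element (shared 4% ancestral + 1% private divergence) plus sub-threshold
fragments and decoys, and second-element copies totalling exactly 0.30% of
the genome.  Insertion callsets plant the lineage's true counts
(54/60 and 31/13) as fragments, full copies and head-to-tail dimers that
pass every filter, plus two decoys per rejection reason.  The standalone
copy-set simulator uses a two-epoch model (healthy copies share a
pre-split ancestor; tumour copies diverge privately), which is what makes
the healthy copies a single cluster in the NJ tree.

**Calibration.**  Four location parameters per lineage — the intergenic
5mC and 5hmC baselines, the methylated-gene-mode location, and the
expression noise SD — were fixed once with `scripts/calibrate_presets.py`,
which measures each lineage's summaries through the actual pipeline and
solves the (linear) offset updates; the outputs are frozen in
`sim/presets.py`.  Everything else is a structural constant.

**What the generator does not emulate,** and hence what passing tests do
not show about real data: real chromosome counts and karyotypes, raw
signal/basecalling error structure (call noise is idealised binomial),
indels and rearrangements within retroelement copies, strand-specific
hemimethylation, biological replicate variability beyond purity mixing,
and genome-scale compositional heterogeneity — the between-window SD here
(≈4 pp) is far below the chromosome-scale value, and the healthy genome's
first-element coverage (~1.3%) is desk-scale, not the real genome's 0.01%
(six full 7.5-kb copies cannot occupy 0.01% of 5 Mb).  Percentages and
counts used as recovery targets are scale-free.  One directional detail is
knowingly not reproduced: in the real data the tumour intergenic
compartment is *more* methylated than the healthy one; at desk scale this
cannot coexist with the global hypomethylation target and the shared gene
architecture, so the tumour baseline sits lower here.

## Numerical conventions and degenerate inputs

Identical constant samples compare as p = 1 ("ns"); the dip of a constant
sample is 1/(2n); empty windows/intervals are undefined, never zero;
zero-variance correlation inputs and all-zero count vectors raise; EM
splits that collapse to one component are returned un-split and flagged;
NJ rejects NaN matrices and clamps negative branch lengths to zero.  Seeds
are threaded explicitly through every stochastic routine via
`numpy.random.SeedSequence`; string sample-ids hash platform-stably.

## Problem sizes

The shipped presets use 5-Mb genomes (≈230k CpGs, ≈370 genes, 50 windows),
an 8-sample cohort, ~100-record insertion callsets and 22-taxon copy sets.
These sizes keep every stage deterministic-feeling (target recovery well
inside tolerance across seeds) while the full suite and the acceptance
script each run in about a minute of compute.
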