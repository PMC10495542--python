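# Methods

## Signal decomposition

The object of study is the cohort-averaged GC profile over TSS-centered
windows (positions p = −1000..+1000, sense strand, every base labelled
with exactly one of six regions).  The full signal %GC(p) is the fraction
of transcripts whose base at p is G or C.  It is decomposed additively:

* the between-region signal b(p) = Σ_r a(r)·d_r(p), where a(r) is the
  region's pooled GC fraction over the whole window and d_r(p) the
  fraction of transcripts carrying region r at p, and
* the within-region signal w(p) = %GC(p) − b(p), reported together with
  per-region constituent vectors that sum to it.

The additivity %GC = b + w and the density partition Σ_r d_r(p) = 1 are
algebraic identities of the implementation, checked to 1e−12 in tests.
Pooling for a(r) deliberately runs over the full window even though some
regions exist only downstream; the normalised within-region signal
ŵ(p,r) divides the constituent by its density and is reported as missing
(not zero) where no transcript carries the region.

**Coverage denominator.** Spliced (mRNA) windows have variable length,
so the per-position denominator is the number of records that actually
cover p rather than a fixed T; for standard full-length windows the two
are identical.  Positions covered by no record are missing (NaN).

**N bases** count in denominators and contribute 0 to GC numerators by
default; `n_policy="exclude"` removes them from both sides.

**Smoothing** (3-bp centered moving average, shrinking at the edges) is
presentation-only.  Every statistic — signal sizes, clustering features,
regression inputs — uses raw signals; a window flag exists but defaults
to raw everywhere downstream.

## CDS component split

Reading frames are reconstructed per transcript from the annotated
translation start by concatenating CDS bases in window order (a codon
may be interrupted by an intron); each base inherits its codon's amino
acid at its original, unspliced position.  The amino-acid-choice signal
c(p) replaces each coding base by the pooled average GC a′(x) of its
amino acid (pooled over downstream positions p = 0..1000 only, an
asymmetry kept as defined relative to the full-window a(r)), minus the
CDS between-term; the synonymous-codon signal s(p) is the residual.

The printed label set of 20 amino acids cannot tile all CDS bases:
stop-codon bases, bases upstream of the translation start and trailing
partial codons would break the additivity c + s = CDS-within.  The label
set is therefore completed with STOP and UNASSIGNED, each with its own
pooled average, making the identity exact at every CDS position; the
per-amino-acid table flags those two rows as auxiliary.  The genetic
code is the standard nuclear code, injectable for alternatives.

## Signal size and splicing

σ_S is the mean absolute deviation of a signal from its own mean over
the 1000 strictly-downstream positions (p = 1..1000; the TSS base is
excluded, matching the statistic's summation limits).  A constant signal
scores exactly 0 (guarded against floating-point mean round-off);
missing positions drop out with n reduced.  For spliced cohorts both the
mean and the deviation average are weighted by per-position record
counts, so sparsely covered window tails — where the per-position
binomial noise of a thin cohort would otherwise dominate — contribute in
proportion to the data behind them.

Splicing removes intron bases downstream of the TSS, drops the upstream
flank (it does not exist on mRNA), re-indexes the survivors from p = 0
and remaps the translation start.  Pre/post signal sizes are compared
per organism and per group with a two-sided Wilcoxon signed-rank test;
zero differences are dropped (standard signed-rank practice) and groups
with fewer than 6 organisms, or with all-zero differences, are reported
not-testable rather than raising.  Significance tiers: \*P<0.05,
\*\*P≤0.01, \*\*\*P≤0.001, \*\*\*\*P≤0.0001.

## Peak location

The within-region constituents of interest are broad (sd ~75 bp) bumps
riding on per-position sampling noise of order sqrt(g(1−g)/T) ≈ 0.02 at
T = 500.  The raw argmax of such a signal is noise-dominated (its
dispersion spans tens of bp), so peak position and height are estimated
by least-squares fitting A·exp(−(p−c)²/2s²) + b over p = 1..1000,
initialised from a 51-bp moving average.  The free offset b absorbs the
centering of within-region constituents (which subtracts the pooled
bump mass from the whole region), so A measures the full excursion of
the peak above its local baseline.

## Clustering and regression

Species are projected onto six signal sizes: the between-region signal
and the five downstream within-region constituents (the 5'end flank is
excluded as purely upstream).  Features are clustered unscaled — they
share GC-fraction units — with Ward linkage on Euclidean distances; a
z-scoring flag exists.  The cluster count maximises the
Calinski-Harabasz index over k = 2..10 (ties toward smaller k), with the
silhouette argmax reported alongside and disagreement flagged rather
than resolved.  Per-cluster feature importances come from a 500-tree
random forest on the one-vs-all membership problem, seeded, with
`max_features=None` so every split ranks all six features by impurity
reduction (information gain) instead of the per-node subsampling used
for generalisation-oriented forests; importances are normalised to
percentages and aggregated across clusters by member-weighted averaging.
The dendrogram exports as Newick with merge heights as branch lengths.

The component regression fits sigma(CDS within) on sigma(aa choice) and
sigma(syn codon) with an intercept by OLS, per taxonomic group (minimum
4 organisms), with two-tailed t-tests on the weights and the Pearson
correlation between the two component sizes reported alongside.
Rank-deficient designs yield NaN p-values, not exceptions.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Layout.** 1000 bp of 5'end flank; downstream, a 5'UTR, alternating
  coding exons and introns, 3'UTR, and 3'end fill, all drawn from
  integer-range distributions and truncated at +1000.  The default
  (vertebrate-like) grammar uses a compact 5'UTR (20–80 bp) and first
  exon (51–99 bp) with long introns (300–900 bp), so first introns
  typically begin within ~200 bp of the TSS and dominate the window —
  the regime in which an intron-borne peak at +250 bp is observable.  A
  plant-like grammar (exons 120–300 bp, introns 80–200 bp) gives
  CDS-dense windows for studying the coding components.
* **Non-CDS sequence** is drawn base-wise from per-region GC
  probabilities, optionally modulated by position (Gaussian peak, sine
  wave, step); modulated probabilities are clipped to [0.01, 0.99] with
  a clip count reported.  G vs C and A vs T are split 50:50 since every
  statistic depends only on GC status.
* **CDS** is built codon-by-codon: an ATG initiator, body amino acids
  drawn from a (possibly position-interpolated) composition over the 20
  residues, codons drawn within each synonymous set with probability
  ∝ exp(β(p)·GC(codon)), and an in-frame stop codon when the CDS
  completes inside the window.  Introns fall between codons by default;
  a flag allows mid-codon interruption to exercise the split-codon
  annotation path.  Excluding stops from the composition guarantees no
  internal stop codons.
* **Defaults** are vertebrate-flavoured GC baselines (5'end 0.45, 5'UTR
  0.55, intron 0.42, 3'UTR 0.40, 3'end 0.42) and an uncurated curation
  mix; everything is deterministic given the seed.

Named study conditions: `intron_peak_config` (Gaussian bump on introns,
center +250 bp, amplitude 0.1, sd 75), `aa_gradient_config` (Gly/Ala →
Phe/Lys composition slide, uniform codons), `codon_bias_config` (uniform
composition, β sliding +2 → −2 across the window), and
`intron_signal_panel` (all baselines pinned to the expected GC of an
unbiased CDS, 169/360, with a sine modulation on introns only — the
construction in which splicing must weaken the signal).  The default
species-panel archetypes differ by an intron sine wave because a
zero-mean modulation leaves the pooled intron average, and hence the
between-region signal, essentially untouched, making the intron
within-region size the sole systematic discriminator.

What the generator does **not** emulate: splice-site motifs, isoform
structure, dinucleotide periodicity, CpG islands, chromatin context, or
any evolutionary covariance between species.  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generative model, not biological conclusions about real genomes — real
cohorts enter through the same FASTA/TSV interface.

## Problem sizes and runtime

Tests and the acceptance script use cohorts of 10–1000 transcripts
(typically 500), species panels of 20–40, and 50-cohort identity sweeps;
the full suite and the acceptance run each complete in well under a
minute on one CPU.  These sizes put sampling noise (per-position SE
~0.02 at T = 500) an order of magnitude below the injected effects
(amplitudes ~0.1), which is the regime the recovery tolerances assume.

## Known limitations

* Transcripts are treated independently; no collapsing of isoforms to
  one record per gene.
* Curation-based selection implements fixed thresholds (>5% vertebrates,
  >30% plants); kingdoms outside {vertebrate, plant, other} are
  rejected rather than guessed.
* The coverage-weighted treatment of short mRNA windows is one
  defensible convention; conclusions about splice weakening should be
  checked against alternatives (e.g. restricting to a fixed covered
  prefix) on real data.
* a′(x) pools downstream positions only while a(r) pools the full
  window; the asymmetry is intentional but means c(p) is not exactly
  centered over the pooling window.
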