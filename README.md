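# gcsignal

Decomposition of the GC-content profile around transcription start sites
(TSS) into the parts of the transcript that encode it.

## The problem

Nucleosomes prefer GC-rich DNA, and in multicellular genomes the
genome-averaged GC content shows a characteristic signal around TSSs.
Downstream of the TSS that signal has to be written into sequence that is
simultaneously 5'UTR, coding exon, intron or 3'UTR — and inside coding
exons it has to coexist with the protein code.  This package decomposes a
cohort-averaged GC profile into the contributions of those regions, and
splits the coding-exon contribution further into what the *choice of
amino acids* contributes versus what the *choice of synonymous codons*
contributes.  It is aimed at people studying nucleosome-positioning
sequence signals, codon-usage bias, or any positional base-composition
structure anchored at a genomic landmark.

## The model

A cohort is T transcripts, each a sense-strand window of positions
p = −1000..+1000 around its TSS, every base labelled with one region
r ∈ {5'end, 5'UTR, CDS, intron, 3'UTR, 3'end}.  With n(t,p) = 1 when the
base is G or C and r(t,p) = 1 when position p of transcript t lies in
region r:

- **full signal** %GC(p) = Σ_t n(t,p) / T
- **region average** a(r) = Σ_{t,p} n(t,p) r(t,p) / Σ_{t,p} r(t,p)
- **between-region signal** b(p) = Σ_r a(r) Σ_t r(t,p) / T — the part of
  the profile explained by which regions sit at p and their average GC
- **within-region signal** w(p) = %GC(p) − b(p), with per-region
  constituents; it captures positional GC structure inside regions
- **normalised within-region signal** ŵ(p,r) = per-bp GC among the
  transcripts that have region r at p

Inside the CDS, each coding base inherits the pooled average GC a′(x) of
the amino acid x whose codon covers it (reading frames follow the
annotated translation start through intron interruptions).  The CDS
within-region constituent then splits exactly as c(p) + s(p), where c is
the amino-acid-choice signal (expected GC from residue occupancy) and s
the synonymous-codon signal (residual after removing that expectation).

Scalar comparisons use the **signal size** σ_S = Σ_{p=1..1000} |s_p − μ_S| / 1000,
the mean absolute deviation of a signal from its own mean over the
downstream kilobase.  On top of this sit: intron removal with TSS-anchored
re-indexing and paired Wilcoxon signed-rank comparison of pre-mRNA vs
mRNA sizes; Ward-linkage clustering of species on six signal-size
features with Calinski-Harabasz/silhouette model selection and one-vs-all
random-forest feature importances; and OLS regression of the CDS
within-region size on its two component sizes.

A synthetic-cohort generator (`gcsignal.simulate`) produces cohorts with
controllable region grammars, per-region GC baselines, positional GC
modulations, amino-acid composition gradients and positional
synonymous-codon bias, so every stage has parameter-recovery tests
without any genome downloads.

## Worked example

```
python analysis/01_decompose_tss_signal.py --seed 1
```

generates a 500-transcript vertebrate-like cohort carrying a Gaussian GC
bump on introns (center +250 bp, amplitude 0.1, sd 75 bp) and prints:

```
cohort: 500 transcripts (intron_peak)
decomposition residual max |full - between - within| = 0.00e+00
pooled region GC averages:
  a(5end) = 0.4507
  a(5utr) = 0.5471
  a(cds) = 0.4644
  a(intron) = 0.4434
  a(3utr) = 0.3936
  a(3end) = 0.4266
within-region intron peak: center 248.4 bp downstream of TSS, amplitude 0.0942 GC fraction
```

The residual confirms the decomposition is exactly additive; the pooled
averages recover the generator's per-region GC levels; and the
within-region intron constituent recovers the injected bump — its fitted
center (248.4 bp) and amplitude (0.094 above the local baseline) match
the construction.  The remaining drivers follow the same pattern:
`analysis/02_cds_components.py` (amino-acid vs codon-bias
disentanglement), `03_splice_comparison.py` (pre-mRNA vs mRNA sizes,
Wilcoxon), `04_cluster_species.py` (Ward clustering + importances),
`05_regress_components.py` (component regression).  Each writes its
tables under `results/`.

The same stages are available as a CLI for on-disk cohorts
(FASTA + region/metadata TSVs):

```
gcsignal simulate --out cohort/ --seed 3
gcsignal decompose --in cohort/ --out sig/
gcsignal sizes --in sig/ --out sizes/
```

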