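# Methods

## The measurement model

A *CpG dimer* is a forward-strand CG dinucleotide together with its
reverse-strand partner, keyed by the position of the forward C; all
coordinates in the package are 0-based half-open. Methylation levels are
expressed in percent (0–100) everywhere, so RMSE/MAE and the methylN
concordance metrics downstream are in percentage points.

Bisulfite conversion turns unmethylated C into T; the probability that a
read shows C at a cytosine with methylation level ℓ∈[0,1] is

    p_C = ℓ·(1 − e) + (1 − ℓ)·(1 − c)

with conversion rate c (default 0.99) and the residual error e on
methylated cytosines (default 0.01). Conversion-based estimates are
therefore slightly biased toward 50%; the package reports raw
meth/total ratios, as callers do, and the bias cancels to first order in
the two-sample differences that the models consume.

Strand merging sums a plus-strand CG call at p with the minus-strand call
at p+1 into the dimer at p; dimers covered on one strand only are
retained. The pairwise coverage rule keeps dimers with ≥5 reads in *both*
samples (the `min_cov` default), reading the protocol's "covered by at
least 5 reads on both" as both samples, consistent with how the pairwise
coverage tables are laid out; a both-strands variant is deliberately not
offered.

## Digestion

Recognition sites are exact string matches (never across N). The shipped
enzyme table is MspI/HpaII (CCGG, cut after the first C), HinP1I (GCGC),
and AciI (CCGC); AciI's non-palindromic site is also searched on the
reverse strand and reported in forward coordinates (configurable).
Fragments are the intervals between consecutive cut positions plus the
chromosome ends, so fragment lengths always sum to the chromosome length.
The RRBS reduced reference is the MspI digest restricted to 20–500 bp
fragments, with records named `chrom:start-end` so coordinates map back.

## Window read counts

MREBS reads are filtered on the expected 5' trimer of an MRE cut
(CGG/CGC by default; the set is configurable because a fully converted
cut-site C would read TGG/TGC). A read is assigned to the 1 kb window
`[p − 500, p + 500)` around a dimer at p by its 5' alignment position —
the cut site is the signal — with an overlap-based mode available. One
read may count toward several nearby dimers. The window filter keeps
dimers with ≥2 reads in at least one sample. No library-size
normalisation is applied by default (replicate libraries from a single
protocol are closely matched); per-million scaling is available with
explicit library sizes.

## Regression models and metrics

All four models are plain OLS with an intercept (no weights, no
regularisation), fit via statsmodels on the dimers where the response and
the model's predictors are all present. Degenerate inputs are errors, not
silent zeros: constant response, constant predictor, rank-deficient
design, or fewer than (coefficients + 2) observations. R² is
1 − SS_res/SS_tot, which for these fits equals the squared
observed-vs-fitted Pearson correlation (asserted to 1e-10 in tests).
Prediction is offered on every dimer with the predictors present,
response or not; the combined estimator overwrites model-4 values with
model-2 values where both exist, so its support is the union (in practice
equal to model 4's, since the model-2 filters are strictly stronger).
methylN thresholds are inclusive (|observed − fitted| ≤ N). Correlation
matrices between tracks are computed pairwise on the intersection of
defined dimers, reported alongside the intersection size, with pairs
sharing fewer than 3 dimers left undefined.

## Chromatin-state summaries

Given a 200 bp-window segmentation with integer state labels (1–18), a
window's mean methylation is the mean over its dimers with ≥5X coverage
(membership by the C position, half-open; a dimer whose C is the last
base of a window belongs to it although the G overhangs); windows without
such a dimer are excluded, and the same rule is applied to the
genome-wide distribution. Enrichment per state is
log2((covered windows in s / covered total) / (annotation windows in s /
annotation total)); a state with no covered windows yields −inf as a
documented sentinel, since small genomes will have empty states.

## The simulator

The simulator defines the study conditions under which the package is
tested; its defaults were fixed once, as follows.

**Genome.** 200 kb over two chromosomes (a desk-scale stand-in for a
mammalian genome), i.i.d. bases at 42% GC, with CpG dinucleotides in the
background thinned to an observed/expected ratio of 0.2 — the CpG
depletion characteristic of mammalian DNA. Five percent of each
chromosome is covered by 1 kb CpG-island segments generated at 60% GC
without depletion. The depletion step is load-bearing: without it, MRE
sites are so dense that fully digested hypomethylated regions fragment
below the size-selection window and the count/methylation relationship
inverts.

**Methylomes.** Background dimer levels are Beta(6, 2)·100 (mean 75%,
matching the 70–80% of CpGs methylated in mammalian genomes); island
dimers are Beta(0.6, 12)·100 (near zero). Twenty differential blocks of
2 kb shift sample B against sample A by ±50 percentage points, clipped to
[0, 100]. Blocks are placed outside islands: core islands stay
hypomethylated in both samples, as differential methylation concentrates
in shores and enhancer-like sequence rather than island cores (placing
blocks on islands also exposes a fragment-length non-monotonicity — see
limitations).

**MREBS libraries.** Each of 200 molecules per library is a full genome
copy. Every cocktail site's CpG draws an independent Bernoulli
methylation state from its level, and the site is cut iff unmethylated on
that molecule — so partially methylated sites are cut on a proportional
fraction of molecules, which is what makes window counts a continuous
readout. Fragments between consecutive cuts within the size window each
yield one 100 bp single-end read from the fragment 5' end on the forward
strand (the study sequenced 100 bp single-end; no paired-end or
reverse-strand reads). The default size window is 80–380 bp of *genomic
insert*: the protocol size-selects 200–500 bp after ligating ~120 bp of
TruSeq adapters, and using 200–500 bp of raw genomic fragment instead
discards precisely the short fragments that digested hypomethylated
regions produce (measured on the default genome, the count/methylation
correlation degrades from −0.82 to −0.07). Both bounds are configurable.
Conversion is applied to read sequences only (alignment is upstream of
this package); per-dimer conversion calls are derived from reads whose
genomic 5' trimer passes the CGG/CGC filter, mirroring the protocol's
filter-then-call order. Read BED names carry `PRE|POST` — the genomic and
the converted 5' trimer — and the pipeline filters on the genomic form,
matching the published rule; filtering on the converted form is possible
by widening the allowed set to TGG/TGC.

**WGBS/RRBS calls.** Per-dimer coverage is Poisson (default mean 10),
split binomially between strands, with methylated counts binomial at the
conversion-adjusted probability above. RRBS mode zeroes coverage off the
size-selected MspI fragments.

**Seeding.** Every output is a pure function of (config, seed): each
generator stage derives its own stream from the seed plus a fixed tag, and
fixture bundles are byte-identical across runs.

**Scale.** At these sizes a full simulated study plus analysis runs in a
few seconds. The window-filter fraction (~58–63% of dimers) matches the
regime the method targets; the 5X-in-both conversion fraction (~16%) is
necessarily higher than in a mammalian-genome study (~3%), because on
200 kb a fixed library samples the cut-site neighbourhoods much more
densely — coverage *geometry*, not method behaviour. Tests on this
simulator therefore validate directions, orderings, filters and algebra,
not genome-scale coverage percentages.

## Numerical and design choices

- OLS is delegated to statsmodels; tests cross-check coefficients against
  an independent closed-form normal-equations solve (max |Δβ| < 1e-8 over
  random problems).
- Ties and boundaries are all half-open and inclusive thresholds are
  stated as such (≥5X, ≥2 reads, |d| ≤ N), so keep/drop decisions are
  deterministic.
- Models are fit per MREBS replicate, with model 1 (RRBS) fit once since
  it does not involve MREBS data.
- The per-dimer record table uses NaN for unavailable signals; each model
  drops incomplete rows for its own predictor set, which implements the
  per-model support rules directly.

## Limitations

- The molecule-level Bernoulli cutting model treats cutting efficiency at
  an unmethylated site as 1 and sites as independent; real digestion
  efficiency and chromatin accessibility are not modelled.
- No PCR duplicates, GC bias, mapping error, or sequencing error beyond
  bisulfite conversion; reads come only from fragment 5' ends on the
  forward strand.
- Fragment counts are non-monotonic in methylation when site spacing is
  comparable to the size-selection window (methylating a very CpG-dense
  region can lengthen fragments *into* the window). The simulator's
  defaults keep differential blocks out of that regime, as real DMRs
  largely are, but analyses of island-core differential methylation from
  counts alone would face it.
- The simulator emits MREBS conversion calls aggregated to the forward
  C of each dimer (its reads are forward-strand only); the WGBS/RRBS
  paths exercise two-strand calling and merging.
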