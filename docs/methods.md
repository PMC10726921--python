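# Methods

This note documents the models, conventions and numerical choices behind
`radtmb`, in the order the pipeline uses them.

## Coordinates, channels and conventions

Mutation positions are 1-based (VCF convention); all intervals are 0-based
half-open (BED convention), so a mutation at position *p* falls in fragment
[s, e) iff s ≤ p−1 < e. SBS96 channels are ordered canonically: the six
pyrimidine-centred substitutions C>A, C>G, C>T, T>A, T>C, T>G, each crossed
with the 16 flanking pairs in lexicographic (A, C, G, T) order. SNVs with a
purine reference are reverse-complemented onto the pyrimidine strand before
channel assignment, which makes channel extraction strand-involutive. Records
whose trinucleotide contains N or sits at a contig end are excluded from
profiles and counted; a reference-base mismatch raises an error by default
(it almost always means a genome-build mixup) but can be demoted to
drop-with-count.

Every inequality that defines a threshold is strict where the definition
reads "greater than": CS > 0.9, TCW fraction > 0.4, TMB > 10 mutations/Mb,
coverage fraction > 0.10. Size-selection bounds (70–378 bp) are inclusive.

## Signature recapitulation

For each sample, subset size *n* and replicate r = 1..10, `radtmb` draws *n*
mutations without replacement and computes the cosine similarity between the
subsample's SBS96 profile and the sample's full profile. Cosine similarity is
scale-invariant, so counts and frequencies are interchangeable; a zero
profile has no defined similarity and errors. RNG substreams are derived from
a single seed per (sample, size, replicate) with a counter-based spawn-key
scheme, so tables are bit-reproducible and embarrassingly parallel.

A sample *succeeds* at *n* when the majority (≥ ⌈R/2⌉) of its replicates
exceed the CS cut. The per-sample replicate proportion Pr(CS > 0.9) is
reported alongside. Per *n*, the number of succeeding samples is tested
against a success proportion p₀ with a one-sided exact binomial test
(alternative: proportion > p₀); p-values are corrected across the *n*-grid
(Bonferroni by default, Holm selectable) and *n\** is the smallest *n* with
corrected p < α = 0.05. The one-sided 95% exact (Clopper–Pearson) lower
confidence bound on the proportion is reported per *n*.

Majority-of-replicates was chosen over all-replicates because a single
unlucky draw should not disqualify a sample whose profile is otherwise
recapitulated; the per-replicate proportion remains available for stricter
summaries.

**Power floor for small subsets.** The minimum attainable p-value at p₀ with
m tested samples is p₀^m, so a 10-sample subset can never reach α = 0.05 at
p₀ = 0.95. Subset analyses must size p₀ to the group: the packaged contrast
experiment (10 hypermutated vs 90 typical samples) uses p₀ = 0.5 for both
groups, fixed from the group sizes before any experiment is run.

## APOBEC statistics

Hypermutation is > 40% of profile mass on the four channels T[C>T]A, T[C>T]T,
T[C>G]A, T[C>G]T. The enrichment test of a clone against its parental is the
one-sided upper-tail exact binomial P(X ≥ k | n, π₀), with k the clone's
T[C>T]W count (C>T only by default; the four-channel scope is selectable), n
its total context-resolvable mutations, and π₀ the parental T[C>T]W fraction.
A parental fraction of exactly 0 or 1 falls back to 0.5 pseudo-counts. The
upper tail is the only direction compatible with testing *enrichment*; the
lower-tail reading of the same counts would test depletion.

YTCA/RTCA fractions resolve the base two positions 5′ of the mutated C in
pyrimidine-strand orientation (on reverse-strand events this is the
complement of the base two positions 3′ on the forward strand); pyrimidine
(C/T) at −2 indicates APOBEC3A-like, purine APOBEC3B-like editing.

## In-silico digestion

Recognition sites are all forward-strand matches of the IUPAC motif; for
motifs that are not their own reverse complement the reverse-complement
pattern is also scanned and positions deduplicated. Overlapping matches
count; genome N matches nothing. Breakpoints sit at motif starts — cut-offset
geometry of type IIS enzymes is deliberately ignored, since fragment
definition here only needs the recognition-site map. Fragments are the
intervals between adjacent breakpoints; terminal regions (before the first
and after the last site) are dropped because a sequenceable RAD fragment
needs a cut at both ends. Double digests pool breakpoints from both motifs
before fragment construction.

Library coverage is the merged (union) interval length minus N bases —
assembly gaps are unsequencable and must not inflate coverage. The library
retention rules apply in order: high-fidelity duplicate enzymes (same motif;
the lexicographically first name is kept), methylation-sensitive enzymes,
libraries whose median captured mutations per sample is below 2 (mean
selectable), and libraries covering more than 10% of the non-N genome. Each
library gets the first applicable reason. Panels built from BED regions are
merged but not size-selected.

## TMB accuracy metrics

Rates are mutations per Mb: captured count over library coverage for the
library, catalogue count over the non-N genome length for WGS (the WGS
denominator is configurable). Three per-library metrics over the cohort:
Pearson *r* of library vs WGS rates (with Holm-adjusted p-values across
libraries), the median absolute rate difference, and the multiplicative bias
θ = median over samples of (library rate / WGS rate), with zero-WGS-rate
samples excluded and counted. θ has no printed formula in the literature this
design follows; the median ratio was chosen as a robust multiplicative-bias
estimator with ideal value 1.

The error–coverage model is OLS of log₂(metric) on log₂(coverage) across
libraries with r ≥ 0.9, with t-based 95% intervals. The default metric is the
median absolute difference; |log₂ θ| is selectable. The coverage fold-change
that halves the error under slope b < 0 is 2^(−1/b). A library is an outlier
when its log₂(metric) exceeds the upper bound of the 95% *prediction*
interval at its coverage — the prediction band, not the mean-confidence band,
because the question is whether a single new library is consistent with the
model.

Under uniform mutation placement the captured count is binomial, the error
scales as coverage^(−1/2), and the fitted slope is −1/2 (the package's
synthetic reproduction recovers this within ±0.1 provided library coverage
stays below the 10% ceiling; above it the (1−c) factor steepens the local
slope). Real genomes cluster mutations (kataegis, regional rate variation),
inflating low-coverage error more slowly than binomial and flattening the
slope toward −1/3 — hence "8-fold coverage to halve the error" on real
cohorts versus 4-fold in the uniform ideal.

## Simulated ICB trials

Response probability is a linear ramp from p = 0 at TMB 0 to p = 0.5 at
11 mutations/Mb, flat beyond (a logistic alternative through the same
anchors is selectable; the ramp is the default because only the three anchor
values are well-determined). Setting p_min = p_max yields the null model with
no TMB effect. Each trial draws independent Bernoulli responses from the
*true* TMB; each cutoff dichotomises patients by the *measured* TMB, so using
a library estimate instead of WGS truth degrades the detectable association
without touching the outcome generation. Association per cutoff is Fisher's
exact test; the reported odds ratio is the conditional MLE of the noncentral
hypergeometric (the R `fisher.test` convention), with a Haldane-corrected
sample OR available for degenerate tables, which themselves give p = 1 and
are logged. Cutoff p-values are Bonferroni-corrected within each trial —
each simulated trial is analysed as a real one would be — and the per-cutoff
power is the fraction of trials with adjusted p < 0.05. Default cutoffs are
2–10 mutations/Mb in unit steps. Per-trial RNG substreams derive from the
top-level seed by trial index.

## Clone pipeline

VCF-derived sites are filtered to depth ≥ 20 *and* allele fraction ≤ 0.75.
The two rules are conjoined as retention criteria (equivalently, shallow
sites and high-AF sites are each removed): keeping only sites failing both
rules would retain shallow low-AF artefacts, defeating the filter's purpose.
Clone mutation rate divides by bases covered at ≥ 20×, supplied as a
coverage summary. Pairwise cosine matrices are symmetric with unit diagonal;
a zero profile errors, naming the sample.

## Synthetic data generator

The generator exists so every stage is testable without downloads; its
defaults encode the cohort structure the pipeline was designed around.

- **Genomes** are i.i.d. bases at a given GC content (default 0.41,
  human-like). No repeats, no assembly gaps, no isochores.
- **Signatures**: flat (1/96), APOBEC (mass f_tcw on the four TCW channels,
  split 0.4/0.4/0.1/0.1 so C>T dominates, remainder flat), and convex
  mixtures.
- **Catalogues** draw each mutation's channel from the signature, then a
  uniform genome position whose pyrimidine-normalised trinucleotide matches
  the channel's context (either strand), emitting strand-resolved ref/alt so
  re-extraction reproduces the drawn channel exactly. Positions are unique
  within a sample. A one-pass context index makes generation linear-time.
- **Cohorts**: each sample is hypermutated with probability
  `apobec_fraction` (default 49/560 ≈ 0.0875); counts are log-normal around
  group medians (defaults 10,110 hypermutated / 3,270 typical, σ = 0.8 for a
  right-skewed order-of-magnitude spread); hypermutated samples draw from an
  APOBEC signature with f_tcw = 0.6, typical samples from a flat signature.
- **Uniform catalogues** place mutations uniformly over non-N bases with
  random alts, for error-scaling studies; an optional clustered mode places
  mutations in bursts to emulate kataegis-like clustering and study why real
  error–coverage slopes are shallower than −1/2.

What the generator does *not* emulate — mutation clustering by default,
replication-timing and chromatin covariates, copy number, sequencing error,
real trinucleotide composition — bounds what passing tests show: they
validate the statistical machinery and the sampling theory it rests on, not
the behaviour of any particular tumour cohort. Real-data conclusions (e.g.
the exact n\* values or the fitted slope) depend on the real catalogue's
clustering and signature mix.

## Problem sizes in the packaged experiments

The test-suite and acceptance-script experiments run at desk scale, chosen
once as the smallest sizes at which each effect is statistically decisive:
a 300 kb genome and 100 samples (10 hypermutated + 90 typical, counts
log-normal around 3,000, minimum 2,000) for the recapitulation contrast with
subset grid 25–1,000; a 5 Mb genome, 100 samples with counts log-normal
around 5,000, and a 32-design digest ladder (18 single, 14 double digests,
retained below the 10% coverage ceiling) for the error-scaling law; 500
trials on 500-sample cohorts for the trial engine; 1,000 simulations of
500-mutation clones against a 10,000-mutation parental for enrichment
calibration. The Monte-Carlo type-I rate of the enrichment test is compared
against its closed-form value (the binomial rejection probability at the
parental fraction), which is itself asserted ≤ 0.05.

## Known limitations

- Digest breakpoints ignore cut-site offsets, star activity, partial
  digestion and methylation state (methylation-sensitive enzymes are removed
  instead of modelled).
- θ's estimator is a design choice (median ratio); other bias estimators
  would give numerically different, similarly ordered results.
- The ICB response model is a deliberately minimal single-ramp model — no
  survival endpoints, tumour-type calibration or covariates.
- The exact-test conventions match R's `fisher.test` (conditional MLE,
  two-sided by probability mass); SciPy's sample odds ratio would differ on
  the same tables.
- Signature extraction (NMF), indel/doublet signatures, and clonal/subclonal
  decomposition are out of scope; the pipeline starts from SNV catalogues or
  VCFs and ends at the statistics described above.
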