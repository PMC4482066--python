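# Methods

This note documents the models, conventions and numerical choices behind
`p53scape`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and overlap

All coordinates are 0-based half-open (`[start, end)`), the BED
convention; BED input is read verbatim. Region strings in browser style
(`chrN:x-y`) are treated as 1-based inclusive and converted on ingest
(`start = x − 1, end = y`). Overlap means ≥ 1 shared base pair on the
same chromosome, with strand ignored; no reciprocal-fraction option
exists in this version. Set coverage is always the length of the union of
a set's intervals, so duplicated or overlapping members never count
twice. Shared peaks between two replicate peak sets are reported
reference-asymmetrically (the peaks of the first argument that touch any
peak of the second); the convention is recorded in the result's source
label because replicate peak boundaries rarely coincide.

## Expression and peak filters

The upstream differential-expression caller is treated as a black box
that supplies per-sample FPKM, log2 fold changes and significance flags.
Three filters are applied downstream:

* significant protein-coding genes are kept when their summary FPKM
  (maximum over samples, configurable to mean) reaches the top 75% of
  expressed genes. The 25th-percentile cutoff is computed over **all**
  genes with nonzero expression — "expressed genes" refers to the
  transcriptome, not the significant subset — with a configuration switch
  for the subset-based reading;
* significant lincRNAs are kept when FPKM exceeds 1 (strictly) in at
  least one sample;
* peaks are kept when their intensity (read FPKM) reaches the top 75%.

Quantile cutoffs use lower-nearest interpolation, so the reported cutoff
is always an observed value and no interpolation ambiguity exists.
Filters record a provenance tag on their output (persisted through the
TSV round-trip), which makes them idempotent — reapplying the same filter
is a no-op rather than a further 75%-of-75% cut — and lets target calling
warn when handed an unfiltered table.

## Direct-target calling

A gene's regulatory window is `[TSS − W, TSS + W]`, inclusive on both
flanks (hence `TSS + W + 1` in half-open coordinates), clipped at the
chromosome boundaries; W defaults to 30 kb (human preset) or 20 kb
(mouse). The window is symmetric, so strand affects only distance signs.
A gene is a direct target when ≥ 1 filtered peak overlaps the window with
its full extent (maximal sensitivity, in the spirit of the deliberately
large windows); direction comes from the sign of the fold change. Two
distance conventions coexist deliberately:

* per-call `min_tss_distance` is the signed distance from the TSS to the
  nearest base of the nearest supporting peak (0 when the TSS lies inside
  the peak), which is bounded by W for any supporting peak;
* genome-wide distance profiles use the peak **midpoint** to the nearest
  TSS by absolute distance, the convention in which peak-to-TSS
  histograms are usually drawn. Nearest-TSS ties break toward the
  smaller coordinate, deterministically.

Bound and unbound genes' log2 fold changes are compared with the
two-sample Kolmogorov–Smirnov test (asymptotic p-value).

## Response-element scanner

The p53 response element is two degenerate 7-mer half-sites, `RCWWGYY`
and `RRCWWGY`, separated by a 2–4 nt spacer of arbitrary sequence.
Matching is exact against the IUPAC degeneracies — no mismatch allowance,
and `N` in the genome never matches any pattern letter (a stringent
search). The scan enumerates all start positions for every admissible
spacer length, including overlapping footprints, ordered by
`(start, spacer_length)`. Because the reverse complement of
`RCWWGYY·N_k·RRCWWGY` is itself, a single forward-strand pass covers both
strands for the default motif and hits are reported with strand "both";
user-supplied non-palindromic specs are scanned on both strands and
deduplicated by footprint. A peak "has a motif" when ≥ 1 hit lies inside
it — peak counts, not hit counts, are what the downstream summaries use.

## Coverage-normalized enrichment

The enrichment of a feature in a subset of units against a background is
the ratio of per-nucleotide densities
`(c_s / L_s) / (c_b / L_b)`. The equivalent bookkeeping that divides each
count by (coverage of its data set / coverage of the feature) is also
implemented; the feature coverage cancels algebraically and the two forms
agree to machine precision (this is property-tested). A zero background
count makes the ratio undefined and is reported as missing with a note,
never as infinity. The background is the whole unit universe (e.g. the
transcriptome **including** the subset). A consequence worth knowing: a
planted subset-vs-rest density contrast of r appears in this statistic as
`r / (1 − q + q·r)` where q is the subset's share of the universe — the
contrast is diluted whenever the subset is non-negligible. The
complement-based estimator `complement_density_ratio` removes the subset
from the background and is the consistent estimator of a planted
contrast; parameter-recovery checks use it, while reported enrichment
tables keep the inclusive definition.

Significance uses label shuffling at the granularity appropriate to each
analysis: for repeats, subset membership is shuffled across transcripts;
for chromatin states, state labels are shuffled across segments (one
shuffle re-labels the whole map and yields a null draw for every state at
once, moving coverages along with counts); for TFs, the factor-bound flag
is shuffled across enhancers, preserving how many enhancers the factor
binds. With n shuffles (default 100) and b null statistics at or above
the observed one, `p = (1 + b) / (1 + n)` — the pseudocount form, so p is
never 0 and its floor is `1/101` under the default. Enrichment and
depletion p-values are both reported, each one-sided. Bonferroni
correction multiplies by the number of labels tested, capped at 1.

Each label draws its permutations from an RNG substream derived from the
pipeline seed and a hash of the label name, so adding a label to an
analysis never perturbs any other label's null distribution.

For the TF-within-p53-bound-enhancer analysis, an enhancer is "bound" by
a factor when ≥ 1 of the factor's sites overlaps it; the observed ratio
is the density of p53-bound enhancers among factor-bound enhancers over
the density of p53-bound enhancers among all enhancers, so a factor bound
at every enhancer scores exactly 1. For the chromatin-state analysis the
background is the whole genome (all peaks over total genome length); in
the histone-mark variant, per-mark interval sets stand in for state
segments and are shuffled the same way. Because a peak of width L
straddling segment boundaries can overlap more than one segment, the
count-based ratio carries a small upward bias of order L divided by the
mean segment length, identically across states; narrow peaks make it
negligible.

## Hybrid state maps and TF co-occurrence

The hybrid chromatin state map across cell types keeps exactly the base
pairs assigned the **same** state label in every input map — agreement is
per base pair, not per segment boundary — and merges the result per
label. The construction is associative and order-invariant, and its
coverage is bounded by each input's.

Pairwise TF co-occurrence over N enhancers uses the hypergeometric upper
tail `P(X ≥ k)` for X ~ Hypergeom(N, K_a, K_b), one-sided in the
enrichment direction, symmetric in the margins, and evaluated through the
survival function (log-space internals). k = 0 gives exactly p = 1.
Bonferroni correction uses m = C(F, 2) over the tested factor pairs; the
diagonal is not applicable and left as NaN; a factor binding zero
enhancers gets p = 1 against every partner and is flagged.

## Guilt by association

Expression profiles are normalized to probability vectors and compared
with the Jensen–Shannon distance: the square root of the JS divergence in
log base 2, a metric bounded by 1 and attaining 1 on disjoint supports.
Genes are ranked ascending (most similar first) with ties broken by gene
id. Gene sets are scored on the ranked list with the classic weighted
running-sum statistic: hits increment the sum proportionally to
`|1 − distance|` (weighting exponent 1), misses decrement uniformly, and
the enrichment score is the signed maximal deviation. The p-value
permutes gene labels with the same `(1 + b)/(1 + n)` convention,
one-sided in the direction of the observed score. A gene set equal to
the whole list is degenerate (the running sum can only rise) and is
reported with p = 1. Curated gene sets are supplied as GMT files rather
than bundled.

## Synthetic-data generator

The generator emulates the *structure* the statistics consume, not the
physics of sequencing:

* **Genome and annotation** — i.i.d. uniform nucleotides over two 5 Mb
  chromosomes by default; 400 protein-coding genes and 60 lincRNAs of
  2–8 kb dropped into randomly chosen 12 kb slots (so transcripts never
  overlap), random strand, TSS at the strand-aware 5′ end.
* **Expression** — per-gene baseline FPKM is log-normal; fold changes are
  N(0, 0.5) background and sign·N(2.0, 0.3) at planted targets (30%
  repressed). The significance flag emulates the upstream caller's
  classification and is assigned independently of the fold changes
  (25% of transcripts), which makes the bound/unbound comparison an
  exact null when no targets are planted.
* **Targets and peaks** — planted targets are drawn from significant,
  clearly expressed transcripts (above the 40th percentile of baseline
  FPKM, so the downstream top-75% filter cannot swallow a planted fact)
  whose TSS window admits a peak placement outside every other
  significant gene's window; the supporting peak is placed uniformly in
  that exclusive region. Decoy peaks avoid all significant-gene windows
  entirely. Bound peaks draw intensities from a higher log-normal than
  decoys (true binding sites have higher read density — the premise of
  the top-75% coverage filter). An exact response element, sampled
  uniformly from the degenerate consensus expansion, is written into 40%
  of peaks; chance matches in the remaining sequence are possible and
  simply add the expected background rate.
* **Repeats** — per-transcript occurrence counts are Poisson at 0.5/kb
  background density; Alu-family elements in a designated transcript
  subset use 2.5/kb (a planted 5× contrast), with ~300 nt occurrence
  lengths at uniform positions in transcript coordinates.
* **States and TFs** — the genome is cut into 1–3 kb segments and state
  labels are allocated as an exact multiset of the configured fractions
  (active promoter 2%, enhancer 5%, weak transcription 50% — ten times
  the enhancer share, as in real state maps — repressed 15%, the rest
  unannotated), so rare states realize their coverage tightly; i.i.d.
  per-segment draws would leave the enhancer coverage, and with it any
  analytic enrichment ratio, far too variable. Each cell type's map is
  the backbone with 10% label noise, making the hybrid intersection
  nontrivial. Twenty TF catalogs drop 200 bp sites into backbone
  enhancers at a 15% marginal rate; cFos/cJun co-bind with odds ratio 30
  (they act as the obligate AP-1 heterodimer, so their planted
  association is far above any incidental pair), via the Plackett
  construction for a bivariate Bernoulli with given margins and odds.
  A configurable factor (KAP1 by default) concentrates into p53-bound
  enhancers with a 3× lift at preserved marginal rate.
* **Compendium** — a 300-gene × 12-tissue matrix with a 30-gene module
  sharing the query's archetype profile up to 25% multiplicative noise.

All randomness flows from one seed through named per-stage substreams;
two runs with equal configurations are byte-identical. What passing tests
on this generator do **not** show: robustness to GC bias, mappability
artifacts, overlapping genes, correlated repeat placement, or peak-calling
noise — none of which the downstream statistics model either.

## Problem sizes and defaults

Defaults were chosen once as desk-scale study conditions: 2 × 5 Mb
genome, 460 transcripts, 300 peaks, 100 permutations (p-value floor
1/101), 100-replicate calibration and recovery simulations. Permutation
counts and simulation sizes in the test suite are balanced so the whole
suite runs in well under a minute-scale budget per module while keeping
binomial error bars comfortably inside the asserted tolerances.

## Known limitations

* Overlap is any-bp; no reciprocal-fraction or gapped-intersection rules.
* The enrichment null shuffles labels only; no GC-, length- or
  composition-matched backgrounds (and no analytic binomial/Poisson
  alternative).
* The TF co-occurrence criterion "unique Bonferroni-significant pair"
  operates at the family-wise error boundary by construction: with 190
  factor pairs at α = 0.05, a false extra pair appears in roughly 5% of
  cohorts no matter how strong the planted pair is; the discreteness of
  the hypergeometric tail is what keeps the realized rate at or below
  nominal.
* Fold-change significance flags are independent of effect size in the
  generator; a realistic coupling would not change any pipeline logic but
  would make the bound/unbound null calibration only approximate.
* No figure rendering; distance profiles and enrichment tables are
  emitted as data, with histogram binning provided on the profile object.
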