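# Methods

This note documents the statistical model behind `recmotif`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## The analysis in one paragraph

Given a genome and a per-window recombination map, the pipeline asks
whether the local density of short tandem-repeat motifs predicts the local
recombination rate.  The map is smoothed at a ladder of genomic scales and
each chromosome is split at its median rate into high- and low-recombining
bins; repeat motifs enriched in the high class are discovered by exhaustive
enumeration and an exact contingency test, collapsed into a consensus set,
and located genome-wide with a position-weight-matrix scan carrying exact
p-values and false-discovery q-scores.  The per-kilobase sum of `1 - q`
over matches is the motif-density statistic, and Spearman rank correlation
plus ordinary least squares quantify its association with the rate track
per motif, chromosome and scale, and pooled genome-wide.

## Recombination maps

A map is a per-chromosome vector of rates over fixed-width bins (default
1 kb), in either population-scaled ρ (per bp) or cM/Mb, with missing bins
as NaN.  The two units differ by ρ = N_e × r: LD-based estimates fold in
the effective population size, so absolute calibration requires external
genetic anchors.  `normalize_to_cM` applies one global constant
`c = (Σ anchor cM) / (Σ map genetic length over the anchor intervals)` so
the anchors jointly re-sum to their known genetic length; bin-to-bin ratios
are untouched.  The anchor set is user-supplied; partial bin overlap is
handled by fractional weighting and missing bins inside anchors contribute
zero mass.

### Smoothing

The primary smoother is the moving median, windows of 1, 5, 25, 101, 501
and 2,501 kb (an odd number of bins each).  Two properties motivate it:
insensitivity to the heavy-tailed noise of LD-based rate estimates, and
membership — with an odd window, the output is always an element of the
input window's multiset, so smoothed maps contain only observed rates.
Design choices where several behaviours are defensible:

* **Edges.**  Windows are truncated at chromosome ends so the output has
  the same length as the input.  A truncated (even-sized) window takes the
  *lower* of the two central order statistics, preserving membership at the
  edges too.
* **Missing data.**  NaN bins are excluded from each window's multiset
  (which can also make interior windows even-sized; the same lower-median
  rule applies); a window that is entirely missing stays missing.
* **LOESS** (tricube-weighted local linear regression, span as a fraction
  of the chromosome's bins, negative fits clipped to 0) is provided as an
  alternative; it reproduces linear tracks exactly and gives qualitatively
  equivalent smoothed maps, but does not have the membership property.

### Median split

Each chromosome is partitioned at the median of its non-missing rates:
strictly greater than the median → high, otherwise → low, missing →
excluded.  "Strictly greater" makes *higher than median* literal; ties sit
in the low class.  Note a consequence: when more than half the bins share
the maximum rate the high class is empty even though rates are not all
equal — the code warns, and discovery refuses to run on a degenerate
split.  The split is recomputed on each smoothed map, so discovery can be
repeated per scale.

## Motif discovery

Enumerative differential enrichment replaces an EM-based motif search: the
target family is short tandem repeats, so the candidate space — all repeats
of primitive 1–3 bp units with total length 8–12 bp, deduplicated by unit
rotation and reverse complement (42 candidates at the defaults) — covers it
exhaustively, and exact counting is both faster and oracle-checkable.  This
is an explicit design substitution, not a reimplementation of a PWM
optimizer: complex or degenerate motifs are out of scope.

Per candidate, occurrence start positions (exact string matches of the
candidate and of its reverse complement, overlaps allowed) are classed by
the high/low label of the bin holding them.  The one-sided hypergeometric
tail on the 2×2 table (match/non-match × high/low positions) tests excess
in the high class, and `E = p × number of candidates` gives Bonferroni-style
expected-hit semantics.  Counting is per start *position*, not per base.

### Consensus construction

Discovered motifs from several species and scales collapse in two steps:
keep motif strings reaching `E ≤ 0.01` in at least one record; simplify
probability matrices to their most-likely base per position (ties broken
alphabetically); group by canonical minimal repeat unit up to rotation and
reverse complement; fix each group's length to the minimum over
contributing species of that species' maximum record length (the longest
length representable in all species, truncated to whole units); and emit
`[unit]count` strings.  Groups observed in a single species are kept and
flagged rather than dropped.  When a species holds a motif at several
scales the minimum E across scales decides retention.

## Scanning

A consensus string becomes a letter-probability matrix in a *hard*
(expected base 1.0, others 0.0) or *soft* (0.97 vs 0.01) dialect.  Scores
are `log2(p'/bg)` with background-proportional pseudocount regularization
`p' = (p + ε·bg)/(1 + ε)`, ε = 0.1 by default — required for hard columns
to have finite mismatch scores, and matching common scanner practice.  The
background is the genome's strand-symmetrized order-0 base composition
(N skipped, zero frequencies floored at 1e-6).

Scores are discretized to 1e-3-bit steps; the null distribution of the
total score of a background-drawn word is the exact convolution of the
per-column score distributions at that discretization, so every reported
p-value `P(S ≥ s)` is exact for the discretized matrix (verified against
brute-force enumeration over all 4^L words for L ≤ 8).  Both strands are
scanned (reverse strand = reverse-complement matrix on the forward
sequence; the null distribution is identical because the background is
strand-symmetric), windows containing N are skipped, overlapping matches
are all reported, and matches with `p ≤ 1e-4` are kept.

**q-scores.**  Benjamini–Hochberg step-up over the reported p-values with
denominator `n_tests` = the number of scanned (N-free) positions on both
strands: `q_(i) = min_{j≥i}(p_(j)·n_tests/j)`, capped at 1.  This is a
deterministic, oracle-checkable choice; an empirical-null q-value estimator
would differ by a monotone rescaling and leave density-track *ordering*
unchanged.  A consequence worth knowing: on a genome where a motif occurs
no more often than chance, `p·n_tests` matches or exceeds the occurrence
count, every q is 1 and the density track is identically zero — the
statistic deliberately reports "nothing above background".

## Density tracks

Each occurrence contributes `1 - q` to the bin holding its start
coordinate.  Assignment by start (rather than splitting boundary-spanning
matches) keeps the conservation identity exact: the sum over bins equals
the genome-wide discounted total, before and after rebinning to coarser
windows (a trailing partial group is kept as its own shorter bin).  The
default is a non-overlapping 1-kb tiling, which is what the downstream
correlation requires; an overlapping sliding-window variant exists for
visualization but is not used in the association grid.  For maps at coarser
native resolution, densities are rebinned to the map's bin size — never the
map to the density.

## Association

Spearman's ρ uses average ranks for ties; its p-value is the two-sided
t-approximation with n − 2 df for n ≥ 10 and the exact permutation
distribution over all n! orderings below that.  The OLS fit regresses rate
on density; the slope p is the two-sided t-test, and an exactly
zero-residual fit reports the floor constant 1e-300 rather than p = 0.
Bins with a missing rate or density are dropped pairwise; constant input on
either side leaves the statistic undefined and the grid cell missing (with
a warning), never silently zero.  Pooling concatenates the per-chromosome
bin vectors without weighting.  The grid reports raw p-values per cell; an
optional Benjamini–Hochberg column across cells is available but off by
default.

## The synthetic-data generator

`recmotif.synthetic` generates the fixtures the test suite and acceptance
script run on.  What it emulates:

* **Landscape shapes.**  `sim_like`: a flat plateau (default 3 cM/Mb, a
  realistic *Drosophila* chromosome-arm average) suppressed to plateau/50
  within `edge_drop_width` (default 100 kb) of each chromosome end —
  near-uniform recombination with sharp terminal drops.  `mel_like`:
  plateau × logistic rise with length constant `decay_scale` and midpoint
  at two decay lengths from each end — the gradual centromere/telomere
  suppression.  Two parameters each reproduce the qualitative contrast
  between the two landscape styles; the true functional forms are not
  published, so these are modelling choices.
* **Rate noise.**  Multiplicative lognormal noise, mean 1, per raw bin,
  with coefficient of variation `noise_cv` (default 0.3).  LD-based raw
  maps are noisy but no quantitative noise magnitude is available to match;
  0.3 makes raw tracks visibly rough while leaving the landscape legible,
  and the smoothing ladder is exercised either way.
* **Coupling.**  Motif copies are planted per bin as
  Poisson((a + b·rate)·bin_kb), uniformly placed, never overlapping each
  other (rejection sampling; a copy that cannot be placed after 50 draws in
  a saturated bin is dropped — negligible at sane intensities, and an
  expected footprint above 20% of the genome is refused outright).  `b > 0`
  embeds the hypothesis under test — density tracking rate — with known
  strength; `b = 0` is the null.  Planted copies overwrite the background,
  so the plus-strand substring at each truth interval equals the motif
  exactly.
* **Determinism.**  One global seed expands by fixed offsets into genome,
  planting and per-chromosome landscape streams, all recorded in the
  manifest; regeneration from a manifest is byte-identical.

What it does **not** emulate, and hence what passing tests do not show
about real data: linked selection and demography distorting ρ along real
chromosomes; sequence heterogeneity (isochores, repeat expansions, N gaps)
that makes a single order-0 background an approximation; motif clustering
beyond Poisson placement; and any mechanistic link between repeats and
crossover formation — recovery tests demonstrate that the pipeline measures
a known planted signal correctly, not that such a signal exists in nature.

## Problem sizes

The recovery fixtures use two 5-Mb chromosomes at 1-kb bins (10,000
association bins, ~16,000 planted copies), twenty seeds for the recovery
and null-rate checks, and a 2-Mb two-level landscape for discovery —
sizes at which every effect tested is far from its decision boundary while
the full suite stays comfortably runnable on a laptop core.

## Known limitations

* Order-0 background only; no higher-order Markov backgrounds.
* Unambiguous consensus motifs only — no IUPAC codes, gaps or multipart
  motifs.
* The BH q-score is not identical to empirical-null q-value estimators;
  absolute density values are comparable only within a scanning
  configuration.
* The hypergeometric enrichment test treats positions as exchangeable;
  overlapping occurrences of a repeat are correlated, so its p-values are
  anticonservative for strongly clumped candidates — acceptable here
  because the E ≤ 0.01 retention decision is applied to effects orders of
  magnitude beyond the threshold, and the null calibration is verified on
  label-shuffled fixtures.
* Cross-species comparison is qualitative (shared consensus units); no
  formal cross-species contrast statistic is computed.
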