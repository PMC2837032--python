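# Methods

## The conditional count-comparison test

Digital expression profiling measures a transcript's abundance as the
number of reads (`hit counts`) assembled into its contig in each library.
Under the model that each read is an independent draw from the library's
transcript pool, a contig's count in a library of `n` total reads is
binomial — effectively Poisson — with rate proportional to its true
relative abundance. Conditioning on the count `x` observed among `n1`
reads in the first library, the count `y` among `n2` reads in the second
library under the null hypothesis of equal relative abundance follows

    p(y | x) = (n2/n1)^y · (x+y)! / (x! · y!) · (1 + n2/n1)^-(x+y+1)

which is exactly the negative-binomial pmf with size `x+1` and success
probability `n1/(n1+n2)` (a Poisson rate integrated over its flat-prior
posterior given `x`). The test statistic is one-tailed: the library with
the larger raw count supplies the conditioning count `x` and total `n1`,
and the p-value is the lower-tail sum over the other library's count,
`p = Σ_{y'=0..y} p(y'|x)`. Assumptions worth keeping in mind:

* each read maps to exactly one contig (counts partition the library);
* library totals are fixed and known — all relative frequencies and
  p-values must use the *full* library totals even when a subset of
  contigs is analysed;
* no overdispersion beyond sampling noise (no biological replicates exist
  in this design, so between-replicate variance is unidentifiable).

### Numerics

Tail sums are accumulated in log space: each term via the negative-
binomial log-pmf (gammaln-based), segments combined by a shift-by-max
log-sum-exp. The p-value is carried as `log10 p` with the linear value as
a derived view, so tails near 1e-250 — which would underflow any naive
product of factorial terms — retain ~1e-12 relative accuracy in `log p`
(verified against exact big-integer rational summation over the full grid
`0 ≤ x, y ≤ 200` at three depth configurations in the test suite).

### Conventions and edge cases

* **Direction** follows the relative frequencies (`rel_d = hits_d/n_d`
  vs `rel_l = hits_l/n_l`); the **conditioning side** follows the raw
  counts. With unequal totals the two can disagree for nearly-equal
  counts; both facts are recorded and a warning is logged.
* A raw-count **tie** conditions on the deeper library. This choice is
  deterministic and makes the statistic exactly invariant under
  exchanging the two libraries (counts and totals together); at equal
  totals the two possible choices coincide.
* A contig absent from both libraries gets `p = 1`, direction `tie`.
* The **ratio** column is the majority-over-minority relative frequency
  (≥ 1 by construction, `inf` when the minority count is 0); it is
  recomputed from counts and totals, never from rounded intermediates.
* Significance is `p < alpha`, strict, with `alpha = 0.05` by default. No
  multiple-testing correction is applied to the per-contig p-values; the
  significant set should be read as a screening set, not an FDR-controlled
  discovery list (see *Limitations*).

## Quantitation and reporting

* Detection means ≥ 1 hit in a library. "At least 5 hits" (≥ 5) marks the
  stratum where the test has meaningful power; "≤ 5 in both" marks the
  stratum where no differential call can reach p < 0.05.
* The hit-count histogram uses adjacent upper ranges — a count falls in
  the first bin whose upper bound is ≥ it (default uppers 1, 5, 10, 50,
  100, 500, 1000, ∞; only the first two are conventional, the rest are a
  readable log-ish spacing).
* Ranked top-N tables are filtered to significant transcripts of one
  direction with a non-empty ortholog accession, sorted by ratio
  descending, ties broken by p-value then contig id. The p-value is the
  admission filter, not the sort key. A flag admits unannotated rows for
  completeness listings.
* "More abundant in X" uses strict relative-frequency inequality (raw
  counts are incomparable across libraries of different depth).
* The high-abundance list takes relative frequency > 0.005 (strict) in
  either library — the handful of transcripts that dominate a two-library
  scatter plot.

## GO-term overrepresentation

Each GO term on ≥ 1 annotated contig of the up- or down-regulated sets is
tested with a two-tailed Fisher exact test on the 2×2 table (contigs
with/without the term × up/down set). Two-tailed means summing all
hypergeometric point probabilities ≤ the observed one, with a 1e-7
relative tolerance on the comparison — the convention of R and the common
enrichment tools. Only contigs carrying ≥ 1 GO term participate; each
contig counts once per term. Adjusted values use Benjamini–Hochberg
step-up (the standard choice where only "an FDR filter" is conventional),
reported at threshold 0.01 by default. Terms are tested exactly as
annotated — no ontology-ancestor propagation, since annotation pipelines
typically emit already-expanded term lists and propagation rules vary.

## Guilt-by-association networks

The network stage does not predict interactions: it consumes a prior
edge table (accession pairs with an interaction probability from curated
databases or an external predictor) and restricts it to the selected
transcripts (significant at alpha, top-N per direction, or high relative
frequency). Nodes carry expression direction and counts; edges carry the
prior probability and a `significant` flag for probability > 0.9
(strict). Cross-direction edges are kept — bridging the up- and
down-regulated groups is exactly what makes such networks informative.
Exports: SIF (`id interacts id`, isolated nodes on their own line) and
GraphML with all attributes.

## Synthetic data generator

The generator emulates a deep two-library run with planted truth:

1. baseline abundances: log-normal weights (default log-sd 1.8),
   normalised — this reproduces the observed heavy tail in which most
   contigs draw 1–5 hits while a few draw hundreds;
2. DE assignment: fractions `pi_up`/`pi_down` (defaults 0.10/0.08,
   the order observed in deep two-library comparisons) drawn uniformly
   from eligible contigs (optionally restricted to baseline expectation ≥
   `min_expected_de` hits);
3. fold changes: `exp(±|N(log_fold_mean, log_fold_sd)|)` applied to the
   second library's weights, which are then renormalised (so planted
   "null" contigs still experience a small compositional shift — as they
   do in real relative-abundance data);
4. counts: multinomial draws conditional on the exact library totals
   (defaults 125,456 and 99,632), matching the conditioning of the test;
5. annotations: per-term Bernoulli assignment with heavy-tailed term
   prevalences scaled to a mean density (default 0.87 terms/contig over a
   200-term vocabulary, so ~40% of contigs are annotated); planted terms
   get a fixed common prevalence (default 0.1) multiplied by their
   enrichment factor on up-truth contigs, validated ≤ 1 before sampling.

All draws come from one `numpy.random.default_rng(seed)` stream in the
order above, so outputs are bit-reproducible from the config.

What the generator does **not** emulate: sequencing error and assembly
artifacts, between-replicate biological variance (none exists in the
design), correlated annotations along the GO hierarchy, and any
relationship between abundance and annotation status. Passing recovery
tests therefore demonstrate the statistical machinery, not robustness to
those real-data features.

### Validation scenarios

The test suite uses fixed scenario sizes chosen to probe distinct regimes:

* **Null calibration**: m = 10,000 contigs, no planted signal. The
  fraction significant at alpha 0.05 stays within binomial noise of the
  nominal level (measured ~0.050–0.054). The one-tailed convention is
  near-nominal on well-expressed contigs and conservative only in the
  low-count strata.
* **Strong-signal recovery**: m = 13,169, e² median folds planted on 8%
  of contigs restricted to expectation ≥ 20 hits. Power > 0.9 and
  direction accuracy > 0.99 across 10 seeds. The empirical FDR of the
  uncorrected alpha = 0.05 screen in this scenario is high (~0.6): with
  near-nominal false-positive rates and ≤ 9% planted prevalence,
  FP/(FP+TP) is large by arithmetic necessity, and compositional dilution
  from up-folds on mass-heavy contigs adds to it. This is a property of
  the uncorrected screening design itself and is reported as measured.
* **Planted enrichment**: m = 2,000 with 100+100 strongly differential
  contigs and one GO term at enrichment factor 4 on the up set; the term
  is recovered as the top hit at FDR < 0.01 with no decoy reported
  (10/10 and 10/10 seeds measured).

## Limitations

* No replicates → no overdispersion estimate; p-values are exact only
  under pure sampling noise and should be read as screening statistics.
* The significant set is not FDR-controlled (by design, matching the
  classic workflow); use the enrichment stage's BH adjustment, or apply
  one externally, where error control matters.
* Relative frequencies are compositional: strong changes in a few
  abundant transcripts shift every other transcript's relative frequency.
* The network stage is only as good as the supplied prior table; it
  performs no inference.
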