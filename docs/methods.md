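# Methods

## Scoring model

The pipeline assumes an arrayed colony screen in which each physical plate
(one per temperature × replicate × grid chunk) carries a multiplicative
growth offset shared by all its colonies (media batch, stack position,
incubation humidity). Plate-median normalization removes exactly this
structure: `NG = size / median(plate)` is invariant under rescaling every
colony on a plate by any k > 0, and with ~1,500 colonies per 32×48 plate a
few dozen strong interactions cannot move the median materially. The median
is therefore taken over **all** non-missing library colonies, hits
included.

Order of operations is fixed as colony → replicate → ratio: NG is computed
per colony, replicate NG values are aggregated per gene and temperature by
their **median** (robust to one failed pinning in a triplicate design;
genes with fewer than `min_replicates = 2` usable replicates are flagged
`LOW_REPLICATES` but still scored), and only then is `NGR =
NG(19°C)/NG(30°C)` formed from the aggregates. Aggregating before taking
the ratio keeps a single bad replicate at one temperature from
contaminating the ratio.

Degenerate sizes: a missing colony is an absent row (no NG); a measured
size of 0 is a dead colony — legal as the cold-temperature numerator
(NGR = 0, log₂ NGR = −∞, excluded from outlier calling as non-finite and
reported in the excluded side table) and illegal as the reference-
temperature denominator (`ZERO_SIZE` flag, NGR undefined, gene retained
for 30 °C-only analysis).

## Outlier calling

Both callers operate on a log₂ statistic (`log2_ngr` for cold-specific
effects, `log2_ng_30` for interactions at the permissive temperature; the
routing is a pure, logged function of the analysis goal).

* **2 SD rule.** Center = distribution median (robust against the
  interaction tails); spread = sample SD with n−1 denominator. Whether the
  SD is taken about the mean (default) or the median is a recorded
  configuration field (`sd_center`), since the two centerings give slightly
  different thresholds on skewed screens. A zero SD is an error: no
  threshold exists.
* **Top 25th percentile.** Applied per direction (suppressor and
  synthetic-sick lists are compiled separately): the k = ⌈0.25·n⌉ largest
  (or smallest) values, selected by rank rather than by an interpolated
  quantile so the selection cannot drift across quantile-algorithm
  dialects. Ties at the boundary value are all included when that grows
  the list by at most ⌈0.01·n⌉ genes; otherwise the tie is broken by
  lexicographic gene identifier. The rule is deterministic and is mirrored
  by an independent brute-force implementation in the test suite.

## Multi-screen classification

* *Query-specific filtering*: a primary-screen hit is removed when the
  comparison screen shows a same-direction effect of at least
  `similarity_fraction = 0.5` of the hit's magnitude, or is itself a
  same-direction hit there. The screens state no numeric rule for
  "similar interaction", so the fraction is an explicit, logged parameter.
* *Suppressors*: positive-direction log₂ NGR hits of the taz1 screen
  (default caller: top 25th percentile).
* *Reverters*: negative-direction log₂ NGR hits in **both** double-query
  screens (intersection — both alleles query the same mitotic function),
  AND quiet in both single-mutant screens. "Quiet" means not a 2 SD
  outlier in either direction and |log₂ NGR| ≤ `single_mutant_tolerance_sd
  = 1` spread of that screen's own distribution. The tolerance is defined
  relative to the empirical spread because absolute effect sizes depend on
  noise level and replicate count. Top-quartile membership alone is
  deliberately *not* used as evidence of a single-mutant effect: in a
  null-like screen a quarter of genes occupy each tail by construction.
  Genes lacking a usable statistic in any required screen are reported as
  `unclassifiable`, never silently dropped.

Classification is a pure function of score tables and hit lists; input row
order never changes an assignment. When one gene satisfies several class
rules it takes the most evidence-specific class (reverter > suppressor >
query-specific negative).

## Enrichment

Over-representation of ontology groups uses the one-sided (upper-tail)
hypergeometric test via `scipy.stats.hypergeom.sf` with Benjamini–Hochberg
adjustment (`statsmodels`), the standard desk replacement for interactive
web enrichment tools. The universe is the set of genes actually scored
(post-QC) in the relevant screen, conditioning on testability;
unannotated genes stay in the universe and inform N. Terms with fewer than
`min_term_size = 3` annotated universe genes are skipped. The annotation
is treated as a flat, pre-slimmed term set — no ontology-graph ancestor
propagation.

## Synthetic screens

The generator emulates: per-strain intrinsic fitness offsets (log-normal,
SD 0.1 natural-log units, shared across screens since the same library is
crossed into every query), per-plate multiplicative effects (log-normal,
SD 0.15), per-colony log-normal noise (SD 0.5 on the log₂ scale — chosen
for planted-effect recoverability, as no replicate-variance figures exist
to calibrate against), colony dropout (2%, absent rows), technical
triplicates, and a 32×48 grid with genes split across numbered plates when
capacity is exceeded. Planted fitness factors multiply the expected size
outside the exponential noise term, so power-of-two factors survive
scoring exactly in noise-free runs. An optional first/last-row edge
penalty exists but is off by default. One master seed drives everything;
per (query, temperature, replicate) streams are derived by fixed
arithmetic (label CRC + indices), so adding a query screen never perturbs
another's data.

The default five-screen study scenario plants 40 suppressors (log₂ NGR
+3) and 40 shared-sickness genes (log₂ NG30 −3) in the taz1 screen, 40
reverters (log₂ NGR −3 in both double screens, neutral in the singles),
20 "fake reverters" (sick in the singles as well — the classifier must
reject them), and a background of 10% of the library per screen with
|log₂ NGR| effects uniform on [2, 4] of random sign. The background
emulates the broad genuine-interaction spectrum of a real query screen;
it also sets the empirical spread against which the single-mutant
tolerance is measured. What the simulation does **not** model: spatial
gradients within plates beyond the optional edge penalty, correlated
pinning failures, growth-curve kinetics, batch effects shared across
replicates, or selection-marker artifacts — so passing tests demonstrate
correctness of the analysis under the stated noise model, not robustness
to every artifact of real plate data.

## Numerical choices

* Equality tolerances: log₂ fields are consistent with their linear
  counterparts to 1e−12 relative; scale invariance of NG is asserted to
  4 ulp; all other float comparisons at 1e−9 relative unless stated.
* Plates whose median is undefined or ≤ 0 are excluded with a logged
  warning and listed in the score table's metadata.
* Deterministic ordering everywhere: hit lists sorted by (strength, gene
  id), enrichment by (p-value, term id), TSVs written with `%.17g` floats
  so write→read round-trips are exact.
* Problem sizes in the test and acceptance runs (2,000-gene five-screen
  scenarios over 20 seeds; 1,000 randomized caller instances; exhaustive
  enumeration up to N = 12 for the hypergeometric oracle) were chosen to
  make the Monte-Carlo margins comfortably narrower than the asserted
  bounds.

## Known limitations

* The percentile caller's rank-based definition guarantees ~25% of genes
  per tail are "hits" even in a null screen; intersection-based classes
  (reverters) therefore pick up chance overlaps under this caller. The
  2 SD caller is the conservative alternative and is what the reverter
  filter uses for single-mutant exclusion.
* Whether replicate aggregation should precede or follow the NGR ratio,
  and whether the outlier SD is mean- or median-centered, are genuinely
  open protocol choices; the pipeline fixes aggregate-then-ratio and
  mean-centered SD, and exposes `sd_center` in the configuration echo so
  a run's provenance is explicit.
* Enrichment p-values inherit the usual caveats of over-representation
  analysis on correlated gene sets; they are conservative under the null
  (discrete test) but not corrected for annotation redundancy.
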