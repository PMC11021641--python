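# Methods

## The problem

Over-representation analysis (ORA) ranks gene sets — GO terms, KEGG /
Reactome / WikiPathways pathways — by how strongly their members are
enriched among differentially expressed (DE) features. The annotation
databases behind those sets churn: members are added and removed between
releases, whole pathways are merged or retired. A set whose enrichment
depends on a handful of member features can move hundreds of rank
positions when a few of them disappear, and a biological interpretation
built on such a set does not reproduce. `bootrank` quantifies that
fragility by re-running the enrichment on random subsamples of the gene
universe and asking which sets keep their rank.

## Pipeline

1. **Original analysis.** DE features are selected from the upstream
   differential-expression table (default: adjusted p < 0.05, no
   fold-change filter; a raw-p + |logFC| mode is available). Each gene set
   (intersected with the measured universe, size filters 5–5000) is scored
   with the one-sided hypergeometric test: for a universe of N features
   with K selected and a set of n members overlapping k of them,
   p = P(X ≥ k), X ~ Hypergeometric(N, K, n). Sets are ranked by ascending
   p with mean ranks for ties, so ranks always sum to N(N+1)/2.
2. **Subsampling ("bootstrap") replicates.** Each of B replicates
   (default B = 100) draws floor(f·N) features without replacement
   (default f = 0.95), restricts the DE selection and every set to the
   subsample, re-applies the size filters and re-ranks. Set compositions
   therefore differ in every replicate, which is exactly the perturbation
   annotation churn produces. The DE statistics themselves are *not*
   recomputed — the DE model is upstream of this pipeline and its output
   table is the input contract; a replicate only intersects the already
   selected features with its subsampled universe.
3. **Rank aggregation.** Replicate ranks are normalised by the replicate's
   list length; a set missing from a replicate (filtered out there)
   contributes the worst normalised rank 1.0, which is how survival across
   replicates enters the score. The aggregation score is the
   RobustRankAggreg-style uniform-order-statistic statistic
   rho = min_k P(U_(k) ≤ r_(k)), with P(U_(k) ≤ r) the Beta(k, m−k+1) CDF.
   All k = 1..m enter the minimum. rho is monotone (worse ranks can never
   lower it) and permutation invariant. By default rho is reported
   uncorrected — it is only transformed into a rank; a Bonferroni-style
   ×m correction is available behind a flag for users who want
   conservative score values.
4. **Robustness diagnostics.** gain = original rank − aggregated rank
   (positive: gained evidence, negative: lost, zero: retained; retained
   requires exact tie-averaged-rank equality — ranks are rationals with
   denominator ≤ 2, so no tolerance is needed). The gain distribution's
   2.5% and 97.5% linear-interpolation quantiles flag sets with extreme
   losses/gains as unreliable. Quantile thresholds, rather than fixed gain
   cutoffs, adapt to the number of sets in the analysis.
5. **Multi-level integration.** Rankings from different omics levels (or
   independent studies — the machinery is identical) are restricted to
   their common set vocabulary, re-ranked within it (levels annotate
   different numbers of sets, so raw list positions are not comparable),
   normalised by the common-vocabulary size, and combined with the same
   rho score with m = number of levels. A set gets a small integrated
   score only when every level ranks it high.

## Synthetic benchmark

Real inputs for the published applications require repository downloads
and database snapshots, so the package ships a generator that emulates the
structure the pipeline consumes, at the p-value level (simulating
expression matrices would exercise out-of-scope upstream code):

* p-values: Uniform(0,1) for the π₀ = 0.95 null fraction, Beta(a=0.15, 1)
  for alternatives, Benjamini–Hochberg adjustment; log fold changes from a
  symmetric two-component normal model (σ = 0.3 around 0 for nulls,
  |N(2, 0.5)| with random sign for alternatives).
* Default universe 5,000 features with 200 background sets of 10–80
  uniformly drawn members — a mid-sized expression study.
* 10 **robust** planted sets: 50 members, half drawn from the features
  passing the DE selection, so the enrichment signal is spread over many
  members and survives any 5% subsample.
* 10 **fragile** planted sets: exactly 2 DE driver members among
  otherwise-null members, with the set size chosen (by scanning the
  hypergeometric tail) as the largest at which the two drivers are jointly
  significant at p < 0.05 but dropping a single driver from the universe
  flips the decision. Fragility is thus defined operationally — few
  drivers whose removal flips the call — matching the mechanism the
  subsampling probes.
* The paired-level generator uses a smaller layout (2,000 features, 60
  background sets) and plants 8 sets enriched in both levels, 8 per level
  enriched in exactly one (background composition in the other), and 5
  vocabulary-exclusive sets per level so the intersection step is
  non-trivial.

What passing these benchmarks shows: the pipeline separates
spread-out from driver-dependent enrichment signal and rewards
cross-level consistency, under an idealised null (independent uniform
p-values, no inter-feature correlation, no batch structure). What it does
not show: behaviour under correlated features, overlapping-set
redundancy at GO-hierarchy scale, or count-level noise — real-data
properties the generator deliberately does not model.

## Numerical choices

* Hypergeometric tails come from `scipy.stats.hypergeom.sf`, computed in
  log-stable form; agreement with exact rational enumeration is at the
  1e-16 level for all instances with N ≤ 12 (checked exhaustively).
* Tie detection before rank-averaging uses *relative* rounding to 40
  mantissa bits (~12 significant digits, `round_significant`). Absolute
  rounding at 1e-12 would collapse every p-value below ~5e-13 — common at
  the top of a real enrichment ranking — into one giant tie; relative
  rounding merges only floating-point noise.
* Per-replicate RNG streams are spawned as `default_rng([seed, b])`, a
  splittable counter scheme: enlarging B extends the rank matrix without
  reshuffling earlier replicates, and identical inputs give bitwise
  identical matrices.
* Subsample size is floor(f·N); f = 1 makes every replicate identical to
  the original analysis and the whole pipeline reduces exactly to it (an
  end-to-end regression test).
* Degenerate inputs: an empty DE selection is legal (all enrichment
  p-values become 1, a warning is logged); a set absent from every
  replicate scores rho = 1; quantile flagging needs at least two gains.

## Statistical testing conventions

The planted-signal and multi-level benchmarks are judged by sign tests
over independent simulation seeds (20 single-level seeds, 50 paired
simulations) at p < 0.05. The Monte-Carlo validation of rho uses 1e5
draws per instance and a 3-standard-error band per instance; since ~0.5
chance crossings are expected among 200 instances, the suite asserts the
family-level binomial bound (at most 3 crossings) plus a median deviation
under 1 SE, and compares at the binding order statistic k because the
minimum over k of noisy tail estimates is biased low. Benchmark problem
sizes (B = 50 with 5,000 features for the single-level study, B = 15 with
2,000 features for the 50 paired simulations) were chosen as the smallest
at which the planted effects are unambiguous, keeping the default suite
fast.

## Limitations

* Only Fisher/hypergeometric ORA is built in. The scorer interface is
  pluggable (any callable producing the ranking-table contract), but
  preranked permutation GSEA and GO-hierarchy-aware scorers are not
  provided.
* The aggregated ranking is score-based, not p-value-based: there is no
  natural significance threshold on rho once it has been transformed into
  a rank; the gain quantiles are the intended selection device.
* Feature identifiers are matched as exact strings; cross-platform or
  cross-species identifier mapping must happen upstream.
* Kendall τ between levels is provided as a descriptive utility; on the
  synthetic benchmark the two levels share only a few planted sets, so
  global τ values are near zero by construction.
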