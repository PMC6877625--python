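# Methods note

## Model

A country's food-system sustainability is summarized hierarchically:
normalized indicator values in [0, 1] → four dimension scores → one aggregate
score. Let x_{ci} be the collapsed (window-mean) value of indicator *i* for
country *c* over the scored country set *S*.

**Normalization chain** (per indicator, over exactly *S*):

1. *Year collapse*: arithmetic mean of the observations inside the analysis
   window (a "latest value" collapse is also available).
2. *Special transform*: water pH is folded to |pH − 7|; the folded deviation
   is monotone-negative in sustainability regardless of the original sign.
3. *Box-Cox*: applied iff the bias-corrected (adjusted Fisher-Pearson) sample
   skewness exceeds 2 in absolute value; λ by profile maximum likelihood
   (scipy); series containing values ≤ 0 are shifted by 1 − min first
   (order-preserving).
4. *Orientation*: negation for indicators whose raw direction is
   "larger = less sustainable", so larger always means more sustainable.
5. *Min-max*: (x − min)/(max − min) over *S*. The bounds belong to the
   country set: scoring a different set rescales every indicator, which is
   exactly the instability the stabilized chain (below) manages.

Every step is logged in a per-indicator provenance record (steps, effective
sign, skewness, λ, bounds, window).

**Aggregation.** Dimension rules: arithmetic mean for economic and food &
nutrition (internally correlated blocks), geometric mean for environment and
social (weakly correlated blocks); the aggregate score is the geometric mean
of the four dimension scores. Min-max produces exact zeros (some country
holds each minimum), so values are floored at EPS_FLOOR = 1e-3 before any
geometric product; without the floor a single minimum would annihilate the
aggregate. A single indicator is its own dimension score under either rule.
Ranks use competition ranking ("1224"), descending.

## Coverage trade-off and stabilized selection

The availability matrix marks (country, indicator) pairs with at least one
observation in the window. A combination is admissible if it has ≥ 4
indicators covering all four dimensions; its country set is the set of
countries complete on all its indicators. The trade-off frontier keeps, per
indicator count *k*, the combination with the largest country count (ties:
lexicographically smallest indicator set). Exhaustive enumeration is
available at small scale; at full scale a backward best-removal beam search
(default width 5) explores the subset lattice from the top.

The backward chain starts at the largest frontier combination covering at
least two countries and repeatedly removes the single indicator whose removal
frees the most countries (ties: smallest indicator id), down to k = 4. By
construction the indicator sets are nested and the country sets grow
monotonically; consequently the country dropout between adjacent levels is
never negative.

**Selection criteria**, computed on the chain's per-level score tables:

- *dropout*: countries lost from level k−1 to k;
- *score_sd*: population SD (ddof = 0) of the across-country mean aggregate
  score over levels k_min..k (cumulative mode; an adjacent two-level mode is
  available);
- *rank_shift*: mean absolute rank displacement between adjacent levels over
  the shared countries (a Kendall-distance variant is available).

Each criterion is min-max normalized over the candidate levels and the three
are summed with equal weights. The base level k = 4 has no incoming
transition, so it is excluded from the candidates (its normalized values are
NaN); including it would make the trivial four-indicator index win by
construction. Ties resolve to the smaller k; a single-level chain selects
itself.

## Sensitivity and temporal analyses

*Perturbation sensitivity*: per scenario (10 or 20 random countries × rate
10/20/30% × dimension), the raw values of the dimension's first registry
indicator in the combination are multiplied by (1 + rate) for the drawn
countries, the normalization chain is re-run for that indicator (bounds
recomputed, so spillover onto unperturbed countries is included) and the
percent change of the across-country mean aggregate score is averaged over
replicates. Each grid cell draws its own child seed (< 2^31) from a
SeedSequence, so grids are bit-identical under a fixed seed. A zero rate
yields exactly 0% change. Because single-indicator dimensions pass a
perturbation straight to the dimension score while a 12-indicator dimension
dilutes it twelvefold, matched perturbations move the aggregate far more
through thin dimensions.

*Sub-period scores*: years are collapsed within each sub-period (default
2000–03 / 04–06 / 07–09 / 10–12 / 13–16) and the whole transform chain is
fitted on the pooled (country, period) values, so scores are comparable
across periods and identical data in two periods scores identically.
Per-period renormalization is available as an option. (Country, period) rows
with incomplete data are dropped with a warning.

## Synthetic-data generator

Values are drawn from a Gaussian copula with per-dimension equicorrelation
(Cholesky), shifted by a latent per-country sustainability propensity whose
sign follows the indicator's orientation. Marginals: normal by default,
lognormal (σ = 1.0) for "high-skew" indicators, and pH generated as
7 + 0.8·w·exp(−0.4·effect·propensity) so that better countries sit closer to
neutral. Coverage models: full, random (i.i.d. Bernoulli) and blocky
(contiguous block on one seeded country permutation, wrap-around — similar
marginal counts, structured overlap). Country codes are ISO-style triples
(AAA, AAB, …).

Packaged profiles:

- `table2_profile`: mirrors the packaged 27-indicator registry
  (8/3/3/13 per dimension), coverage fractions equal to each indicator's
  source country count out of 249, two heavily skewed indicators, the pH
  special transform.
- `sweet_spot_panel`: a panel engineered so the selection criteria are
  jointly minimized at a known k\*. Design: a quiet base quartet (one
  indicator per dimension) plus mid-chain "contrarian" indicators that carry
  the *same value multiset* as their dimension's base indicator, reassigned
  in propensity-opposed order — arithmetic dimension means are
  permutation-invariant, so these indicators reshuffle ranks while they are
  being traversed but leave level means untouched; one contrarian sits in a
  geometric dimension and produces a single stable mean drop just above
  k_min. Cumulative score SD therefore peaks early and declines to k\*, where
  rank shift is also minimal. Partially covered noisy duplicates above k\*
  keep the frontier populated.
- `frontier_hopping_panel`: two opposed six-indicator families over 30
  countries; family *a* sits on rotating 20-country windows (the per-k
  frontier optimum loses two countries per added indicator), family *b*
  shares one spread-out 11-country set and opposes family *a*'s ordering. The
  per-k frontier jumps wholesale from *a*-subsets to the all-*b* subset,
  churning bounds and rankings, while the backward chain stays within one
  family — the fixture that isolates the stabilization effect.
- `parameter_recovery_suite`: fits the full pipeline on generated panels and
  reports the propensity–score Spearman ρ (over each country's mean score
  across the chain levels that include it — the union of scored countries,
  not one possibly tiny combination), a null simulation, beam-vs-exhaustive
  frontier agreement and the sweet-spot recovery rate. The null simulation
  uses a zero propensity effect with full coverage at 250 countries: the null
  Spearman's sampling SD is then ≈ 1/√249 ≈ 0.063, so the estimate resolves
  zero correlation instead of echoing small-sample noise.

## Numerical choices

- EPS_FLOOR = 1e-3 inside all geometric means; skewness threshold 2 (bias-
  corrected); Box-Cox shift 1 − min when min ≤ 0; constant series: skewness
  defined as 0, min-max maps to 0.5 with a warning (degenerate toy inputs
  remain usable).
- All simulation seeds are spawned from `numpy.random.SeedSequence` and
  reduced modulo 2^31, so derived seeds stay in 32-bit signed range.
- Spearman matrices require ≥ 3 countries; constant columns are reported as
  NaN.

## Limitations

- The beam search is heuristic: combinations missed by the beam cannot appear
  on the frontier. Exhaustive mode is exact but exponential, intended for
  ≲ 12-indicator pools.
- The criteria weights are fixed and equal; the selection is a transparent
  convention, not an estimator with sampling theory.
- Min-max bounds, and hence every score, are relative to the scored country
  set and window; scores are not comparable across different country sets
  unless bounds are pooled (as the sub-period analysis does).
- The generator's coverage patterns are stylized (Bernoulli or contiguous
  blocks on one permutation); real missingness is more structured.
- No inferential uncertainty is attached to scores or ranks; the sensitivity
  grid quantifies specific perturbations only.
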