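# Methods

This note records the statistical model behind the package, the
defaults and the reasoning for every genuinely open design choice.

## Pipeline model and assumptions

The package targets balanced factorial experiments laid out in
randomized complete blocks, with optional within-plot pseudo-replication
(several plants per plot). The analysis chain is:

1. **Plot means.** Plants within a plot are averaged first, so the
   experimental unit entering every later stage is the plot. Missing
   plants are simply dropped from their plot mean; a plot with no
   observation at all for some trait is an error rather than an imputed
   value (the means table must be complete, and imputation policy is a
   modelling decision we refuse to make silently).
2. **MANOVA screen.** The fixed-effects multivariate linear model
   `Y = Xb + e` is decomposed sequentially (blocks first, then main
   effects, then interactions). On balanced data the decomposition is
   orthogonal, so it coincides with every sum-of-squares type;
   unbalanced data is rejected outright because marginal means would
   then depend on the SS convention. Pillai's trace `V = tr[H(H+E)⁻¹]`
   is the test statistic, converted to an F statistic with the standard
   approximation (`s = min(p, q)`, `m = (|p−q|−1)/2`,
   `n = (v_e−p−1)/2`, `F = ((2n+s+1)/(2m+s+1)) · (V/s)/(1−V/s)` on
   `(s(2m+s+1), s(2n+s+1))` df). The screen is advisory: it flags which
   terms justify a means table, but the user may rank any term.
   The block term is included by default; an `include_block=False`
   switch fits the pure factorial model `X` (n × m, m = product of
   treatment-factor levels), whose error df can be recognized in
   published factorial MANOVA tables of this design family.
3. **Rescaling.** Per trait, a linear map sends the observed column
   extremes to {0, 100} with 100 at the declared desired pole. The
   bounds are taken from the table being rescaled, not from external
   reference values — the index is a *within-experiment* ranking.
   A constant column is dropped with a warning (strict mode raises):
   the map is undefined there and a constant trait cannot rank anything.
4. **Factor analysis.** Pearson correlation of the rescaled means,
   eigendecomposition, Guttman-Kaiser retention (strictly > 1, floored
   at one factor), principal-component loadings, varimax rotation,
   regression-style scores through the Moore-Penrose pseudo-inverse.
5. **Index.** Ideal scores from the all-100 row, Euclidean distance,
   stable ascending ranks, per-factor distance shares, selection
   differentials on the original mean scale.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `direction` (per trait) | required | which pole is desirable; the single piece of domain knowledge the index needs |
| `weight` θ (per trait) | 1 | multiplies the standardized ideal before projection; >1 inflates the factor carrying the trait and pulls selection toward it |
| `new_max`/`new_min` | 100 / 0 | rescaling bounds; changing them rescales distances globally but not ranks |
| `n_factors` | eigenvalues > 1 | retention override for sensitivity analysis |
| `kaiser_normalize` | True | Kaiser row-normalization inside varimax; the dominant convention in reference implementations. It changes loadings at the second decimal, so the switch is exposed for cross-checks |
| `k` (selected) | ⌈g/2⌉ | selection intensity; entirely the analyst's call |
| `alpha` | 0.05 | MANOVA flag threshold, advisory only |
| `include_block` | True | block term in the MANOVA model |

## Numerical choices

- **Pseudo-inverse everywhere `R⁻¹` appears.** The flagship use case
  (few treatments, many traits) makes `R` singular by construction
  (rank ≤ g − 1). Rank is detected at `largest σ × 1e-10`; a warning is
  emitted whenever the pseudo-inverse path is taken.
- **Sign convention.** Every loading/score column is flipped so its
  largest-|entry| is positive. This pins the output across eigensolvers;
  the index itself is provably invariant to these sign choices (tested).
- **Varimax.** Cyclic pairwise Givens rotations with the closed-form
  optimal angle per pair, iterated until the criterion improves by less
  than 1e-10 or 1000 sweeps. With Kaiser normalization the returned
  rotation matrix satisfies the rotation identity on the row-normalized
  loadings (the usual convention); without it,
  `rotated = loadings @ T` exactly.
- **Ties in ranking** are broken by input order (stable sort); a tie
  exactly at the selection boundary logs a warning.
- **SD% with a zero overall mean** falls back to the absolute
  difference, flagged in the output, since the percentage is undefined.
- **Desired-sense counting** treats SD% = 0 as desired: no movement is
  not adverse.

## Weighting semantics

Trait weights act on the *ideal* only: the standardized all-100 row is
multiplied elementwise by θ before the score projection. This is the
literal reading of weighting the ideal's score vector, and it produces
the intended behaviour — the factor containing an upweighted trait gets
a proportionally larger ideal score, shrinking the distance of
treatments strong in that factor. A factor-level mode
(`weight_mode="factor"`) is exposed as the explicit alternative reading,
multiplying the projected ideal scores by a length-f weight vector.
Unit weights reproduce the unweighted index bitwise.

## The trial simulator

`simulate_trial` draws from the additive Gaussian RCBD model
`y_ijt = μ_t + τ_it + β_jt + ε_ijt` with treatment effects, block
effects and residuals all Gaussian, residuals drawn jointly across
traits through a symmetric PSD square root of the declared correlation
matrix. Defaults — grand mean 100, unit treatment/block/residual SDs,
identity correlation — are a generic agronomic-trial scale chosen once.
One integer seed drives a single `numpy.random.Generator`.

`planted_best_scenario` adds a deterministic shift of
`effect_size × residual_sd` to one treatment, toward the desired pole
of every trait, making it the true ideal for recovery tests.

What the simulator does **not** emulate: non-Gaussian traits, spatial
field trends, genotype-by-environment structure, unbalanced or missing
plots, and heteroscedasticity across treatments. Tests passing on these
simulations therefore certify the *algorithm* (identities, oracle
agreement, calibration, recovery under the assumed model), not
robustness of the index to real-data pathologies.

Problem sizes used by the default test run and the acceptance script —
5 treatments × 4 blocks with 3–6 traits, 200 replicates for recovery
rates and 1000 for the null calibration — were chosen as the smallest
sizes at which the Monte-Carlo error of the reported rates is a small
fraction of the margins being checked.

## Known limitations

- **Pillai F conservatism.** The standard F approximation for Pillai's
  trace is conservative when the error degrees of freedom are small
  relative to `s = min(p, q)`: at 5 treatments × 4 blocks × 3 traits
  (12 error df, s = 3) the null rejection rate at α = 0.05 is ≈ 0.026
  rather than 0.05. This is a property of the approximation itself —
  the per-dataset statistics agree with independent MANOVA
  implementations to ~1e-10 — and it fades as the error df grow.
  Screens at this design size are conservative, not anti-conservative.
- **Rank-deficient factor space.** With g treatments and p ≥ g traits,
  the retained factors always explain 100% of the variance and the
  factor solution is driven by at most g − 1 dimensions; loadings
  should be read as descriptive, not inferential, in that regime.
- **Positively correlated traits with opposite goals** end up in the
  same factor, where the index cannot push them in opposite directions;
  this is intrinsic to any factor-space distance.
- The MANOVA front-end handles complete balanced designs only, by
  design.
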