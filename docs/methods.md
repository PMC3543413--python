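# Methods

## Data model

A *sampling record* is one input of occurrence information (a collection
sheet, a relevé, a field observation) contributing one or more species to
exactly one *sampling unit* (typically a grid cell). Units are represented
as binary record-by-species incidence matrices; species identity is an
opaque string (no taxonomic normalization), and a record with no species
cannot exist — accumulation theory assumes every sample contributes
incidences, so the loader rejects empty species cells.

## Accumulation curves

Two interchangeable constructions of the expected curve S(n), n = 1..H:

- **Permutation mean** — cumulative distinct-species counts averaged over
  `n_perm` uniformly random record orderings (default 1000), with the
  across-permutation SD. Implemented by ranking each record per
  permutation and histogramming each species' first appearance, so cost is
  O(n_perm · H + S · n_perm) per unit.
- **Analytic (Mao Tau)** — the exact expectation via hypergeometric
  absence probabilities, τ(h) = S_obs − Σ_j s_j · C(H−j, h)/C(H, h), with
  s_j the number of species occurring in exactly j records. Binomials are
  evaluated in log space (Γ-function form) so H ≈ 100 does not overflow.

The permutation mean converges to τ as n_perm grows (asserted in tests);
τ is deterministic, so slope-type measures use it by default. Accumulation
is record-based throughout: the effort axis is sampling records, not
individuals.

Reproducibility contract: one root seed per run; per-unit generators are
seeded by (root, unit-id CRC), so unit iteration order never changes
results.

## Completeness measures

- **NPE** = S_obs / Jackknife-1, with Jackknife-1 = S_obs + Q₁·(H−1)/H
  (the classic incidence form; first order chosen as the conventional
  default). Values in (0, 1]; high = well sampled.
- **STE** = terminal secant slope (y_i − y_{i−1})/(x_i − x_{i−1}) of the
  Mao Tau curve; with unit spacing this equals τ(H) − τ(H−1), which is
  analytically Q₁/H. Low = well sampled.
- **FIDEGAM** = first derivative at n = H of a penalized-spline GAM fitted
  to the curve (below). Low = well sampled. All three measures require
  H ≥ 3; units below that are flagged unassessable rather than scored.

## The GAM

Single-smooth P-spline GAM with log link, written here (not wrapped):

- **Basis**: cubic B-splines on uniform knots extending `degree` segments
  beyond [1, H] (Eilers–Marx construction), dimension min(10, H−1); the
  degree drops below cubic only when H ≤ 4, where the model degenerates
  toward a log-linear GLM. Uniform extended knots matter: clamped boundary
  knots make the second-difference penalty act unevenly at the ends and
  visibly bias the terminal derivative.
- **Penalty**: second-order coefficient differences, S = D₂ᵀD₂; the
  penalty null space is the log-linear (exponential-mean) model.
- **Fitting**: penalized IRLS on the working response, Cholesky solves
  with a 1e−10 ridge; effective degrees of freedom
  edf = tr[(XᵀWX + λS)⁻¹ XᵀWX].
- **Smoothness selection**: UBRE with fixed scale 1,
  UBRE(λ) = D/n + 2·edf/n − 1, minimized on a 25-point log₁₀λ grid over
  [−6, 10] with golden-section refinement between the grid neighbours of
  the minimum.
- **Family**: Poisson first. If the Pearson statistic over the residual
  df exceeds 1.5 (a conventional conservative trigger), the dispersion α
  of an NB2 family is moment-matched on the Poisson residuals and the
  model is refitted. Permutation-mean curves are much smoother than raw
  counts, so in practice the Poisson family is retained there.
- **Derivative**: η′(n) from the analytic basis derivative, chain-ruled
  through the link, d(n) = exp(η(n))·η′(n). Pointwise 95% bands from 1000
  draws of the coefficients from N(β̂, (XᵀWX + λS)⁻¹) (the Bayesian
  posterior covariance), taking the 2.5/97.5 percentiles of d(n).

The fitter was validated against mgcv (`s(x, bs="ps"), family=poisson,
method="GCV.Cp")`): fitted values and terminal derivatives agree to a few
parts in 10³ on saturating test curves, and the test suite keeps one such
cross-check.

Two boundary behaviours are worth knowing. On a constant curve the fit
collapses to the penalty null space, so edf → 2 (not 1) while the
derivative is numerically zero. On short low-count curves (e.g. the
identity line over 10 records) the likelihood is weak and UBRE legitimately
buys the exponential-mean fit, whose terminal derivative exceeds the
arithmetic slope — mgcv shows exactly the same values. Over longer identity
curves the terminal derivative settles near 1 with a ~10% upward bias
intrinsic to the log-link smooth. Consequently FIDEGAM values are not
confined to [0, 1]: units whose records carry many species each can score
well above 1; such values are reported unclamped with a warning, since only
the ordering of units matters for discrimination and thresholding.

## Discrimination analysis

Labeling rules: (i) record count strictly above the median → well sampled
(ties below — a deterministic convention); (ii) with simulator truth,
completeness 100·SR_sub/SR_true strictly above 70% → well sampled. Scores
are oriented before ROC so larger always means better sampled (NPE as-is,
STE and FIDEGAM negated).

The logistic model P[S1|Y] = logit⁻¹(β₀ + β₁Y) supplies the predicted
probabilities (for the density diagnostics and the Youden back-mapping);
the AUC point estimate is the nonparametric Mann–Whitney pair statistic
(ties ½), which any monotone transform — including the logistic — leaves
unchanged. CIs are percentile intervals over 1000 class-stratified case
resamples. Under complete separation the GLM is flagged non-converged and
the empirical ROC on the raw scores is kept. The Youden cut c₀ maximizes
TPR − FPR over probability cut-points; the threshold is mapped back to the
measure's own scale through the fitted coefficients (and through the
orientation flip, so for FIDEGAM "above threshold" means poorly sampled).

## Simulator

The full database emulates an exhaustively prospected region: 180 units;
per unit an intensity level drawn uniformly from three record-count bins
(20–50, 51–80, 81–110); per record a species count uniform on [1, 30] drawn
without replacement from a common 400-species pool. True richness is the
unit's observed richness.

The low-exhaustiveness database re-runs that generation per unit using the
information the full database gathered: the record count is redrawn
uniformly on [3, min(25, H_full)] (the lower bound keeps every unit
assessable), and each new record draws min(U[1,30], 20, pool) species from
the unit's gathered species set. This preserves species-level nesting
(SR_sub ⊆ SR_true per unit), which is what makes 100·SR_sub/SR_true a
genuine detection percentage, and it ties the observable curve shape to
true completeness: with per-record detection probability q = c̄/SR_true,
the expected terminal slope c̄·(1−q)^h is proportional to one minus the
expected completeness 1−(1−q)^h.

What the simulator does *not* emulate: spatial autocorrelation, detection
heterogeneity among species (all pool species are exchangeable), abundance
structure, and taxonomic error. Passing validation here therefore shows the
measures behave correctly under uniform random sampling with known truth —
not that they are robust to niche-structured or biased field data.

Under these conditions the true-completeness labeling is strongly
imbalanced (typically only a handful of units exceed 70% detection), so the
AUC under that rule carries more seed-to-seed variability than the
median-record one.

## Distinctiveness workflow

Default index: mean pairwise Sørensen dissimilarity of a unit's species set
against the other units in scope; the metric is a plug-in (any callable on
two species sets), since published distinctiveness formulas vary. The
filtered re-analysis drops units whose FIDEGAM value exceeds the Youden
threshold and recomputes the index on the retained set only; unassessable
units (H < 3) are reported separately.

## Problem sizes and determinism

The full experiment (180 units, 1000 SAC permutations, per-unit GAM fits,
1000 bootstrap resamples) runs in a few seconds on one CPU, so tests and
the acceptance script use it at full scale. Every stochastic stage —
simulation, permutations, posterior draws, bootstrap — derives its
generator from the root seed and a stable per-purpose tag, so repeated runs
are byte-identical.
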