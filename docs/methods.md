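# Methods

## The measurement model

Source-monitoring data are multinomial: each test item of a given type
(true source × a-priori credibility) elicits one response out of a fixed
category set ("ad", "test", "new" for the two-source design; plus
"unknown" for the three-source design). The MPT model expresses each
category probability as a sum over tree branches of products of latent
process probabilities:

* `D_s` — probability of recognizing an item of type `s` as old (for new
  items: detecting them as new). The two-high-threshold assumption treats
  old- and new-detection symmetrically.
* `d_s` — conditional probability of retrieving the source given
  recognition; a recognized item without retrieved source falls through to
  guessing.
* `b` — probability of guessing "old" for an unrecognized item.
* `a` / `g` — source-guessing probabilities for recognized /
  unrecognized-but-guessed-old items. These carry the schematic-bias
  hypothesis: guessing "advertisement" should be more likely for
  statements that are implausible a priori.

Trees are duplicated per credibility level with suffixed parameter names
(`D_ad.high`, `b.low`, …); the base models impose no cross-credibility
equalities, so every substantive question is a testable restriction.

**Three-way guess nodes.** In the three-source model the guess over
{ad, test, unknown} is a simplex. Internally it is parameterized by two
binary stick-breaking parameters, `a_ad = P(guess ad)` and
`a_test = P(guess test | not ad)` (likewise `g_ad`, `g_test`), which keeps
every branch a plain product of `θ`/`(1−θ)` factors — the standard binary
MPT form that the likelihood and its gradient exploit. Equating `a = g`
on the stick-breaking parameters is algebraically equivalent to equating
the three simplex probabilities (verified in the tests), and conversion
helpers report guesses on the simplex scale.

## Identifiability and degrees of freedom

Per credibility level, the unrestricted two-source model has 8 parameters
against 6 free data categories (3 trees × (3−1)), hence df = −2: not
identifiable. The identifiable base model imposes `D_ad = D_test = D_new`
and `a_ad = g_ad` within each level, leaving 5 free parameters per level
and df = 2 over both levels. The three-source parsimonious base imposes
only `D_unknown = D_new` per level (df = 2 over both levels); the final
base additionally equates detection across all item types and `a = g`
(df = 10). Degrees of freedom are always computed on the restricted model
as free categories minus free parameters after resolving the restriction
graph (union-find over equality classes, with conflict detection for
contradictory constants), never by counting restriction lines — so the
Δdf of every catalogued hypothesis (1 for the single-parameter contrasts,
4 for detection-across-sources and for `a = g` over both levels) is
derived, not asserted.

A numerical local-identifiability check is provided: the rank of the
central-difference Jacobian of the stacked category probabilities with
respect to the free parameters at a reference point (singular values
thresholded at `1e−8` relative). Boundary reference points are perturbed
inward with a warning, since the Jacobian is one-sided there.

## Estimation

Fitting minimizes `G²(θ) = 2·Σ f·ln(f/(n·p(θ)))` with `0·ln 0 = 0` and
expected probabilities floored at `1e−12` inside logarithms. Free
parameters are optimized on the logit scale (smooth handling of the
[0, 1] box), with analytic gradients propagated through the branch
products, L-BFGS-B, and logits capped at ±25 (`expit(25)` differs from 1
by ~1e−11). Defaults: 20 starts (one at the hypercube center, the rest
uniform-random), early exit when a start reaches `G² ≤ 1e−9` (a perfect
fit). A start whose line search aborts after the optimum is reached —
which happens when an estimate sits on the boundary and the logit-scale
gradient flattens — is accepted when the projected gradient norm is below
`1e−3`. Non-convergence after all starts is flagged on the result, never
silent.

Data are pooled over participants into a single frequency table per
experiment (aggregate-data MPT fitting, one G² per experiment); `p`-values
use the χ² survival function at the model's df. For nested comparisons the
restricted model is refit from multiple starts; `ΔG²` values in
(−1e−6, 0) are clamped to zero as optimization noise, anything more
negative raises an error because it indicates a non-converged parent fit.

**Bootstrap.** Standard errors are parametric-bootstrap: `B` tables are
resampled from the fitted category probabilities at the observed per-tree
totals and refit (default `B = 1000`; random starts seeded from the
bootstrap seed, so a fixed seed is bit-reproducible). Replicates that fail
to converge are dropped with a logged count; more than 10% failures abort.
Equality-class members share their representative's SE; constants get
SE 0. Whether the original analyses used a parametric or nonparametric
bootstrap, and with how many replicates, is not documented anywhere we
could rely on; parametric with `B = 1000` is this package's documented
choice.

## Power

For a test with `df` restrictions at level `α`, power is
`P(X > χ²_{1−α}(df))` with `X ~ ncχ²(df, λ)`, `λ = N·w²`, and `w` Cohen's
effect size for chi-square tests. `N` is interpreted as participants ×
test items, matching the pooled-data likelihood. The inverse problem
(minimum detectable `w` at a target power) is solved by bisection to
`1e−6`; for the two-source design (N = 122×160, df = 1, α = .05) it gives
`w ≈ 0.0258`, i.e. 95% power comfortably covers effects of `w = 0.03`.

## The synthetic experiment generator

The generator emulates the two study designs exactly:

* exp1 — 122 participants; 20 studied items per credibility × source cell
  (40 + 40 studied), 40 new items per credibility; 160 test trials.
* exp2 — 111 participants; 13 per credibility × source cell over three
  sources (39 + 39 studied), 39 new per credibility; 156 test trials.

Per participant the 160-statement pool (80 per credibility level) is
freshly randomized into studied/new sets and source assignments. Test
responses are drawn from the generative MPT tree of the item's type;
ratings are truncated-normal on [−3.5, 3.5] around a cell mean
(phase × source × credibility), rounded to the −3..+3 grid. The cell SD
defaults to 1.5 — a free knob, since only standard errors of cell means
(not SDs) are typically reported for such ratings; the means for new test
items (0.80 high / −1.55 low) are likewise the package's own plausible
choice. The default memory parameters are a labeled synthetic fixture in
the empirically typical range (detection ≈ .75–.85, source memory 0–.4,
old-guessing .2–.35, advertisement-guessing higher for low than for high
credibility); they are generating values for tests and demos, not
estimates of any dataset.

What the generator does **not** emulate: participant heterogeneity (all
participants share one parameter vector, matching the aggregate-data
likelihood — a documented extension point), item effects, presentation
details (fonts, label timing, distractor task), and response times.
Passing recovery tests therefore show that the pipeline is correct for
the model it assumes, not that real data satisfy that model.

## Descriptive tables

The attribution table reports, per credibility × true source, the
cross-participant mean (±SEM) proportion of items attributed to
advertising. The default denominator is *all* items of the cell, counting
a "new" response as not-attributed; conditioning on items classified
"old" is available via `denominator="old"`. Which denominator underlies
published attribution figures is typically ambiguous; the default is
documented and both are supported. Rating summaries average within
participant first, then across participants. Hypothesis-test p-values are
reported unadjusted for multiple testing, and the report metadata says so.

## Test and acceptance problem sizes

The statistical calibration checks run at sizes chosen to make their
Monte-Carlo error small relative to the tolerance they assert: parameter
recovery uses 100 replicates of the full exp1 design (median absolute
estimation error per parameter ≤ 0.05); the type-I-error check uses 1,000
null simulations of the ΔG²(1) test (acceptance band 5% ± 2 points, vs. a
binomial SE of ~0.7 points); the grid-search oracle uses the
one-credibility-level base model (5 free parameters, 21 grid points each,
~4.1 M evaluations) because a dense grid over the full 10-parameter model
is combinatorially out of reach while the half-design exercises the same
likelihood code path; bootstrap scaling uses B = 150 replicates at two
sample sizes. The null-distribution Kolmogorov–Smirnov check against
χ²(1) uses 300 replicates in the unit suite.

## Known limitations

* Aggregate fitting ignores participant-level variability; parameter
  estimates are consistent for the pooled process, and hierarchical MPT
  extensions are out of scope.
* Only the 2- and 3-source × 2-credibility designs are catalogued;
  arbitrary models can still be built through the core tree machinery or
  the text format.
* Fisher-information standard errors and information criteria (AIC/BIC)
  are deliberately not provided; inference is G²-based with bootstrap SEs.
* The ΔG² calibration relies on interior true parameters; with true
  values on the boundary (e.g. a source-memory probability of exactly 0)
  the χ² reference distribution is conservative.
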