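# Methods

## Scale model

A dichotomous scale is a `ScaleKey`: item count, reverse-keyed items and
severity bands.  The built-in `ScaleKey.gds15()` encodes the 15-item
Geriatric Depression Scale short form: items 1, 5, 7, 11 and 13 score on a
"no" answer, all others on "yes", and totals are banded normal (0–4),
mild (5–8), moderate (9–11), severe (12–15).  Bands must be contiguous and
cover the whole score range, so severity labelling is a total function.

Missing answers propagate through scoring and are handled by **listwise
deletion only**: incomplete questionnaires are dropped from totals and from
every analysis stage.  Proration and imputation are deliberately not offered —
the analysis chain assumes complete response patterns, and any fill-in rule
would silently change the trait metric.  Item indices are 1-based everywhere
user-facing.

## 2PL calibration and EAP scoring

Items follow the two-parameter logistic model
P(Y_i = 1 | θ) = σ(a_i(θ − b_i)) with discrimination a_i and difficulty b_i.
The 2PL is the natural dichotomous member of the graded-response family that
logistic-DIF software conventionally pairs with ordinal items; since every
item here is binary, the 2PL is adopted as the measurement model.

Calibration is marginal maximum likelihood via Bock–Aitkin EM:

* **Quadrature**: 49 equally spaced nodes on [−6, 6] carrying normalized
  normal-density weights (default, configurable).  The node spacing of 0.25
  is fine enough that EAP scores agree with a 481-node grid to ~1e-10.
* **M-step**: per item, a damped Newton–Raphson weighted logistic regression
  of expected correct counts on node locations (slope/intercept
  parameterization, so items with near-zero discrimination stay numerically
  stable; b = −intercept/slope is derived afterwards).
* **Convergence**: max |Δparameter| < 1e-4, at most 500 cycles.  The marginal
  log-likelihood is asserted non-decreasing every cycle; hitting the cycle cap
  raises a `ConvergenceWarning`, never a silent success.
* **Degenerate items** (a single observed response category) are an error
  naming the item rather than being dropped, because silent dropping would
  desynchronize item numbering against the scale key.
* Items whose fitted |a| falls below 0.2 trigger a low-discrimination warning.

The **multi-group** fit constrains anchor items equal across groups while
each DIF item gets one (a, b) pair per group level.  The trait metric is
identified by fixing the reference group's prior to N(0, 1); focal-group
prior means and SDs are free and updated inside EM from the posterior
moments (anchor-based linking).  Whether the trait prior should be
re-estimated per group is genuinely open in this design space; free focal
moments are the simplest scheme that lets real group-level trait differences
("impact") be absorbed by the prior instead of leaking into item parameters.
An empty DIF set is the fully constrained model and is computed as the pooled
single-group fit.  EAP scores always use each person's group-specific
parameters and prior when they exist.

## Per-item DIF regression

Each item is tested through the nested binary logistic models
M0 (θ), M1 (θ + G), M2 (θ + G + θG), fitted by Newton–Raphson with
step-halving to a score max-norm below 1e-8.  Uniform DIF: G² = 2(lnL₁−lnL₀);
non-uniform: G² = 2(lnL₂−lnL₁); both χ² with L−1 df for an L-level group
(the group main effect and interaction are coefficient *blocks*, giving one
joint test per item even for 3-level factors).  Items here are yes/no, so the
ordinal-logistic formulation reduces exactly to binary logistic regression;
the proportional-odds generalization is out of scope for this version.

Effect sizes: Δβ₁ = |(β₁⁽M0⁾−β₁⁽M1⁾)/β₁⁽M0⁾| (undefined and reported as
not-available when β₁⁽M0⁾ = 0), ΔR₁ = 1 − lnL(M1)/lnL(M0),
ΔR₂ = 1 − lnL(M2)/lnL(M1).  Δβ₁ always concerns the θ slope, never the group
coefficients, also for multi-level groups.  Defaults: α = 0.01, largeness
thresholds 0.01 / 0.07 / 0.07; no multiple-testing correction (an optional
Bonferroni switch exists but is off, matching the convention of reporting
per-item tests uncorrected).  Only the magnitude threshold for Δβ₁ is
implemented; no significance test for Δβ₁ is defined here because no standard
one exists for the ratio form.

**Separation**: when ML diverges (quasi-complete separation), the affected
fits are redone with a tiny ridge penalty (1e-6) and the item's row is marked
`penalized` instead of failing the scan.  Any other per-item failure yields an
`untestable` row and the scan continues.

## The hybrid purification loop

1. Initial ability: EAP from a single-group 2PL on all items (default), or a
   standardized total score (`initial_ability="standardized_total"`).  Both
   readings of "observed ability" are provided because either is defensible;
   the IRT score is the default since it is the quantity the loop refines.
2. Scan all items; flag those failing the uniform **or** non-uniform test at
   α.  Significance gates purification; effect sizes are reported only.
3. Re-calibrate with group-specific parameters for flagged items, re-score
   abilities, re-scan.
4. Stop when two consecutive scans flag the same set (`converged`) or after
   `max_iter` scans (default 10, warning + last results returned — bounded
   runtime with full transparency via the `PurificationTrace`).

If every item is ever flagged there is no anchor left and the run aborts with
the trace attached.  The impact assessment compares group totals with and
without the uniform-DIF items using Mann–Whitney U for two groups; for three
or more groups Kruskal–Wallis is the appropriate k-sample analogue and is
used even though two-sample U tests are the convention in the published
tables this layout mirrors.

## Reliability and one-factor fit

Cronbach's α uses the variance identity on the scored 0/1 items (complete
cases).  Tetrachoric correlations come from bivariate-normal quadrant
probabilities with thresholds at the marginal endorsement rates, solved by
Brent's method; empty 2×2 cells get a 0.5 continuity correction with a
warning, and the matrix is repaired to positive semi-definite by eigenvalue
flooring (logged) when needed.

The single-factor model is fitted to the tetrachoric matrix by unweighted
least squares (standard for binary items when the original estimator is
unstated; exact reproduction of any published table is not a goal).
McDonald's ω-total = (Σλ)²/((Σλ)² + Σ(1−λ²)); SRMR is the RMS of off-diagonal
residual correlations.  RMSEA/CFI/TLI are derived from the ML discrepancy of
the fitted matrix evaluated at the ULS solution against the independence
baseline, treating the tetrachoric matrix as an ordinary correlation matrix
of n observations — a pragmatic approximation; SRMR and ω do not depend on
it.  Heywood loadings are clipped to |1| with a warning; singular inputs
(e.g. perfectly consistent items) leave the χ²-based indices undefined (NaN)
while ω and SRMR remain exact.  Default out-of-range cutoffs: SRMR > .08,
RMSEA > .06, CFI < .95, TLI < .95 (configurable; the cutoff source gives
ranges, not a single canon).

## Synthetic cohorts

`make_gds_like(seed)` draws a 15-item spec with a ~ U[0.8, 2],
b ~ U[−1.5, 1.5], two groups of 684 and 789 persons (the unbalanced split of
the motivating field study) and standard-normal traits.  Uniform DIF is
injected as a per-group difficulty shift and non-uniform DIF as a
discrimination shift — the IRT-side realizations of a group main effect and a
group-by-trait interaction in the logistic models.  Trait asymmetry scenarios
use a two-component normal mixture (simple, controllable skew).  A master
seed spawns independent child seeds per replicate, so Monte-Carlo studies are
reproducible and parallel-safe.

What the generator does *not* emulate: real demographic joint distributions,
missingness mechanisms, multidimensional traits, local item dependence, or
careless responding.  Passing tests on these cohorts show the machinery is
correct and calibrated under the 2PL data-generating process, not that any
particular real scale is unbiased.

## Numerical and testing choices

* All optimizers are damped Newton (step-halving), guaranteeing monotone
  objectives; logistic fits finish at score max-norm < 1e-8.
* Determinism: identical inputs, configuration and seed give bit-identical
  results and byte-identical report bundles (no timestamps in outputs).
* Test problem sizes: the type-I calibration uses 500 null replicates at
  500 per group (7500 item-tests) matched on the true simulated trait so the
  test isolates the regression machinery from calibration noise; hybrid
  recovery uses 20 seeds at 1000 per group with a 0.6-logit shift; difficulty
  recovery uses 10 seeds at 2000 persons; shift-recovery unit checks average
  6 seeds at 800 per group because a single seed's difficulty gap is noisy
  when the drawn item sits in a trait tail.
* The Mann–Whitney enumeration check uses tie-free totals, where the exact
  null distribution is unambiguous.

## Known limitations

* Dichotomous items only; no 3PL guessing, no polytomous graded response.
* No Monte-Carlo estimation of empirical flagging thresholds; α-level χ²
  tests only.
* No alternative DIF frameworks (Mantel–Haenszel, SIBTEST, Rasch trees).
* The χ²-based fit indices inherit the binary-data approximation noted above.
* Focal-group prior SD is floored at 0.01 inside EM for stability.
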