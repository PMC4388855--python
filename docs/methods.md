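# Methods

## Model and parameterizations

Two independent binomials, `Y1 ~ Bin(n1, π1)` and `Y2 ~ Bin(n2, π2)`, with
both group sizes fixed by design. Interest parameter: the log odds ratio
`ψ = logit(π1) − logit(π2)`. Two nuisance parameterizations are carried
throughout:

- canonical `λ = logit(π2)`, in which `(ψ, λ)` are jointly canonical for
  the exponential family with sufficient statistics `(y1, y+)`;
- orthogonal `λ* = (n1π1 + n2π2)/(n1 + n2)`, the marginal probability of
  success, whose global MLE `y+/n+` does not depend on ψ.

`ParamPoint` stores all parameterizations at once. The inverse map
`(ψ, λ*) → λ` has no closed form; it is solved by bracketed Brent
root-finding on a monotone score (initial bracket `[−50, 50]`, expanded by
doubling if needed, residual < 1e-12). Round-trip conversions between any
two interior parameterizations agree to better than 1e-10 (property-tested
with hypothesis over ψ ∈ [−8, 8], λ* ∈ [0.02, 0.98]).

Boundary maximum-likelihood estimates are represented as signed infinities,
never as large finite surrogates; a 0/0 odds-ratio estimate (all failures
or all successes) is flagged `nan` ("undefined") rather than given an
arbitrary value. Enumeration keeps counts as exact integers.

## Likelihoods

All likelihood arithmetic is in log space. The normalizer
`C(ψ, y+) = Σ_u C(n1,u) C(n2,y+−u) e^{ψu}` is computed by log-sum-exp over
the conditioned support `max(0, y+−n2) ≤ u ≤ min(n1, y+)` and is stable for
|ψ| up to at least 500 (tested against the dominant-term asymptote).
The exact factorization — full = conditional + marginal in log likelihood —
is verified to 1e-12 over randomized tables and interior points, as is the
reduction of the row-conditioned four-cell Poisson model to the dual
binomial under the mean-ratio substitution.

The conditional MLE solves the tilted-mean equation `E_ψ[Y1 | y+] = y1`
(strictly increasing in ψ) by Brent's method with an expanding bracket;
it is ±∞ when y1 sits at an end of the conditioned support. Conditioning
shrinks the estimate: over the full 11×11 grid of tables with n1 = n2 = 10
the conditional MLE lies weakly between 0 and the unconditional MLE.

Pseudo-likelihoods built from the full likelihood:

- **profile**: maximize over λ at fixed ψ, via the monotone constrained
  score `y+ = n1·expit(ψ+λ) + n2·expit(λ)` (Brent, tolerance ~1e-13).
  Profiling over the canonical λ or over λ* gives the same curve (the
  maximized value does not depend on how the nuisance is coordinatized).
- **estimated** (plug-in): full likelihood along the slice `λ* = y+/n+`.
  Because λ* is orthogonal to ψ, the standardized estimated and profile
  curves agree to < 1e-6 on the worked example — tested, not assumed.
- **modified profile**: `ℓ_p(ψ) + ½ log j_λλ(ψ, λ̂_ψ)` with
  `j_λλ = n1π1(1−π1) + n2π2(1−π2)` at the constrained nuisance MLE.
  Barndorff-Nielsen's formula multiplies the profile likelihood by
  `|j_λλ(ψ, λ̂_ψ)|^{−1/2}` and by the sample-space Jacobian
  `|∂λ̂/∂λ̂_ψ|`; for a canonical nuisance the MLE equations give
  `∂λ̂_ψ/∂λ̂ = j_λλ(ψ̂, λ̂)/j_λλ(ψ, λ̂_ψ)`, so up to a ψ-free constant the
  net curvature exponent is **+½**. The sign matters: with +½ the
  standardized modified-profile curve is within 0.003 of the conditional
  curve on the worked example (the two are visually indistinguishable);
  with −½ the discrepancy is ~0.12. The acceptance property asserts
  sup-distance < 0.01 on ψ ∈ [−6, 2]. The curve is reported only where the
  constrained nuisance MLE exists (it does not for y+ = 0 or y+ = n+).

Curve grids default to 401 points on `[ψ̂_c − 8, ψ̂_c + 8]` clipped to
`[−12, 12]`, configurable.

## Tests and p-values

- **Pearson χ²**: `n+(|ad − bc| − c)² / (n1 n2 y+ (n+ − y+))` with c = 0 or
  n+/2 (Yates, floored so the corrected difference is never negative),
  upper-tail χ²₁. Undefined (error) when a margin is degenerate.
- **Fisher's exact test**: tail sums of the central hypergeometric pmf.
  Two-sided either by probability ordering (sum of outcomes no more likely
  than observed) or by doubling the smaller one-sided p (capped at 1). The
  two coincide for balanced designs by symmetry of the null conditional
  distribution — verified over all y+ for n1 = n2 = 10. Floating-point pmf
  values are never compared exactly: ties use relative tolerance 1e-7.
- **mid-p**: the observed outcome contributes only half its probability.
  The two-sided probability-ordering variant and the doubled one-sided
  variant give the same value (0.07585) on the worked example, so the
  choice is observationally equivalent there; the probability-ordering
  variant is implemented as the two-sided default.
- **Tocher's randomized test**: rejects outright when `P_ex + P_obs ≤ α`,
  accepts when `P_ex > α`, and otherwise rejects with probability
  `γ = (α − P_ex)/P_obs` (seeded). Summing γ against the null pmf over the
  conditioned support returns α exactly — the analytic identity is tested
  to 1e-12 at several y+ and α. In the observed-table report the tail is
  taken toward the observed deviation; in size simulations a fixed tail is
  used, since choosing the tail from the data doubles the size.
- **Conditional LR test**: `−2[ℓ_c(0) − ℓ_c(ψ̂_c)]` against χ²₁. When the
  conditional MLE is infinite the supremum of the conditional likelihood
  is 1, so the statistic reduces to `−2 ℓ_c(0)`.

A note on printed precision: the reference value 0.0509 for the
uncorrected χ² p corresponds to the exact 0.050962 (terminal-digit
truncation); tests assert agreement within one unit in the last printed
digit.

## Support intervals

A 1/k support interval is `{ψ : L(ψ)/L(ψ̂) ≥ 1/k}`. Endpoints are found by
expanding a bracket outward from the MLE and bisecting the standardized
log-likelihood against −log k (tolerance 1e-8 in ψ). The standardized
likelihood's limit as ψ → ±∞ is evaluated at |ψ| = 500, far beyond where
the discrete extreme-support term dominates; an endpoint is reported as ±∞
when that limit still exceeds 1/k (boundary tables). Intervals are nested
in k by construction and tested.

## Bayesian intervals

Independent conjugate priors `Beta(a, a)` on π1 and π2 with a = ½
(Jeffreys) or 1 (uniform); the posterior of ψ is sampled by drawing the two
Beta posteriors and transforming (default 100,000 draws, seeded numpy
Generator). Intervals are equal-tailed empirical quantiles — the
conventional choice for this comparison — not HPD. Draws are almost surely
interior, so sampled ψ is finite.

## Simulation studies

Scenarios are `(π1, π2, n1, n2, reps, seed, α)` under the generating dual-
binomial model. Because every decision depends on the data only through
`(y1, y2)`, each study precomputes its rule over the `(n1+1)(n2+1)` grid of
attainable tables and tabulates the simulated stream against it; 20,000
replicates (the default, MCSE ≈ 0.0015 at α = 0.05) run in seconds.
Results are bit-for-bit reproducible given the seed (randomized decisions
use a seed+1 substream). Degenerate replicates (y+ = 0 or n+) count as
non-rejections for tests and as covering for intervals, with the count
reported. Support intervals with an infinite endpoint cover whenever the
true ψ lies on the infinite side.

The generator emulates exactly the stated sampling model — independent
binomials with fixed group sizes. It does not emulate features of real
comparative studies such as overdispersion, dependent responses, or
data-driven stopping, so passing simulations demonstrate calibration under
the model, not robustness to violations of it.

## Figures

Likelihood surfaces are drawn over `(ψ, λ*)` — default window ψ ∈ [−10, 10],
λ* ∈ [0.02, 0.98], 201×201, deliberately wide so the near-flatness of the
marginal likelihood in ψ is visible. The color map is monotone in
likelihood value; the palette is cosmetic and configurable. The evidence
plot overlays standardized conditional / profile / modified-profile curves
with horizontal rulers at 1/k; all plotted numbers come from the likelihood
and evidence modules and the returned curves are cross-checked against
direct module calls in tests.

## Known limitations

- No r×c or stratified (2×2×K) tables, no continuity-corrected OR
  estimators, no unconditional exact (Barnard/Boschloo) tests, no
  test-inversion confidence intervals, no higher-order (saddlepoint)
  p-value approximations.
- The modified profile likelihood uses the canonical-nuisance
  exponential-family reduction; its validation here is agreement with the
  conditional likelihood, which is the relevant benchmark for this model.
- Bayesian inference is limited to the two named noninformative priors
  with equal-tailed intervals.
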