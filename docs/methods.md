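# Methods

## Model

Adverse outcomes (AOs) after discharge are recurrent events of a
non-homogeneous Poisson process. Conditional on a patient's covariates
`X` and frailty `Z`, the intensity is

```
λ(t | X, Z) = Z e^{XB} λ₀(t) = h λ₀(t),     h = Z e^{XB},
```

with `Z ~ Gamma(mean 1, variance σ)` capturing unobserved heterogeneity
and `λ₀` a parametric baseline hazard. The model assumes an increasing
baseline with `λ₀(0) = 0`: patients leave the hospital clinically stable
and risk accrues afterwards. AO treatment is a *minimal repair* — it
restores function without changing the hazard trajectory — which is what
makes the NHPP expected-count calculus exact.

Baselines supported: Weibull (`λ₀(t) = (k/s)(t/s)^{k-1}`, cumulative
hazard `(t/s)^k`), Gamma and Log-Normal (hazard `f/S` and cumulative
hazard `−log S` through `scipy.stats`). Parameter sets producing a
non-increasing hazard are accepted — some published fits are of this kind
— but flagged (`increasing=False`) with a logged warning, because the
dominance and sign guarantees below then no longer hold.

## Checkup effect: virtual age

A follow-up policy `(n, τ)` delivers periodic checkups at times `t_i`.
Each checkup discounts the age accrued since the previous one by the
age-reduction factor `θ ∈ [0, 1]`, so the virtual age after the i-th
checkup is

```
v_i = v_{i-1} + θ (t_i − t_{i-1}) = θ t_i        (v₀ = 0),
```

and between checkups the intensity is `h λ₀(v_{i-1} + t − t_{i-1})`.
For policies whose checkups start at time zero (I, III) this reduces to
the arithmetic form `v_i = i τ θ`. For policy II, whose first checkup
falls at `W + τ`, we deliberately use the telescoped `v_i = θ t_i`
(a Kijima type-I update) rather than the arithmetic form: the arithmetic
form would let a single *ineffective* checkup (`θ = 1`) rewind a
patient's age from `W + τ` to `τ` — a rejuvenation for free — breaking
the defining property that `θ = 1` leaves the hazard exactly unchanged
under every policy. With `v_i = θ t_i`, `θ = 1` collapses every policy
to the no-follow-up profile and `θ = 0` is a full reset, uniformly across
policies.

A checkup landing exactly at `W` (e.g. `τ = 3`, `W = 12`) belongs to the
warranty-window schedule and its virtual age governs the post-warranty
hazard. Policy II's stretch `[W, W + τ)` before its first checkup keeps
the calendar-time age. Checkup counts follow the floor rule
`n₁ = ⌊W/τ⌋`, `n₂ = ⌊(L−W)/τ⌋`, `n₃ = ⌊L/τ⌋`, `n₄ = ⌊W/τ⌋`, evaluated
with a 1e−9 tolerance so fractional `τ` hitting a boundary exactly still
counts. An empty schedule (large `τ`) is legal and reproduces the
no-follow-up profile.

## Integration

Expected counts are integrals of the piecewise effective-age intensity.
The effective-age map is non-smooth at checkup times, so integration is
done segment by segment, never across a boundary, using the family's
closed-form cumulative hazard on each segment:
`∫ λ₀(a + t − t₀) dt = Λ₀(a + u₁) − Λ₀(a + u₀)`. This is exact up to the
evaluation of `Λ₀` itself (machine precision for Weibull; `scipy`'s
`logsf` for Gamma/Log-Normal). A fixed-step Riemann oracle in the test
suite guards the segment bookkeeping to 1e−5 relative.

## Stratification and group weights

Patients are stratified on `h` restricted to the observed range
`[h_min, h_max]` (mass outside the range is ignored). Cutoffs are the
quantiles of the truncated distribution — `ppf` seeded, polished by
Brent root-finding on the CDF to 1e−10 — giving `N` groups of equal
truncated mass. Group weights use the incomplete-gamma identity
`∫ h g(h) dh = mean · [F_{k+1}(hi) − F_{k+1}(lo)]` for the Gamma family,
a closed form for the uniform family, and adaptive quadrature otherwise.
Brute-force trapezoid oracles (2·10⁶ points) confirm both the masses and
`Σφ_k` to 1e−8.

## Expected costs and price bounds

With `H_pol(a, b)` the baseline-time integral of a policy's profile and
`φ_k` the group weight, the four expected costs per group are

| party, decision | cost |
|---|---|
| patient, no purchase | `c_k^r φ_k H_none(W, L)` |
| patient, purchase at P | `P + c_k^r φ_k H_pol(W, L)` |
| hospital, no provision | `c_k^r φ_k H_none(0, W)` |
| hospital, provision at P | `c_k^r φ_k H_pol(0, W) + n_j c_f − P` |

Setting purchase equal to no-purchase (and provision to no-provision)
gives the bounds

```
P_p = c_k^r φ_k [H_none(W,L) − H_pol(W,L)]
P_h = c_k^r φ_k [H_pol(0,W) − H_none(0,W)] + n_j c_f
```

computed directly in this difference-of-cumulative-hazards form (not by
differencing the full cost functions, which would cancel
catastrophically). The indifference identities are asserted to 1e−8 in
the tests, tying the bounds back to the cost functions they came from.
`P_h` is floored at zero — prices cannot be negative — and the raw value
is kept on the `PriceInterval` for monotonicity diagnostics. A
non-existent interval is `exists=False` with width 0.

Structural consequences, all asserted as tests: `P_h` for policy II is
exactly `n₂ c_f` (the warranty-window hazard is untouched), invariant to
`θ` and treatment costs; `P_p` is linear in `c_k^r` and independent of
`c_f`; `P_h` is nondecreasing in `c_f`; interval width (on the raw bound)
is nondecreasing in `c_k^r`; `θ = 1` forces `P_p = 0` everywhere.

## Fitting

`fit_frailty_model` maximises the marginal likelihood in which the Gamma
frailty is integrated out analytically per patient: with `m` events at
times `t_j` on `[0, T]`, `a = 1/σ` and `μ = e^{XB} Λ₀(T)`,

```
log L = Σ_j [XB + log λ₀(t_j)] + lnΓ(a+m) − lnΓ(a) − a log1p(μ/a) − m log(a+μ).
```

Optimisation is L-BFGS-B over `(B, log σ, log baseline params)` with
`σ ∈ [10⁻⁶, 50]`; the `log1p` form keeps the `σ → 0` (Poisson) limit
stable, and a degenerate-frailty cohort drives `σ̂` to the lower
boundary. Candidate baseline families are fitted independently and
ranked by log marginal likelihood (AIC is reported alongside; with
equally-sized parameter vectors the rankings coincide). The fitted
heterogeneity distribution is summarised by moment-matching
`h = Z e^{XB}` to a Gamma — `E[h] = mean(e^{X_iB})`,
`Var[h] = (1+σ̂) mean(e^{2X_iB}) − E[h]²` — mirroring the two-stage
treatment of the case study, and the observed range is the min/max of
per-patient empirical-Bayes values `ĥ_i = e^{X_iB̂}(a+m_i)/(a+μ_i)`.

## Synthetic cohorts

`simulate_cohort` draws covariates, `Z`, `h`, and AO times from the
policy's effective-age NHPP by Lewis–Shedler thinning with a
piecewise-constant majorant per segment (`λ₀` at the segment's right
effective age for increasing baselines; a bracketed numeric supremum with
5 % headroom otherwise). Every accepted point is re-checked against the
majorant; a violation raises, making the thinning self-auditing. The
thinning touches only the *pointwise* hazard, so Monte-Carlo cost
estimates are an independent check on the closed-form integrals. All
randomness flows from one seed via spawned per-patient substreams, so
cohorts are bit-reproducible and stable under reordering.

Default study conditions — chosen once, by design, before any test was
run — emulate a paediatric chronic-disease cohort followed for 36
months: an increasing Weibull baseline (shape 2, scale 15 months, ≈ 6
expected AOs per average patient over the window), frailty variance
`σ = 0.6`, and two covariates with coefficients `B = (0.3, −0.05)`: a
glycaemic-control deviation score (sd 1.8; hazard ratio 1.35 per unit is
in line with chronic-disease cohorts) and centred age in years (sd 4 for
a paediatric cohort; hazard ratio 0.95 per year). A Fisher-information
sketch motivates the spread: with frailty, the per-patient information
about `B_j` saturates near `E[x_j²]/σ`, so at `n = 500` the standard
errors are ≈ 0.02 and 0.009 — comfortably inside the 15 % recovery
tolerance used in the validation tests (measured as 2-norm relative
error of the coefficient vector, the standard vector-recovery metric).
What the generator does *not* emulate: dropout, noncompliance,
treatment-cost variability (costs enter as fixed per-group means),
interval censoring, or time-varying covariates — so passing recovery
tests validate the estimator under the model, not robustness to
real-data violations of it.

`simulate_expected_cost` draws `h` by inverse-CDF from the
stratum-truncated distribution (no rejection inefficiency in narrow
strata) and averages `c_k^r × count` plus the deterministic checkup and
price terms. It conditions on stratum membership (probability one),
whereas the closed form carries the stratum probability inside `φ_k`;
comparisons therefore multiply the Monte-Carlo mean by the stratum mass.

## Case-study defaults and known limitations

The default configuration reproduces the case study: three risk groups
with cutoffs (0.0449, 0.1331, 0.2300, 0.7182) and AO costs
(6520, 10200, 15580), `c_f = 428`, `θ = 0.1`, `W = 12`, `L = 36`,
`τ = 3`, and the printed Weibull baseline fit (shape 0.12, scale 1.657).
Two published inconsistencies are inherited deliberately rather than
papered over. First, that Weibull fit is a *decreasing* hazard under the
standard parameterisation, violating the model's monotone-risk
assumption; the package accepts it with a warning (both parameter
orderings can be expressed through the named `shape`/`scale` config
keys). Second, the reported `h` moments (mean 2.4006, variance 0.0813)
place negligible mass below the reported cutoff 0.7182, so group weights
computed from them are vanishingly small. Consequently only the
checkup-bill family of results (`P_h^II = n₂ c_f` and its `c_f`/`L`
rescalings) is reproduced exactly under the defaults; the remaining
case-study interval bounds depend on the unrecoverable baseline
parameterisation and are covered by structural and Monte-Carlo tests on
internally consistent configurations instead.

Test and validation problem sizes — 500-patient fits, 20 000-replicate
Monte-Carlo checks, 2·10⁶-point quadrature oracles — were chosen as the
smallest sizes at which the statistical tolerances above are well
powered.

Currency is unit-agnostic; outputs carry the configured label (default
"CNY"). Out of scope by design: optimisation of `(n, τ)` or `L`,
aperiodic or adaptive schedules, warranty renewal after hospitalisation,
regulator reimbursement design, nonparametric baselines, and non-Gamma
frailty families.
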