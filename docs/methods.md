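# Methods

## M-estimation and the generalized redescending family

The package estimates the simple linear model y = α + βx + e by
minimizing Σρ(rᵢ) over the residuals rᵢ. Differentiating gives the
estimating equations Σψ(rᵢ) = Σψ(rᵢ)xᵢ = 0 with ψ = ρ′, solved by
iteratively reweighted least squares with weights w(r) = ψ(r)/r. The
generalized family

    ρ(r) = (k²/2a)·[1 − {1+(r/k)²}^(−a)],   ψ(r) = r·[1+(r/k)²]^(−a−1)

has a bounded loss (supremum k²/2a), an influence that peaks at
|r| = k/√(2a+1) and redescends to zero, and a weight that is strictly
positive everywhere: extreme observations are downweighted smoothly
rather than truncated, which keeps the IRLS map differentiable. The
exponent a is a second tuning knob: at fixed k, a larger a gives
uniformly smaller weights away from zero, i.e. a more aggressive
rejection. Nine comparator families are registered with the tuning
constants conventionally quoted for them (Huber 1.345, Andrews 3.2,
Tukey 4.865, Qadir 4, Ali 4, Insha 4, Alamgir 3, Khalil 4, Hampel
(2, 4, 8)); all are exposed through one registry so fitters, efficiency
computations and the CLI treat them interchangeably.

Two families required editorial decisions. Insha's ψ as often printed,
[1+(r/k)⁴]^(−2), is even with ψ(0) = 1 — not an influence function at
all; the registry uses the corrected odd form r·[1+(r/k)⁴]^(−2), which
is the only reading consistent with ψ = ρ′ and w = ψ/r, and the even
form remains available via `insha_psi(..., as_printed=True)`. Alamgir's
ψ genuinely jumps at |r| = k (the inner expression does not vanish
there); it is implemented as written and the discontinuity handled
explicitly in quadrature. Khalil's zero branch applies for |r| > k, the
same pattern as every other hard redescender.

## Fitting

`fit_irls` iterates residuals → weights → weighted least squares, using
the closed-form weighted normal equations (so each iterate satisfies
Σw·r = Σw·r·x = 0 exactly for the weights that produced it).
Convergence: maximum coefficient change, relative to the coefficient
magnitude (floored at 1), below `tol` (default 1e-8), capped at
`max_iter = 200`. Non-convergence is reported by flag and warning, not
an exception; all weights underflowing to zero is an error suggesting a
larger k.

Residuals are standardized by a robust scale recomputed each iteration,
σ̂ = median(|r − median r|)/0.6745 (`scale="mad"`, the default): the
tuning constants are then in standard-deviation units, and this choice
reproduces the benchmark tables below. `scale="none"` applies ψ to raw
residuals for the case where k is meant in response units. Redescending
losses are non-convex, so the IRLS fixed point depends on the start;
`start` may be `"ols"` (default), `"lms"`, `"huber"` (a monotone-ψ
pre-fit), or explicit coefficients. On the China benchmark, for
example, the raw-residual proposed fit and the MAD-scaled one sit in
different basins; only the latter matches the published coefficients.

`fit_lms` minimizes the median squared residual over two-point elemental
lines — exhaustively when C(n,2) ≤ `n_subsets` (default 5000, i.e.
exact for n ≤ 100), else over a seeded random subsample. Candidates are
enumerated after sorting the data lexicographically by (x, y), so the
result is invariant to observation order; ties keep the first candidate
in that canonical order.

`flag_outliers` calls an observation an outlier when its final relative
weight w(r)/w(0) falls below `weight_cutoff` (default 0.1); for
weightless fits (OLS/LMS) when |r| exceeds `residual_cutoff` (default
2.5) times 1.4826·MAD of the residuals. Weights are stored relative to
w(0) because two families (Alamgir, with w(0) = 4, and Qadir/Ali with
w(0) < 1) would otherwise not be comparable on a [0, 1] scale.

On the telephone benchmark the defaults flag exactly the 1963–1970
block (16 of 24 retained); on the China data the known outliers
(responses 15.50 and 364.00) get weights ≈ 10⁻¹⁵. Retained-subset SSEs
for the benchmark tables are computed over those conventional retained
sets (16 telephone points; the first 7 China points).

## Gaussian efficiency

`gaussian_efficiency` evaluates eff = (E[ψ′(Z)])²/E[ψ(Z)²] for standard
normal Z by adaptive quadrature on [−12, 12] (the omitted tails are
below 1e-31), split at each family's breakpoints. ψ′ is analytic for
Huber, Tukey, Andrews and the proposed family and a central difference
(h = 1e-6) inside smooth pieces elsewhere. At Alamgir's jump the
distributional derivative's point mass is deliberately ignored — the
efficiency is defined from the smooth part only, and the Monte-Carlo
cross-check in the tests (10⁶ draws, delta-method standard error) is
run on continuous families where the two definitions coincide.
`calibrate_k` inverts the map by Brent root-finding to |Δeff| < 1e-5;
Hampel's corners scale as (k, 2k, 4k) during calibration, and the
proposed family's a is held fixed. Reproduced classical values: Huber
k = 1.345 → 0.95000; the 95% Tukey constant is 4.685 (the 4.865
sometimes quoted for it actually gives 0.9567).

## Simulation study

`run_study` draws replicates of n = 100 from y = 2 + x + e with
x ~ N(20, 10²) and e ~ N(0, 1) (N(20,10) is read as mean/SD; pass
x_sd=√10 for the variance reading), fits each estimator on the clean
sample (Case I) and on a copy with 10% of responses shifted by +50
(Case II), and averages coefficients. The shift of +50 makes the
expected contaminated OLS intercept 2 + 0.1·50 = 7, matching how badly
OLS is expected to degrade; fraction and shift are parameters. Two
sampling modes: `"fixed"` draws without replacement from one population
of 10,000 generated up front — faithful to the classical design, but
the replicate means then converge to that population's *realized*
coefficients, not (α, β) — and `"fresh"` draws every replicate directly
from the model, which is the mode used for parameter-recovery
assertions since there the Monte-Carlo standard error is the correct
yardstick. Replicate RNG streams are spawned from the master seed
independently of the estimator list, so results per estimator are
unchanged when other estimators are added. Default 1,000 replicates
(the tests use 300–1,000); the CLI exposes full-scale runs. Fit
failures are excluded from the averages and counted, never silent.

## What the generator does and does not emulate

The synthetic study emulates gross, asymmetric y-direction
contamination on a Gaussian linear model — the regime redescenders are
built for. It does not emulate leverage (x-direction) outliers, to
which plain M-estimators are known to be vulnerable; heteroscedastic or
heavy-tailed-but-uncontaminated errors; or model misspecification.
Passing tests therefore show correct behaviour under clean-plus-gross-
contamination conditions, not general-purpose robustness.

## Known limitations

- Single-predictor API only; no standard errors or tests for robust
  fits; no MM/S-estimation stages.
- Redescending IRLS finds a local minimum; pathological starts can land
  elsewhere. The start-strategy option is the mitigation.
- LMS by elemental subsampling is approximate for n > 100 at the
  default budget and has many near-optimal solutions; its coefficients
  should be read as a high-breakdown baseline, not a unique optimum.
- About 1% of contaminated replicates stop at max_iter with coefficient
  movement only in the ~9th decimal; they are included in the averages
  (the flag and warning record it).
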