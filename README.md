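# redescend

Robust simple linear regression with **redescending M-estimators**, for
analysts whose datasets — call volumes, growth rates, lab measurements —
contain a handful of gross outliers in the response that wreck an
ordinary least-squares fit.

## The model

For data (xᵢ, yᵢ) and the line y = α + βx, an M-estimate replaces the
squared-error loss with a bounded loss ρ:

    minimize over (α, β):   Σᵢ ρ(rᵢ),    rᵢ = yᵢ − α − βxᵢ.

Its influence function ψ = ρ′ determines how strongly a residual pulls
the fit; the weight w(r) = ψ(r)/r is the multiplier each point gets in
the iteratively-reweighted-least-squares (IRLS) solution of the
estimating equations Σψ(rᵢ) = Σψ(rᵢ)xᵢ = 0. A family is *redescending*
when ψ(r) → 0 as |r| → ∞, so gross outliers lose all influence.

The package's centerpiece is a generalized redescending family

    ρ(r) = (k²/2a)·[1 − {1 + (r/k)²}^(−a)]
    ψ(r) = r·[1 + (r/k)²]^(−a−1)
    w(r) =   [1 + (r/k)²]^(−a−1)

with tuning constant k and an exponent a that dials how fast outlier
weights decay (larger a → harder rejection), while w stays strictly
positive — no observation is ever discarded outright. Nine classical
ψ-families (Huber, Hampel, Andrews, Tukey, Qadir, Ali, Insha, Alamgir,
Khalil) are registered alongside it, plus OLS and least-median-of-squares
(LMS) baselines, Gaussian asymptotic efficiency
eff(ψ) = (E[ψ′(Z)])²/E[ψ(Z)²] with tuning-constant calibration, two
classic outlier benchmarks, and a contamination Monte-Carlo study.

## Worked example

```python
import numpy as np
from redescend import TuningSpec, fit_irls, fit_ols, flag_outliers, load_fixture, subset_sse

fx = load_fixture("china")        # price growth rates, China 1940-48
ols = fit_ols(fx.data)
rob = fit_irls(fx.data, "proposed", TuningSpec("proposed", k=2, a=8))
print(ols.coefficients, rob.coefficients)
print(flag_outliers(rob))
```

Running `python examples/benchmark_fits.py` prints:

```
--- china (n=9) ---
OLS:       intercept -1049.4678  slope 24.84500  SSE(all) 78531.35
proposed:  intercept    -2.6369  slope  0.10630  SSE(retained 7) 0.610229
flagged as outliers (x values): [43, 46, 47, 48]
```

The two hyperinflation years (responses 15.50 and 364.00) drag the OLS
slope to 24.8; the redescending fit weights them to ~10⁻¹⁵ and recovers
the ≈0.11 trend of the seven ordinary years, with a retained-subset SSE
of 0.61 instead of 78 531. The other examples print the Gaussian
efficiency table (Huber k = 1.345 → 0.9500, Tukey 95% constant
k* = 4.685) and the contamination study, where 10% response shifts of
+50 inflate the mean OLS intercept from 2.01 to 7.13 while the proposed
estimator moves only from 2.02 to 2.03.

A thin CLI wraps the same calls:

```sh
redescend fit china --estimator proposed --k 2 --a 8
redescend efficiency --target 0.95
redescend reproduce 3          # full estimator panel on the china data
redescend simulate --reps 1000 --seed 1
```

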