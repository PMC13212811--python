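# monosurv

Covariate-adjusted **monotone baseline-hazard estimation** for
left-truncated, right-censored (LTRC) survival data.

In cohorts with delayed entry — retirement-home mortality, registry data,
prevalent-case studies — a subject is observed only if the event time
exceeds the entry time (*left truncation*), and follow-up may end before
the event (*right censoring*). The classical fixes, the truncated
Kaplan–Meier estimator and the Breslow baseline hazard with entry-adjusted
risk sets, become unstable when early risk sets are small: one or two
early failures can send the estimated survival curve crashing. When the
hazard can be assumed nondecreasing (aging, disease progression), the
maximum-likelihood estimator under that shape constraint remains well
behaved. `monosurv` implements that estimator under the Cox
proportional-hazards model, together with the comparators it generalizes,
and a Weibull simulation harness for benchmarking all of them.

## The estimator

Observed data are i.i.d. vectors (tᵢ, yᵢ, δᵢ, zᵢ): entry time, follow-up
time yᵢ = min(xᵢ, cᵢ), event indicator, covariates. Under the Cox model
λ(y|z) = λ₀(y)·exp(β᝘z), with β̂ fitted by the delayed-entry partial
likelihood (risk sets {j : tⱼ ≤ y ≤ yⱼ}, Breslow ties), the conditional
likelihood of a nondecreasing baseline hazard reduces on the merged grid
v₁ < … < v_k of all entry and follow-up times to

    ℓ*(λ₀) = Σᵢ₌₁ᵏ⁻¹ { sᵢ log λ₀(vᵢ) − λ₀(vᵢ) } wᵢ,

with interval weights and levels

    wᵢ = (vᵢ₊₁ − vᵢ) · Σₗ exp(β̂᝘zₗ)·1{tₗ ≤ vᵢ < yₗ},    sᵢ = d(vᵢ)/wᵢ,

where d(vᵢ) counts failures at vᵢ. The maximizer subject to
λ̂₁ ≤ … ≤ λ̂_{k−1} is the weighted isotonic regression of s on w —
equivalently the left-derivative sequence of the greatest convex minorant
of the cumulative-sum diagram, or the max–min formula

    λ̂ⱼ = max_{r≤j} min_{j≤s≤k−1} (Σᵢ₌ᵣˢ d(vᵢ)) / (Σᵢ₌ᵣˢ wᵢ).

The step hazard integrates to a continuous piecewise-linear Λ̂₀, giving a
continuous covariate-specific survival curve
Ŝ(y|z) = exp(−Λ̂₀(y)·exp(β̂᝘z)). With no covariates the estimator is
Tsai's univariate monotone MLE; with no truncation it is the
Lopuhaä–Nane estimator for right-censored data. Both reductions are
exported (`tsai_estimator`, `lopuhaa_estimator`) along with the
non-monotone comparators (`km_truncated`, `cox_fit` + `breslow_cumhaz`).

## Worked example

Simulate one replicate of the two-group Weibull design (event and
censoring times Weibull(a=2, θ) with θ=1000 for males and 2000 for
females, truncation Weibull(2, 250), initial n=1000) and estimate survival
at the true male median:

```python
import numpy as np
from monosurv import (Scenario, generate_scenario, cox_fit,
                      monotone_baseline, km_truncated, true_median)

scen = Scenario(shape=2.0, trunc_scale=250.0, n_initial=1000)
sample, dropped = generate_scenario(scen, np.random.default_rng(7))
print(f"observed n = {sample.n} (dropped {dropped} left-truncated), "
      f"events = {sample.n_events}")
fit = cox_fit(sample)
print(f"beta_hat = {fit.beta[0]:.4f}  (truth a*log(1/2) = {scen.true_beta:.4f}), "
      f"{fit.iterations} Newton iterations, converged = {fit.converged}")
hz = monotone_baseline(sample, fit.beta)
m0 = true_median(2.0, 1000.0)
print(f"true male median m_0 = {m0:.1f}")
print(f"proposed  S(m_0 | male) = {hz.survival(m0, fit.beta, [0.0]):.4f}")
males = sample.subset(sample.covariates[:, 0] == 0)
print(f"truncated KM on the {males.n} males: "
      f"S(m_0) = {km_truncated(males).evaluate(m0):.4f}")
```

which prints

```
observed n = 922 (dropped 78 left-truncated), events = 457
beta_hat = -1.1931  (truth a*log(1/2) = -1.3863), 4 Newton iterations, converged = True
true male median m_0 = 832.6
proposed  S(m_0 | male) = 0.5446
truncated KM on the 442 males: S(m_0) = 0.5317
```

One replicate's β̂ of −1.19 estimates the true log hazard ratio −1.386
(females vs males, hazard ratio (1/2)²); the survival probability at the
true male median should be 0.5, and both estimators land nearby — the
proposed curve uses all 922 subjects through the Cox model, the truncated
KM only the 442 males. Averaged over 1000 replicates the proposed
estimator's male bias is ≈0.012 with empirical standard error ≈0.025.

The same fits are available from the shell:

```sh
monosurv fit --estimator proposed --input data.csv \
             --covariate-profile 0 --out curve.csv
monosurv simulate --scenario a=2,b=250 --n 1000 --reps 1000 --seed 7 \
                  --out metrics.csv
monosurv reproduce --table 4 --reps 1000 --seed 7 --out table4.csv
```

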