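# censimpute

Bayesian posterior-predictive imputation of right-censored survival times
under Weibull and Birnbaum-Saunders (fatigue-life) lifetime models.

## The problem

In time-to-event studies most datasets are right-censored: for many
subjects we only know that the event time exceeds the recorded time `c`.
Deleting censored records biases every downstream summary, and naive
single-value imputation ignores both the censoring constraint and
parameter uncertainty. `censimpute` replaces each censored time by a
summary of its **posterior-predictive conditional distribution**

    f(t | T >= c, D) = ∫ f(t | T >= c, θ) p(θ | D) dθ,
    f(t | T >= c, θ) = f(t | θ) / S(c | θ),

so every imputed value respects `t >= c`, and the uncertainty in θ is
integrated out via MCMC. Two lifetime families are supported:

- **Weibull** in proportional-hazards form, `S(t) = exp(-β t^α)`, with the
  censoring-conditional median available in closed form,
  `t_med = ((ln 2)/β + c^α)^(1/α)`;
- **Birnbaum-Saunders** `BS(γ, δ)`, defined by
  `Z = (1/γ)(√(T/δ) − √(δ/T)) ~ N(0,1)`, whose median equals the scale
  parameter δ exactly.

The scale of either family can be tied to a binary covariate through
`scale = exp(b1 + b2·x)`. Priors are gamma on positive parameters and
normal on coefficients; sampling is adaptive random-walk Metropolis on
log-transformed parameters, and the default protocol retains exactly
10,000 draws (1,000 burn-in, 100,000 iterations thinned by 10). Convergence
is monitored with Geweke z-scores, effective sample size, and
autocorrelation; competing families are ranked by DIC. A calibration module
solves for the exponential censoring rate θ that produces any nominal
censoring fraction, and a scenario simulator generates the full
3 shapes × 3 sample sizes × 3 censoring levels study grid per family plus
a 220-record breast-cancer-like synthetic cohort.

## Worked example

```python
import censimpute as ci
from censimpute.simulate import ScenarioConfig, generate_scenario

# one study scenario: Weibull shape 2, n=200, nominal 20% censoring,
# PH rate exp(-3 + 0.3 x), censoring times Exp(0.06)
cfg = ScenarioConfig("weibull", 2.0, 200, 0.20, 0.06, -3.0, 0.3, seed=11)
data = generate_scenario(cfg)                      # 200 records, 36 censored

post = ci.fit_scale_regression(data, "weibull", config=ci.MCMCConfig(seed=11))
result = ci.impute_dataset(data, post, summary="median", seed=11)
report = ci.diagnose(post, data)
```

This prints (via the obvious inspection calls):

```
posterior means:  shape 2.116, b1 -3.175, b2 0.138      (truth: 2, -3, 0.3)
acceptance rate:  0.236
censored times [2.91 3.76 2.29] -> imputed medians [4.52 5.07 4.34]
ESS:    shape 7263, b1 7525, b2 7614    (all > 1000)
Geweke: shape -0.76, b1 0.41, b2 -0.91  (all within ±2)
DIC:    689.3 (pD = 2.96)
```

Every imputed value exceeds its censoring time; the effective sample sizes
say the 10,000 retained draws behave like >7,000 independent ones; the
Geweke scores detect no nonstationarity; pD ≈ 3 matches the three free
parameters.

The same pipeline is scriptable from the shell:

```sh
censimpute simulate --family bs --shape 0.5 --n 200 --censoring 0.2 --seed 1 --out data.csv
censimpute impute data.csv --family bs --out results/        # augmented CSV, chains,
                                                             # KM curve TSVs, diagnostics JSON
censimpute calibrate --family weibull --shape 2 --target 0.5 # prints theta
censimpute study --family weibull --out study/               # all 27 scenarios
```

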