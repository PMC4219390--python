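# baselinejm

Joint longitudinal–survival modelling that corrects the measurement-error
attenuation of *baseline* biomarker effects on a time-to-event outcome.

## The problem

Prognostic models routinely put a single observed baseline biomarker value
(systolic blood pressure, say) into a survival model.  Biomarkers are
measured with error, and classical error in a regressor biases its hazard
ratio toward the null (regression dilution) — risk scores built this way
understate the biomarker's effect.  Registries usually *do* contain repeated
measurements; they are just ignored.

`baselinejm` uses those repeated measurements.  A linear mixed model
describes the biomarker,

```
Y_ij = W_i(t_ij) + e_ij,            e_ij ~ N(0, sigma_e^2)
W_i(t) = x_i'(t) beta + z_i'(t) b_i + u_i' delta,    b_i ~ MVN(0, Sigma)
```

and a proportional-hazards model describes survival, linked through the
subject-specific *intercept* so that the hazard depends on the true
(error-free) baseline level:

```
h_i(t) = h0(t) exp( alpha * (beta_0 + b_0i) + phi' v_i )
```

`alpha` is the log hazard ratio per unit of the true baseline biomarker.
Because this association is time-independent, the cumulative hazard has a
closed form under any parametric baseline (Weibull, or a Royston–Parmar
restricted-cubic-spline log cumulative hazard), and the joint likelihood
needs only a low-dimensional Gauss–Hermite integral over the random
effects.  The naive comparator `h_i(t) = h0(t) exp(alpha_3 Y_0i + phi'v_i)`
is implemented alongside; its `alpha_3` is the attenuated quantity the
joint model fixes.  For a new patient with only a baseline measurement, the
package predicts survival by averaging over the Gaussian posterior of the
patient's random intercept, propagating the baseline measurement error.

## Worked example

```python
import numpy as np
from baselinejm import (JointModel, fit_naive_baseline, predict_survival,
                        NewPatient, SimulationScenario, simulate_joint)

sc = SimulationScenario(alpha=0.5, sigma_e=1.0)   # true log HR 0.5, noisy biomarker
long, surv, truth = simulate_joint(sc, seed=1)

naive = fit_naive_baseline(surv, covariates=("trt", "age"))
jm = JointModel(surv_covariates=("trt", "age")).fit(long, surv)

pt = NewPatient(baseline_value=2.0, covariates={"trt": 0.0, "age": 65.0})
curve = predict_survival(jm, pt, np.array([1.0, 3.0, 5.0]), naive_fit=naive)
```

prints (via `naive.coef_table()`, `jm.alpha_`, `curve`):

```
records: 978 subjects: 300 events: 227
naive alpha3 = 0.221 (95% CI 0.121, 0.321)
joint alpha  = 0.481 (95% CI 0.271, 0.690)
sigma_e = 0.984   loglik = -2124.4
 time  surv_plugin  surv_marginal  surv_naive
  1.0        0.775          0.767       0.769
  3.0        0.275          0.281       0.285
  5.0        0.065          0.080       0.075
```

With measurement-error SD 1 the naive model halves the association
(0.221 vs the true 0.5); the joint model recovers it (0.481, CI covering
0.5) and estimates the error SD itself (0.984).  `surv_plugin` is the
survival curve at the patient's shrunken (posterior-mean) intercept,
`surv_marginal` additionally averages over the posterior — the recommended
curve, since it carries the baseline measurement uncertainty through to
the prediction.

A command-line interface wraps the same functionality:

```
baselinejm simulate --seed 42 --out-prefix sim1
baselinejm fit --long sim1_long.csv --surv sim1_surv.csv --covariates trt,age --out fit.json
baselinejm predict --fit fit.json --baseline 2.0 --covar trt=0,age=65 --times 0:10:0.1 --out curve.csv
baselinejm simstudy --alphas 0.5 --sigmas 0.5,1 --reps 200 --seed 1 --out table/
```

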