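# distillsurv

Sparse right-censored survival models via knowledge distillation
(pre-conditioning).  Intended for analysts who want interpretable,
feature-sparse risk models from moderate- to high-dimensional cohorts
(clinical + molecular covariates) without the hyperparameter fragility of
directly penalized Cox models.

## The idea

Directly Lasso-penalized survival models are sensitive to the
regularization hyperparameter λ: small changes can swing both the
selected features and the predictive performance.  Distillation splits
the problem in two:

1. **Teacher.**  Fit a flexible, *unpenalized* (or mildly regularized)
   survival model to the training data and record its linear predictors
   η̂ᵢ on the training rows.  Available teachers:
   * Cox proportional hazards, log partial likelihood with Breslow or
     Efron tie corrections;
   * semiparametric accelerated failure time (AFT) and extended hazards
     (EH) models, fitted by maximizing a kernel-smoothed profile
     likelihood — the EH hazard `λ(t|x) = λ₀(t e^{x'β₁}) e^{x'β₂}` nests
     Cox (β₁ = 0) and AFT (β₁ = β₂);
   * anything else that emits linear predictors for training rows.
2. **Student.**  Regress η̂ on the raw features with an elastic net
   (`α‖β‖₁ + (1−α)/2 ‖β‖₂²`), solved by coordinate descent along a
   100-point λ path.  Because the student chases a *noise-free* target
   (the teacher's predictions rather than the censored outcomes), its
   performance is flat across much of the path, so the analyst can pick
   a sparsity level almost at will.

λ is chosen by event-stratified k-fold cross-validation, scoring each λ
with the teacher-family log-likelihood of the student's predictions
(Verweij–van Houwelingen by default), under one of three rules: `min`
(best mean score), `1se` (sparsest within one standard error) or `pcvl`
(penalized CV likelihood, taxing each active coefficient — sparser still).

In-house baseline-hazard and survival-function estimators (Breslow-type,
including the transformed-time-scale variant for AFT/EH) plus Harrell /
Uno / Antolini concordance and the (integrated) Brier score complete the
pipeline; a simulation module generates Cox/AFT/EH data with known
coefficients for testing.  See `docs/methods.md` for formulas and
conventions.

## Worked example

```python
import numpy as np
from distillsurv import KDSurv, harrell_c, simulate_survival

train, truth = simulate_survival("cox", n=400, p=30, beta=[1.0, -1.0, 0.5],
                                 censor_rate=0.3, seed=1)
test, _ = simulate_survival("cox", n=400, p=30, beta=[1.0, -1.0, 0.5],
                            censor_rate=0.3, seed=2)

model = KDSurv(train, teacher="cox_breslow", alpha=0.9, k=5, seed=0)
student = model.fit(rule="pcvl")
print(student.summary())
eta = student.predict_linear(test.X)
print(f"teacher C: {harrell_c(student.teacher.predict_linear(test.X), test.time, test.event):.3f}")
print(f"student C: {harrell_c(eta, test.time, test.event):.3f}")
```

```
StudentModel  family=cox_breslow  rule=pcvl  alpha=0.9
selected path index 39 (lambda=0.1985); 3 of 30 features active
      coef
x1  0.8706
x2 -0.8995
x3  0.3701
teacher C: 0.803
student C: 0.812
```

The pcvl rule keeps exactly the three true signals out of 30 features,
with coefficients shrunk slightly toward zero by the penalty, and the
sparse student generalizes at least as well as its dense teacher (its
coefficients are a denoised, thresholded version of the teacher's).
With `rule="min"` the model is denser; with `rule="1se"` sparser.

The same pipeline from the shell:

```
distillsurv simulate --family cox --n 400 --p 30 --beta 1,-1,0.5 --seed 1 --out train.csv
distillsurv fit --data train.csv --teacher cox_breslow --rule pcvl --seed 0 \
    --model-out model.json --cv-out cv.csv
distillsurv predict --model model.json --data test.csv --out pred.csv --survival-out surv.csv
distillsurv evaluate --pred pred.csv --data test.csv --train-data train.csv \
    --survival surv.csv --out metrics.csv
```

Models serialize to JSON (sparse coefficients, baseline hazard knots,
teacher metadata); deserializing reproduces predictions exactly.

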