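# gofsurv

Goodness-of-fit two-phase sampling designs for time-to-event outcomes.

## The problem

Prospective cohort studies of rare diseases often cannot afford to assay
an expensive biomarker on everyone. Two-phase designs measure cheap
covariates X on the full cohort (phase I) and the biomarker Z on a
selected subset (phase II); the classic choice is the case-cohort design,
which pairs all cases with a random subcohort. `gofsurv` implements a more
informative alternative: given an external working survival model on X
(a published risk calculator, or a preliminary Cox fit), score every
subject by how badly the working model explains their observed outcome,

    D(T, delta, X) = | delta - 1 + S_e(T | X) |,

and select phase II with probability min{1, c_k D}, oversampling the
poorly-fit subjects — exactly the ones whose risk the missing biomarker
might explain. The constants c_k are calibrated so the expected phase-II
sample hits a target case-control ratio (all cases are kept by default).
The log hazard ratios (beta, alpha) of the Cox model

    lambda(t | X, Z) = lambda_0(t) exp(beta'X + alpha'Z)

are then estimated from the phase-II subset by inverse-probability-
weighted partial likelihood with robust (sandwich) standard errors.

The package bundles everything needed to study this design end to end:

- `gofsurv.cohort` — synthetic cohorts (six epidemiological risk factors,
  an AGE-correlated biomarker, Weibull-baseline Cox event times,
  calibrated censoring);
- `gofsurv.coxph` — weighted Cox estimation written from first
  principles: Newton-Raphson, Breslow/Efron ties, model-based and
  sandwich covariance, Wald tests, Breslow baseline hazard;
- `gofsurv.external` — the working model S_e(t|x) fit on bootstrapped
  phase-I data;
- `gofsurv.gof` — the D quantity, constant calibration, unstratified and
  balanced (stratified) Bernoulli selection, IPW weights;
- `gofsurv.cc` — size-matched case-cohort comparators (the weighted
  Prentice / Borgan I reduction);
- `gofsurv.engine` — the Monte-Carlo study: bias, empirical SD, mean
  robust SE, 95% coverage, type-I error / power, relative efficiency.

## Worked example

```python
import numpy as np
from gofsurv import (CohortConfig, GofDesignConfig, SurvivalData,
                     assemble_cohort, fit_coxph, fit_external, select_phase2)

cohort = assemble_cohort(CohortConfig(seed=42))        # N=2000, ~5% events
external = fit_external(cohort, bootstrap_size=10_000, seed=1)
sample = select_phase2(cohort, external, GofDesignConfig(case_control_ratio=1.0, seed=2))

sel = sample.selected == 1
df = cohort.data
terms = ["age", "agemen", "biopsy", "ftp", "rel", "race", "z"]
fit = fit_coxph(SurvivalData(df["time"][sel], df["event"][sel],
                             df[terms][sel].to_numpy(),
                             weights=sample.weight[sel], names=terms))
print(f"cases={int(df['event'].sum())}  phase II m={sample.realized_m}")
print(f"alpha_hat={fit.coef[-1]:.3f}  robust SE={fit.se_robust[-1]:.3f}")
```

This prints

```
cases=89  phase II m=170
alpha_hat=0.179  robust SE=0.201
```

a phase-II sample of 170 of the 2000 subjects (all 89 cases plus ~81
poorly-fit controls) whose IPW estimate of the biomarker log hazard
ratio, 0.18 ± 0.20, is consistent with the generating value alpha = 0.2
at under a tenth of the assay cost of the full cohort.

A full design-comparison study runs from the command line:

```sh
gofsurv simulate --config scenarios.yaml --out results/ --seed 1
gofsurv summarize --in results/
```

where `scenarios.yaml` lists `ScenarioConfig` fields (event_rate,
alpha_true, ratio, stratification, n_replicates, designs, master_seed).
The output directory gets per-replicate fit tables, per-scenario metric
tables, a combined table across scenarios, an SE-comparison figure and a
flat manifest that makes the run bit-for-bit reproducible.

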