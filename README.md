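# cloneirt

Bayesian item response modeling, model checking, and optimal test assembly
for **clone-structured item banks** — banks of puzzle *templates* (e.g.
matrix-reasoning items) each realized as several perceptual/distractor
*clones*.

Test developers using such banks face three linked questions: how difficult
and discriminating is every item (and how do complexity attributes such as
element and rule number shape that); are the clones of a template
psychometrically exchangeable; and how should fixed short forms be
assembled so that parallel versions measure with equal, maximal precision.
`cloneirt` answers them with a single pipeline:

1. **Simulation** of complete calibration studies (stratified item sets,
   counterbalanced clone assignment, censored response times, data-quality
   artifacts) with known ground truth.
2. **Estimation** of six nested additive multilevel item structure (AMIS)
   3PL models by Hamiltonian Monte Carlo,

       P(correct) = γ + (1 − γ) · logistic(α_jk θ_i − β_jk),
       β_jk = μ_β + Q_j δ_β + ε_βj + R_k δ_β' + ε_βk   (likewise α_jk),
       θ_i  = X_i ρ + ε_i,   V(ε_i) = 1 − Σρ²,

   with guessing fixed at γ = 0.25, discrimination bounded to [0, 5], and
   person covariates (age, gender, response-time behavior) explaining
   ability.
3. **Comparison** of the six models by PSIS leave-one-cluster-out
   cross-validation, where a cluster is an item template and held-out
   residuals are integrated over their priors.
4. **Checking** via posterior predictive p values for the observed-score
   χ² discrepancy and the SGDDM local-dependence statistic, a
   score-distribution check for new samples under fixed item parameters,
   and a parameter-recovery harness.
5. **Response-time analysis**: a mixed model of log RT on
   accuracy × rest-score × difficulty, and the person-level RT covariates.
6. **Assembly** of parallel test forms by mixed integer programming:
   maximize the minimum test information over an ability grid subject to
   form length, one-clone-per-template, distractor homogeneity,
   shared-template and clone-uniqueness constraints, with matched test
   information across forms.

## Worked example

```python
import numpy as np
from cloneirt import (desk_config, simulate_study, fit_amis, desk_sampler,
                      summarize_item_params, marginal_attribute_effect)

study = simulate_study(desk_config(seed=11))          # 16 templates x 6 clones, 300 persons
fit = fit_amis(study.responses, study.bank, 5,        # model 5: best-supported structure
               desk_sampler(seed=1), persons=study.persons)
print(fit.diagnostics["rhat_max"], fit.diagnostics["divergences"])
# 1.0068 0

truth = study.item_params.set_index("clone_id").loc[fit.data.clone_ids]
est = fit.draws["beta"].mean(axis=0)
print(np.corrcoef(truth["beta"], est)[0, 1])
# 0.9527
```

The fit converges under the sampler contract (all split R-hat < 1.01, no
divergences), and the 96 true clone difficulties are recovered with
correlation ≈ 0.95 from 300 simulated respondents.

The closed-form attribute contrasts — how much a one-unit change in an
attribute costs an average-ability respondent — come straight from the
response model:

```python
for name, delta in [("element", 0.579), ("rule", 0.514), ("distractor", 1.105)]:
    print(name, round(marginal_attribute_effect(delta, mu_beta=0.177), 1), "%")
# element 10.7 %
# rule 9.5 %
# distractor 20.1 %
```

A one-unit increase in element or rule number each costs roughly 10
percentage points of accuracy; minimal-difference distractors cost about 20
relative to paired-difference ones — the basis for treating clones as
*non*-exchangeable and constraining assembly accordingly.

There is also a thin CLI over the same functions:

```bash
cloneirt simulate --out run/study --seed 3 --n-persons 300
cloneirt compare --study run/study --models 1,3 --out run/comparison.csv
cloneirt assemble --items run/items.csv --forms 3 --length 12 --shared-templates --out run/forms.csv
```

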