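# setshift

Simulation and hierarchical Bayesian modelling of set-shifting task
behaviour: **probabilistic reversal learning (PRL)** and the **Wisconsin
Card Sorting Task (WCST)**.

The package is for computational-psychiatry researchers who analyse
trial-level choice data from these two paradigms — e.g. comparing patient
and control groups on *how* they learn rather than only on summary scores.
It provides the full chain:

* **task environments** — an 80/20 probabilistic two-choice task whose
  contingencies reverse after 40 trials, and a 9-set card-sorting task whose
  hidden rule changes after 10 consecutive correct sorts;
* **generative models** — the 4-parameter reinforcement learner for PRL
  (reward rate α⁺, punishment rate α⁻, reinforcement sensitivity β,
  stickiness κ) with choice rule
  P(a) ∝ exp(β·Q_a + κ·1[a = previous choice]) and delta-rule value
  updates Q ← Q + α(o − Q); and the 3-parameter sequential attention model
  for WCST (reward rate r, punishment rate p, decision consistency d) with
  P(deck k) ∝ m(k)^d over attention-weighted match signals;
* **behavioural measures** — accuracy, switch-after-spurious-negative,
  stay-after-veridical-positive, perseveration (PRL); sets completed and the
  perseverative / nonperseverative / unique error taxonomy (WCST);
* **hierarchical Bayesian fitting** per group (probit-linked normal
  populations, Metropolis-within-Gibbs with numba-compiled likelihoods,
  arviz diagnostics), group contrasts as highest-density intervals of the
  posterior mean difference (patient minus control), and **bridge-sampled
  marginal likelihoods** for model comparison;
* a **synthetic-cohort generator and parameter-recovery harness** — the
  validation standard for cognitive models, and the stand-in for clinical
  datasets that cannot be shared.

## Worked example

Fit both groups of a synthetic two-group cohort and contrast the model
parameters (this is `examples/04_group_contrast.py`):

```python
import numpy as np, warnings
import setshift as ss
from setshift.fitting import FitConfig

spec = ss.paper_like_prl(n_per_group=15, seed=21)   # control vs patient
trials, truth = ss.generate_cohort(spec)

posts = {}
for i, g in enumerate(("control", "patient")):
    seed = int(np.random.SeedSequence([4, i]).generate_state(1)[0] % 2**31)
    posts[g] = ss.fit_hierarchical(
        ss.prl_model_spec(), trials[trials.group == g],
        FitConfig(chains=4, warmup=400, draws=400, seed=seed), group_name=g)

for name in ("alpha_rew", "alpha_pun", "beta", "kappa"):
    c = ss.group_contrast(posts["patient"], posts["control"], name)
    print(name, round(c.mean, 3), c.hdi95, c.excludes_zero_95)
```

Output:

```
patient minus control, natural scale:
  alpha_rew  MD +0.128  95% HDI [-0.156, +0.357]
  alpha_pun  MD -0.258  95% HDI [-0.431, -0.081] *
  beta       MD -5.006  95% HDI [-8.241, -1.990] *
  kappa      MD -0.195  95% HDI [-0.721, +0.267]
```

The cohort was generated with patient-minus-control gaps of +0.21 (reward
rate), −0.29 (punishment rate), −4.91 (sensitivity) and −0.35 (stickiness).
All four estimated mean differences point the right way; at 15 subjects per
group the punishment-rate and sensitivity differences are already credible
(their 95% HDIs exclude zero, starred), while the reward-rate and
stickiness gaps need larger samples.

The other scripts in `examples/` each demonstrate one capability: task
simulation and measures (01), exact sequence likelihoods (02), a single
hierarchical fit with diagnostics (03), bridge-sampled model comparison
against an analytic benchmark (05), and full parameter recovery (06).

A thin CLI mirrors the pipeline stages:

```bash
setshift simulate --preset paper_like_prl --n-per-group 10 --out trials.csv
setshift measures trials.csv --out measures.csv
setshift run examples/quickstart.yaml --out-dir results/quickstart
```

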