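"""Marginal likelihoods by bridge sampling: analytic check, then a model race.

First the estimator is validated on a conjugate problem with a closed-form
answer; then the full PRL model races its no-stickiness reduction on data
simulated from strongly sticky agents.
"""

import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

import setshift as ss
from setshift.bridge import compare_models, log_marginal_bridge
from setshift.fitting import FitConfig, make_log_unnorm_posterior

# --- analytic testbed: prior N(0,1), one observation y = 0.5 ~ N(theta, 1)
rng = np.random.default_rng(0)
draws = rng.normal(0.25, math.sqrt(0.5), size=(4000, 1))  # exact posterior
est = log_marginal_bridge(
    draws, lambda t: norm.logpdf(t[:, 0]) + norm.logpdf(0.5, t[:, 0], 1), seed=1
)
print(f"bridge estimate {est.log_ml:.4f} vs analytic {norm.logpdf(0.5, 0, math.sqrt(2)):.4f}"
      f"  (MC error {est.mc_error:.1e}, {est.n_iter} iterations)")

# --- model race on sticky data
frames = [
    ss.prl_simulate(ss.PRLParams(0.4, 0.4, 4.0, 2.0), seed=s, subject_id=f"s{s}", group="g")
    for s in range(8)
]
trials = pd.concat(frames, ignore_index=True)
estimates = {}
with warnings.catch_warnings():
    warnings.simplefilter("ignore", ss.ConvergenceWarning)
    for model in (ss.prl_model_spec(), ss.prl_nostick_model_spec()):
        post = ss.fit_hierarchical(model, trials, FitConfig(chains=2, warmup=300, draws=600, seed=2))
        logpost, _ = make_log_unnorm_posterior(model, trials)
        estimates[model.model_id] = log_marginal_bridge(
            post.to_matrix(), logpost, seed=3, dataset="sticky-demo"
        )
print("\n" + compare_models(estimates).to_string(index=False))
# The winning row has log_bf_vs_best = 0; with kappa = 2 in the generating
# process the 4-parameter model should win despite its extra complexity.
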