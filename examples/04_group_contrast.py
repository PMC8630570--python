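"""Contrast two groups on the PRL model parameters via HDIs of the mean
difference.

Both groups are fitted independently; the contrast differences the posterior
draws of the natural-scale population means (patient minus control) and asks
whether the 95% highest density interval excludes zero.
"""

import warnings

import numpy as np
import setshift as ss
from setshift.fitting import FitConfig

spec = ss.paper_like_prl(n_per_group=15, seed=21)
trials, _ = ss.generate_cohort(spec)

posts = {}
with warnings.catch_warnings():
    warnings.simplefilter("ignore", ss.ConvergenceWarning)
    for i, g in enumerate(("control", "patient")):
        seed = int(np.random.SeedSequence([4, i]).generate_state(1)[0] % 2**31)
        posts[g] = ss.fit_hierarchical(
            ss.prl_model_spec(),
            trials[trials.group == g],
            FitConfig(chains=4, warmup=400, draws=400, seed=seed),
            group_name=g,
        )

print("patient minus control, natural scale:")
for name in ("alpha_rew", "alpha_pun", "beta", "kappa"):
    c = ss.group_contrast(posts["patient"], posts["control"], name)
    star = "*" if c.excludes_zero_95 else " "
    print(f"  {name:10s} MD {c.mean:+.3f}  95% HDI [{c.hdi95[0]:+.3f}, {c.hdi95[1]:+.3f}] {star}")
# The generating gaps are +0.21 (reward rate), -0.29 (punishment rate),
# -4.91 (sensitivity), -0.35 (stickiness); a starred row means the interval
# excludes zero, i.e. the difference is credibly nonzero at this sample size.
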