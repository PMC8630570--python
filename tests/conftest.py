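"""Shared fixtures: small simulated sessions and one reusable tiny fit."""

import warnings

import numpy as np
import pytest

import setshift as ss
from setshift.fitting import FitConfig


@pytest.fixture(scope="session")
def prl_session():
    """One 80-trial PRL session from a moderately exploitative agent."""
    params = ss.PRLParams(alpha_rew=0.4, alpha_pun=0.3, beta=5.0, kappa=0.5)
    return params, ss.prl_simulate(params, ss.PRLConfig(), seed=123)


@pytest.fixture(scope="session")
def wcst_session():
    """One WCST session from a competent attention-learning agent."""
    params = ss.WCSTParams(r=0.5, p=0.5, d=3.0)
    return params, ss.wcst_simulate(params, ss.WCSTConfig(), seed=321)


@pytest.fixture(scope="session")
def tiny_prl_fit():
    """A small but real hierarchical PRL fit, shared across tests.

    8 subjects, 2 chains; enough to exercise posterior containers, contrasts
    and diagnostics without repeating the cost per test.
    """
    spec = ss.paper_like_prl(n_per_group=8, seed=42)
    trials, truth = ss.generate_cohort(spec)
    cfg = FitConfig(chains=2, warmup=200, draws=200, seed=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ss.ConvergenceWarning)
        post = ss.fit_hierarchical(
            ss.prl_model_spec(),
            trials.loc[trials["group"] == "control"],
            cfg,
            group_name="control",
        )
    return trials, truth, post
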