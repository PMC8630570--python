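"""Hierarchical fitting machinery: HDI, contrasts, diagnostics, sampler."""

import warnings

import numpy as np
import pandas as pd
import pytest

import setshift as ss
from setshift.fitting import (
    hdi_nested,
    FitConfig,
    contrast_from_draws,
    diagnostics,
    eff_sample_size,
    hdi,
    pack_trials,
    split_rhat,
)


def brute_force_hdi(draws, mass):
    """Exhaustive minimal-window search, the independent oracle for hdi()."""
    a = np.sort(np.asarray(draws, dtype=float))
    n = a.size
    m = int(np.ceil(mass * n))
    best = None
    for i in range(n - m + 1):
        w = a[i + m - 1] - a[i]
        if best is None or w < best[0]:
            best = (w, a[i], a[i + m - 1])
    return best[1], best[2]


class TestHDI:
    def test_degenerate_distribution(self):
        assert hdi([3.0] * 25, 0.95) == (3.0, 3.0)

    def test_sorted_integers_leftmost_window(self):
        lo, hi = hdi(np.arange(1, 101, dtype=float), 0.95)
        assert (lo, hi) == (1.0, 95.0)

    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n = int(rng.integers(10, 200))
            draws = rng.standard_normal(n) * rng.uniform(0.5, 3)
            if rng.random() < 0.5:
                draws = np.exp(draws)  # skewed case
            for mass in (0.5, 0.9, 0.95):
                assert hdi(draws, mass) == brute_force_hdi(draws, mass)

    def test_narrower_than_equal_tailed_for_skewed_sample(self):
        rng = np.random.default_rng(11)
        draws = rng.lognormal(0, 1, size=2000)
        lo, hi = hdi(draws, 0.9)
        eq = np.quantile(draws, [0.05, 0.95])
        assert hi - lo < eq[1] - eq[0]

    def test_nesting(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal(500)
        lo95, hi95 = hdi(draws, 0.95)
        lo90, hi90 = hdi(draws, 0.90)
        assert lo95 <= lo90 and hi90 <= hi95

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hdi(np.arange(5, dtype=float), 0.9)  # too few draws
        with pytest.raises(ValueError):
            hdi(np.arange(100, dtype=float), 1.2)

    def test_nested_pair_always_nests_even_on_tied_samples(self):
        """Unconstrained minimal windows of different masses need not nest on
        tied or multimodal samples; the reported pair must."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(10, 120))
            draws = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            (lo95, hi95), (lo90, hi90) = hdi_nested(draws)
            assert lo95 <= lo90 and hi90 <= hi95
            assert (lo95, hi95) == brute_force_hdi(draws, 0.95)


class TestDiagnostics:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 1000))
        assert 0.99 <= split_rhat(x) <= 1.01

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 500))
        x[1] += 3.0
        assert split_rhat(x) > 1.1

    def test_ess_of_iid_draws_near_n(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, 1000))
        assert abs(eff_sample_size(x) - 4000) / 4000 < 0.2

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.zeros((1, 100)))

    def test_fit_diagnostics_table(self, tiny_prl_fit):
        _, _, post = tiny_prl_fit
        d = diagnostics(post)
        # every model parameter appears at group level and per subject
        for name in post.model.param_names:
            assert f"mu_latent[{name}]" in set(d.parameter)
            assert f"{name}[control_000]" in set(d.parameter)
        assert d.rhat.notna().all()
        with pytest.raises(ValueError):
            bad = post.__class__(
                model=post.model,
                subject_ids=post.subject_ids,
                group_name="x",
                z=post.z[:1],
                mu_latent=post.mu_latent[:1],
                sigma_latent=post.sigma_latent[:1],
            )
            diagnostics(bad)


class TestContrast:
    def test_identical_posteriors_give_zero(self, tiny_prl_fit):
        _, _, post = tiny_prl_fit
        con = ss.group_contrast(post, post, "alpha_pun")
        assert con.mean == 0.0
        assert con.hdi95 == (0.0, 0.0)
        assert not con.excludes_zero_95 and not con.excludes_zero_90
        assert con.hdi90[0] >= con.hdi95[0] and con.hdi90[1] <= con.hdi95[1]

    def test_missing_parameter(self, tiny_prl_fit):
        _, _, post = tiny_prl_fit
        with pytest.raises(KeyError):
            ss.group_contrast(post, post, "not_a_parameter")

    def test_unequal_draw_counts_subsampled(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 0.1, size=4000)
        b = rng.normal(0.0, 0.1, size=1000)
        con = contrast_from_draws(a, b, "p", "A", "B")
        assert con.n_draws == 1000
        assert con.mean == pytest.approx(1.0, abs=0.05)
        assert con.excludes_zero_95


class TestFitHierarchical:
    def test_seed_reproducibility(self, tiny_prl_fit):
        trials, _, post = tiny_prl_fit
        cfg = FitConfig(chains=2, warmup=200, draws=200, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ss.ConvergenceWarning)
            again = ss.fit_hierarchical(
                ss.prl_model_spec(),
                trials.loc[trials["group"] == "control"],
                cfg,
                group_name="control",
            )
        np.testing.assert_array_equal(post.mu_latent, again.mu_latent)
        np.testing.assert_array_equal(post.z, again.z)

    def test_posterior_tracks_truth(self, tiny_prl_fit):
        """Even a small fit should put the group mean in the right region and
        order subjects roughly by their true punishment rate."""
        trials, truth, post = tiny_prl_fit
        from scipy.stats import spearmanr

        tr = truth[truth.group == "control"]
        gm = post.group_mean_natural("alpha_pun").mean()
        assert abs(gm - tr["alpha_pun"].mean()) < 0.2
        rho = spearmanr(
            tr["alpha_pun"], post.posterior_mean_subjects("alpha_pun")
        ).statistic
        assert rho > 0.2

    def test_subject_order_invariance(self, tiny_prl_fit):
        """Group-mean posterior is unchanged (within MC error) when subject
        rows are presented in a different order."""
        trials, _, post = tiny_prl_fit
        sub = trials.loc[trials["group"] == "control"]
        order = list(dict.fromkeys(sub.subject_id))[::-1]
        permuted = pd.concat(
            [sub[sub.subject_id == s] for s in order], ignore_index=True
        )
        cfg = FitConfig(chains=2, warmup=200, draws=200, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ss.ConvergenceWarning)
            post2 = ss.fit_hierarchical(
                ss.prl_model_spec(), permuted, cfg, group_name="control"
            )
        a = post.group_mean_natural("alpha_pun")
        b = post2.group_mean_natural("alpha_pun")
        assert abs(a.mean() - b.mean()) < 3 * (a.std() + b.std()) / np.sqrt(min(
            eff_sample_size(a), eff_sample_size(b)
        ))

    def test_low_sensitivity_cohort_recovered_low(self):
        """Subjects simulated with near-zero sensitivity should yield a group
        sensitivity posterior concentrated well below the prior midpoint."""
        frames = [
            ss.prl_simulate(
                ss.PRLParams(0.4, 0.4, 0.2, 0.0),
                seed=s,
                subject_id=f"s{s}",
                group="flat",
            )
            for s in range(8)
        ]
        trials = pd.concat(frames, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ss.ConvergenceWarning)
            post = ss.fit_hierarchical(
                ss.prl_model_spec(),
                trials,
                FitConfig(chains=2, warmup=200, draws=200, seed=4),
            )
        assert post.group_mean_natural("beta").mean() < 4.0  # prior midpoint is 10

    def test_input_validation(self, tiny_prl_fit):
        trials, _, _ = tiny_prl_fit
        one_subject = trials[trials.subject_id == "control_000"]
        with pytest.raises(ss.TrialDataError):
            ss.fit_hierarchical(ss.prl_model_spec(), one_subject)
        with pytest.raises(ValueError):
            ss.fit_hierarchical(
                ss.prl_model_spec(), trials, FitConfig(chains=1)
            )
        mixed = trials.copy()
        mixed.loc[mixed.index[:80], "task"] = "wcst"
        with pytest.raises(ss.TrialDataError):
            pack_trials(mixed, "prl")
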