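"""Hierarchical Bayesian fitting of the task models.

Model structure (one fit per group, groups fitted independently):

* each subject ``s`` has a latent parameter vector ``z_s`` in R^P;
* natural-scale parameters are ``theta_s = link(z_s)`` — probit links for
  unit-interval rates, scaled probit for bounded-positive parameters
  (reinforcement sensitivity, decision consistency), identity for stickiness;
* ``z_sp ~ Normal(mu_p, sigma_p)`` with priors ``mu_p ~ Normal(0, 1)`` and
  ``sigma_p ~ half-Normal(0.5)``.

Inference is Metropolis-within-Gibbs: adaptive random-walk Metropolis for the
subject latents (one parameter column at a time, all subjects in parallel —
subjects are conditionally independent given the group level), a conjugate
Gibbs draw for each group mean, and random-walk Metropolis on ``log sigma``
for the group SDs.  Trial likelihoods are numba-compiled.

The "group mean on the natural scale" reported for contrasts is the
population mean of ``link(Z)`` under the group normal, which is available in
closed form for every link used (probit: ``upper * Phi(mu / sqrt(1+sigma^2))``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from ._kernels import prl_loglik_batch, wcst_loglik_batch
from .io import TrialDataError, str_to_card
from .tasks import DIMENSIONS, KEY_CARDS, STIMULI

__all__ = [
    "ProbitLink",
    "ScaledProbitLink",
    "IdentityLink",
    "ParamSpec",
    "HierModelSpec",
    "FitConfig",
    "PosteriorSamples",
    "GroupContrast",
    "ConvergenceWarning",
    "prl_model_spec",
    "prl_nostick_model_spec",
    "wcst_model_spec",
    "wcst_shared_rate_model_spec",
    "model_spec_by_id",
    "pack_trials",
    "fit_hierarchical",
    "hdi",
    "hdi_nested",
    "group_contrast",
    "diagnostics",
    "split_rhat",
    "eff_sample_size",
    "make_log_unnorm_posterior",
]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when R-hat or acceptance diagnostics look bad."""


# ---------------------------------------------------------------------------
# Links
# ---------------------------------------------------------------------------


class ProbitLink:
    """Unit-interval parameter: theta = Phi(z)."""

    upper = 1.0

    def to_natural(self, z):
        return ndtr(z)

    def to_latent(self, x):
        return ndtri(np.clip(x, 1e-12, 1 - 1e-12))

    def population_mean(self, mu, sigma):
        return ndtr(mu / np.sqrt(1.0 + sigma**2))


class ScaledProbitLink:
    """Bounded positive parameter: theta = upper * Phi(z)."""

    def __init__(self, upper: float):
        self.upper = float(upper)

    def to_natural(self, z):
        return self.upper * ndtr(z)

    def to_latent(self, x):
        return ndtri(np.clip(np.asarray(x) / self.upper, 1e-12, 1 - 1e-12))

    def population_mean(self, mu, sigma):
        return self.upper * ndtr(mu / np.sqrt(1.0 + sigma**2))


class IdentityLink:
    def to_natural(self, z):
        return z

    def to_latent(self, x):
        return np.asarray(x, dtype=float)

    def population_mean(self, mu, sigma):
        return mu


@dataclass(frozen=True)
class ParamSpec:
    name: str
    link: object


@dataclass(frozen=True)
class HierModelSpec:
    """A hierarchical task model: free parameters with links, priors, and the
    mapping from free to kernel parameters (used by nested reductions that
    clamp or share a parameter)."""

    model_id: str
    task: str  # "prl" | "wcst"
    params: tuple
    prior_mu_sd: float = 1.0
    prior_sigma_scale: float = 0.5
    expand: Callable[[np.ndarray], np.ndarray] | None = None  # [S,Pfree]->[S,Pkernel]

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.params]

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        """Map latent [.., P] to natural scale column-wise."""
        out = np.empty_like(np.asarray(z, dtype=float))
        for j, p in enumerate(self.params):
            out[..., j] = p.link.to_natural(z[..., j])
        return out

    def to_kernel(self, z: np.ndarray) -> np.ndarray:
        nat = self.to_natural(z)
        return nat if self.expand is None else self.expand(nat)


def prl_model_spec(beta_upper: float = 20.0) -> HierModelSpec:
    """The four-parameter PRL model (reward rate, punishment rate,
    reinforcement sensitivity, stickiness)."""
    return HierModelSpec(
        model_id="prl_rl4",
        task="prl",
        params=(
            ParamSpec("alpha_rew", ProbitLink()),
            ParamSpec("alpha_pun", ProbitLink()),
            ParamSpec("beta", ScaledProbitLink(beta_upper)),
            ParamSpec("kappa", IdentityLink()),
        ),
    )


def prl_nostick_model_spec(beta_upper: float = 20.0) -> HierModelSpec:
    """Nested reduction: stickiness clamped to zero."""

    def expand(nat):
        return np.concatenate([nat, np.zeros((*nat.shape[:-1], 1))], axis=-1)

    return HierModelSpec(
        model_id="prl_rl3_nostick",
        task="prl",
        params=(
            ParamSpec("alpha_rew", ProbitLink()),
            ParamSpec("alpha_pun", ProbitLink()),
            ParamSpec("beta", ScaledProbitLink(beta_upper)),
        ),
        expand=expand,
    )


def wcst_model_spec(d_upper: float = 10.0) -> HierModelSpec:
    """The three-parameter WCST sequential attention model."""
    return HierModelSpec(
        model_id="wcst_seq3",
        task="wcst",
        params=(
            ParamSpec("r", ProbitLink()),
            ParamSpec("p", ProbitLink()),
            ParamSpec("d", ScaledProbitLink(d_upper)),
        ),
    )


def wcst_shared_rate_model_spec(d_upper: float = 10.0) -> HierModelSpec:
    """Nested reduction: a single learning rate for reward and punishment."""

    def expand(nat):
        return np.concatenate([nat[..., :1], nat], axis=-1)

    return HierModelSpec(
        model_id="wcst_seq2_sharedrate",
        task="wcst",
        params=(
            ParamSpec("rate", ProbitLink()),
            ParamSpec("d", ScaledProbitLink(d_upper)),
        ),
        expand=expand,
    )


_MODEL_FACTORIES = {
    "prl_rl4": prl_model_spec,
    "prl_rl3_nostick": prl_nostick_model_spec,
    "wcst_seq3": wcst_model_spec,
    "wcst_seq2_sharedrate": wcst_shared_rate_model_spec,
}


def model_spec_by_id(model_id: str) -> HierModelSpec:
    try:
        return _MODEL_FACTORIES[model_id]()
    except KeyError:
        raise KeyError(
            f"unknown model_id {model_id!r}; available: {sorted(_MODEL_FACTORIES)}"
        ) from None


# ---------------------------------------------------------------------------
# Data packing
# ---------------------------------------------------------------------------

_DIM_BIT = {d: 1 << i for i, d in enumerate(DIMENSIONS)}

# 64 cards x 4 decks match bitmasks are card-determined; precompute lazily
_card_bits_cache: dict[tuple, np.ndarray] = {}


def _card_bits(card) -> np.ndarray:
    key = (card.color, card.shape, card.number)
    bits = _card_bits_cache.get(key)
    if bits is None:
        bits = np.zeros(4, dtype=np.uint8)
        for k, deck in enumerate(KEY_CARDS):
            b = 0
            for d in DIMENSIONS:
                if card.attribute(d) == deck.attribute(d):
                    b |= _DIM_BIT[d]
            bits[k] = b
        _card_bits_cache[key] = bits
    return bits


def pack_trials(trials: pd.DataFrame, task: str) -> dict:
    """Pack long-format trials into padded per-subject arrays for the numba
    kernels.  Subjects keep their order of first appearance."""
    tasks_seen = set(trials["task"].unique()) if "task" in trials.columns else {task}
    if len(tasks_seen) > 1:
        raise TrialDataError(f"mixed tasks in one cohort: {sorted(tasks_seen)}")
    subjects = list(dict.fromkeys(trials["subject_id"]))
    if len(subjects) < 1:
        raise TrialDataError("empty cohort")
    groups = [trials.loc[trials["subject_id"] == s] for s in subjects]
    n_trials = np.array([len(g) for g in groups], dtype=np.int64)
    T = int(n_trials.max())
    S = len(subjects)
    if task == "prl":
        choices = np.zeros((S, T), dtype=np.int8)
        outcomes = np.zeros((S, T), dtype=np.int8)
        for i, g in enumerate(groups):
            choices[i, : n_trials[i]] = [STIMULI.index(c) for c in g["choice"]]
            outcomes[i, : n_trials[i]] = g["feedback"].to_numpy(dtype=np.int8)
        return {
            "task": "prl",
            "subjects": subjects,
            "choices": choices,
            "outcomes": outcomes,
            "n_trials": n_trials,
        }
    elif task == "wcst":
        choices = np.zeros((S, T), dtype=np.int8)
        feedback = np.zeros((S, T), dtype=np.int8)
        match_bits = np.zeros((S, T, 4), dtype=np.uint8)
        for i, g in enumerate(groups):
            choices[i, : n_trials[i]] = g["choice"].to_numpy(dtype=np.int64) - 1
            feedback[i, : n_trials[i]] = g["feedback"].to_numpy(dtype=np.int8)
            for t, text in enumerate(g["stimulus_or_card"]):
                match_bits[i, t] = _card_bits(str_to_card(text))
        return {
            "task": "wcst",
            "subjects": subjects,
            "choices": choices,
            "feedback": feedback,
            "match_bits": match_bits,
            "n_trials": n_trials,
        }
    raise ValueError(f"unknown task {task!r}")


def _make_loglik(model: HierModelSpec, packed: dict) -> Callable[[np.ndarray], np.ndarray]:
    """Per-subject log-likelihood as a function of the latent matrix [S, P]."""
    if model.task == "prl":
        choices, outcomes, n_trials = (
            packed["choices"],
            packed["outcomes"],
            packed["n_trials"],
        )

        def ll(z):
            return prl_loglik_batch(choices, outcomes, n_trials, model.to_kernel(z))

    else:
        match_bits, choices, feedback, n_trials = (
            packed["match_bits"],
            packed["choices"],
            packed["feedback"],
            packed["n_trials"],
        )

        def ll(z):
            return wcst_loglik_batch(
                match_bits, choices, feedback, n_trials, model.to_kernel(z)
            )

    return ll


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    chains: int = 4
    warmup: int = 500
    draws: int = 500
    seed: int = 0
    target_accept: float = 0.44  # per-coordinate random-walk optimum


@dataclass
class PosteriorSamples:
    """Posterior draws of one hierarchical fit.

    Arrays are indexed ``[chain, draw, ...]``; subject latents additionally by
    subject then parameter.  Natural-scale views are derived on demand.
    """

    model: HierModelSpec
    subject_ids: list
    group_name: str
    z: np.ndarray  # [chain, draw, S, P] latent subject parameters
    mu_latent: np.ndarray  # [chain, draw, P]
    sigma_latent: np.ndarray  # [chain, draw, P]
    accept_rate: dict = field(default_factory=dict)
    divergences: int = 0  # random-walk kernel: no divergent transitions exist

    @property
    def n_chains(self) -> int:
        return self.z.shape[0]

    @property
    def n_draws(self) -> int:
        return self.z.shape[1]

    def subject_natural(self, parameter: str) -> np.ndarray:
        """Draws of one subject-level parameter, natural scale [chain, draw, S]."""
        j = self.model.param_names.index(parameter)
        return self.model.params[j].link.to_natural(self.z[..., j])

    def group_mean_natural(self, parameter: str) -> np.ndarray:
        """Draws of the population mean on the natural scale [chain, draw]."""
        j = self.model.param_names.index(parameter)
        link = self.model.params[j].link
        return link.population_mean(self.mu_latent[..., j], self.sigma_latent[..., j])

    def posterior_mean_subjects(self, parameter: str) -> np.ndarray:
        """Posterior mean of each subject's natural-scale parameter [S]."""
        return self.subject_natural(parameter).mean(axis=(0, 1))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.model.param_names:
            gm = self.group_mean_natural(name).ravel()
            rows.append(
                {
                    "parameter": name,
                    "group_mean": float(gm.mean()),
                    "group_mean_sd": float(gm.std()),
                    "sigma_latent": float(
                        self.sigma_latent[..., self.model.param_names.index(name)].mean()
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_matrix(self) -> np.ndarray:
        """Flatten draws to the unconstrained layout used by bridge sampling:
        ``[z_11..z_1P, ..., z_S1..z_SP, mu_1..mu_P, log sigma_1..log sigma_P]``.
        """
        C, D, S, P = self.z.shape
        z = self.z.reshape(C * D, S * P)
        mu = self.mu_latent.reshape(C * D, P)
        eta = np.log(self.sigma_latent.reshape(C * D, P))
        return np.concatenate([z, mu, eta], axis=1)

    def to_inferencedata(self):
        """Export to an :class:`arviz.InferenceData` for storage/diagnostics."""
        import arviz as az

        post = {
            "mu_latent": self.mu_latent,
            "sigma_latent": self.sigma_latent,
            "z": self.z,
        }
        for name in self.model.param_names:
            post[f"group_mean_{name}"] = self.group_mean_natural(name)
        return az.from_dict(
            posterior=post,
            dims={
                "mu_latent": ["param"],
                "sigma_latent": ["param"],
                "z": ["subject", "param"],
            },
            coords={
                "param": self.model.param_names,
                "subject": [str(s) for s in self.subject_ids],
            },
            attrs={"model_id": self.model.model_id, "group": self.group_name},
        )


def _halfnormal_logpdf(x, scale):
    return (
        0.5 * math.log(2.0 / math.pi)
        - math.log(scale)
        - 0.5 * (np.asarray(x) / scale) ** 2
    )


def _run_chain(
    model: HierModelSpec,
    loglik: Callable,
    S: int,
    cfg: FitConfig,
    rng: np.random.Generator,
):
    """One MCMC chain.  Per sweep:

    1. per-coordinate random-walk Metropolis on each subject latent column
       (all subjects in parallel — conditionally independent given the group);
    2. a joint per-subject proposal from an adapted covariance (handles
       within-subject parameter trade-offs such as sensitivity vs stickiness);
    3. conjugate Gibbs draw of each group mean;
    4. group translation: shift mu_j and every subject's z_j together
       (decouples group-mean mixing from the slow drift of subject latents);
    5. group scale: rescale residuals and sigma_j together, then a
       random-walk Metropolis refresh of log sigma_j.
    """
    P = len(model.params)
    z = rng.normal(0.0, 0.5, size=(S, P))
    mu = z.mean(axis=0)
    sigma = np.full(P, 0.5)
    ll_cur = loglik(z)

    log_step_z = np.full((S, P), math.log(0.5))
    log_step_joint = np.full(S, math.log(1.0))
    log_step_shift = np.full(P, math.log(0.3))
    log_step_scale = np.full(P, math.log(0.3))
    log_step_s = np.full(P, math.log(0.5))
    prior_mu_var = model.prior_mu_sd**2

    # running per-subject moments for the adaptive joint proposal
    run_mean = z.copy()
    run_cov = np.tile(0.25 * np.eye(P), (S, 1, 1))
    run_n = 1

    keep_z = np.empty((cfg.draws, S, P))
    keep_mu = np.empty((cfg.draws, P))
    keep_sigma = np.empty((cfg.draws, P))
    acc_z = 0
    acc_z_n = 0

    total = cfg.warmup + cfg.draws
    for it in range(total):
        warm = it < cfg.warmup
        gamma = (it + 1) ** -0.6 if warm else 0.0

        # --- 1. subject latents, one column at a time
        for j in range(P):
            prop = z[:, j] + np.exp(log_step_z[:, j]) * rng.standard_normal(S)
            z_prop = z.copy()
            z_prop[:, j] = prop
            ll_prop = loglik(z_prop)
            logr = (
                ll_prop
                - ll_cur
                - 0.5 * ((prop - mu[j]) ** 2 - (z[:, j] - mu[j]) ** 2) / sigma[j] ** 2
            )
            acc = np.log(rng.random(S)) < logr
            z[acc, j] = prop[acc]
            ll_cur[acc] = ll_prop[acc]
            if warm:
                log_step_z[:, j] += gamma * (acc.astype(float) - cfg.target_accept)
            else:
                acc_z += int(acc.sum())
                acc_z_n += S

        # --- 2. joint per-subject move from the adapted covariance
        chol = np.linalg.cholesky(run_cov + 1e-6 * np.eye(P))
        step = (2.38 / math.sqrt(P)) * np.exp(log_step_joint)
        eps = np.einsum("spq,sq->sp", chol, rng.standard_normal((S, P)))
        z_prop = z + step[:, None] * eps
        ll_prop = loglik(z_prop)
        dprior = -0.5 * (
            ((z_prop - mu) / sigma) ** 2 - ((z - mu) / sigma) ** 2
        ).sum(axis=1)
        acc = np.log(rng.random(S)) < ll_prop - ll_cur + dprior
        z[acc] = z_prop[acc]
        ll_cur[acc] = ll_prop[acc]
        if warm:
            log_step_joint += gamma * (acc.astype(float) - 0.23)
            run_n += 1
            w = 1.0 / (run_n + 1)
            diff = z - run_mean
            run_mean += w * diff
            run_cov = (1 - w) * run_cov + w * np.einsum("sp,sq->spq", diff, diff)
        else:
            acc_z += int(acc.sum())
            acc_z_n += S

        # --- 3. group means: conjugate normal draw
        for j in range(P):
            prec = S / sigma[j] ** 2 + 1.0 / prior_mu_var
            mean = (z[:, j].sum() / sigma[j] ** 2) / prec
            mu[j] = mean + rng.standard_normal() / math.sqrt(prec)

        # --- 4. group translation: mu_j and all z_j move together.
        # Residuals are unchanged, so only the likelihood and mu prior enter.
        for j in range(P):
            delta = math.exp(log_step_shift[j]) * rng.standard_normal()
            z_prop = z.copy()
            z_prop[:, j] += delta
            ll_prop = loglik(z_prop)
            mu_new = mu[j] + delta
            logr = (
                float(ll_prop.sum() - ll_cur.sum())
                - 0.5 * (mu_new**2 - mu[j] ** 2) / prior_mu_var
            )
            if math.log(rng.random()) < logr:
                z = z_prop
                ll_cur = ll_prop
                mu[j] = mu_new
            if warm:
                log_step_shift[j] += gamma * (
                    float(min(1.0, math.exp(min(logr, 0.0)))) - 0.23
                )

        # --- 5a. group scale: z_j <- mu_j + c (z_j - mu_j), sigma_j <- c sigma_j.
        # The residual prior change cancels against the transform Jacobian up
        # to one factor of c (see acceptance below).
        for j in range(P):
            eps_c = math.exp(log_step_scale[j]) * rng.standard_normal()
            c = math.exp(eps_c)
            z_prop = z.copy()
            z_prop[:, j] = mu[j] + c * (z[:, j] - mu[j])
            s_new = c * sigma[j]
            ll_prop = loglik(z_prop)
            logr = (
                float(ll_prop.sum() - ll_cur.sum())
                + float(
                    _halfnormal_logpdf(s_new, model.prior_sigma_scale)
                    - _halfnormal_logpdf(sigma[j], model.prior_sigma_scale)
                )
                + eps_c
            )
            if math.log(rng.random()) < logr:
                z = z_prop
                ll_cur = ll_prop
                sigma[j] = s_new
            if warm:
                log_step_scale[j] += gamma * (
                    float(min(1.0, math.exp(min(logr, 0.0)))) - 0.23
                )

        # --- 5b. group SDs: random-walk Metropolis on log sigma
        for j in range(P):
            eta = math.log(sigma[j])
            eta_prop = eta + math.exp(log_step_s[j]) * rng.standard_normal()
            s_prop = math.exp(eta_prop)
            resid = z[:, j] - mu[j]

            def sd_logpost(s, e):
                return (
                    -S * math.log(s)
                    - 0.5 * float(resid @ resid) / s**2
                    + float(_halfnormal_logpdf(s, model.prior_sigma_scale))
                    + e  # Jacobian of the log transform
                )

            logr = sd_logpost(s_prop, eta_prop) - sd_logpost(sigma[j], eta)
            acc_s = math.log(rng.random()) < logr
            if acc_s:
                sigma[j] = s_prop
            if warm:
                log_step_s[j] += gamma * (float(acc_s) - 0.3)

        if not warm:
            k = it - cfg.warmup
            keep_z[k] = z
            keep_mu[k] = mu
            keep_sigma[k] = sigma

    return keep_z, keep_mu, keep_sigma, acc_z / max(acc_z_n, 1)


def fit_hierarchical(
    model: HierModelSpec,
    trials: pd.DataFrame,
    fit_config: FitConfig = FitConfig(),
    group_name: str | None = None,
) -> PosteriorSamples:
    """Fit one group's trial data hierarchically; returns posterior draws.

    Emits a :class:`ConvergenceWarning` (never an error) when any split
    R-hat exceeds 1.01.  Refitting with identical data, config and seed is
    bit-reproducible.
    """
    if fit_config.chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    packed = pack_trials(trials, model.task)
    S = len(packed["subjects"])
    if S < 2:
        raise TrialDataError("hierarchical fit requires at least 2 subjects")
    if group_name is None:
        group_name = str(trials["group"].iloc[0]) if "group" in trials.columns else "group"
    loglik = _make_loglik(model, packed)

    zs, mus, sigmas, accs = [], [], [], []
    for chain in range(fit_config.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(fit_config.seed), chain])
        )
        kz, km, ks, acc = _run_chain(model, loglik, S, fit_config, rng)
        zs.append(kz)
        mus.append(km)
        sigmas.append(ks)
        accs.append(acc)

    post = PosteriorSamples(
        model=model,
        subject_ids=list(packed["subjects"]),
        group_name=group_name,
        z=np.stack(zs),
        mu_latent=np.stack(mus),
        sigma_latent=np.stack(sigmas),
        accept_rate={"subject_latents": float(np.mean(accs))},
    )
    diag = diagnostics(post, include_subjects=False)
    bad = diag.loc[diag["rhat"] > 1.01, "parameter"].tolist()
    if bad:
        warnings.warn(
            f"fit of group {group_name!r} ({model.model_id}): R-hat > 1.01 for {bad}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return post


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def split_rhat(x: np.ndarray) -> float:
    """Split R-hat of draws shaped [chain, draw]."""
    import arviz as az

    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("split_rhat needs [chain, draw] with >= 2 chains")
    return float(az.rhat(az.convert_to_dataset(x[..., None]))["x"].values[0])


def eff_sample_size(x: np.ndarray) -> float:
    """Bulk effective sample size of draws shaped [chain, draw]."""
    import arviz as az

    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("eff_sample_size needs [chain, draw] with >= 2 chains")
    return float(az.ess(az.convert_to_dataset(x[..., None]))["x"].values[0])


def diagnostics(samples: PosteriorSamples, include_subjects: bool = True) -> pd.DataFrame:
    """Split R-hat and bulk ESS per parameter, with a flag at R-hat > 1.01."""
    if samples.n_chains < 2:
        raise ValueError("diagnostics undefined for a single chain")
    rows = []

    def add(name, arr2d):
        rows.append(
            {
                "parameter": name,
                "rhat": split_rhat(arr2d),
                "ess_bulk": eff_sample_size(arr2d),
            }
        )

    for j, name in enumerate(samples.model.param_names):
        add(f"mu_latent[{name}]", samples.mu_latent[..., j])
        add(f"sigma_latent[{name}]", samples.sigma_latent[..., j])
        add(f"group_mean[{name}]", samples.group_mean_natural(name))
        if include_subjects:
            nat = samples.subject_natural(name)
            for i, sid in enumerate(samples.subject_ids):
                add(f"{name}[{sid}]", nat[..., i])
    df = pd.DataFrame(rows)
    df["flag"] = df["rhat"] > 1.01
    return df


# ---------------------------------------------------------------------------
# HDI and contrasts
# ---------------------------------------------------------------------------


def hdi(draws: Sequence[float], mass: float) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` sorted
    draws; on width ties the leftmost window wins."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    a = np.sort(np.asarray(draws, dtype=float).ravel())
    n = a.size
    if n < 10:
        raise ValueError(f"need at least 10 draws, got {n}")
    m = int(math.ceil(mass * n))
    widths = a[m - 1 :] - a[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first (leftmost) minimum
    return float(a[i]), float(a[i + m - 1])


def hdi_nested(draws: Sequence[float]) -> tuple[tuple[float, float], tuple[float, float]]:
    """95% and 90% HDIs with nesting guaranteed by construction.

    The 95% interval is the exact minimal window; the 90% interval is the
    minimal window containing ``ceil(0.9 n)`` draws searched *within* the
    95% interval.  For well-behaved (effectively unimodal) draws this equals
    the unconstrained minimal window; it differs only in degenerate tie or
    multimodal cases, where unconstrained minimal windows of different masses
    need not nest.
    """
    a = np.sort(np.asarray(draws, dtype=float).ravel())
    n = a.size
    lo95, hi95 = hdi(a, 0.95)
    m90 = int(math.ceil(0.90 * n))
    i0 = int(np.searchsorted(a, lo95, side="left"))
    i1 = int(np.searchsorted(a, hi95, side="right"))
    inner = a[i0:i1]
    widths = inner[m90 - 1 :] - inner[: inner.size - m90 + 1]
    i = int(np.argmin(widths))
    return (lo95, hi95), (float(inner[i]), float(inner[i + m90 - 1]))


@dataclass(frozen=True)
class GroupContrast:
    """Posterior of a group mean difference (group A minus group B) with its
    95% and 90% highest density intervals."""

    parameter: str
    group_a: str
    group_b: str
    draws: np.ndarray
    mean: float
    hdi95: tuple[float, float]
    hdi90: tuple[float, float]
    excludes_zero_95: bool
    excludes_zero_90: bool

    @property
    def n_draws(self) -> int:
        return self.draws.size


def _match_length(x: np.ndarray, n: int) -> np.ndarray:
    if x.size == n:
        return x
    idx = (np.arange(n) * (x.size / n)).astype(int)  # deterministic stride
    return x[idx]


def group_contrast(
    post_a: PosteriorSamples, post_b: PosteriorSamples, parameter: str
) -> GroupContrast:
    """Difference of the natural-scale group-mean posteriors, A minus B.

    The two fits are independent, so the pairing of draws is arbitrary; the
    larger draw set is deterministically strided down to match the smaller.
    """
    for post in (post_a, post_b):
        if parameter not in post.model.param_names:
            raise KeyError(
                f"parameter {parameter!r} not in model {post.model.model_id}"
            )
    return contrast_from_draws(
        post_a.group_mean_natural(parameter),
        post_b.group_mean_natural(parameter),
        parameter,
        post_a.group_name,
        post_b.group_name,
    )


def contrast_from_draws(
    a: np.ndarray, b: np.ndarray, parameter: str, group_a: str, group_b: str
) -> GroupContrast:
    """Build a contrast from two raw draw arrays of group means (A minus B)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n = min(a.size, b.size)
    diff = _match_length(a, n) - _match_length(b, n)
    h95, h90 = hdi_nested(diff)
    return GroupContrast(
        parameter=parameter,
        group_a=group_a,
        group_b=group_b,
        draws=diff,
        mean=float(diff.mean()),
        hdi95=h95,
        hdi90=h90,
        excludes_zero_95=not (h95[0] <= 0.0 <= h95[1]),
        excludes_zero_90=not (h90[0] <= 0.0 <= h90[1]),
    )


# ---------------------------------------------------------------------------
# Unnormalised posterior density (for bridge sampling)
# ---------------------------------------------------------------------------


def make_log_unnorm_posterior(
    model: HierModelSpec, trials: pd.DataFrame
) -> tuple[Callable[[np.ndarray], np.ndarray], int]:
    """Log unnormalised posterior on the unconstrained scale used by
    :meth:`PosteriorSamples.to_matrix`; returns ``(fn, dim)``.

    Layout per row: subject latents (subject-major), group means, log group
    SDs.  The log-SD Jacobian is included, so the density is with respect to
    the unconstrained vector.
    """
    packed = pack_trials(trials, model.task)
    S = len(packed["subjects"])
    P = len(model.params)
    loglik = _make_loglik(model, packed)
    dim = S * P + 2 * P
    scale = model.prior_sigma_scale
    mu_sd = model.prior_mu_sd

    def logpost(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if theta.shape[1] != dim:
            raise ValueError(f"expected dimension {dim}, got {theta.shape[1]}")
        out = np.empty(theta.shape[0])
        for i, row in enumerate(theta):
            z = row[: S * P].reshape(S, P)
            mu = row[S * P : S * P + P]
            eta = row[S * P + P :]
            sigma = np.exp(eta)
            lp = float(loglik(z).sum())
            lp += float(norm.logpdf(z, loc=mu, scale=sigma).sum())
            lp += float(norm.logpdf(mu, scale=mu_sd).sum())
            lp += float(_halfnormal_logpdf(sigma, scale).sum()) + float(eta.sum())
            out[i] = lp
        return out

    return logpost, dim
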