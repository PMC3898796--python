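"""Posterior inference over subjective distributions and observer parameters.

Given one subject's responses in one task, the posterior over the mixture
prior P and the observer nuisance parameters Omega is

    P(P, Omega | R, S*)  propto  P(P) P(Omega) prod_t P(R_t | S*_t, P, Omega)

with the per-trial response probabilities supplied by the ideal observer
model (perceptual noise already integrated out analytically).  Sampling is
by random-walk Metropolis-within-Gibbs over parameter blocks in an
unconstrained parameterization:

  * mixing weights      — additive log-ratio (ALR) logits, Dirichlet prior
                          with the ALR Jacobian;
  * component means     — isotropic Gaussian prior, sampled directly;
  * covariances         — per component, log eigen-scales (Gaussian prior on
                          the log, i.e. log-normal scales) and a rotation
                          angle (uniform on [0, pi));
  * log sigma_p, log temperature — Gaussian priors on the logs;
  * logit lapse         — Beta prior with the logistic Jacobian.

Proposal scales adapt toward a target acceptance rate during burn-in only,
so detailed balance holds for every retained draw, and all randomness flows
from one seeded generator: identical seed and settings give bit-identical
draws.  Covariance parameterization by eigen-scales and a rotation is
specific to 2-D feature spaces, the only configuration exercised here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .ideal_observer import (
    FAMILIARITY,
    ODD_ONE_OUT,
    ObserverParams,
    Response,
    choice_log_probabilities_batch,
    familiarity_log_likelihoods_batch,
    ooo_log_likelihoods_batch,
    stack_stimuli,
)
from .subjective_model import (
    FeatureSpace,
    GridDensity,
    SubjectiveDistribution,
    _mixture_unchecked,
)

__all__ = [
    "PriorConfig",
    "SamplerSettings",
    "PosteriorSamples",
    "log_posterior",
    "fit",
    "posterior_mean_grid",
    "sample_prior",
]

_LOG_PI = math.log(math.pi)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the priors over P and Omega.

    Scales are in SD units of the feature space.  Log-normal priors are given
    as (location, scale) of the underlying normal on the log.
    """

    n_components: int = 3
    dirichlet_alpha: float = 2.0
    mean_prior_sd: float = 2.0
    logscale_loc: float = math.log(0.6)
    logscale_scale: float = 0.5
    sigma_p_loc: float = math.log(0.5)
    sigma_p_scale: float = 0.5
    temperature_loc: float = math.log(2.0)
    temperature_scale: float = 0.75
    lapse_a: float = 1.0
    lapse_b: float = 9.0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        for name in (
            "dirichlet_alpha",
            "mean_prior_sd",
            "logscale_scale",
            "sigma_p_scale",
            "temperature_scale",
            "lapse_a",
            "lapse_b",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SamplerSettings:
    """Metropolis-within-Gibbs settings.

    burn_in defaults to 25% of n_steps; post-burn-in draws are thinned so at
    most max_draws are retained.  likelihood_weight = 0 samples the prior
    alone (used for prior-recovery checks); adaptation of proposal scales
    happens during burn-in only.
    """

    n_steps: int = 20_000
    burn_in: Optional[int] = None
    max_draws: int = 2_000
    target_accept: float = 0.25
    adapt_rate: float = 0.05
    likelihood_weight: float = 1.0
    n_init: int = 32

    @property
    def effective_burn_in(self) -> int:
        return self.n_steps // 4 if self.burn_in is None else self.burn_in


@dataclass
class PosteriorSamples:
    """Retained posterior draws plus sampler diagnostics and provenance."""

    draws: list
    log_posterior_trace: np.ndarray
    acceptance_rates: dict
    seed: int
    config: dict
    task: str
    space: FeatureSpace

    def __post_init__(self) -> None:
        if not self.draws:
            raise ValueError("draws must be nonempty")
        trace = np.asarray(self.log_posterior_trace, dtype=float)
        if not np.all(np.isfinite(trace)):
            raise ValueError("log posterior trace must be finite")
        self.log_posterior_trace = trace
        for v in self.acceptance_rates.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("acceptance rates must lie in [0, 1]")

    @property
    def n_draws(self) -> int:
        return len(self.draws)


# --------------------------------------------------------------------------
# Unconstrained parameterization
# --------------------------------------------------------------------------


class _Layout:
    """Index layout of the flat unconstrained parameter vector."""

    def __init__(self, k: int, d: int = 2):
        if d != 2:
            raise ValueError("inference supports 2-D feature spaces only")
        self.k, self.d = k, d
        i = 0

        def take(n):
            nonlocal i
            sl = slice(i, i + n)
            i += n
            return sl

        self.alr = take(k - 1)  # empty slice when k == 1
        self.means = take(k * d)
        self.log_scales = take(k * d)
        self.angles = take(k)
        self.log_sigma_p = take(1)
        self.log_temperature = take(1)
        self.logit_lapse = take(1)
        self.size = i

    def blocks(self) -> list:
        out = []
        if self.k > 1:
            out.append(("weights", self.alr))
        out += [
            ("means", self.means),
            ("scales", self.log_scales),
            ("angles", self.angles),
            ("sigma_p", self.log_sigma_p),
            ("temperature", self.log_temperature),
            ("lapse", self.logit_lapse),
        ]
        return out


def _weights_from_alr(alr: np.ndarray) -> np.ndarray:
    z = np.concatenate([alr, [0.0]])
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def _alr_from_weights(w: np.ndarray) -> np.ndarray:
    return np.log(w[:-1]) - math.log(w[-1])


def _cov_from(log_scales: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return rot @ np.diag(np.exp(2.0 * log_scales)) @ rot.T


def _cov_decompose(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigen-scales (log of sqrt eigenvalues) and rotation angle in [0, pi)."""
    vals, vecs = np.linalg.eigh(cov)
    log_scales = 0.5 * np.log(vals)
    v = vecs[:, 0]
    angle = math.atan2(v[1], v[0]) % math.pi
    return log_scales, angle


def _theta_to_model(
    theta: np.ndarray, layout: _Layout, space: FeatureSpace
) -> tuple[SubjectiveDistribution, ObserverParams]:
    k, d = layout.k, layout.d
    w = _weights_from_alr(theta[layout.alr]) if k > 1 else np.array([1.0])
    means = theta[layout.means].reshape(k, d)
    log_scales = theta[layout.log_scales].reshape(k, d)
    angles = theta[layout.angles]
    covs = np.stack([_cov_from(log_scales[m], angles[m]) for m in range(k)])
    p = _mixture_unchecked(space, w, means, covs)
    params = ObserverParams(
        perceptual_sigma=math.exp(theta[layout.log_sigma_p][0]),
        temperature=math.exp(theta[layout.log_temperature][0]),
        lapse=1.0 / (1.0 + math.exp(-theta[layout.logit_lapse][0])),
    )
    return p, params


def _model_to_theta(
    p: SubjectiveDistribution, params: ObserverParams, layout: _Layout
) -> np.ndarray:
    theta = np.empty(layout.size)
    if layout.k > 1:
        theta[layout.alr] = _alr_from_weights(p.weights)
    theta[layout.means] = p.means.ravel()
    ls = np.empty((layout.k, layout.d))
    ang = np.empty(layout.k)
    for m in range(layout.k):
        ls[m], ang[m] = _cov_decompose(p.covariances[m])
    theta[layout.log_scales] = ls.ravel()
    theta[layout.angles] = ang
    theta[layout.log_sigma_p] = math.log(params.perceptual_sigma)
    theta[layout.log_temperature] = math.log(params.temperature)
    lapse = min(max(params.lapse, 1e-12), 1.0 - 1e-12)
    theta[layout.logit_lapse] = math.log(lapse / (1.0 - lapse))
    return theta


def _log_prior_theta(theta: np.ndarray, layout: _Layout, prior: PriorConfig) -> float:
    """Log prior density in the unconstrained parameterization (with Jacobians)."""
    k = layout.k
    lp = 0.0
    if k > 1:
        w = _weights_from_alr(theta[layout.alr])
        if np.any(w <= 0.0):
            return -np.inf
        a = prior.dirichlet_alpha
        # symmetric Dirichlet on w plus the ALR Jacobian prod_k w_k
        lp += gammaln(k * a) - k * gammaln(a) + (a - 1.0) * np.sum(np.log(w))
        lp += float(np.sum(np.log(w)))
    means = theta[layout.means]
    lp += float(
        -0.5 * np.sum((means / prior.mean_prior_sd) ** 2)
        - means.size * (math.log(prior.mean_prior_sd) + 0.5 * math.log(2 * math.pi))
    )
    ls = theta[layout.log_scales]
    z = (ls - prior.logscale_loc) / prior.logscale_scale
    lp += float(
        -0.5 * np.sum(z**2)
        - ls.size * (math.log(prior.logscale_scale) + 0.5 * math.log(2 * math.pi))
    )
    lp += -k * _LOG_PI  # angles uniform on [0, pi)
    for sl, loc, scale in (
        (layout.log_sigma_p, prior.sigma_p_loc, prior.sigma_p_scale),
        (layout.log_temperature, prior.temperature_loc, prior.temperature_scale),
    ):
        z = (theta[sl][0] - loc) / scale
        lp += -0.5 * z * z - math.log(scale) - 0.5 * math.log(2 * math.pi)
    # Beta(a, b) on lapse with the logistic Jacobian lapse * (1 - lapse)
    ll = theta[layout.logit_lapse][0]
    log_lapse = -np.logaddexp(0.0, -ll)
    log_1m = -np.logaddexp(0.0, ll)
    a, b = prior.lapse_a, prior.lapse_b
    lp += float(
        gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * log_lapse
        + (b - 1.0) * log_1m
        + log_lapse
        + log_1m
    )
    return float(lp)


# --------------------------------------------------------------------------
# Likelihood plumbing
# --------------------------------------------------------------------------

_BATCH = {
    FAMILIARITY: familiarity_log_likelihoods_batch,
    ODD_ONE_OUT: ooo_log_likelihoods_batch,
}


def _prepare_data(responses: Sequence[Response]):
    trials = [r.trial for r in responses]
    task, stimuli = stack_stimuli(trials)
    choices = np.array([r.choice for r in responses], dtype=int)
    return task, stimuli, choices


def _choice_loglik(log_values: np.ndarray, params: ObserverParams, choices: np.ndarray) -> float:
    lp = choice_log_probabilities_batch(log_values, params)
    return float(lp[np.arange(lp.shape[0]), choices].sum())


def log_posterior(
    p: SubjectiveDistribution,
    params: ObserverParams,
    responses: Sequence[Response],
    prior: PriorConfig,
    likelihood_weight: float = 1.0,
) -> float:
    """Log posterior density (up to a constant) at a given (P, Omega).

    The prior density is evaluated in the sampler's unconstrained
    parameterization (including transform Jacobians), so this function and
    :func:`fit` target exactly the same distribution.  Parameters outside the
    prior support yield -inf rather than raising.
    """
    layout = _Layout(p.n_components, p.space.n_dims)
    # the logistic Jacobian vanishes at the lapse boundaries, and a zero
    # mixing weight has no finite ALR image: zero density, not an exception
    if not (0.0 < params.lapse < 1.0) or np.any(p.weights <= 0.0):
        return -np.inf
    try:
        theta = _model_to_theta(p, params, layout)
    except (ValueError, FloatingPointError):
        return -np.inf
    lp = _log_prior_theta(theta, layout, prior)
    if not np.isfinite(lp):
        return -np.inf
    if responses and likelihood_weight != 0.0:
        task, stimuli, choices = _prepare_data(responses)
        log_values = _BATCH[task](stimuli, p, params)
        lp += likelihood_weight * _choice_loglik(log_values, params, choices)
    return float(lp)


# --------------------------------------------------------------------------
# Sampler
# --------------------------------------------------------------------------

_INITIAL_SCALES = {
    "weights": 0.4,
    "means": 0.3,
    "scales": 0.2,
    "angles": 0.3,
    "sigma_p": 0.15,
    "temperature": 0.2,
    "lapse": 0.5,
}


def _initial_theta(
    layout: _Layout, prior: PriorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Weights uniform, means from their prior, scales/Omega at prior medians,
    rotation angles uniform (a rotation has no meaningful median)."""
    theta = np.zeros(layout.size)
    theta[layout.means] = rng.normal(0.0, prior.mean_prior_sd, size=layout.k * layout.d)
    theta[layout.log_scales] = prior.logscale_loc
    theta[layout.angles] = rng.uniform(0.0, math.pi, size=layout.k)
    theta[layout.log_sigma_p] = prior.sigma_p_loc
    theta[layout.log_temperature] = prior.temperature_loc
    med = (prior.lapse_a - 1.0 / 3.0) / (prior.lapse_a + prior.lapse_b - 2.0 / 3.0)
    med = min(max(med, 1e-3), 1 - 1e-3)
    theta[layout.logit_lapse] = math.log(med / (1.0 - med))
    return theta


def fit(
    responses: Sequence[Response],
    prior: Optional[PriorConfig] = None,
    settings: Optional[SamplerSettings] = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Invert the ideal observer model: sample P(P, Omega | responses).

    All responses must come from one subject and one task.  Returns thinned
    post-burn-in draws; identical seed and settings reproduce the draws
    bit for bit.
    """
    if not responses:
        raise ValueError("need at least one response")
    prior = prior or PriorConfig()
    settings = settings or SamplerSettings()
    task, stimuli, choices = _prepare_data(responses)
    space = responses[0].trial.space
    layout = _Layout(prior.n_components, space.n_dims)
    rng = np.random.default_rng(seed)
    lweight = settings.likelihood_weight
    batch = _BATCH[task]

    def loglik_parts(theta: np.ndarray):
        """Returns (log_values, loglik); log_values cached for Omega-only moves."""
        p, params = _theta_to_model(theta, layout, space)
        if lweight == 0.0:
            return None, 0.0, params
        log_values = batch(stimuli, p, params)
        return log_values, lweight * _choice_loglik(log_values, params, choices), params

    # initialization: best finite log posterior among prior-seeded candidates
    best = None
    n_finite = 0
    wanted = max(settings.n_init, 1)
    for _ in range(wanted + 100):
        cand = _initial_theta(layout, prior, rng)
        lp = _log_prior_theta(cand, layout, prior)
        if not np.isfinite(lp):
            continue
        lv, ll, _ = loglik_parts(cand)
        total = lp + ll
        if np.isfinite(total):
            n_finite += 1
            if best is None or total > best[0]:
                best = (total, cand, lv)
            if n_finite >= wanted:
                break
    if best is None:
        raise RuntimeError(
            "could not find a finite initial log posterior after 100 attempts"
        )
    cur_lp_total, theta, cur_log_values = best

    blocks = layout.blocks()
    scales = {name: _INITIAL_SCALES[name] for name, _ in blocks}
    accept_counts = {name: 0 for name, _ in blocks}
    proposal_counts = {name: 0 for name, _ in blocks}

    n_steps = settings.n_steps
    burn_in = settings.effective_burn_in
    kept = n_steps - burn_in
    thin = max(1, math.ceil(kept / settings.max_draws))

    trace = np.empty(n_steps)
    draws_theta: list[np.ndarray] = []

    omega_only = {"temperature", "lapse"}
    for it in range(n_steps):
        for name, sl in blocks:
            prop = theta.copy()
            width = sl.stop - sl.start
            prop[sl] = prop[sl] + scales[name] * rng.standard_normal(width)
            if name == "angles":
                prop[sl] = np.mod(prop[sl], math.pi)
            lprior = _log_prior_theta(prop, layout, prior)
            if np.isfinite(lprior):
                if lweight == 0.0:
                    lv, ll, params = None, 0.0, None
                elif name in omega_only:
                    # P and sigma_p unchanged: reuse cached hypothesis likelihoods
                    _, params = _theta_to_model(prop, layout, space)
                    lv = cur_log_values
                    ll = lweight * _choice_loglik(lv, params, choices)
                else:
                    lv, ll, params = loglik_parts(prop)
                total = lprior + ll
            else:
                total = -np.inf
            proposal_counts[name] += 1
            if np.isfinite(total) and math.log(rng.uniform()) < total - cur_lp_total:
                theta = prop
                cur_lp_total = total
                cur_log_values = lv
                accept_counts[name] += 1
                accepted = True
            else:
                accepted = False
            if it < burn_in:
                scales[name] *= math.exp(
                    settings.adapt_rate * ((1.0 if accepted else 0.0) - settings.target_accept)
                )
        trace[it] = cur_lp_total
        if it >= burn_in and (it - burn_in) % thin == 0:
            draws_theta.append(theta.copy())

    draws = [_theta_to_model(t, layout, space) for t in draws_theta]
    acceptance = {
        name: accept_counts[name] / max(proposal_counts[name], 1) for name, _ in blocks
    }
    config = {
        "prior": asdict(prior),
        "settings": asdict(settings),
        "proposal_scales": scales,
    }
    return PosteriorSamples(
        draws=draws,
        log_posterior_trace=trace,
        acceptance_rates=acceptance,
        seed=seed,
        config=config,
        task=task,
        space=space,
    )


def posterior_mean_grid(samples: PosteriorSamples, resolution: int = 100) -> GridDensity:
    """Posterior-mean density image: average of the draws' grids, renormalized."""
    if not samples.draws:
        raise ValueError("need at least one draw")
    acc = None
    for p, _ in samples.draws:
        g = p.to_grid(resolution)
        acc = g.masses.copy() if acc is None else acc + g.masses
    acc /= acc.sum()
    return GridDensity(samples.space, resolution, acc)


def sample_prior(
    prior: PriorConfig, space: FeatureSpace, n: int, seed: int = 0
) -> list:
    """Draw (P, Omega) pairs from the prior; used for prior-predictive checks."""
    rng = np.random.default_rng(seed)
    layout = _Layout(prior.n_components, space.n_dims)
    out = []
    for _ in range(n):
        theta = np.empty(layout.size)
        if layout.k > 1:
            w = rng.dirichlet(np.full(layout.k, prior.dirichlet_alpha))
            w = np.clip(w, 1e-12, None)
            w /= w.sum()
            theta[layout.alr] = _alr_from_weights(w)
        theta[layout.means] = rng.normal(0, prior.mean_prior_sd, layout.k * layout.d)
        theta[layout.log_scales] = rng.normal(
            prior.logscale_loc, prior.logscale_scale, layout.k * layout.d
        )
        theta[layout.angles] = rng.uniform(0, math.pi, layout.k)
        theta[layout.log_sigma_p] = rng.normal(prior.sigma_p_loc, prior.sigma_p_scale)
        theta[layout.log_temperature] = rng.normal(
            prior.temperature_loc, prior.temperature_scale
        )
        lapse = rng.beta(prior.lapse_a, prior.lapse_b)
        lapse = min(max(lapse, 1e-12), 1 - 1e-12)
        theta[layout.logit_lapse] = math.log(lapse / (1 - lapse))
        out.append(_theta_to_model(theta, layout, space))
    return out
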