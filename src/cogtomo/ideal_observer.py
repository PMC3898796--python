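"""Ideal observer forward models for the familiarity and odd-one-out tasks.

Each task defines a set of hypotheses about how the presented stimuli S*
arose.  The observer perceives noisy versions S of the presented stimuli
(isotropic Gaussian perceptual noise with SD ``perceptual_sigma``), computes
the marginal likelihood of each hypothesis with the latent perceived and
underlying stimuli integrated out analytically (Gaussian convolution), and
responds by a noisy comparison of the hypothesis likelihoods: a softmax with
temperature on the log likelihoods, mixed with a lapse probability of a
uniformly random response.

Familiarity (2 stimuli): hypothesis k says stimulus k is the familiar one —
a perceptually noisy sample from the subjective distribution P — while the
other stimulus is drawn uniformly from the feature box.

Odd-one-out (3 stimuli): hypothesis k says the other two stimuli are noisy
realizations of a single underlying face sampled from P, while stimulus k is
a noisy realization of an independent second sample from P.  Because the
pair hypothesis spends one sample from P where the two-face account spends
two, its relative likelihood scales with the density of P near the stimuli:
observers are more inclined to call nearby stimuli "really different" in
high-probability regions.

All likelihood arithmetic is in log space with a floor of exp(-745) to
prevent underflow for far-outlying stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .subjective_model import FeatureSpace, SubjectiveDistribution

__all__ = [
    "FAMILIARITY",
    "ODD_ONE_OUT",
    "ObserverParams",
    "Trial",
    "Response",
    "HypothesisLikelihoods",
    "familiarity_likelihoods",
    "ooo_likelihoods",
    "choice_probabilities",
    "response_probability",
    "ooo_by_familiarity",
]

FAMILIARITY = "familiarity"
ODD_ONE_OUT = "odd_one_out"
TASKS = (FAMILIARITY, ODD_ONE_OUT)
_N_STIMULI = {FAMILIARITY: 2, ODD_ONE_OUT: 3}

LOG_FLOOR = -745.0  # log of the smallest positive double


@dataclass(frozen=True)
class ObserverParams:
    """Observer nuisance parameters (the non-prior part of the model).

    perceptual_sigma : SD of isotropic Gaussian perceptual noise (SD units).
    temperature : softmax sharpness on log hypothesis likelihoods; large
        values approach deterministic maximum-likelihood responding.
    lapse : probability of a uniformly random response, in [0, 1].
    """

    perceptual_sigma: float
    temperature: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not (self.perceptual_sigma > 0):
            raise ValueError("perceptual_sigma must be positive")
        if not (self.temperature > 0):
            raise ValueError("temperature must be positive")
        if not (0.0 <= self.lapse <= 1.0):
            raise ValueError("lapse must lie in [0, 1]")


@dataclass(frozen=True)
class Trial:
    """Presented stimuli for one trial.

    stimuli : (n, n_dims) feature-space coordinates of the presented faces,
        n = 2 for familiarity and 3 for odd-one-out; all inside the box.
    repeat_group : optional identifier shared by repeated presentations of
        identical stimuli (used for consistency scoring).
    """

    task: str
    stimuli: np.ndarray
    space: FeatureSpace = FeatureSpace()
    repeat_group: Optional[int] = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        s = np.asarray(self.stimuli, dtype=float)
        n = _N_STIMULI[self.task]
        if s.shape != (n, self.space.n_dims):
            raise ValueError(
                f"{self.task} trial needs stimuli of shape ({n}, {self.space.n_dims})"
            )
        if not self.space.contains(s):
            raise ValueError("stimuli must lie inside the feature box")
        object.__setattr__(self, "stimuli", s)

    @property
    def n_alternatives(self) -> int:
        return _N_STIMULI[self.task]


@dataclass(frozen=True)
class Response:
    """A subject's discrete choice on one trial (0-based stimulus index)."""

    trial: Trial
    choice: int

    def __post_init__(self) -> None:
        if not (0 <= self.choice < self.trial.n_alternatives):
            raise ValueError(
                f"choice {self.choice} out of range for {self.trial.task}"
            )


@dataclass(frozen=True)
class HypothesisLikelihoods:
    """Per-hypothesis marginal likelihood densities, stored in log space."""

    log_values: np.ndarray

    def __post_init__(self) -> None:
        lv = np.maximum(np.asarray(self.log_values, dtype=float), LOG_FLOOR)
        if not np.all(np.isfinite(lv)):
            raise ValueError("log likelihoods must be finite")
        object.__setattr__(self, "log_values", lv)

    @property
    def values(self) -> np.ndarray:
        return np.exp(self.log_values)


# --------------------------------------------------------------------------
# Batch likelihood kernels (used both by the public per-trial API and by the
# MCMC, where they are evaluated tens of thousands of times).
# --------------------------------------------------------------------------


def familiarity_log_likelihoods_batch(
    stimuli: np.ndarray, p: SubjectiveDistribution, params: ObserverParams
) -> np.ndarray:
    """Log hypothesis likelihoods for familiarity trials, shape (T, 2).

    Hypothesis k: stimulus k is a noisy sample from P, so its marginal is the
    mixture convolved with the perceptual noise, evaluated at s*_k; the other
    stimulus contributes the uniform box density u.  (The convolution of the
    uniform with perceptual noise is approximated by u itself; edge effects
    are of order sigma_p / half_width.)
    """
    stimuli = np.asarray(stimuli, dtype=float)
    t, n, d = stimuli.shape
    var = params.perceptual_sigma**2
    logmix = p.logpdf(stimuli.reshape(-1, d), add_var=var).reshape(t, n)
    log_u = np.log(p.space.uniform_density)
    return np.maximum(logmix + log_u, LOG_FLOOR)


def ooo_log_likelihoods_batch(
    stimuli: np.ndarray, p: SubjectiveDistribution, params: ObserverParams
) -> np.ndarray:
    """Log hypothesis likelihoods for odd-one-out trials, shape (T, 3).

    Hypothesis k (odd one = k, pair = {i, j}):
        N(s*_i; s*_j, 2 sigma_p^2 I)
        * mix((s*_i + s*_j)/2; Sigma_m + sigma_p^2/2 I)   [shared-face pair]
        * mix(s*_k; Sigma_m + sigma_p^2 I)                [independent odd face]
    with both latent faces integrated out analytically.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    t, n, d = stimuli.shape
    var = params.perceptual_sigma**2

    log_single = p.logpdf(stimuli.reshape(-1, d), add_var=var).reshape(t, n)

    # midpoint of the pair complementary to each hypothesis k
    pair_idx = [(1, 2), (0, 2), (0, 1)]
    mids = np.stack(
        [0.5 * (stimuli[:, i, :] + stimuli[:, j, :]) for i, j in pair_idx], axis=1
    )  # (T, 3, d)
    log_pair_mix = p.logpdf(mids.reshape(-1, d), add_var=0.5 * var).reshape(t, n)

    sq = np.stack(
        [np.sum((stimuli[:, i, :] - stimuli[:, j, :]) ** 2, axis=1) for i, j in pair_idx],
        axis=1,
    )  # (T, 3)
    log_pair_norm = -sq / (4.0 * var) - 0.5 * d * np.log(4.0 * np.pi * var)

    return np.maximum(log_pair_norm + log_pair_mix + log_single, LOG_FLOOR)


def choice_log_probabilities_batch(
    log_values: np.ndarray, params: ObserverParams
) -> np.ndarray:
    """Noisy decision rule applied row-wise to log hypothesis likelihoods.

    p = (1 - lapse) * softmax(temperature * log_values) + lapse / n.
    Returns log probabilities, shape like ``log_values``.
    """
    z = params.temperature * log_values
    peak = z.max(axis=-1, keepdims=True)
    log_sm = z - (peak + np.log(np.exp(z - peak).sum(axis=-1, keepdims=True)))
    n = log_values.shape[-1]
    if params.lapse == 0.0:
        return log_sm
    probs = (1.0 - params.lapse) * np.exp(log_sm) + params.lapse / n
    return np.log(probs)


_BATCH_LOGLIK = {
    FAMILIARITY: familiarity_log_likelihoods_batch,
    ODD_ONE_OUT: ooo_log_likelihoods_batch,
}


def response_log_probabilities_batch(
    task: str,
    stimuli: np.ndarray,
    p: SubjectiveDistribution,
    params: ObserverParams,
) -> np.ndarray:
    """Log response probabilities for a batch of same-task trials, (T, n)."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    log_values = _BATCH_LOGLIK[task](stimuli, p, params)
    return choice_log_probabilities_batch(log_values, params)


# --------------------------------------------------------------------------
# Per-trial public API
# --------------------------------------------------------------------------


def _require_task(trial: Trial, task: str) -> None:
    if trial.task != task:
        raise ValueError(f"expected a {task} trial, got {trial.task}")


def familiarity_likelihoods(
    trial: Trial, p: SubjectiveDistribution, params: ObserverParams
) -> HypothesisLikelihoods:
    """Marginal likelihood of each 'stimulus k is the familiar one' hypothesis."""
    _require_task(trial, FAMILIARITY)
    lv = familiarity_log_likelihoods_batch(trial.stimuli[None], p, params)[0]
    return HypothesisLikelihoods(lv)


def ooo_likelihoods(
    trial: Trial, p: SubjectiveDistribution, params: ObserverParams
) -> HypothesisLikelihoods:
    """Marginal likelihood of each 'stimulus k is the odd one out' hypothesis."""
    _require_task(trial, ODD_ONE_OUT)
    lv = ooo_log_likelihoods_batch(trial.stimuli[None], p, params)[0]
    return HypothesisLikelihoods(lv)


def choice_probabilities(
    lik: HypothesisLikelihoods, params: ObserverParams
) -> np.ndarray:
    """Response probabilities from hypothesis likelihoods (softmax + lapse)."""
    return np.exp(choice_log_probabilities_batch(lik.log_values[None], params)[0])


def response_probability(
    trial: Trial, p: SubjectiveDistribution, params: ObserverParams
) -> np.ndarray:
    """P(R | S*, P, Omega): the observer's response distribution for a trial."""
    if trial.task == FAMILIARITY:
        lik = familiarity_likelihoods(trial, p, params)
    elif trial.task == ODD_ONE_OUT:
        lik = ooo_likelihoods(trial, p, params)
    else:  # pragma: no cover - Trial validates task
        raise ValueError(f"unknown task {trial.task!r}")
    return choice_probabilities(lik, params)


def familiarity_scores(
    stimuli: np.ndarray, p: SubjectiveDistribution, params: ObserverParams
) -> np.ndarray:
    """Log familiarity score per stimulus: log mix(s*_k; Sigma_m + sigma_p^2 I)."""
    stimuli = np.asarray(stimuli, dtype=float)
    var = params.perceptual_sigma**2
    return p.logpdf(stimuli, add_var=var)


def ooo_by_familiarity(
    trial: Trial,
    p: SubjectiveDistribution,
    params: ObserverParams,
    mode: str = "most",
) -> np.ndarray:
    """Alternative odd-one-out decision rules borrowed from the familiarity task.

    mode='most' picks the most familiar face as the odd one out; mode='least'
    the least familiar (negated log familiarity scores).  These deliberately
    wrong-headed rules test whether the two tasks share a decision process.
    """
    _require_task(trial, ODD_ONE_OUT)
    if mode not in ("most", "least"):
        raise ValueError("mode must be 'most' or 'least'")
    scores = familiarity_scores(trial.stimuli, p, params)
    scores = np.maximum(scores, LOG_FLOOR)
    if mode == "least":
        scores = -scores
    return np.exp(
        choice_log_probabilities_batch(scores[None], params)[0]
    )


def ooo_by_familiarity_log_batch(
    stimuli: np.ndarray,
    p: SubjectiveDistribution,
    params: ObserverParams,
    mode: str = "most",
) -> np.ndarray:
    """Batch log response probabilities under the familiarity-based OOO rules."""
    if mode not in ("most", "least"):
        raise ValueError("mode must be 'most' or 'least'")
    stimuli = np.asarray(stimuli, dtype=float)
    t, n, d = stimuli.shape
    var = params.perceptual_sigma**2
    scores = p.logpdf(stimuli.reshape(-1, d), add_var=var).reshape(t, n)
    scores = np.maximum(scores, LOG_FLOOR)
    if mode == "least":
        scores = -scores
    return choice_log_probabilities_batch(scores, params)


def stack_stimuli(trials: Sequence[Trial]) -> tuple[str, np.ndarray]:
    """Validate that trials share one task and stack stimuli into (T, n, d)."""
    if not trials:
        raise ValueError("need at least one trial")
    task = trials[0].task
    if any(t.task != task for t in trials):
        raise ValueError("trials must all be of one task")
    return task, np.stack([t.stimuli for t in trials])
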