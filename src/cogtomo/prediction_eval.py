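"""Predicting responses from fitted posteriors, and evaluating predictions.

Because the subjective distribution is task-independent in the model, a
posterior fitted on one task can predict trials of the other: only the
ideal observer's hypothesis set changes.  The observer parameters Omega
transfer along with P (refitting them on the target task would leak
target-task information into an ostensibly across-task prediction).

Two performance measures are provided: the mean probability assigned to the
subject's actual choices (threshold-free, proper-scoring-rule-adjacent) and
hard accuracy (fraction of trials where the argmax prediction matches the
choice).  The consistency-derived ceiling on prediction is most natural for
accuracy, so bound comparisons use it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .ideal_observer import Response, Trial, response_log_probabilities_batch, stack_stimuli
from .inference import PosteriorSamples

__all__ = [
    "PredictionSet",
    "predict",
    "predictive_performance",
    "predictive_accuracy",
    "consistency_score",
    "consistency_upper_bound",
]


@dataclass(frozen=True)
class PredictionSet:
    """Per-trial response probability vectors.

    ``source_task`` records which task's data the posterior was fitted on;
    it may differ from ``task`` (across-task prediction).
    """

    probs: np.ndarray  # (T, n_alternatives)
    task: str
    source_task: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2:
            raise ValueError("probs must be a (trials, alternatives) array")
        if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each row of probs must be a probability vector")
        object.__setattr__(self, "probs", p)

    @property
    def n_trials(self) -> int:
        return int(self.probs.shape[0])


def predict(samples: PosteriorSamples, trials: Sequence[Trial]) -> PredictionSet:
    """Posterior-predictive response probabilities for novel trials.

    Averages the ideal observer's response distribution over all posterior
    draws.  The trials may belong to a different task than the fitted data.
    """
    if not samples.draws:
        raise ValueError("posterior has no draws")
    task, stimuli = stack_stimuli(trials)
    # average in probability space via logsumexp over draws
    log_probs = np.stack(
        [
            response_log_probabilities_batch(task, stimuli, p, params)
            for p, params in samples.draws
        ]
    )
    mean_log = logsumexp(log_probs, axis=0) - np.log(len(samples.draws))
    probs = np.exp(mean_log)
    probs /= probs.sum(axis=1, keepdims=True)
    return PredictionSet(probs=probs, task=task, source_task=samples.task)


def _aligned_choices(pred: PredictionSet, responses: Sequence[Response]) -> np.ndarray:
    if len(responses) != pred.n_trials:
        raise ValueError("predictions and responses must align trial by trial")
    if any(r.trial.task != pred.task for r in responses):
        raise ValueError("response task does not match prediction task")
    return np.array([r.choice for r in responses], dtype=int)


def predictive_performance(pred: PredictionSet, responses: Sequence[Response]) -> float:
    """Mean probability assigned to the subject's actual choices.

    Chance level is 1/2 for familiarity and 1/3 for odd-one-out.
    """
    choices = _aligned_choices(pred, responses)
    return float(pred.probs[np.arange(len(choices)), choices].mean())


def predictive_accuracy(pred: PredictionSet, responses: Sequence[Response]) -> float:
    """Fraction of trials whose argmax prediction matches the actual choice."""
    choices = _aligned_choices(pred, responses)
    return float((pred.probs.argmax(axis=1) == choices).mean())


def consistency_score(responses: Sequence[Response]) -> float:
    """Fraction of same-stimulus presentation pairs answered identically.

    Pools all unordered pairs of presentations within each repeat group: a
    model-free measure of response repeatability that caps how well any
    predictor can do.
    """
    groups: dict = defaultdict(list)
    for r in responses:
        if r.trial.repeat_group is not None:
            groups[(r.trial.task, r.trial.repeat_group)].append(r.choice)
    total = 0
    matching = 0
    for choices in groups.values():
        k = len(choices)
        if k < 2:
            continue
        total += k * (k - 1) // 2
        arr = np.asarray(choices)
        # ordered equal pairs include the diagonal; unordered = (eq - k) / 2
        eq = int(np.sum(arr[:, None] == arr[None, :]))
        matching += (eq - k) // 2
    if total == 0:
        raise ValueError("need at least one repeat group with >= 2 presentations")
    return matching / total


def consistency_upper_bound(c: float, n_alternatives: int) -> float:
    """Expected ceiling on predictor accuracy implied by a consistency score.

    Assumes a symmetric response model per repeated stimulus: the majority
    option has probability p and the rest split the remainder equally.  Then
    consistency c = p^2 + (1-p)^2 for two alternatives, and
    c = p^2 + (1-p)^2 / 2 for three.  A predictor that knows the subject's
    response distribution achieves expected accuracy p at best:

        n = 2:  p = (1 + sqrt(2c - 1)) / 2
        n = 3:  p = (1 + sqrt(6c - 2)) / 3
    """
    if n_alternatives == 2:
        if c < 0.5:
            raise ValueError("consistency below chance level 1/2")
        return float((1.0 + np.sqrt(2.0 * c - 1.0)) / 2.0)
    if n_alternatives == 3:
        if c < 1.0 / 3.0:
            raise ValueError("consistency below chance level 1/3")
        return float((1.0 + np.sqrt(6.0 * c - 2.0)) / 3.0)
    raise ValueError("n_alternatives must be 2 or 3")
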