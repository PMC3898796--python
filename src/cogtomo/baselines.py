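"""Comparison predictors without (full) subjective distributions.

Two baselines bracket the contribution of structured priors to prediction:

* ``moment_matched_predict`` replaces each posterior draw's mixture by the
  single Gaussian with the same mean and covariance, testing whether
  structure beyond second moments carries behavioral information.

* A discriminative baseline — a squared-exponential-kernel probabilistic
  classifier fit directly on stimulus coordinates — predicts responses with
  no notion of a subjective distribution at all.  Task symmetries are built
  in by data augmentation (stimulus swap for familiarity, cyclic rotations
  for odd-one-out) and enforced at prediction time by averaging over the
  same augmentation group.  Because the classifier learns one task's
  stimulus-to-response mapping, it structurally cannot predict across
  tasks; asking it to do so raises an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.kernel_approximation import Nystroem
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline

from .ideal_observer import FAMILIARITY, ODD_ONE_OUT, Response, Trial, stack_stimuli
from .inference import PosteriorSamples
from .prediction_eval import PredictionSet, predict
from .subjective_model import moment_match

__all__ = [
    "TaskMismatchError",
    "DiscriminativeModel",
    "moment_matched_predict",
    "discriminative_fit",
    "discriminative_predict",
]


class TaskMismatchError(ValueError):
    """A discriminative model was asked to predict a task it was not fit on."""


def moment_matched_predict(
    samples: PosteriorSamples, trials: Sequence[Trial]
) -> PredictionSet:
    """Posterior-predictive probabilities with every draw moment-matched.

    Each draw's subjective distribution is collapsed to its moment-matched
    single Gaussian (observer parameters kept), then averaged exactly as in
    :func:`cogtomo.prediction_eval.predict`.
    """
    collapsed = PosteriorSamples(
        draws=[(moment_match(p), params) for p, params in samples.draws],
        log_posterior_trace=samples.log_posterior_trace,
        acceptance_rates=samples.acceptance_rates,
        seed=samples.seed,
        config=samples.config,
        task=samples.task,
        space=samples.space,
    )
    return predict(collapsed, trials)


# --------------------------------------------------------------------------
# Discriminative baseline
# --------------------------------------------------------------------------


def _augmented_views(stimuli: np.ndarray, task: str):
    """Feature matrices for each element of the task's symmetry group,
    together with the label permutation that undoes the transformation."""
    t, n, d = stimuli.shape
    if task == FAMILIARITY:
        perms = [np.array([0, 1]), np.array([1, 0])]
    else:
        perms = [np.roll(np.arange(3), -r) for r in range(3)]
    views = []
    for perm in perms:
        x = stimuli[:, perm, :].reshape(t, n * d)
        views.append((x, perm))
    return views


@dataclass
class DiscriminativeModel:
    """A fitted kernel classifier on one task's trial features."""

    task: str
    estimator: Pipeline
    classes: np.ndarray
    n_alternatives: int


def discriminative_fit(
    responses: Sequence[Response],
    kernel_settings: Optional[dict] = None,
    seed: int = 0,
) -> DiscriminativeModel:
    """Fit the discriminative baseline on one task's responses.

    Features are the concatenated stimulus coordinates; training data are
    augmented over the task's symmetry group with labels transformed
    accordingly.  Hyperparameters (RBF kernel width gamma and inverse
    regularization C) are chosen by a seeded cross-validated grid search.
    """
    if len(responses) < 20:
        raise ValueError("need at least 20 trials to fit the baseline")
    trials = [r.trial for r in responses]
    task, stimuli = stack_stimuli(trials)
    choices = np.array([r.choice for r in responses], dtype=int)
    n_alt = trials[0].n_alternatives

    xs, ys = [], []
    for x, perm in _augmented_views(stimuli, task):
        # stimuli permuted by perm: the original choice c sits at position
        # argwhere(perm == c) in the permuted trial
        inv = np.argsort(perm)
        xs.append(x)
        ys.append(inv[choices])
    x_all = np.vstack(xs)
    y_all = np.concatenate(ys)

    settings = {
        "gammas": (0.03, 0.125, 0.5),
        "cs": (0.3, 3.0),
        "n_components": 200,
        "cv_folds": 3,
    }
    if kernel_settings:
        settings.update(kernel_settings)

    # keep the kernel basis within the smallest CV training fold
    n_comp = min(
        settings["n_components"],
        x_all.shape[0] * (settings["cv_folds"] - 1) // settings["cv_folds"],
    )
    pipe = Pipeline(
        [
            ("kernel", Nystroem(gamma=0.125, n_components=n_comp, random_state=seed)),
            ("clf", LogisticRegression(max_iter=2000)),
        ]
    )
    grid = {
        "kernel__gamma": list(settings["gammas"]),
        "clf__C": list(settings["cs"]),
    }
    cv = KFold(n_splits=settings["cv_folds"], shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, cv=cv, scoring="neg_log_loss", n_jobs=1)
    search.fit(x_all, y_all)
    est = search.best_estimator_
    classes = est.named_steps["clf"].classes_
    return DiscriminativeModel(
        task=task, estimator=est, classes=classes, n_alternatives=n_alt
    )


def discriminative_predict(
    model: DiscriminativeModel, trials: Sequence[Trial]
) -> PredictionSet:
    """Class probabilities for same-task trials, symmetry-averaged.

    Predictions are averaged over the augmentation group used in training,
    so a familiarity trial and its stimulus-swapped twin receive mirror-image
    probabilities exactly.  Supplying trials from a different task raises
    :class:`TaskMismatchError` — the model has no way to transfer.
    """
    task, stimuli = stack_stimuli(trials)
    if task != model.task:
        raise TaskMismatchError(
            f"model was fit on {model.task!r}; it cannot predict {task!r} trials"
        )
    t = stimuli.shape[0]
    n_alt = model.n_alternatives
    acc = np.zeros((t, n_alt))
    views = _augmented_views(stimuli, task)
    for x, perm in views:
        raw = model.estimator.predict_proba(x)
        full = np.zeros((t, n_alt))
        for col, cls in enumerate(model.classes):
            full[:, int(cls)] = raw[:, col]
        # position k of the permuted trial is original stimulus perm[k]
        acc[:, perm] += full
    probs = acc / len(views)
    probs /= probs.sum(axis=1, keepdims=True)
    return PredictionSet(probs=probs, task=task, source_task=task)
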