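"""Synthetic observers: ground-truth priors, stimulus designs, responses.

This module defines the study conditions for every recovery and transfer
experiment in the package: a synthetic subject is a known Gaussian-mixture
subjective distribution plus observer parameters, and their responses are
sampled from the ideal observer's response distribution.  Stimulus designs
mirror the behavioral experiments: familiarity trials are independent
uniform pairs in the feature box; odd-one-out trials are predominantly
(default 90%) equilateral triads — for which the three hypotheses are
distinguishable only through the subjective distribution — with the
remainder independent uniform triples.  A configurable fraction of trials
is presented twice (shared ``repeat_group``) so that response consistency
can be measured; repeated presentations are answered independently, which
is what makes consistency scores fall below 1.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .ideal_observer import (
    FAMILIARITY,
    ODD_ONE_OUT,
    ObserverParams,
    Response,
    Trial,
    response_log_probabilities_batch,
    stack_stimuli,
)
from .subjective_model import FeatureSpace, SubjectiveDistribution

__all__ = ["make_ground_truth", "make_stimuli", "simulate_responses"]

_MAX_RETRIES = 10_000


def make_ground_truth(
    seed: int,
    n_components: int = 3,
    separation: float = 2.5,
    space: FeatureSpace = FeatureSpace(),
    eigen_scale_range: tuple[float, float] = (0.3, 1.0),
    mean_margin: float = 0.5,
) -> SubjectiveDistribution:
    """A random ground-truth mixture with well-separated components.

    Component means are sampled uniformly in the box (inset by
    ``mean_margin`` so modes keep most of their mass representable inside
    the box) under a minimum pairwise distance of ``separation``, by
    rejection with capped retries.  Weights come from a flat simplex;
    covariances have eigen-SDs uniform in ``eigen_scale_range`` and a
    uniform random orientation.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    lim = space.half_width - mean_margin
    if lim <= 0:
        raise ValueError("mean_margin leaves no room in the box")

    means = np.empty((n_components, space.n_dims))
    placed = 0
    for _ in range(_MAX_RETRIES):
        cand = rng.uniform(-lim, lim, size=space.n_dims)
        if placed == 0 or np.all(
            np.linalg.norm(means[:placed] - cand, axis=1) >= separation
        ):
            means[placed] = cand
            placed += 1
            if placed == n_components:
                break
    else:
        raise RuntimeError(
            f"could not place {n_components} means with separation {separation} "
            f"in a box of half-width {space.half_width}"
        )

    weights = rng.dirichlet(np.ones(n_components))
    lo, hi = eigen_scale_range
    covs = np.empty((n_components, space.n_dims, space.n_dims))
    for m in range(n_components):
        scales = rng.uniform(lo, hi, size=space.n_dims)
        angle = rng.uniform(0, math.pi)
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s], [s, c]]) if space.n_dims == 2 else np.eye(space.n_dims)
        covs[m] = rot @ np.diag(scales**2) @ rot.T
    return SubjectiveDistribution(space, weights, means, covs)


def _equilateral_triad(
    rng: np.random.Generator, space: FeatureSpace, side_range: tuple[float, float]
) -> np.ndarray:
    """Equilateral triad with uniform center, orientation and side length,
    all vertices inside the box (rejection)."""
    hw = space.half_width
    for _ in range(_MAX_RETRIES):
        side = rng.uniform(*side_range)
        r = side / math.sqrt(3.0)  # circumradius
        center = rng.uniform(-hw, hw, size=2)
        phase = rng.uniform(0, 2 * math.pi)
        angles = phase + 2 * math.pi * np.arange(3) / 3
        verts = center + r * np.stack([np.cos(angles), np.sin(angles)], axis=1)
        if np.all(np.abs(verts) <= hw):
            return verts
    raise RuntimeError("could not place an equilateral triad inside the box")


def make_stimuli(
    task: str,
    n_trials: int,
    repeat_fraction: float = 0.1,
    equidistant_fraction: float = 0.9,
    seed: int = 0,
    space: FeatureSpace = FeatureSpace(),
    side_range: tuple[float, float] = (1.0, 4.0),
) -> list[Trial]:
    """Stimulus design for one task.

    Generates ``n_trials`` base trials, then appends a duplicate of a
    ``repeat_fraction`` of them; each duplicated pair shares a
    ``repeat_group`` identifier.  The returned list therefore has
    ``n_trials * (1 + repeat_fraction)`` entries (rounded).
    """
    if task not in (FAMILIARITY, ODD_ONE_OUT):
        raise ValueError(f"unknown task {task!r}")
    if not (0.0 <= repeat_fraction <= 1.0 and 0.0 <= equidistant_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hw = space.half_width

    base: list[Trial] = []
    for i in range(n_trials):
        if task == FAMILIARITY:
            stim = rng.uniform(-hw, hw, size=(2, space.n_dims))
        else:
            if rng.uniform() < equidistant_fraction:
                stim = _equilateral_triad(rng, space, side_range)
            else:
                stim = rng.uniform(-hw, hw, size=(3, space.n_dims))
        base.append(Trial(task=task, stimuli=stim, space=space))

    n_rep = int(round(repeat_fraction * n_trials))
    rep_idx = rng.choice(n_trials, size=n_rep, replace=False) if n_rep else []
    trials = list(base)
    for g, i in enumerate(rep_idx):
        tagged = Trial(task=task, stimuli=base[i].stimuli, space=space, repeat_group=g)
        trials[i] = tagged
        trials.append(tagged)
    return trials


def simulate_responses(
    p: SubjectiveDistribution,
    params: ObserverParams,
    trials: Sequence[Trial],
    seed: int = 0,
) -> list[Response]:
    """Sample one choice per trial from the ideal observer's response
    distribution.  Repeated trials are answered independently."""
    if not trials:
        return []
    task, stimuli = stack_stimuli(trials)
    probs = np.exp(response_log_probabilities_batch(task, stimuli, p, params))
    rng = np.random.default_rng(seed)
    cum = np.cumsum(probs, axis=1)
    u = rng.uniform(size=len(trials))
    choices = (u[:, None] > cum).sum(axis=1)
    return [Response(trial=t, choice=int(c)) for t, c in zip(trials, choices)]
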