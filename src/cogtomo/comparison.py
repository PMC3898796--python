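"""Comparing recovered subjective distributions across tasks and subjects.

Distances between grid-discretized densities are Jensen-Shannon divergences
in bits ("js_bits") or their square roots ("sqrt_js"); the square root is a
true metric and is what multidimensional scaling operates on.  The central
scientific question — is the prior task-invariant within a subject? — is
posed as a one-sided rank-sum comparison of same-subject/different-task
distances against different-subject/same-task distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .subjective_model import GridDensity, js_divergence

__all__ = ["DistanceMatrix", "distance_matrix", "within_between_test", "mds_embed"]

METRICS = ("js_bits", "sqrt_js")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between labeled grid densities.

    Labels are (subject id, task) pairs.
    """

    labels: tuple
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("values must be square with one row per label")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("matrix must be symmetric")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)


def distance_matrix(
    grids: Sequence[tuple], metric: str = "js_bits"
) -> DistanceMatrix:
    """All pairwise JS (or root-JS) distances between labeled grids.

    ``grids`` is a sequence of (label, GridDensity) pairs sharing one grid.
    For 20 grids the strict upper triangle holds 190 distances.
    """
    if len(grids) < 2:
        raise ValueError("need at least two grids")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    labels = tuple(lbl for lbl, _ in grids)
    gs = [g for _, g in grids]
    for g in gs[1:]:
        if not gs[0].same_grid(g):
            raise ValueError("all grids must share space and resolution")
    n = len(gs)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = js_divergence(gs[i], gs[j])
            if metric == "sqrt_js":
                d = float(np.sqrt(d))
            v[i, j] = v[j, i] = d
    return DistanceMatrix(labels=labels, values=v, metric=metric)


def within_between_test(dm: DistanceMatrix) -> dict:
    """Are same-subject/cross-task distances smaller than between-subject ones?

    Labels must be (subject, task) pairs covering >= 2 subjects x 2 tasks.
    For each task, the same-subject/different-task distances (one per
    subject) are compared against the different-subject/same-task distances
    of that task with a one-sided Wilcoxon rank-sum (Mann-Whitney U) test.
    Returns per-task means, statistics and p-values plus the pooled
    within-subject mean.  If every distance is zero the comparison is
    degenerate and p = 1 by contract.
    """
    subjects = sorted({lbl[0] for lbl in dm.labels})
    tasks = sorted({lbl[1] for lbl in dm.labels})
    if len(subjects) < 2 or len(tasks) != 2:
        raise ValueError("need >= 2 subjects and exactly 2 tasks")
    index = {lbl: i for i, lbl in enumerate(dm.labels)}
    for s in subjects:
        for t in tasks:
            if (s, t) not in index:
                raise ValueError(f"missing grid for subject {s!r}, task {t!r}")

    within = np.array(
        [dm.values[index[(s, tasks[0])], index[(s, tasks[1])]] for s in subjects]
    )
    out: dict = {"within_subject_mean": float(within.mean()), "per_task": {}}
    for t in tasks:
        between = np.array(
            [
                dm.values[index[(a, t)], index[(b, t)]]
                for i, a in enumerate(subjects)
                for b in subjects[i + 1 :]
            ]
        )
        if np.all(within == 0) and np.all(between == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = mannwhitneyu(within, between, alternative="less")
        out["per_task"][t] = {
            "between_subject_mean": float(between.mean()),
            "statistic": float(stat),
            "p": float(p),
        }
    return out


def mds_embed(dm: DistanceMatrix, dim: int = 2) -> tuple:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centers the squared distances, takes the top ``dim`` eigenvectors
    scaled by root eigenvalues.  Deterministic up to per-axis sign, which is
    fixed by making each axis's largest-magnitude coordinate positive.
    Requires the sqrt_js metric (raw JS is not a metric); substantial
    negative eigenvalue mass (>10% of the absolute spectrum) triggers a
    warning that the distances are not well embeddable.

    Returns (labels, coords) with coords of shape (n, dim).
    """
    if dm.metric != "sqrt_js":
        raise ValueError("mds_embed requires the sqrt_js metric")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    d2 = dm.values**2
    n = dm.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    neg_mass = np.sum(np.abs(vals[vals < 0]))
    tot_mass = np.sum(np.abs(vals))
    if tot_mass > 0 and neg_mass / tot_mass > 0.10:
        warnings.warn(
            "distance matrix is far from Euclidean: negative eigenvalue mass "
            f"{neg_mass / tot_mass:.1%}",
            stacklevel=2,
        )
    coords = np.zeros((n, dim))
    for a in range(min(dim, n)):
        lam = max(vals[a], 0.0)
        axis = vecs[:, a] * np.sqrt(lam)
        if np.abs(axis).max() > 0 and axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        coords[:, a] = axis
    return dm.labels, coords
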