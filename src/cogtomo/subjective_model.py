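"""Subjective distributions over a bounded stimulus feature space.

A subject's prior over stimuli ("subjective distribution") is represented as
a finite Gaussian mixture over a feature space measured in SD units.  The
mixture is expressive enough to capture multimodal, nonconvex priors while
keeping every observer likelihood analytic: convolving a mixture with
isotropic Gaussian perceptual noise is again a mixture.

Grid discretizations over the bounded box are the common currency for
Jensen-Shannon comparisons, moment summaries and plotting.  Mixture
components are deliberately *not* truncated to the box; grid operations
renormalize over it instead, since mass beyond a few SD is negligible for
realistic fits and truncation would break the analytic marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr

__all__ = [
    "FeatureSpace",
    "SubjectiveDistribution",
    "GridDensity",
    "js_divergence",
    "moment_match",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FeatureSpace:
    """A bounded box of stimulus features, spanning +/- half_width per dimension.

    Coordinates are in units of SD of the population feature distribution
    (for faces, the first two principal components of facial structure).
    """

    n_dims: int = 2
    half_width: float = 4.0

    def __post_init__(self) -> None:
        if self.n_dims < 1:
            raise ValueError("n_dims must be a positive integer")
        if not (self.half_width > 0):
            raise ValueError("half_width must be positive")

    @property
    def uniform_density(self) -> float:
        """Density of the uniform distribution over the box."""
        return float((2.0 * self.half_width) ** (-self.n_dims))

    @property
    def volume(self) -> float:
        return float((2.0 * self.half_width) ** self.n_dims)

    def contains(self, x: np.ndarray, atol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(np.asarray(x, dtype=float)) <= self.half_width + atol))

    def grid_axes(self, resolution: int) -> np.ndarray:
        """Cell-center coordinates of a regular grid covering the box exactly."""
        edges = np.linspace(-self.half_width, self.half_width, resolution + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    def grid_points(self, resolution: int) -> np.ndarray:
        """All cell centers, shape (resolution**n_dims, n_dims), x fastest last."""
        axes = [self.grid_axes(resolution)] * self.n_dims
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)


def _validate_mixture(weights: np.ndarray, means: np.ndarray, covariances: np.ndarray, n_dims: int) -> None:
    if weights.ndim != 1 or weights.shape[0] < 1:
        raise ValueError("weights must be a nonempty 1-D array")
    k = weights.shape[0]
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if abs(float(weights.sum()) - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1 within 1e-12")
    if means.shape != (k, n_dims):
        raise ValueError(f"means must have shape ({k}, {n_dims})")
    if covariances.shape != (k, n_dims, n_dims):
        raise ValueError(f"covariances must have shape ({k}, {n_dims}, {n_dims})")
    for m in range(k):
        c = covariances[m]
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError(f"covariance {m} is not symmetric")
        if np.min(np.linalg.eigvalsh(c)) <= 0:
            raise ValueError(f"covariance {m} is not positive definite")


@dataclass(frozen=True)
class SubjectiveDistribution:
    """A Gaussian-mixture prior over the feature space.

    Parameters
    ----------
    space : FeatureSpace
    weights : (K,) mixing weights, nonnegative, summing to one.
    means : (K, n_dims) component means, SD units.
    covariances : (K, n_dims, n_dims) symmetric positive-definite, SD^2 units.
    """

    space: FeatureSpace
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        cov = np.asarray(self.covariances, dtype=float)
        _validate_mixture(w, mu, cov, self.space.n_dims)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "covariances", cov)

    @property
    def n_components(self) -> int:
        return int(self.weights.shape[0])

    # ---- density -----------------------------------------------------------

    def logpdf(self, x: np.ndarray, add_var: float = 0.0) -> np.ndarray:
        """Log mixture density at points ``x``, shape (..., n_dims).

        ``add_var`` adds an isotropic variance to every component covariance,
        which evaluates the mixture convolved with Normal(0, add_var * I) —
        the analytic marginal of a Gaussian-noise-corrupted sample.
        """
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.space.n_dims:
            raise ValueError(
                f"points have dimension {x.shape[-1]}, expected {self.space.n_dims}"
            )
        pts = x.reshape(-1, self.space.n_dims)
        d = self.space.n_dims
        comp = np.empty((pts.shape[0], self.n_components))
        for m in range(self.n_components):
            cov = self.covariances[m]
            if add_var:
                cov = cov + add_var * np.eye(d)
            diff = pts - self.means[m]
            if d == 2:
                a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
                det = a * c - b * b
                d0, d1 = diff[:, 0], diff[:, 1]
                quad = (c * d0 * d0 - 2.0 * b * d0 * d1 + a * d1 * d1) / det
                logdet = np.log(det)
            else:
                chol = np.linalg.cholesky(cov)
                y = np.linalg.solve(chol, diff.T)
                quad = np.sum(y * y, axis=0)
                logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
            comp[:, m] = -0.5 * (quad + logdet + d * _LOG_2PI)
        with np.errstate(divide="ignore"):
            comp += np.log(self.weights)
        # inlined logsumexp: this sits on the MCMC hot path
        peak = comp.max(axis=1, keepdims=True)
        out = peak[:, 0] + np.log(np.exp(comp - peak).sum(axis=1))
        return out.reshape(x.shape[:-1])

    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Mixture density at points ``x``; finite and nonnegative."""
        return np.exp(self.logpdf(x))

    # ---- sampling ----------------------------------------------------------

    def sample(self, n: int, seed: int | np.random.Generator) -> np.ndarray:
        """Draw ``n`` ancestral samples (component by weight, then Gaussian)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        comps = rng.choice(self.n_components, size=n, p=self.weights)
        out = np.empty((n, self.space.n_dims))
        for m in range(self.n_components):
            idx = np.flatnonzero(comps == m)
            if idx.size:
                out[idx] = rng.multivariate_normal(
                    self.means[m], self.covariances[m], size=idx.size
                )
        return out

    # ---- discretization ----------------------------------------------------

    def to_grid(self, resolution: int = 100) -> "GridDensity":
        """Discretize onto a regular grid over the box; masses renormalized."""
        if resolution < 8:
            raise ValueError("resolution must be >= 8")
        pts = self.space.grid_points(resolution)
        dens = self.pdf(pts)
        masses = dens / dens.sum()
        shape = (resolution,) * self.space.n_dims
        return GridDensity(self.space, resolution, masses.reshape(shape))

    # ---- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "space": {"n_dims": self.space.n_dims, "half_width": self.space.half_width},
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectiveDistribution":
        space = FeatureSpace(int(d["space"]["n_dims"]), float(d["space"]["half_width"]))
        return cls(
            space,
            np.asarray(d["weights"], dtype=float),
            np.asarray(d["means"], dtype=float),
            np.asarray(d["covariances"], dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "SubjectiveDistribution":
        return cls.from_dict(json.loads(s))


def _mixture_unchecked(
    space: FeatureSpace, weights: np.ndarray, means: np.ndarray, covariances: np.ndarray
) -> SubjectiveDistribution:
    """Construct a SubjectiveDistribution skipping invariant checks.

    Only for callers that guarantee validity by construction (e.g. the MCMC
    builds covariances from eigen-scales and a rotation, so they are always
    symmetric positive definite); validation dominates runtime on that path.
    """
    obj = object.__new__(SubjectiveDistribution)
    object.__setattr__(obj, "space", space)
    object.__setattr__(obj, "weights", weights)
    object.__setattr__(obj, "means", means)
    object.__setattr__(obj, "covariances", covariances)
    return obj


@dataclass(frozen=True)
class GridDensity:
    """A normalized density discretized on a regular grid over the box."""

    space: FeatureSpace
    resolution: int
    masses: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        expected = (self.resolution,) * self.space.n_dims
        if m.shape != expected:
            raise ValueError(f"masses must have shape {expected}, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("masses must be nonnegative")
        if abs(float(m.sum()) - 1.0) > 1e-9:
            raise ValueError("masses must sum to 1 within 1e-9")
        object.__setattr__(self, "masses", m)

    def same_grid(self, other: "GridDensity") -> bool:
        return self.space == other.space and self.resolution == other.resolution

    def mean(self) -> np.ndarray:
        """Grid-weighted mean coordinate."""
        pts = self.space.grid_points(self.resolution)
        return pts.T @ self.masses.ravel()

    def to_frame(self):
        """Long-format table (x, y, mass) for 2-D grids, for plotting/export."""
        import pandas as pd

        if self.space.n_dims != 2:
            raise ValueError("to_frame is defined for 2-D grids")
        pts = self.space.grid_points(self.resolution)
        return pd.DataFrame(
            {"x": pts[:, 0], "y": pts[:, 1], "mass": self.masses.ravel()}
        )


def moment_match(p: SubjectiveDistribution) -> SubjectiveDistribution:
    """The single Gaussian with the same mean and covariance as ``p``.

    Uses the law of total covariance:
    mu = sum_k w_k mu_k;  Sigma = sum_k w_k (Sigma_k + mu_k mu_k^T) - mu mu^T.
    Used to test whether structure beyond second moments matters for behavior.
    """
    if p.n_components == 1:
        return p  # already Gaussian; avoids a one-ulp round trip through mu mu^T
    w = p.weights
    mu = w @ p.means
    second = np.einsum("k,kij->ij", w, p.covariances) + np.einsum(
        "k,ki,kj->ij", w, p.means, p.means
    )
    cov = second - np.outer(mu, mu)
    cov = 0.5 * (cov + cov.T)
    return SubjectiveDistribution(
        p.space, np.array([1.0]), mu[None, :], cov[None, :, :]
    )


def js_divergence(p: GridDensity, q: GridDensity) -> float:
    """Jensen-Shannon divergence between two grid densities, in bits.

    JS = 1/2 KL(p || m) + 1/2 KL(q || m) with m = (p + q) / 2 and base-2
    logarithms, so the result lies in [0, 1]; 0 log 0 is treated as 0.
    Its square root is a metric and is what multidimensional scaling uses.
    """
    if not p.same_grid(q):
        raise ValueError("grids must share space and resolution")
    a = p.masses.ravel()
    b = q.masses.ravel()
    m = 0.5 * (a + b)
    kl_pm = rel_entr(a, m).sum()
    kl_qm = rel_entr(b, m).sum()
    return float(0.5 * (kl_pm + kl_qm) / np.log(2.0))
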