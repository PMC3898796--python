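"""Independent numerical oracles used by the tests.

These deliberately avoid the package's analytic likelihood path: marginal
likelihoods are computed by Gauss-Legendre quadrature over the latent face,
and mixture densities by summing scipy's per-component Gaussian pdfs.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.stats import multivariate_normal

_GL_CACHE: dict = {}


def gl_grid(half_width: float = 12.0, n_nodes: int = 240):
    """Tensor-product Gauss-Legendre nodes/weights on [-hw, hw]^2."""
    key = (half_width, n_nodes)
    if key not in _GL_CACHE:
        x, w = leggauss(n_nodes)
        x = x * half_width
        w = w * half_width
        xx, yy = np.meshgrid(x, x, indexing="ij")
        _GL_CACHE[key] = (
            np.stack([xx.ravel(), yy.ravel()], axis=-1),
            np.outer(w, w).ravel(),
        )
    return _GL_CACHE[key]


def mixture_pdf_bruteforce(p, x: np.ndarray) -> np.ndarray:
    """Mixture density via scipy per-component pdfs (no shared code path)."""
    x = np.atleast_2d(x)
    out = np.zeros(x.shape[0])
    for w, mu, cov in zip(p.weights, p.means, p.covariances):
        out += w * multivariate_normal.pdf(x, mean=mu, cov=cov)
    return out


def quad_noisy_marginal(s: np.ndarray, p, var: float) -> float:
    """integral of N(s; f, var I) p(f) df by quadrature over the latent f."""
    pts, wts = gl_grid()
    d2 = np.sum((pts - s) ** 2, axis=1)
    kern = np.exp(-d2 / (2.0 * var)) / (2.0 * np.pi * var)
    return float(np.sum(wts * kern * mixture_pdf_bruteforce(p, pts)))


def quad_pair_marginal(si: np.ndarray, sj: np.ndarray, p, var: float) -> float:
    """integral of N(si; f, var I) N(sj; f, var I) p(f) df by quadrature."""
    pts, wts = gl_grid()
    di = np.sum((pts - si) ** 2, axis=1)
    dj = np.sum((pts - sj) ** 2, axis=1)
    kern = np.exp(-(di + dj) / (2.0 * var)) / (2.0 * np.pi * var) ** 2
    return float(np.sum(wts * kern * mixture_pdf_bruteforce(p, pts)))


def quad_familiarity_likelihoods(trial, p, params) -> np.ndarray:
    """Quadrature version of the familiarity hypothesis likelihoods."""
    var = params.perceptual_sigma**2
    u = p.space.uniform_density
    return np.array(
        [u * quad_noisy_marginal(s, p, var) for s in trial.stimuli]
    )


def quad_ooo_likelihoods(trial, p, params) -> np.ndarray:
    """Quadrature version of the odd-one-out hypothesis likelihoods."""
    var = params.perceptual_sigma**2
    pairs = [(1, 2), (0, 2), (0, 1)]
    out = np.empty(3)
    for k, (i, j) in enumerate(pairs):
        out[k] = quad_pair_marginal(
            trial.stimuli[i], trial.stimuli[j], p, var
        ) * quad_noisy_marginal(trial.stimuli[k], p, var)
    return out


def js_divergence_bruteforce(p_masses: np.ndarray, q_masses: np.ndarray) -> float:
    """Cell-by-cell JS in bits, accumulated in a plain Python loop."""
    total = 0.0
    for a, b in zip(p_masses.ravel().tolist(), q_masses.ravel().tolist()):
        m = 0.5 * (a + b)
        if a > 0:
            total += 0.5 * a * np.log2(a / m)
        if b > 0:
            total += 0.5 * b * np.log2(b / m)
    return total


def random_mixture(seed: int, space, k: int = 3, scale_range=(0.3, 1.2)):
    """A random valid mixture for randomized oracle checks."""
    from cogtomo import SubjectiveDistribution

    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(k))
    means = rng.uniform(-space.half_width * 0.8, space.half_width * 0.8, (k, 2))
    covs = np.empty((k, 2, 2))
    for m in range(k):
        scales = rng.uniform(*scale_range, size=2)
        ang = rng.uniform(0, np.pi)
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s], [s, c]])
        covs[m] = rot @ np.diag(scales**2) @ rot.T
    return SubjectiveDistribution(space, w, means, covs)
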