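"""Empirical-Bayes two-groups inference on per-unit z-values.

The marginal density of unit-level z-scores is modelled as the mixture

    f(z) = p0 · f0(z) + (1 − p0) · f1(z)

with f0 the *empirical* null N(μ0, σ0²) and p0 the null proportion.  The
marginal f is estimated by Poisson-regression spline smoothing of the z
histogram.  The null is estimated by central matching: a quadratic in z is
fitted to the histogram counts by Poisson likelihood over the central bins,
which determines (μ0, σ0, p0) in closed form; the fit is then refreshed over
all bins that the current null accounts for (≥90% of the smoothed counts),
so that null-dominated flanks sharpen the estimate without admitting bins
carrying real effects.  The local false discovery rate is

    lfdr(z) = p0 · f0(z) / f(z)     (clipped to [0, 1])

and the per-unit posterior probability of a true effect is 1 − lfdr.
"Achieved power" is summarised as the mean posterior over units whose
posterior exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.stats import norm

__all__ = ["EbiFit", "ebi_fit"]


@dataclass
class EbiFit:
    """Fitted two-groups model over test units."""

    z: np.ndarray
    p0: float
    null_mean: float
    null_sd: float
    local_fdr: np.ndarray
    posterior: np.ndarray
    achieved_power: float
    f_hat: np.ndarray  # marginal density at each unit's z


def _poisson_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Poisson regression by Newton iteration (log link)."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-3))
    for _ in range(200):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        hess = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(X.shape[1]), grad)
        except np.linalg.LinAlgError:
            return None
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta


def _null_from_quadratic(beta, n, width):
    """(p0, μ0, σ0) from log-count quadratic b0 + b1 z + b2 z²."""
    b0, b1, b2 = beta
    if b2 >= 0:
        return None
    sd = float(np.sqrt(-1.0 / (2.0 * b2)))
    mu = float(b1 * sd**2)
    p0 = float(
        np.exp(b0 + mu**2 / (2 * sd**2)) * sd * np.sqrt(2 * np.pi) / (n * width)
    )
    return min(p0, 1.0), mu, sd


def _spline_design(x: np.ndarray, lo: float, hi: float, df: int) -> np.ndarray:
    k = 3
    interior = np.linspace(lo, hi, df - k + 1)[1:-1]
    t = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
    return BSpline.design_matrix(np.clip(x, lo, hi), t, k).toarray()


def ebi_fit(
    z: np.ndarray,
    n_bins: int = 90,
    df: int = 12,
    dominance: float = 0.90,
    n_refit: int = 3,
) -> EbiFit:
    """Fit the two-groups model to a vector of z-values (needs ≥ 100 units)."""
    z = np.asarray(z, float)
    if z.ndim != 1 or z.size < 100:
        raise ValueError("ebi_fit needs a 1-D array of at least 100 z-values")
    if not np.all(np.isfinite(z)):
        raise ValueError("z-values must be finite")
    if np.ptp(z) == 0:
        raise ValueError("degenerate z-values (all equal)")

    lo, hi = z.min(), z.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    width = edges[1] - edges[0]

    # marginal density by Poisson spline smoothing
    Xs = _spline_design(centers, lo, hi, df)
    beta_s = _poisson_fit(Xs, counts.astype(float))
    if beta_s is None:
        raise ValueError("marginal density estimation failed")

    def density(at: np.ndarray) -> np.ndarray:
        eta = np.clip(_spline_design(at, lo, hi, df) @ beta_s, -30, 30)
        return np.exp(eta) / (z.size * width)

    # empirical null by central matching
    smoothed = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    mode = centers[int(np.argmax(smoothed))]
    sd_rough = float(np.diff(np.quantile(z, [0.25, 0.75]))[0]) / 1.349
    if sd_rough == 0:
        sd_rough = z.std() or 1.0

    def quad(sel: np.ndarray):
        X = np.column_stack([np.ones(sel.sum()), centers[sel], centers[sel] ** 2])
        beta = _poisson_fit(X, counts[sel].astype(float))
        return None if beta is None else _null_from_quadratic(beta, z.size, width)

    fit0 = quad(np.abs(centers - mode) <= 1.3 * sd_rough)
    if fit0 is None:
        raise ValueError("central density is not concave; cannot match a null")
    p0, mu0, sd0 = fit0
    central = np.abs(centers - mode) <= 1.0 * sd_rough
    for _ in range(n_refit):
        null_counts = p0 * norm.pdf(centers, mu0, sd0) * z.size * width
        sel = central | (
            (null_counts >= dominance * np.maximum(smoothed, 1e-9))
            & (null_counts >= 2.0)
        )
        refit = quad(sel)
        if refit is None:
            break
        p0, mu0, sd0 = refit

    f_hat = np.maximum(density(z), 1e-300)
    f0 = norm.pdf(z, loc=mu0, scale=sd0)
    lfdr = np.clip(p0 * f0 / f_hat, 0.0, 1.0)
    posterior = 1.0 - lfdr
    hits = posterior > 0.5
    power = float(posterior[hits].mean()) if hits.any() else 0.0
    return EbiFit(
        z=z,
        p0=p0,
        null_mean=mu0,
        null_sd=sd0,
        local_fdr=lfdr,
        posterior=posterior,
        achieved_power=power,
        f_hat=f_hat,
    )
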