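"""Analytic expected error of individual features.

For a scalar feature x measured at (unknown) downwind distance y, the best
possible regression function is the posterior mean

    f*(x) = <y | x> = int_0^R y p(y|x) dy,

with posterior p(y|x) proportional to p(x|y) p(y). Sampling locations
uniformly over a cone of length R gives the triangular prior
p(y) = 2y / R^2, whose mean is 2R/3 and whose variance is R^2/18. Features
are window averages, so their conditional law is modeled as Gaussian,
p(x|y) = N(g(y), s(y)), with mean and dispersion curves estimated
empirically by binning feature samples against distance.

The expected normalized error of the feature is then

    chi* = int dx int dy (y - f*(x))^2 p(x|y) p(y)  /  (R^2 / 18),

evaluated by nested trapezoidal quadrature. chi* = 1 for an uninformative
feature (the posterior equals the prior) and chi* -> 0 for a noiseless
strictly monotone one; it can never exceed 1 beyond quadrature error
because f* is the minimizer of the expected squared loss.

Caveat: the Gaussian-likelihood assumption is an asymptotic (large-window)
approximation; it is weakest for the mean whiff duration, whose sampling
distribution is markedly skewed in sparse conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad

__all__ = [
    "PriorSpec",
    "LikelihoodEstimate",
    "AnalyticLikelihood",
    "ExpectedErrorResult",
    "prior_moments",
    "estimate_likelihood",
    "regression_function",
    "expected_error",
]


@dataclass(frozen=True)
class PriorSpec:
    """Triangular distance prior p(y) = 2y/R^2 on (0, R]."""

    R: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("cone length R must be > 0")

    def pdf(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return np.where((y > 0) & (y <= self.R), 2.0 * y / self.R**2, 0.0)

    @property
    def mean(self) -> float:
        return 2.0 * self.R / 3.0

    @property
    def denominator(self) -> float:
        """Variance of the prior, int (y - ybar)^2 p(y) dy = R^2/18."""
        return self.R**2 / 18.0


def prior_moments(R: float) -> tuple[float, float]:
    """Prior mean and variance by quadrature, cross-checked against the
    closed forms 2R/3 and R^2/18."""
    prior = PriorSpec(R)
    mean, _ = quad(lambda y: y * prior.pdf(y), 0.0, R)
    var, _ = quad(lambda y: (y - mean) ** 2 * prior.pdf(y), 0.0, R)
    if not (
        np.isclose(mean, prior.mean, rtol=1e-8)
        and np.isclose(var, prior.denominator, rtol=1e-8)
    ):
        raise RuntimeError("quadrature disagrees with closed-form prior moments")
    return float(mean), float(var)


@dataclass(frozen=True)
class LikelihoodEstimate:
    """Binned empirical mean and dispersion of a feature vs distance.

    ``y_centers`` are per-bin mean distances; ``g``/``s`` the per-bin sample
    mean and (unbiased) standard deviation of the feature, the latter
    floored at a small positive value; ``counts`` the bin occupancies.
    Between bin centers the curves are interpolated linearly and clamped at
    the edges.
    """

    y_centers: np.ndarray
    g: np.ndarray
    s: np.ndarray
    counts: np.ndarray
    R: float
    s_floor: float

    def g_at(self, y: np.ndarray) -> np.ndarray:
        return np.interp(y, self.y_centers, self.g)

    def s_at(self, y: np.ndarray) -> np.ndarray:
        return np.interp(y, self.y_centers, self.s)


@dataclass(frozen=True)
class AnalyticLikelihood:
    """Gaussian feature law with known mean/dispersion curves.

    Used when the generative model provides g and s exactly (ground-truth
    laws or constructed features); interchangeable with an empirical
    :class:`LikelihoodEstimate`.
    """

    g_fn: Callable[[np.ndarray], np.ndarray]
    s_fn: Callable[[np.ndarray], np.ndarray]
    R: float

    def g_at(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(self.g_fn(np.asarray(y, dtype=float)), dtype=float)

    def s_at(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(self.s_fn(np.asarray(y, dtype=float)), dtype=float)


def estimate_likelihood(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 20,
    R: float | None = None,
    s_floor_fraction: float = 1e-6,
) -> LikelihoodEstimate:
    """Bin feature samples by distance and estimate g(y), s(y).

    Bins hold equal sample counts (quantile edges in y). Bins left with
    fewer than two points are merged into their neighbor with a warning.
    The dispersion is floored at ``s_floor_fraction`` times the feature
    range so the Gaussian likelihood never becomes singular.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples, at least 4")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if R is None:
        R = float(y.max())
    edges = np.quantile(y, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, edges.size - 2)
    groups = [np.flatnonzero(idx == k) for k in range(edges.size - 1)]
    merged: list[np.ndarray] = []
    for grp in groups:
        if grp.size == 0:
            continue
        if grp.size < 2 and merged:
            warnings.warn("likelihood bin with < 2 points merged into neighbor")
            merged[-1] = np.concatenate([merged[-1], grp])
        else:
            merged.append(grp)
    if merged and merged[0].size < 2 and len(merged) > 1:
        warnings.warn("likelihood bin with < 2 points merged into neighbor")
        merged[1] = np.concatenate([merged[0], merged[1]])
        merged = merged[1:]
    centers = np.array([y[g].mean() for g in merged])
    g_hat = np.array([x[g].mean() for g in merged])
    s_hat = np.array([x[g].std(ddof=1) for g in merged])
    span = float(np.ptp(x))
    floor = s_floor_fraction * span if span > 0 else 1e-12
    s_hat = np.maximum(s_hat, floor)
    order = np.argsort(centers)
    return LikelihoodEstimate(
        y_centers=centers[order],
        g=g_hat[order],
        s=s_hat[order],
        counts=np.array([g.size for g in merged])[order],
        R=R,
        s_floor=floor,
    )


@dataclass(frozen=True)
class ExpectedErrorResult:
    """Tabulated posterior-mean regression function and expected error."""

    x_grid: np.ndarray
    f_star: np.ndarray
    chi_star: float
    n_x: int
    n_y: int
    rel_change: float  # relative change on grid halving (convergence check)
    low_evidence: np.ndarray  # flags where p(x) hit the numerical floor


def _posterior_weights(
    likelihood, prior: PriorSpec, x: np.ndarray, y_grid: np.ndarray
) -> np.ndarray:
    """Unnormalized posterior density over y for each x (rows: x)."""
    g = likelihood.g_at(y_grid)
    s = likelihood.s_at(y_grid)
    z = (x[:, None] - g[None, :]) / s[None, :]
    return np.exp(-0.5 * z**2) / s[None, :] * prior.pdf(y_grid)[None, :]


def regression_function(
    likelihood,
    prior: PriorSpec,
    x: np.ndarray,
    n_y: int = 2048,
) -> np.ndarray:
    """Posterior-mean prediction f*(x) on a y-grid over (0, R].

    Where the evidence p(x) underflows (x far outside the likelihood
    support), the prior mean is returned for that x.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y_grid = np.linspace(prior.R / n_y, prior.R, n_y)
    w = _posterior_weights(likelihood, prior, x, y_grid)
    evidence = np.trapezoid(w, y_grid, axis=1)
    num = np.trapezoid(w * y_grid[None, :], y_grid, axis=1)
    floor = np.finfo(float).tiny * n_y
    out = np.where(evidence > floor, num / np.where(evidence > 0, evidence, 1.0),
                   prior.mean)
    return out


def _chi_star_on_grid(
    likelihood, prior: PriorSpec, n_x: int, n_y: int, chunk: int = 256
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """One pass of the double quadrature, chunked over the x-grid.

    Dispersions are floored at the x-grid spacing: an empirical bin whose
    feature values coincide would otherwise produce a Gaussian far narrower
    than any affordable grid. The floor shrinks with refinement, so the
    convergence loop controls the smearing it introduces.
    """
    y_grid = np.linspace(prior.R / n_y, prior.R, n_y)
    g = likelihood.g_at(y_grid)
    s = likelihood.s_at(y_grid)
    s_max = float(s.max())
    x_lo = float(g.min()) - 5.0 * s_max
    x_hi = float(g.max()) + 5.0 * s_max
    x_grid = np.linspace(x_lo, x_hi, n_x)
    spacing = (x_hi - x_lo) / (n_x - 1)
    s_eff = np.maximum(s, spacing)
    prior_pdf = prior.pdf(y_grid)
    tiny = np.finfo(float).tiny * n_y

    f_star = np.empty(n_x)
    low = np.zeros(n_x, dtype=bool)
    inner = np.empty(n_x)
    for start in range(0, n_x, chunk):
        xb = x_grid[start : start + chunk]
        z = (xb[:, None] - g[None, :]) / s_eff[None, :]
        w = np.exp(-0.5 * z**2) / s_eff[None, :] * prior_pdf[None, :]
        evidence = np.trapezoid(w, y_grid, axis=1)
        num = np.trapezoid(w * y_grid[None, :], y_grid, axis=1)
        lo = evidence <= tiny
        fb = np.where(~lo, num / np.where(evidence > 0, evidence, 1.0), prior.mean)
        sq = (y_grid[None, :] - fb[:, None]) ** 2
        # joint density p(x,y) = p(x|y) p(y) needs the Gaussian normalization
        inner[start : start + chunk] = np.trapezoid(
            sq * w / np.sqrt(2.0 * np.pi), y_grid, axis=1
        )
        f_star[start : start + chunk] = fb
        low[start : start + chunk] = lo
    chi = float(np.trapezoid(inner, x_grid) / prior.denominator)
    return x_grid, f_star, chi, low


def expected_error(
    likelihood,
    prior: PriorSpec,
    n_x: int = 2048,
    n_y: int = 2048,
    rtol: float = 1e-3,
    max_doublings: int = 3,
) -> ExpectedErrorResult:
    """Expected normalized error chi* of a feature by double quadrature.

    The x-range extends five maximal dispersions beyond the range of g.
    Convergence is assessed by grid doubling: the grids are refined until
    consecutive estimates agree within ``rtol`` relative, up to
    ``max_doublings`` refinements; persistent disagreement raises with
    diagnostics.
    """
    chi_prev = _chi_star_on_grid(likelihood, prior, n_x // 2, n_y // 2)[2]
    x_grid, f_star, chi, low = _chi_star_on_grid(likelihood, prior, n_x, n_y)
    rel = abs(chi - chi_prev) / max(abs(chi), 1e-12)
    doublings = 0
    while rel > rtol and doublings < max_doublings:
        doublings += 1
        n_x *= 2
        n_y *= 2
        chi_prev = chi
        x_grid, f_star, chi, low = _chi_star_on_grid(likelihood, prior, n_x, n_y)
        rel = abs(chi - chi_prev) / max(abs(chi), 1e-12)
    if rel > rtol:
        raise RuntimeError(
            f"quadrature not converged: chi*={chi:.6g} vs {chi_prev:.6g} on "
            f"grid doubling (relative change {rel:.2e} > {rtol:g} at "
            f"n_x={n_x}, n_y={n_y})"
        )
    return ExpectedErrorResult(
        x_grid=x_grid,
        f_star=f_star,
        chi_star=chi,
        n_x=n_x,
        n_y=n_y,
        rel_change=rel,
        low_evidence=low,
    )
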