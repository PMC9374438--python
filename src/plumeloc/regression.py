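"""Distance regression: linear baseline and Gaussian-kernel ridge.

The estimator is kernel ridge regression (KRR) with the Gaussian kernel
k(x, x') = exp(-||x - x'||^2 / (2 sigma^2)) and the closed-form coefficients

    c = (K + lambda * N * I)^{-1} y,

which minimize (1/N) ||K c - y||^2 + lambda c^T K c. Features are
standardized (center/scale from the training split) before kernel
evaluation so a single kernel width serves feature subsets with mixed
units. Hyperparameters (lambda, sigma) are selected by 4-fold cross
validation over a log-spaced 8x8 grid followed by a 4x4 refinement around
the minimizer.

Performance is reported as the normalized test error

    chi = sum_i (y_i - f(x_i))^2 / sum_i (y_i - ybar)^2,

for which the constant mean predictor scores exactly 1 and predictions
drawn independently from the output distribution score 2 in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist, pdist

from .features import FEATURE_NAMES, INTENSITY_FEATURES

__all__ = [
    "LinearModel",
    "KernelModel",
    "CVResult",
    "PredictionReport",
    "linear_fit",
    "krr_fit",
    "krr_predict",
    "tune_hyperparameters",
    "chi_error",
    "trivial_predictions",
    "random_predictions",
    "evaluate_feature_sets",
]


# ---------------------------------------------------------------------------
# chi error and baselines


def chi_error(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Normalized squared test error chi.

    Sum of squared prediction errors over the sum of squared deviations of
    the true outputs from their mean. 0 is exact; 1 matches the trivial
    mean predictor; independent random guessing gives 2 in expectation.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    if y_true.size < 2:
        raise ValueError("need at least two test points")
    denom = float(np.sum((y_true - y_true.mean()) ** 2))
    if denom == 0:
        raise ValueError("test outputs are constant: chi undefined")
    return float(np.sum((y_true - y_pred) ** 2) / denom)


def trivial_predictions(y_true: np.ndarray) -> np.ndarray:
    """The trivial predictor: the test-set mean for every point (chi = 1)."""
    y_true = np.asarray(y_true, dtype=float)
    return np.full_like(y_true, y_true.mean())


def random_predictions(
    y_true: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random-guess baseline: i.i.d. draws from the empirical output
    distribution, independent of the targets (E[chi] = 2)."""
    y_true = np.asarray(y_true, dtype=float)
    return rng.choice(y_true, size=y_true.size, replace=True)


# ---------------------------------------------------------------------------
# linear least squares


@dataclass(frozen=True)
class LinearModel:
    weights: np.ndarray
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept


def linear_fit(X: np.ndarray, y: np.ndarray) -> LinearModel:
    """Ordinary least squares with intercept, w = (X^T X)^{-1} X^T y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if n <= d:
        raise ValueError("need more samples than features")
    A = np.column_stack([np.ones(n), X])
    gram = A.T @ A
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise np.linalg.LinAlgError(
            "singular normal matrix; use the regularized kernel path instead"
        )
    coef = np.linalg.solve(gram, A.T @ y)
    return LinearModel(weights=coef[1:], intercept=float(coef[0]))


# ---------------------------------------------------------------------------
# kernel ridge regression


def _gaussian_kernel(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    sq = cdist(A, B, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma**2))


@dataclass(frozen=True)
class Standardizer:
    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(center=center, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale


@dataclass(frozen=True)
class KernelModel:
    """Fitted KRR state: standardized training inputs, coefficients,
    kernel width and regularization."""

    X_train: np.ndarray  # standardized
    coef: np.ndarray
    sigma: float
    lam: float
    standardizer: Standardizer

    @property
    def n_train(self) -> int:
        return self.X_train.shape[0]


def krr_fit(X: np.ndarray, y: np.ndarray, sigma: float, lam: float) -> KernelModel:
    """Closed-form KRR fit: solve (K + lambda N I) c = y.

    At lambda = 0 the solve falls back to a least-squares solution and
    raises if the kernel matrix is numerically singular.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    K = _gaussian_kernel(Xs, Xs, sigma)
    A = K + lam * n * np.eye(n)
    if lam > 0:
        c = cho_solve(cho_factor(A), y)
    else:
        cond = np.linalg.cond(A)
        if cond > 1e12:
            raise np.linalg.LinAlgError(
                f"kernel matrix ill-conditioned at lambda=0 (cond={cond:.2e})"
            )
        c = np.linalg.solve(A, y)
    return KernelModel(X_train=Xs, coef=c, sigma=sigma, lam=lam, standardizer=std)


def krr_predict(
    model: KernelModel, X_new: np.ndarray, chunk: int = 2000
) -> np.ndarray:
    """Evaluate f(x) = sum_i k(x_i, x) c_i, chunked over test points."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"expected {model.X_train.shape[1]} feature columns, "
            f"got {X_new.shape[1]}"
        )
    Xs = model.standardizer.transform(X_new)
    out = np.empty(Xs.shape[0])
    for start in range(0, Xs.shape[0], chunk):
        block = Xs[start : start + chunk]
        out[start : start + chunk] = (
            _gaussian_kernel(block, model.X_train, model.sigma) @ model.coef
        )
    return out


# ---------------------------------------------------------------------------
# cross-validated hyperparameter search


@dataclass(frozen=True)
class CVResult:
    """Grid-search record: (lambda, sigma) grids, mean validation error per
    pair over the folds, and the selected pair after refinement."""

    lam_grid: np.ndarray
    sigma_grid: np.ndarray
    errors: np.ndarray  # coarse grid, shape (n_lam, n_sigma)
    refined_lam_grid: np.ndarray
    refined_sigma_grid: np.ndarray
    refined_errors: np.ndarray
    lam: float
    sigma: float


def _cv_grid_errors(
    X: np.ndarray,
    y: np.ndarray,
    lam_grid: np.ndarray,
    sigma_grid: np.ndarray,
    folds: list[np.ndarray],
) -> np.ndarray:
    """Mean validation chi over folds for every (lambda, sigma) pair.

    For each fold and sigma the kernel matrix is eigendecomposed once, so
    all lambda values share the factorization.
    """
    n_lam, n_sig = lam_grid.size, sigma_grid.size
    errors = np.zeros((n_lam, n_sig))
    counts = np.zeros((n_lam, n_sig))
    idx = np.arange(X.shape[0])
    for fold in folds:
        val = fold
        tr = np.setdiff1d(idx, val, assume_unique=True)
        y_tr, y_val = y[tr], y[val]
        if np.ptp(y_val) == 0 or np.ptp(y_tr) == 0:
            warnings.warn("degenerate CV fold (constant outputs); skipped")
            continue
        std = Standardizer.fit(X[tr])
        Xtr = std.transform(X[tr])
        Xval = std.transform(X[val])
        n_tr = Xtr.shape[0]
        denom = float(np.sum((y_val - y_val.mean()) ** 2))
        for j, sigma in enumerate(sigma_grid):
            K = _gaussian_kernel(Xtr, Xtr, sigma)
            evals, Q = np.linalg.eigh(K)
            b = Q.T @ y_tr
            Kval = _gaussian_kernel(Xval, Xtr, sigma) @ Q
            for i, lam in enumerate(lam_grid):
                coef_spec = b / (evals + lam * n_tr)
                pred = Kval @ coef_spec
                errors[i, j] += np.sum((y_val - pred) ** 2) / denom
                counts[i, j] += 1
    if counts.max() == 0:
        raise ValueError("all CV folds degenerate; cannot tune")
    return errors / np.maximum(counts, 1)


def _log_subgrid(grid: np.ndarray, k: int, n: int) -> np.ndarray:
    """Log-spaced n-point subgrid spanning one coarse step around grid[k]."""
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    return np.geomspace(lo, hi, n)


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 4,
    seed: int = 0,
    lam_range: tuple[float, float] = (1e-9, 1e1),
    sigma_factors: tuple[float, float] = (1e-2, 1e2),
    coarse: int = 8,
    refine: int = 4,
) -> CVResult:
    """Select (lambda, sigma) by k-fold CV grid search with refinement.

    The sigma grid is log-spaced around the median pairwise distance of the
    standardized inputs; the lambda grid spans under- to over-regularized.
    After the coarse grid, a finer subgrid centered on the minimizer is
    searched; the final pair minimizes the mean validation error there.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} samples to tune")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [perm[i::n_folds] for i in range(n_folds)]

    Xs = Standardizer.fit(X).transform(X)
    sub = Xs if n <= 2000 else Xs[rng.choice(n, 2000, replace=False)]
    med = float(np.median(pdist(sub)))
    if med == 0:
        med = 1.0
    lam_grid = np.geomspace(*lam_range, coarse)
    sigma_grid = med * np.geomspace(*sigma_factors, coarse)

    errors = _cv_grid_errors(X, y, lam_grid, sigma_grid, folds)
    i0, j0 = np.unravel_index(np.argmin(errors), errors.shape)
    lam_fine = _log_subgrid(lam_grid, int(i0), refine)
    sigma_fine = _log_subgrid(sigma_grid, int(j0), refine)
    fine_errors = _cv_grid_errors(X, y, lam_fine, sigma_fine, folds)
    i1, j1 = np.unravel_index(np.argmin(fine_errors), fine_errors.shape)
    return CVResult(
        lam_grid=lam_grid,
        sigma_grid=sigma_grid,
        errors=errors,
        refined_lam_grid=lam_fine,
        refined_sigma_grid=sigma_fine,
        refined_errors=fine_errors,
        lam=float(lam_fine[i1]),
        sigma=float(sigma_fine[j1]),
    )


# ---------------------------------------------------------------------------
# feature-set evaluation


@dataclass(frozen=True)
class PredictionReport:
    """Test-set performance of one fitted model.

    ``per_point`` holds each point's squared error divided by the test-set
    mean squared deviation, so its mean is chi.
    """

    features: tuple[str, ...]
    chi: float
    per_point: np.ndarray
    median: float
    p95: float
    lam: float
    sigma: float
    improvement: float | None = None  # pairs: gain over best member

    def summary(self) -> dict:
        out = {
            "features": list(self.features),
            "chi": self.chi,
            "median": self.median,
            "p95": self.p95,
            "lambda": self.lam,
            "sigma": self.sigma,
        }
        if self.improvement is not None:
            out["improvement"] = self.improvement
        return out


def fit_evaluate(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
    tune_subsample: int | None = 1000,
    features: tuple[str, ...] = (),
) -> PredictionReport:
    """Tune, fit and score one feature subset.

    The hyperparameter search optionally runs on a random subsample of the
    training rows (the validation surface has a wide plateau around its
    minimum, so a moderate subsample locates it); the final solve uses the
    full training set.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    rng = np.random.default_rng(seed)
    if tune_subsample is not None and X_train.shape[0] > tune_subsample:
        pick = rng.choice(X_train.shape[0], tune_subsample, replace=False)
        cv = tune_hyperparameters(X_train[pick], y_train[pick], seed=seed)
    else:
        cv = tune_hyperparameters(X_train, y_train, seed=seed)
    model = krr_fit(X_train, y_train, sigma=cv.sigma, lam=cv.lam)
    pred = krr_predict(model, X_test)
    chi = chi_error(y_test, pred)
    denom = np.mean((y_test - y_test.mean()) ** 2)
    per_point = (y_test - pred) ** 2 / denom
    return PredictionReport(
        features=tuple(features),
        chi=chi,
        per_point=per_point,
        median=float(np.median(per_point)),
        p95=float(np.percentile(per_point, 95)),
        lam=cv.lam,
        sigma=cv.sigma,
    )


def evaluate_feature_sets(
    dataset,
    subsets: list[tuple[str, ...]],
    seed: int = 0,
    tune_subsample: int | None = 1000,
) -> dict[tuple[str, ...], PredictionReport]:
    """Run tune -> fit -> predict -> report for each feature subset.

    For pairs whose members were also evaluated individually, the report
    carries the relative improvement of the pair over the better of its two
    members: (min single chi - pair chi) / min single chi.
    """
    y_train = dataset.y("train")
    y_test = dataset.y("test")
    reports: dict[tuple[str, ...], PredictionReport] = {}
    for subset in subsets:
        subset = tuple(subset)
        if len(subset) not in (1, 2, 5):
            raise ValueError("feature subsets must have size 1, 2 or 5")
        reports[subset] = fit_evaluate(
            dataset.X(subset, "train"),
            y_train,
            dataset.X(subset, "test"),
            y_test,
            seed=seed,
            tune_subsample=tune_subsample,
            features=subset,
        )
    # annotate pairwise improvement where both singles are available
    for subset, rep in list(reports.items()):
        if len(subset) != 2:
            continue
        singles = [reports.get((f,)) for f in subset]
        if any(s is None for s in singles):
            continue
        best = min(s.chi for s in singles)
        reports[subset] = PredictionReport(
            **{**rep.__dict__, "improvement": (best - rep.chi) / best}
        )
    return reports


def all_subsets() -> list[tuple[str, ...]]:
    """The full evaluation set: 5 singles, 10 pairs, the quintuple."""
    singles = [(f,) for f in FEATURE_NAMES]
    pairs = [tuple(p) for p in combinations(FEATURE_NAMES, 2)]
    return singles + pairs + [tuple(FEATURE_NAMES)]


def mixed_pairs() -> list[tuple[str, ...]]:
    """Pairs of one intensity and one timing feature."""
    return [
        (a, b)
        for a in INTENSITY_FEATURES
        for b in FEATURE_NAMES
        if b not in INTENSITY_FEATURES
    ]
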