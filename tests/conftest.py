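"""Shared fixtures: small plume realizations per profile and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import minimize

from plumeloc import build_cone, detection_probability_map, generate_plume
from plumeloc.regression import _gaussian_kernel, krr_fit
from plumeloc.synthetic import concentrated_config, dilute_config

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    database=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def conc_plume():
    """Concentrated-profile plume: strong intensity decay, flat sparsity."""
    return generate_plume(concentrated_config(seed=101))


@pytest.fixture(scope="session")
def dil_plume():
    """Dilute-profile plume: weak intensity decay, strong sparsity gradient."""
    return generate_plume(dilute_config(seed=202))


@pytest.fixture(scope="session")
def conc_cone(conc_plume):
    return build_cone(detection_probability_map(conc_plume), conc_plume)


@pytest.fixture(scope="session")
def dil_cone(dil_plume):
    return build_cone(detection_probability_map(dil_plume), dil_plume)


def krr_oracle_gap(
    X: np.ndarray,
    y: np.ndarray,
    sigma: float,
    lam: float,
    cond_cap: float = 1e7,
) -> float:
    """Max |c| gap between the closed-form KRR solution and a second-order
    minimizer of the regularized objective.

    The kernel width is halved until the objective Hessian is well
    conditioned, so the minimizer is numerically unique and the comparison
    meaningful.
    """
    n = len(y)
    while True:
        model = krr_fit(X, y, sigma, lam)
        K = _gaussian_kernel(model.X_train, model.X_train, sigma)
        H = (2.0 / n) * K @ K + 2.0 * lam * K
        if np.linalg.cond(H) <= cond_cap:
            break
        sigma *= 0.5

    def obj(c):
        return np.sum((K @ c - y) ** 2) / n + lam * c @ K @ c

    def jac(c):
        return (2.0 / n) * K @ (K @ c - y) + 2.0 * lam * K @ c

    res = minimize(
        obj,
        np.zeros(n),
        jac=jac,
        hess=lambda c: H,
        method="trust-exact",
        options={"gtol": 1e-14, "maxiter": 500},
    )
    return float(np.abs(res.x - model.coef).max())


@pytest.fixture(scope="session")
def oracle_gap():
    return krr_oracle_gap
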