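"""Hierarchical logistic regression: logistic GLMM with hospital intercepts.

Model:  logit p_i = x_i' beta + u_{h(i)},   u_h ~ Normal(0, sigma_u^2).

Fitted by maximizing the Laplace approximation to the marginal
likelihood: for a candidate sigma_u, the joint penalized log-likelihood
is maximized over (beta, u) by Newton's method (the u-block of the
Hessian is diagonal, so each step costs one p x p solve via the Schur
complement), and sigma_u is then profiled with a bounded scalar
optimizer over

    l_L(sigma) = loglik(beta*, u*) - sum_h u_h*^2 / (2 sigma^2)
                 - H/2 log sigma^2 - 1/2 sum_h log D_h,

where D_h = sum_{i in h} p_i (1 - p_i) + 1 / sigma^2 is the u-curvature.
This is the same objective lme4's glmer uses at nAGQ=1.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .base import ConvergenceError, HospitalAssignment, InputError, RiskModel, _check_probabilities

__all__ = ["HLRModel", "fit_hlr"]


RIDGE = 1e-6  # weak Gaussian prior on beta; stabilizes empty feature columns


def _joint_mode(X, y, group, H, sigma, beta, u, max_iter=200, tol=1e-6):
    """Newton maximization of the penalized log-likelihood over (beta, u)."""
    inv_s2 = 1.0 / (sigma * sigma)
    n, p = X.shape
    for _ in range(max_iter):
        eta = X @ beta + u[group]
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-10
        r = y - mu
        g_beta = X.T @ r - RIDGE * beta
        g_u = np.bincount(group, weights=r, minlength=H) - u * inv_s2
        gnorm = max(np.abs(g_beta).max(), np.abs(g_u).max())
        if gnorm < tol:
            break
        Xw = X * w[:, None]
        A = X.T @ Xw + RIDGE * np.eye(p)                # p x p
        D = np.bincount(group, weights=w, minlength=H) + inv_s2
        # B[:, h] = sum_{i in h} w_i x_i  (p x H, built groupwise)
        B = np.zeros((p, H))
        for j in range(p):
            B[j] = np.bincount(group, weights=Xw[:, j], minlength=H)
        S = A - (B / D) @ B.T
        rhs = g_beta - B @ (g_u / D)
        d_beta = np.linalg.solve(S, rhs)
        d_u = (g_u - B.T @ d_beta) / D
        # step-halving on the penalized objective
        step = 1.0
        f0 = _penalized(X, y, group, beta, u, inv_s2)
        for _ in range(30):
            nb, nu = beta + step * d_beta, u + step * d_u
            if _penalized(X, y, group, nb, nu, inv_s2) > f0 - 1e-12:
                beta, u = nb, nu
                break
            step *= 0.5
        else:
            break
    else:
        # stalled iterations with an essentially-zero gradient are fine;
        # only a genuinely unconverged mode is an error
        if gnorm > max(1e3 * tol, 1e-3):
            raise ConvergenceError(
                f"inner Newton did not converge "
                f"(|grad|={gnorm:.3g}, sigma={sigma:.3g})")
    eta = X @ beta + u[group]
    mu = expit(eta)
    w = mu * (1.0 - mu) + 1e-10
    D = np.bincount(group, weights=w, minlength=H) + inv_s2
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, u, D, loglik


def _penalized(X, y, group, beta, u, inv_s2):
    eta = X @ beta + u[group]
    return float(np.sum(y * eta - np.log1p(np.exp(eta)))
                 - 0.5 * inv_s2 * np.sum(u * u)
                 - 0.5 * RIDGE * np.sum(beta * beta))


class HLRModel(RiskModel):
    """Fitted logistic random-intercept model."""

    model_kind = "HLR"
    has_hospital_effect = True

    def __init__(self, beta, sigma_u, u, hospital_index, feature_names=None,
                 add_intercept=True):
        self.beta = np.asarray(beta, dtype=float)
        self.sigma_u = float(sigma_u)
        self.u = np.asarray(u, dtype=float)       # posterior modes, one per hospital
        self.hospital_index = dict(hospital_index)  # hospital_id -> position
        self.feature_names = feature_names
        self.add_intercept = add_intercept

    def hospital_ids(self):
        return list(self.hospital_index)

    def _effect(self, hospital_ids, assignment):
        if assignment == HospitalAssignment.ACTUAL:
            try:
                pos = np.array([self.hospital_index[h] for h in hospital_ids])
            except KeyError as e:  # pragma: no cover - defensive
                raise InputError(f"unknown hospital {e.args[0]!r}") from e
            return self.u[pos]
        if assignment == HospitalAssignment.POPULATION:
            return 0.0
        kind, h = assignment
        if kind != "forced":
            raise InputError(f"unknown hospital assignment {assignment!r}")
        if h not in self.hospital_index:
            raise InputError(f"unknown forced hospital {h!r}")
        return self.u[self.hospital_index[h]]

    def _design(self, X):
        X = np.asarray(X, dtype=float)
        if self.add_intercept:
            X = np.hstack([np.ones((X.shape[0], 1)), X])
        return X

    def predict(self, inputs, assignment=HospitalAssignment.ACTUAL):
        """``inputs`` is (X, hospital_ids) with X in the same column layout
        passed to :func:`fit_hlr` (the intercept is handled internally)."""
        X, hospital_ids = inputs
        eta = self._design(X) @ self.beta + self._effect(hospital_ids, assignment)
        return _check_probabilities(expit(eta))

    def linear_predictor(self, X):
        return self._design(X) @ self.beta


def fit_hlr(X: np.ndarray, hospital_ids, y: np.ndarray,
            sigma_bounds: tuple[float, float] = (1e-3, 3.0),
            fixed_sigma: float | None = None,
            add_intercept: bool = True,
            feature_names=None) -> HLRModel:
    """Fit the hierarchical logistic regression by Laplace approximation.

    X is the fixed-effect design (comorbidity flags + age + sex in the
    pipeline); an intercept column is prepended unless ``add_intercept``
    is False. ``fixed_sigma`` skips the sigma profile (sigma_u is then
    reported as given; useful for the sigma=0 population model).
    """
    X = np.asarray(X, dtype=float)
    if add_intercept:
        X = np.hstack([np.ones((X.shape[0], 1)), X])
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise InputError("outcome is degenerate (single class)")
    hospital_ids = np.asarray(hospital_ids)
    hospitals = np.unique(hospital_ids)
    if hospitals.size < 2 and fixed_sigma is None:
        raise InputError("need at least 2 hospitals to estimate sigma_u")
    index = {h: i for i, h in enumerate(hospitals)}
    group = np.array([index[h] for h in hospital_ids])
    H = hospitals.size

    state = {"beta": np.zeros(X.shape[1]), "u": np.zeros(H)}

    def laplace_neg(log_sigma):
        sigma = float(np.exp(log_sigma))
        beta, u, D, loglik = _joint_mode(X, y, group, H, sigma,
                                         state["beta"].copy(),
                                         state["u"].copy())
        state["beta"], state["u"] = beta, u
        ll = (loglik - 0.5 * np.sum(u * u) / (sigma * sigma)
              - H * np.log(sigma) - 0.5 * np.sum(np.log(D)))
        return -ll

    if fixed_sigma is not None:
        sigma = max(fixed_sigma, sigma_bounds[0])
        beta, u, _, _ = _joint_mode(X, y, group, H, sigma,
                                    state["beta"], state["u"])
        if fixed_sigma == 0.0:
            u = np.zeros(H)
            beta, _, _, _ = _joint_mode(X, y, group, H, 1e-6,
                                        beta, np.zeros(H))
        return HLRModel(beta, fixed_sigma, u, index, feature_names,
                        add_intercept)

    res = minimize_scalar(laplace_neg,
                          bounds=(np.log(sigma_bounds[0]), np.log(sigma_bounds[1])),
                          method="bounded",
                          options={"xatol": 1e-3})
    sigma = float(np.exp(res.x))
    beta, u, _, _ = _joint_mode(X, y, group, H, sigma, state["beta"], state["u"])
    return HLRModel(beta, sigma, u, index, feature_names, add_intercept)
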