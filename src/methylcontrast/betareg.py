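"""Beta-likelihood regression with optional random intercepts.

The observation model is y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi) with
logit(mu_i) = x_i' beta + sum_k u_{k, g_k(i)}, u_k ~ N(0, sigma_k^2 I).

Estimation: the random-effect integral is handled by a Laplace
approximation.  For fixed variance parameters (log sigma_k, log phi) the
joint penalized log-likelihood is maximized over (beta, u) by Fisher-scoring
Newton steps; the marginal log-likelihood is then

    h(beta_hat, u_hat) - sum_k q_k log sigma_k - 0.5 log det H_uu

with H_uu the negative Hessian of the joint in u.  The variance parameters
are optimized in an outer quasi-Newton loop, so the fixed effects are
profiled at the joint mode.  With sigma -> 0 this reduces exactly to
fixed-effect beta-regression maximum likelihood.

Standard errors of the fixed effects are conditional on the estimated
variance parameters (inverse joint-information block), the usual mixed-model
convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .errors import DataError

_LOG_SIGMA_BOUNDS = (-7.0, 3.0)
_LOG_PHI_BOUNDS = (-2.0, 10.0)
_MU_EPS = 1e-10


@dataclasses.dataclass
class GLMMFit:
    """Result of one beta-GLMM fit."""

    coef: np.ndarray          # fixed-effect estimates, logit scale
    se: np.ndarray            # conditional standard errors
    sigma: np.ndarray         # random-intercept SDs, one per grouping factor
    phi: float                # beta precision
    loglik: float             # Laplace marginal log-likelihood
    converged: bool
    n_obs: int
    n_iter: int
    skipped: bool = False
    theta: np.ndarray | None = None  # (log sigma_k, log phi) at the optimum


def _beta_loglik(eta, logy, log1my, phi):
    mu = special.expit(eta)
    np.clip(mu, _MU_EPS, 1.0 - _MU_EPS, out=mu)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * logy
        + (b - 1.0) * log1my
    )
    return ll.sum(), mu, a, b


def _score_weights(mu, a, b, ystar, phi):
    """Score d(ll)/d(eta) plus expected and observed curvature weights.

    Weights are w = -d2(ll)/d(eta)2; the expected version is always
    positive, the observed one subtracts the residual term.
    """
    m = mu * (1.0 - mu)
    resid = ystar - (special.digamma(a) - special.digamma(b))
    score = phi * m * resid
    w_exp = phi * phi * m * m * (special.polygamma(1, a) + special.polygamma(1, b))
    w_obs = w_exp - phi * (1.0 - 2.0 * mu) * m * resid
    return score, w_exp, w_obs


class BetaGLMM:
    """One-probe beta GLMM; reusable across outer-optimizer evaluations.

    Parameters
    ----------
    y : observation vector, strictly inside (0, 1)
    X : n x p fixed-effect design (full column rank)
    group_indices : list of integer arrays coding grouping-factor levels
        (e.g. [slide_index, patient_index]); empty list = pure fixed effects
    """

    def __init__(self, y, X, group_indices=()):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        if y.ndim != 1 or X.shape[0] != y.size:
            raise DataError("y and X have incompatible shapes")
        if y.size and (y.min() <= 0.0 or y.max() >= 1.0):
            raise DataError("responses must lie strictly inside (0, 1); squeeze first")
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.logy = np.log(y)
        self.log1my = np.log1p(-y)
        self.ystar = self.logy - self.log1my
        self.q_sizes = []
        cols = [X]
        for idx in group_indices:
            idx = np.asarray(idx)
            q = int(idx.max()) + 1 if idx.size else 0
            self.q_sizes.append(q)
            Z = np.zeros((self.n, q))
            Z[np.arange(self.n), idx] = 1.0
            cols.append(Z)
        self.q_total = int(sum(self.q_sizes))
        self.A = np.hstack(cols) if len(cols) > 1 else X
        self.n_groups = len(self.q_sizes)
        self._v = None  # warm-start joint mode

    # -- inner loop ---------------------------------------------------------

    def _penalty_diag(self, sigmas):
        d = np.zeros(self.p + self.q_total)
        off = self.p
        for q, s in zip(self.q_sizes, sigmas):
            d[off : off + q] = 1.0 / (s * s)
            off += q
        return d

    def _joint_mode(self, sigmas, phi, v0=None, tol=1e-8, max_iter=60):
        """Maximize the penalized joint log-lik over v = (beta, u)."""
        A = self.A
        pen = self._penalty_diag(sigmas)
        v = np.zeros(self.p + self.q_total) if v0 is None else v0.copy()

        def objective(v):
            eta = A @ v
            ll, mu, a, b = _beta_loglik(eta, self.logy, self.log1my, phi)
            return ll - 0.5 * np.sum(pen * v * v), mu, a, b

        h, mu, a, b = objective(v)
        converged = False
        for _ in range(max_iter):
            score, w_exp, w_obs = _score_weights(mu, a, b, self.ystar, phi)
            grad = A.T @ score - pen * v
            gnorm = np.max(np.abs(grad))
            if gnorm < tol:
                converged = True
                break
            # Fisher scoring (expected information, always PD) far from the
            # optimum; observed-Hessian Newton (quadratic) once close.
            w = w_obs if gnorm < 1.0 else w_exp
            H = A.T @ (w[:, None] * A)
            H[np.diag_indices_from(H)] += pen
            try:
                c = cho_factor(H, lower=True, check_finite=False)
            except LinAlgError:
                H = A.T @ (w_exp[:, None] * A)
                H[np.diag_indices_from(H)] += pen
                c = cho_factor(H, lower=True, check_finite=False)
            step = cho_solve(c, grad, check_finite=False)
            # step-halving line search on the penalized objective
            t = 1.0
            improved = False
            for _ in range(25):
                v_new = v + t * step
                h_new, mu_n, a_n, b_n = objective(v_new)
                if np.isfinite(h_new) and h_new >= h - 1e-12:
                    improved = True
                    break
                t *= 0.5
            if not improved:
                break
            v, h, mu, a, b = v_new, h_new, mu_n, a_n, b_n
        return v, h, mu, a, b, converged

    def _laplace(self, sigmas, phi, v0=None):
        """Profile Laplace marginal log-likelihood at given variance params."""
        v, h, mu, a, b, conv = self._joint_mode(sigmas, phi, v0=v0)
        if self.q_total == 0:
            return h, v, conv
        _, w, _ = _score_weights(mu, a, b, self.ystar, phi)
        Zu = self.A[:, self.p :]
        H_uu = Zu.T @ (w[:, None] * Zu)
        pen = self._penalty_diag(sigmas)[self.p :]
        H_uu[np.diag_indices_from(H_uu)] += pen
        try:
            c = cho_factor(H_uu, lower=True, check_finite=False)
        except LinAlgError:
            return -np.inf, v, False
        logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        logL = h - float(np.sum(self.q_sizes * np.log(np.asarray(sigmas)))) - 0.5 * logdet
        return logL, v, conv

    # -- outer loop ---------------------------------------------------------

    def _fit_fixed_sigmas(self, sigmas: np.ndarray, tol: float, max_iter: int) -> GLMMFit:
        """Profile only phi with the random-intercept SDs pinned."""
        sigmas = np.maximum(sigmas, 1e-6)
        beta0, phi0 = self._start_values()
        v0 = np.zeros(self.p + self.q_total)
        v0[: self.p] = beta0
        self._v = v0
        n_eval = [0]

        def neg(log_phi):
            n_eval[0] += 1
            logL, v, _ = self._laplace(sigmas, float(np.exp(log_phi)), v0=self._v)
            if np.isfinite(logL):
                self._v = v
            return -logL

        res = optimize.minimize_scalar(
            neg, bounds=_LOG_PHI_BOUNDS, method="bounded",
            options={"xatol": 1e-9, "maxiter": max_iter},
        )
        phi = float(np.exp(res.x))
        logL, v, inner_conv = self._laplace(sigmas, phi, v0=self._v)
        self._v = v
        eta = self.A @ v
        _, mu, a, b = _beta_loglik(eta, self.logy, self.log1my, phi)
        _, w_exp, w = _score_weights(mu, a, b, self.ystar, phi)
        if np.min(w) <= 0:
            w = w_exp
        H = self.A.T @ (w[:, None] * self.A)
        H[np.diag_indices_from(H)] += self._penalty_diag(sigmas)
        se = np.full(self.p, np.nan)
        try:
            dg = np.diag(np.linalg.inv(H))[: self.p]
            se = np.sqrt(dg) if np.all(dg > 0) else se
        except np.linalg.LinAlgError:
            pass
        return GLMMFit(
            coef=v[: self.p].copy(), se=se, sigma=sigmas.copy(), phi=phi,
            loglik=float(logL), converged=bool(inner_conv and np.isfinite(logL)),
            n_obs=self.n, n_iter=n_eval[0],
            theta=np.concatenate([np.log(sigmas), [np.log(phi)]]),
        )

    def _start_values(self):
        # logit-linear least squares for beta; moments for phi
        beta0, *_ = np.linalg.lstsq(self.X, self.ystar, rcond=None)
        mu0 = special.expit(self.X @ beta0)
        resid = self.y - mu0
        v = max(float(np.var(resid)), 1e-6)
        phi0 = float(np.clip(np.mean(mu0 * (1.0 - mu0)) / v - 1.0, 2.0, 500.0))
        return beta0, phi0

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 200,
        theta0=None,
        fixed_sigmas=None,
    ) -> GLMMFit:
        """Fit by outer L-BFGS-B over (log sigma_k, log phi).

        ``theta0`` optionally warm-starts the variance parameters (e.g. from
        a nested model's fit).  ``fixed_sigmas`` pins the random-intercept
        SDs (values <= exp(lower bound) collapse to the fixed-effect model)
        so only phi is profiled — the sigma -> 0 limit used for oracle
        comparisons.  ``tol`` is the inner-Newton gradient tolerance.
        """
        if fixed_sigmas is not None:
            return self._fit_fixed_sigmas(np.asarray(fixed_sigmas, float), tol, max_iter)
        min_obs = self.p + self.n_groups + 3
        if self.n < min_obs:
            nan = np.full(self.p, np.nan)
            return GLMMFit(nan, nan.copy(), np.full(self.n_groups, np.nan), np.nan,
                           np.nan, False, self.n, 0, skipped=True)
        beta0, phi0 = self._start_values()
        v0 = np.zeros(self.p + self.q_total)
        v0[: self.p] = beta0
        self._v = v0
        if theta0 is None:
            theta0 = np.concatenate([np.full(self.n_groups, np.log(0.15)), [np.log(phi0)]])
        else:
            theta0 = np.clip(
                np.asarray(theta0, float),
                [b[0] for b in [_LOG_SIGMA_BOUNDS] * self.n_groups + [_LOG_PHI_BOUNDS]],
                [b[1] for b in [_LOG_SIGMA_BOUNDS] * self.n_groups + [_LOG_PHI_BOUNDS]],
            )
        bounds = [_LOG_SIGMA_BOUNDS] * self.n_groups + [_LOG_PHI_BOUNDS]
        n_eval = [0]

        def neg(theta):
            n_eval[0] += 1
            sigmas = np.exp(theta[: self.n_groups])
            phi = float(np.exp(theta[-1]))
            logL, v, _ = self._laplace(sigmas, phi, v0=self._v)
            if np.isfinite(logL):
                self._v = v
            return -logL

        res = optimize.minimize(
            neg,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-9, "gtol": 3e-5},
        )
        sigmas = np.exp(res.x[: self.n_groups])
        phi = float(np.exp(res.x[-1]))
        logL, v, inner_conv = self._laplace(sigmas, phi, v0=self._v)
        self._v = v

        # conditional covariance of the fixed effects at the joint mode
        eta = self.A @ v
        _, mu, a, b = _beta_loglik(eta, self.logy, self.log1my, phi)
        _, w_exp, w = _score_weights(mu, a, b, self.ystar, phi)
        if np.min(w) <= 0:  # fall back to expected information
            w = w_exp
        H = self.A.T @ (w[:, None] * self.A)
        H[np.diag_indices_from(H)] += self._penalty_diag(sigmas)
        se = np.full(self.p, np.nan)
        ok = True
        try:
            cov = np.linalg.inv(H)
            dg = np.diag(cov)[: self.p]
            if np.all(dg > 0):
                se = np.sqrt(dg)
            else:
                ok = False
        except np.linalg.LinAlgError:
            ok = False
        converged = bool(res.success and inner_conv and ok and np.isfinite(logL))
        return GLMMFit(
            coef=v[: self.p].copy(),
            se=se,
            sigma=sigmas,
            phi=phi,
            loglik=float(logL),
            converged=converged,
            n_obs=self.n,
            n_iter=n_eval[0],
            theta=res.x.copy(),
        )


def fit_beta_glmm(y, X, group_indices=(), tol: float = 1e-8, max_iter: int = 200,
                  fixed_sigmas=None) -> GLMMFit:
    """Convenience wrapper: construct a :class:`BetaGLMM` and fit it."""
    return BetaGLMM(y, X, group_indices).fit(
        tol=tol, max_iter=max_iter, fixed_sigmas=fixed_sigmas
    )
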