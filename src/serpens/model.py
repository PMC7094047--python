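"""Latent-Gaussian Poisson time-series model for monthly surveillance counts.

The observation model for monthly counts ``y_t`` in one municipality is

    y_t ~ Poisson(e_t * exp(eta_t)),
    eta_t = beta_0 + x_t' beta + omega_t + delta_t,

where ``e_t`` is an expected-count offset proportional to population (so that
``exp`` of the predictor is a relative risk), ``x_t`` holds mean-centred
climate covariates (rainfall in mm, specific humidity in g/kg, day and night
land-surface temperature in deg C), ``omega`` is a first-order random-walk
(RW1) temporal field with precision ``tau_omega``, and ``delta`` is an iid
Gaussian field with precision ``tau_delta``.  Both latent fields carry
sum-to-zero constraints so the intercept stays identifiable.

Priors: ``beta_0, beta_j ~ N(0, 1000)``; diffuse ``Gamma(1, 5e-5)`` priors on
both precisions (the conventional diffuse log-gamma-on-the-log-precision
default).  All of this is configurable through :class:`ModelSpec`.

Fitting is by a nested Laplace scheme written from first principles:

1. for fixed hyperparameters ``theta = (log tau_omega, log tau_delta)`` the
   latent field conditional is maximised by Newton-Raphson, giving a Gaussian
   approximation ``N(zhat(theta), H(theta)^{-1})``;
2. the Laplace-approximated hyperparameter posterior
   ``pi~(theta | y) ∝ pi(y, zhat, theta) / pi_G(zhat | theta, y)``
   is maximised numerically, a regular grid is laid over ``theta`` scaled by
   the Hessian at the mode, and latent marginals are reported as
   finite Gaussian mixtures over the weighted grid.

The sum-to-zero constraints are imposed exactly by working in an orthonormal
basis of the sum-zero subspace (see :mod:`serpens.gmrf`), under which the
intrinsic RW1 prior becomes a proper full-rank Gaussian.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .gmrf import rw1_structure, sum_to_zero_basis

__all__ = [
    "ModelSpec",
    "LatentField",
    "HyperParams",
    "RW1PoissonModel",
    "ConvergenceError",
    "compute_offset",
    "log_joint",
]


class ConvergenceError(RuntimeError):
    """Newton or mode-search failure; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: covariates, priors, latent components, constraints.

    Parameters
    ----------
    covariates
        Names of the covariate columns entering the linear predictor.
    beta_prior_variance
        Prior variance of the intercept and each coefficient (default 1000,
        i.e. N(0, 1000) read as variance).
    tau_prior_shape, tau_prior_rate
        Gamma prior on each precision (default Gamma(1, 5e-5), the diffuse
        convention).
    include_trend, include_iid
        Switch the RW1 field ``omega`` and the iid field ``delta`` on or off.
    """

    covariates: tuple = ("rainfall", "humidity", "lstd", "lstn")
    beta_prior_variance: float = 1000.0
    tau_prior_shape: float = 1.0
    tau_prior_rate: float = 5e-5
    include_trend: bool = True
    include_iid: bool = True

    def __post_init__(self):
        if self.beta_prior_variance <= 0:
            raise ValueError("beta prior variance must be positive")
        if self.tau_prior_shape <= 0 or self.tau_prior_rate <= 0:
            raise ValueError("Gamma prior shape and rate must be positive")


@dataclass
class LatentField:
    """Latent components on the natural scale: intercept, betas, fields."""

    beta0: float
    beta: np.ndarray
    omega: np.ndarray
    delta: np.ndarray

    def validate(self, atol: float = 1e-8) -> None:
        if self.omega.size and abs(self.omega.sum()) > atol * max(1, self.omega.size):
            raise ValueError("omega must sum to zero")
        if self.delta.size and abs(self.delta.sum()) > atol * max(1, self.delta.size):
            raise ValueError("delta must sum to zero")


@dataclass
class HyperParams:
    """Precisions of the RW1 and iid latent fields."""

    tau_omega: float
    tau_delta: float

    def __post_init__(self):
        if self.tau_omega <= 0 or self.tau_delta <= 0:
            raise ValueError("precisions must be strictly positive")


def compute_offset(y: np.ndarray, pop: np.ndarray) -> np.ndarray:
    """Expected-count offset ``e_t = pop_t * (sum y / sum pop)``.

    Conserves the total: ``sum(e) == sum(y)`` up to float rounding, so the
    fitted intercept measures departure from the overall mean rate and
    ``exp`` of the predictor is a relative risk.
    """
    y = np.asarray(y, dtype=float)
    pop = np.asarray(pop, dtype=float)
    if y.shape != pop.shape:
        raise ValueError("y and pop must have the same length")
    if np.any(pop <= 0):
        raise ValueError("populations must be strictly positive")
    if y.sum() == 0:
        raise ValueError("all counts are zero: overall rate undefined")
    return pop * (y.sum() / pop.sum())


def _gamma_logpdf_unnorm(tau: float, shape: float, rate: float) -> float:
    return (shape - 1.0) * np.log(tau) - rate * tau


def log_joint(
    latent: LatentField,
    hyper: HyperParams,
    y: np.ndarray,
    e: np.ndarray,
    X: np.ndarray | None,
    spec: ModelSpec,
) -> float:
    """Log joint density of (y, latent, hyper) up to additive constants.

    Includes the Poisson log-likelihood (dropping log y!), Gaussian log-priors
    on the intercept and coefficients, the rank-corrected RW1 prior
    ``((T-1)/2) log tau_w - (tau_w/2) omega' Q omega`` (dropping the constant
    generalised log-determinant of Q), the sum-to-zero iid prior with rank
    T-1, and the Gamma log-priors on both precisions.
    """
    y = np.asarray(y, dtype=float)
    e = np.asarray(e, dtype=float)
    T = y.size
    eta = latent.beta0 + latent.omega + latent.delta
    if X is not None and latent.beta.size:
        eta = eta + X @ latent.beta
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor (check covariates)")
    lp = float(y @ eta - e @ np.exp(eta))

    V = spec.beta_prior_variance
    k = 1 + latent.beta.size
    lp += -0.5 * (latent.beta0**2 + latent.beta @ latent.beta) / V
    lp += -0.5 * k * np.log(2 * np.pi * V)

    Q = rw1_structure(T)
    if spec.include_trend:
        quad = latent.omega @ Q @ latent.omega
        lp += 0.5 * (T - 1) * np.log(hyper.tau_omega / (2 * np.pi)) - 0.5 * hyper.tau_omega * quad
        lp += _gamma_logpdf_unnorm(hyper.tau_omega, spec.tau_prior_shape, spec.tau_prior_rate)
    if spec.include_iid:
        quad = latent.delta @ latent.delta
        lp += 0.5 * (T - 1) * np.log(hyper.tau_delta / (2 * np.pi)) - 0.5 * hyper.tau_delta * quad
        lp += _gamma_logpdf_unnorm(hyper.tau_delta, spec.tau_prior_shape, spec.tau_prior_rate)
    return lp


class RW1PoissonModel:
    """Bayesian Poisson count model with covariates, RW1 trend and iid noise.

    Parameters
    ----------
    y : array of shape (T,)
        Monthly counts.
    X : array of shape (T, p) or None
        Covariate matrix.  Columns should be mean-centred so that the
        intercept is the log relative rate at average climate;
        :meth:`from_series` does this automatically.
    exposure : array of shape (T,)
        Expected-count offset ``e_t`` (strictly positive).
    spec : ModelSpec
    covariate_names : sequence of str, optional
    index : sequence, optional
        Month labels (e.g. pandas PeriodIndex) used in output tables.
    """

    def __init__(self, y, X=None, exposure=None, spec: ModelSpec | None = None,
                 covariate_names: Sequence[str] | None = None, index=None):
        self.y = np.asarray(y, dtype=float)
        self.T = self.y.size
        if self.T < 3:
            raise ValueError("need at least T=3 months")
        if np.any(self.y < 0) or np.any(self.y != np.round(self.y)):
            raise ValueError("counts must be non-negative integers")
        if X is None:
            self.X = np.zeros((self.T, 0))
        else:
            self.X = np.atleast_2d(np.asarray(X, dtype=float))
            if self.X.shape[0] != self.T:
                raise ValueError("X must have one row per month")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite covariate values")
        if exposure is None:
            raise ValueError("exposure (expected counts e_t) is required")
        self.e = np.asarray(exposure, dtype=float)
        if self.e.shape != self.y.shape or np.any(self.e <= 0):
            raise ValueError("exposure must be positive, one value per month")
        self.p = self.X.shape[1]
        self.spec = spec if spec is not None else ModelSpec(
            covariates=tuple(covariate_names) if covariate_names else ())
        if covariate_names is None:
            covariate_names = list(self.spec.covariates)[: self.p]
        if len(covariate_names) != self.p:
            raise ValueError("covariate_names length must match X columns")
        self.covariate_names = list(covariate_names)
        self.index = list(index) if index is not None else list(range(1, self.T + 1))

        # latent layout: [beta0, beta_1..p, u (T-1), v (T-1)]
        self._q = 1 + self.p
        T = self.T
        self._B = sum_to_zero_basis(T)
        self._Q = rw1_structure(T)
        self._Ru = self._B.T @ self._Q @ self._B  # full-rank RW1 precision in basis coords
        sgn, self._logdet_Ru = np.linalg.slogdet(self._Ru)
        blocks = [np.ones((T, 1)), self.X]
        self._slices = {"fixed": slice(0, self._q)}
        pos = self._q
        if self.spec.include_trend:
            blocks.append(self._B)
            self._slices["u"] = slice(pos, pos + T - 1)
            pos += T - 1
        if self.spec.include_iid:
            blocks.append(self._B)
            self._slices["v"] = slice(pos, pos + T - 1)
            pos += T - 1
        self._n = pos
        self._A = np.hstack(blocks)
        self.centering_constants: dict[str, float] = {}

    # ------------------------------------------------------------------
    @classmethod
    def from_series(cls, series: pd.DataFrame, covariates: Sequence[str] | None = None,
                    spec: ModelSpec | None = None):
        """Build a model from a per-city monthly series table.

        ``series`` must have columns ``y`` (counts) and ``pop`` plus the
        covariate columns; covariates are mean-centred here (constants kept in
        ``centering_constants`` for back-transforming the intercept) and the
        offset is computed as ``e_t = pop_t * sum(y)/sum(pop)``.
        """
        from .climate import center_covariates

        if spec is None:
            spec = ModelSpec()
        if covariates is None:
            covariates = [c for c in spec.covariates if c in series.columns]
        centred, constants = center_covariates(series, covariates)
        e = compute_offset(series["y"].to_numpy(), series["pop"].to_numpy())
        index = series["period"] if "period" in series.columns else None
        m = cls(series["y"].to_numpy(), centred[list(covariates)].to_numpy(), e,
                spec=spec, covariate_names=list(covariates),
                index=None if index is None else list(index))
        m.centering_constants = constants
        return m

    # ------------------------------------------------------------------
    # internals: penalised log-likelihood, prior precision, Newton mode
    def _prior_precision(self, tau_w: float | None, tau_d: float | None) -> np.ndarray:
        P0 = np.zeros((self._n, self._n))
        prec_b = 1.0 / self.spec.beta_prior_variance
        idx = np.arange(self._q)
        P0[idx, idx] = prec_b
        if "u" in self._slices:
            s = self._slices["u"]
            P0[s, s] = tau_w * self._Ru
        if "v" in self._slices:
            s = self._slices["v"]
            d = np.arange(s.start, s.stop)
            P0[d, d] = tau_d
        return P0

    def _logdet_P0(self, tau_w, tau_d) -> float:
        out = -self._q * np.log(self.spec.beta_prior_variance)
        if "u" in self._slices:
            out += (self.T - 1) * np.log(tau_w) + self._logdet_Ru
        if "v" in self._slices:
            out += (self.T - 1) * np.log(tau_d)
        return out

    def _pll(self, z: np.ndarray, P0: np.ndarray) -> float:
        eta = self._A @ z
        if np.max(eta) > 500:  # exp overflow guard; rejected by line search
            return -np.inf
        return float(self.y @ eta - self.e @ np.exp(eta) - 0.5 * z @ P0 @ z)

    def _newton_mode(self, P0: np.ndarray, z0: np.ndarray | None = None,
                     tol: float = 1e-8, maxiter: int = 50):
        """Newton-Raphson maximisation of the latent conditional posterior.

        Returns ``(zhat, cho_factor(H), n_iter)`` where H is the negative
        Hessian at the mode.  Uses step-halving when a full step does not
        improve the objective.
        """
        A, y, e = self._A, self.y, self.e
        z = np.zeros(self._n) if z0 is None else z0.copy()
        f = self._pll(z, P0)
        if not np.isfinite(f):
            z = np.zeros(self._n)
            f = self._pll(z, P0)
        trace = []
        for it in range(maxiter):
            eta = A @ z
            m = e * np.exp(eta)
            grad = A.T @ (y - m) - P0 @ z
            H = (A.T * m) @ A + P0
            cho = cho_factor(H, lower=True)
            dz = cho_solve(cho, grad)
            step = 1.0
            znew = z + dz
            fnew = self._pll(znew, P0)
            while (not np.isfinite(fnew) or fnew < f - 1e-12) and step > 1e-6:
                step *= 0.5
                znew = z + step * dz
                fnew = self._pll(znew, P0)
            delta = float(np.max(np.abs(step * dz)))
            trace.append((it, f, delta))
            z, f = znew, fnew
            if delta < tol:
                # refresh Hessian factor at the final iterate
                m = e * np.exp(A @ z)
                H = (A.T * m) @ A + P0
                return z, cho_factor(H, lower=True), it + 1
            if not np.isfinite(f):
                break
        raise ConvergenceError(
            f"Newton did not converge in {maxiter} iterations", trace)

    # ------------------------------------------------------------------
    def _theta_components(self):
        comps = []
        if self.spec.include_trend:
            comps.append("tau_omega")
        if self.spec.include_iid:
            comps.append("tau_delta")
        return comps

    def _taus_from_theta(self, theta: np.ndarray):
        comps = self._theta_components()
        tau_w = tau_d = None
        i = 0
        if "tau_omega" in comps:
            tau_w = float(np.exp(theta[i])); i += 1
        if "tau_delta" in comps:
            tau_d = float(np.exp(theta[i])); i += 1
        return tau_w, tau_d

    def _log_post_theta(self, theta: np.ndarray, warm: dict,
                        tol: float = 1e-8, maxiter: int = 50):
        """Laplace-approximated log posterior of theta, up to a constant.

        ``log pi~(theta|y) = pll(zhat) + 0.5 log|P0| - 0.5 log|H| + log prior(theta)``
        with the log-Jacobian of the log-precision parametrisation included.
        """
        tau_w, tau_d = self._taus_from_theta(theta)
        P0 = self._prior_precision(tau_w, tau_d)
        z, cho, nit = self._newton_mode(P0, warm.get("z"), tol=tol, maxiter=maxiter)
        warm["z"] = z
        warm["iters"] = warm.get("iters", 0) + nit
        logdet_H = 2.0 * np.sum(np.log(np.diag(cho[0])))
        lp = self._pll(z, P0) + 0.5 * self._logdet_P0(tau_w, tau_d) - 0.5 * logdet_H
        a, b = self.spec.tau_prior_shape, self.spec.tau_prior_rate
        for tau in (tau_w, tau_d):
            if tau is not None:
                lp += _gamma_logpdf_unnorm(tau, a, b) + np.log(tau)  # + Jacobian
        return lp, z, cho

    # ------------------------------------------------------------------
    def fit(self, grid_size: int = 9, grid_span: float = 3.0,
            newton_tol: float = 1e-8, newton_maxiter: int = 50,
            theta_start: Sequence[float] | None = None,
            hessian_step: float = 0.1, compute_trend: bool = True):
        """Fit by the nested Laplace scheme; returns :class:`LaplaceResults`.

        Parameters
        ----------
        grid_size
            Points per hyperparameter axis (default 9; 1 collapses to the
            empirical-Bayes fit at the hyper mode).
        grid_span
            Half-width of the grid in posterior standard deviations of theta.
        compute_trend
            If False, skip the (more expensive) temporal-field marginals and
            report coefficients only.
        """
        from .results import LaplaceResults

        comps = self._theta_components()
        nh = len(comps)
        warm: dict = {}

        if nh == 0:
            P0 = self._prior_precision(None, None)
            z, cho, nit = self._newton_mode(P0, tol=newton_tol, maxiter=newton_maxiter)
            thetas = np.zeros((1, 0))
            lps = np.zeros(1)
            modes, chos = [z], [cho]
            theta_mode = np.zeros(0)
            diagnostics = {"newton_iterations": nit, "hyper_mode": {},
                           "grid_points": 1, "boundary_mode": False}
        else:
            x0 = np.full(nh, np.log(100.0)) if theta_start is None else np.asarray(theta_start, float)

            def nlp(th):
                try:
                    lp, _, _ = self._log_post_theta(th, warm, tol=newton_tol,
                                                    maxiter=newton_maxiter)
                except ConvergenceError:
                    return np.inf
                return -lp

            res = minimize(nlp, x0, method="Nelder-Mead",
                           options={"xatol": 2e-2, "fatol": 1e-3, "maxiter": 400})
            if not np.isfinite(res.fun):
                raise ConvergenceError("hyperparameter mode search failed", [res])
            theta_mode = res.x
            # finite-difference Hessian of -log pi~ at the mode
            h = hessian_step
            H = np.zeros((nh, nh))
            f0 = res.fun
            for i in range(nh):
                ei = np.zeros(nh); ei[i] = h
                fpp = nlp(theta_mode + ei)
                fmm = nlp(theta_mode - ei)
                H[i, i] = (fpp - 2 * f0 + fmm) / h**2
                for j in range(i + 1, nh):
                    ej = np.zeros(nh); ej[j] = h
                    fab = nlp(theta_mode + ei + ej)
                    fa_b = nlp(theta_mode + ei - ej)
                    f_ab = nlp(theta_mode - ei + ej)
                    f_a_b = nlp(theta_mode - ei - ej)
                    H[i, j] = H[j, i] = (fab - fa_b - f_ab + f_a_b) / (4 * h**2)
            evals, evecs = np.linalg.eigh(H)
            if np.any(evals <= 0):  # fall back to a conservative spherical scale
                evals = np.maximum(evals, 1.0)
            sds = 1.0 / np.sqrt(evals)
            zs = np.linspace(-grid_span, grid_span, grid_size) if grid_size > 1 else np.zeros(1)
            mesh = np.meshgrid(*([zs] * nh), indexing="ij")
            zpts = np.stack([m.ravel() for m in mesh], axis=1)  # (K, nh)
            thetas = theta_mode + (zpts * sds) @ evecs.T
            lps = np.empty(len(thetas))
            modes, chos = [], []
            for k, th in enumerate(thetas):
                lp, z, cho = self._log_post_theta(th, warm, tol=newton_tol,
                                                  maxiter=newton_maxiter)
                lps[k] = lp
                modes.append(z)
                chos.append(cho)
            on_edge = np.any(np.abs(zpts[np.argmax(lps)]) >= grid_span - 1e-9) and grid_size > 1
            diagnostics = {
                "newton_iterations": warm.get("iters", 0),
                "hyper_mode": dict(zip(comps, np.exp(theta_mode))),
                "grid_points": len(thetas),
                "boundary_mode": bool(on_edge),
            }

        w = np.exp(lps - lps.max())
        w /= w.sum()
        # log marginal likelihood up to a constant (grid Riemann sum)
        if nh > 0 and grid_size > 1:
            step_vol = float(np.prod(sds * (2 * grid_span / (grid_size - 1))))
            diagnostics["log_mlik"] = float(
                lps.max() + np.log(np.sum(np.exp(lps - lps.max()))) + np.log(step_vol))
        else:
            diagnostics["log_mlik"] = float(lps.max())

        # per-grid-point marginal means/sds for fixed effects and fields
        K = len(modes)
        q = self._q
        fixed_mu = np.array([m[:q] for m in modes])            # (K, q)
        fixed_sd = np.empty((K, q))
        Eq = np.zeros((self._n, q))
        Eq[:q, :q] = np.eye(q)
        for k in range(K):
            cols = cho_solve(chos[k], Eq)
            fixed_sd[k] = np.sqrt(np.diag(cols[:q]))
        omega_mu = omega_sd = delta_mu = delta_sd = omdel_cov = None
        B = self._B
        has_u = compute_trend and "u" in self._slices
        has_v = compute_trend and "v" in self._slices
        if has_u:
            su = self._slices["u"]
            omega_mu = np.array([B @ m[su] for m in modes])    # (K, T)
            omega_sd = np.empty((K, self.T))
        if has_v:
            sv = self._slices["v"]
            delta_mu = np.array([B @ m[sv] for m in modes])
            delta_sd = np.empty((K, self.T))
        if has_u and has_v:
            omdel_cov = np.empty((K, self.T))
        if has_u or has_v:
            Tm1 = self.T - 1
            for k in range(K):
                if has_u:
                    Eu = np.zeros((self._n, Tm1))
                    Eu[su, :] = np.eye(Tm1)
                    cols_u = cho_solve(chos[k], Eu)            # Sigma[:, u-block]
                    Suu = cols_u[su]
                    omega_sd[k] = np.sqrt(np.einsum("ij,jk,ik->i", B, Suu, B))
                    if has_v:
                        Suv = cols_u[sv].T                     # (T-1, T-1) cov(u, v)
                        omdel_cov[k] = np.einsum("ij,jk,ik->i", B, Suv, B)
                if has_v:
                    Ev = np.zeros((self._n, Tm1))
                    Ev[sv, :] = np.eye(Tm1)
                    Svv = cho_solve(chos[k], Ev)[sv]
                    delta_sd[k] = np.sqrt(np.einsum("ij,jk,ik->i", B, Svv, B))

        return LaplaceResults(
            model=self, weights=w, thetas=thetas, theta_names=comps,
            fixed_mu=fixed_mu, fixed_sd=fixed_sd,
            omega_mu=omega_mu, omega_sd=omega_sd,
            delta_mu=delta_mu, delta_sd=delta_sd,
            omdel_cov=omdel_cov,
            diagnostics=diagnostics,
        )

    # ------------------------------------------------------------------
    def fit_mcmc(self, n_iter: int = 20000, n_burn: int = 5000, seed: int = 0,
                 thin_fields: int = 10, tune: bool = True):
        """Metropolis-within-Gibbs sampling of the identical posterior.

        Independent of the Laplace machinery; see :mod:`serpens.mcmc`.
        Returns :class:`serpens.results.MCMCResults`.
        """
        from .mcmc import run_chain

        return run_chain(self, n_iter=n_iter, n_burn=n_burn, seed=seed,
                         thin_fields=thin_fields, tune=tune)
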