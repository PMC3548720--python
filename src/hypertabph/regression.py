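"""Proportional-hazards regression with parametric baselines.

The model is h(t|x, θ) = h0(t)·g(x|θ) with relative risk
g(x|θ) = exp(Σ_k θ_k x_k) and survival S(t|x, θ) = S0(t)^g(x|θ).
The baseline h0/S0 comes from one of the families in
:mod:`hypertabph.families` (hypertabastic, Weibull, log-logistic).

Estimation maximises the right-censored log-likelihood

    ℓ = Σ_i δ_i [ln h0(t_i) + x_i'θ] + g(x_i|θ) · ln S0(t_i),

where δ_i is the event indicator, over the baseline parameters (on the
log scale, enforcing positivity) and θ jointly, by quasi-Newton iteration
from several deterministic starts. Standard errors come from the inverse
of the negative finite-difference Hessian at the optimum (observed
information), mapped to the natural parameter scale by the delta method.
Per-parameter Wald statistics (estimate/SE)² are referred to a χ²(1)
upper tail; hazard ratios are exp(θ_k).

The primary surface is :class:`ParametricPH`, a scikit-learn style
estimator; :func:`fit_ph` is a convenience wrapper returning a
:class:`FitResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .families import BaselineFamily, get_family

__all__ = [
    "SurvivalData",
    "PHModelSpec",
    "FitResult",
    "ParametricPH",
    "fit_ph",
    "log_likelihood",
    "relative_risk",
    "ph_survival",
    "ph_hazard",
    "wald_statistic",
    "wald_p",
    "hazard_ratio",
    "aic",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SurvivalData:
    """Right-censored survival sample.

    Attributes
    ----------
    time : ndarray of float
        Follow-up times in years, strictly positive.
    event : ndarray of int
        1 for an observed event, 0 for right censoring.
    covariates : pandas.DataFrame
        One named column per covariate, one row per subject, no missing
        values. May have zero columns.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.ndim != 1:
            raise ValueError("time must be one-dimensional")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("all follow-up times must be positive and finite")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        self.event = self.event.astype(int)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(self.covariates)
        if len(self.covariates) != len(self.time) or len(self.event) != len(self.time):
            raise ValueError("time, event and covariates must have equal length")
        if self.covariates.isna().any().any():
            raise ValueError("covariates must not contain missing values")
        if self.covariates.columns.duplicated().any():
            raise ValueError("covariate names must be unique")

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.covariates.columns]

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def X(self, names: Sequence[str] | None = None) -> np.ndarray:
        cols = self.names if names is None else list(names)
        return self.covariates[cols].to_numpy(dtype=float)

    def subset(self, names: Sequence[str]) -> "SurvivalData":
        return SurvivalData(self.time, self.event, self.covariates[list(names)])


@dataclass(frozen=True)
class PHModelSpec:
    """A fully specified proportional-hazards model.

    ``coefficients`` maps covariate names to θ_k; ``baseline_params`` are
    the two positive baseline parameters of ``family``.
    """

    family: str
    baseline_params: tuple[float, float]
    coefficients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        get_family(self.family)  # validates the name
        a, b = self.baseline_params
        if not (a > 0 and b > 0):
            raise ValueError("baseline parameters must be positive")
        object.__setattr__(self, "baseline_params", (float(a), float(b)))
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    @property
    def names(self) -> list[str]:
        return list(self.coefficients)

    def _family(self) -> BaselineFamily:
        return get_family(self.family)

    def profile_vector(self, profile: Mapping[str, float]) -> np.ndarray:
        try:
            return np.array([float(profile[k]) for k in self.coefficients])
        except KeyError as err:
            raise KeyError(f"profile is missing covariate {err.args[0]!r}") from None

    def linear_predictor(self, profile: Mapping[str, float]) -> float:
        theta = np.array(list(self.coefficients.values()))
        return float(self.profile_vector(profile) @ theta)

    def relative_risk(self, profile: Mapping[str, float]) -> float:
        return float(np.exp(self.linear_predictor(profile)))

    def log_base_sf(self, t):
        return self._family().log_sf(np.asarray(t, dtype=float), self.baseline_params)

    def base_hazard(self, t):
        return self._family().hazard(t, self.baseline_params)

    def survival(self, t, profile: Mapping[str, float]):
        g = self.relative_risk(profile)
        return np.exp(g * self.log_base_sf(t))

    def hazard(self, t, profile: Mapping[str, float]):
        return self.relative_risk(profile) * self.base_hazard(t)


@dataclass
class FitResult:
    """Maximum-likelihood fit of a parametric PH model.

    ``param_names`` lists baseline parameters first, then covariates, and
    all vector fields (``estimates``, ``se`` …) follow that order.
    ``hazard_ratio`` covers the covariates only.
    """

    spec: PHModelSpec
    param_names: list[str]
    estimates: np.ndarray
    loglik: float
    covariance: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    p_value: np.ndarray
    hazard_ratio: np.ndarray
    converged: bool
    n_iter: int
    n_params: int
    status: str = "ok"

    @property
    def minus_two_loglik(self) -> float:
        return -2.0 * self.loglik

    @property
    def aic(self) -> float:
        return self.minus_two_loglik + 2.0 * self.n_params

    def summary(self) -> pd.DataFrame:
        """Table-style summary: estimate, SE, Wald, p, hazard ratio."""
        k = len(self.param_names) - len(self.hazard_ratio)
        hr = np.concatenate([np.full(k, np.nan), self.hazard_ratio])
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "se": self.se,
                "wald": self.wald,
                "p_value": self.p_value,
                "hazard_ratio": hr,
            },
            index=self.param_names,
        )

    def to_dict(self) -> dict:
        """JSON-serialisable report mirroring all fields."""
        return {
            "family": self.spec.family,
            "baseline_params": {
                n: v
                for n, v in zip(
                    get_family(self.spec.family).param_names, self.spec.baseline_params
                )
            },
            "coefficients": dict(self.spec.coefficients),
            "param_names": list(self.param_names),
            "estimates": self.estimates.tolist(),
            "se": self.se.tolist(),
            "wald": self.wald.tolist(),
            "p_value": self.p_value.tolist(),
            "hazard_ratio": self.hazard_ratio.tolist(),
            "covariance": self.covariance.tolist(),
            "loglik": self.loglik,
            "minus_two_loglik": self.minus_two_loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "status": self.status,
        }


# ---------------------------------------------------------------------------
# closed-form pieces


def relative_risk(x, theta) -> float:
    """g(x|θ) = exp(Σ_k θ_k x_k)."""
    x = np.asarray(x, dtype=float)
    th = np.asarray(theta, dtype=float)
    if x.shape[-1] != th.shape[0]:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[-1]} entries, theta has {th.shape[0]}"
        )
    return np.exp(x @ th)


def ph_survival(t, x, spec: PHModelSpec):
    """S(t|x, θ) = S0(t)^g(x|θ)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    g = relative_risk(x, list(spec.coefficients.values()))
    return np.exp(g * spec.log_base_sf(t))


def ph_hazard(t, x, spec: PHModelSpec):
    """h(t|x, θ) = h0(t)·g(x|θ)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be strictly positive")
    g = relative_risk(x, list(spec.coefficients.values()))
    return g * spec.base_hazard(t)


def log_likelihood(data: SurvivalData, spec: PHModelSpec) -> float:
    """Right-censored log-likelihood of ``spec`` on ``data``.

    ℓ = Σ_i δ_i [ln h0(t_i) + x_i'θ] + exp(x_i'θ)·ln S0(t_i). Log-space
    baseline quantities keep the sum finite deep into the tails; a
    non-finite value signals an invalid parameter region and is returned
    as is (never clamped).
    """
    fam = get_family(spec.family)
    X = data.X(spec.names)
    theta = np.array(list(spec.coefficients.values()))
    eta = X @ theta if theta.size else np.zeros(data.n)
    lsf = fam.log_sf(data.time, spec.baseline_params)
    lh = fam.log_hazard(data.time, spec.baseline_params)
    d = data.event
    return float(np.sum(d * (lh + eta)) + np.sum(np.exp(eta) * lsf))


def wald_statistic(estimate: float, se: float) -> float:
    """Wald χ² statistic (estimate/SE)²."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    return (estimate / se) ** 2


def wald_p(w: float) -> float:
    """Upper-tail χ²(1) probability of a Wald statistic."""
    if w < 0:
        raise ValueError("Wald statistic must be non-negative")
    return float(stats.chi2.sf(w, df=1))


def hazard_ratio(estimate: float) -> float:
    """exp(θ_k): multiplicative hazard effect of a unit covariate change."""
    return float(np.exp(estimate))


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion −2ℓ + 2k (smaller is better)."""
    if n_params < 1:
        raise ValueError("n_params must be at least 1")
    return -2.0 * loglik + 2.0 * n_params


# ---------------------------------------------------------------------------
# numerical machinery


def numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of scalar ``f`` at ``x``."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _unpack_y(y):
    """Accept (time, event) in the common encodings.

    Supported: a structured array with event/time fields (scikit-survival
    convention), a DataFrame with 'time' and 'event' columns, a 2-column
    array ordered (time, event), a (time, event) tuple, or SurvivalData.
    """
    if isinstance(y, SurvivalData):
        return y.time, y.event
    if isinstance(y, pd.DataFrame):
        return np.asarray(y["time"], dtype=float), np.asarray(y["event"])
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        tname = next((n for n in names if "time" in n.lower()), None)
        ename = next(
            (n for n in names if n != tname), None
        )
        if tname is None or ename is None:
            raise ValueError("structured y must carry a time field and an event field")
        return np.asarray(y[tname], dtype=float), np.asarray(y[ename]).astype(int)
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return np.asarray(y[0], dtype=float), np.asarray(y[1])
    y = np.asarray(y)
    if y.ndim == 2 and y.shape[1] == 2:
        return y[:, 0].astype(float), y[:, 1]
    raise ValueError("could not interpret y as right-censored survival outcomes")


_START_PERTURBATIONS = (
    (0.0, 0.0),
    (0.7, 0.0),
    (-0.7, 0.0),
    (0.0, 0.7),
    (0.0, -0.7),
)


class ParametricPH(BaseEstimator):
    """Parametric proportional-hazards regression (scikit-learn API).

    Parameters
    ----------
    family : {"hypertabastic", "weibull", "loglogistic"}, default "hypertabastic"
        Baseline hazard family.
    n_starts : int, default 5
        Number of deterministic optimiser starts (perturbations of a
        moment-based baseline guess).
    max_iter : int, default 500
        Iteration cap per start.
    gtol : float, default 1e-6
        Gradient-norm convergence criterion.
    ftol : float, default 1e-10
        Relative log-likelihood change convergence criterion.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Covariate coefficients θ at the MLE.
    baseline_params_ : tuple of float
        Fitted baseline parameters (α, β for the hypertabastic family).
    se_, wald_, p_values_ : ndarray over (baseline params + covariates)
        Delta-method standard errors, Wald statistics and χ²(1) p-values.
    hazard_ratios_ : ndarray of shape (n_features,)
        exp(θ) per covariate.
    covariance_ : ndarray
        Parameter covariance on the natural scale.
    log_likelihood_, aic_ : float
    converged_ : bool
    n_iter_ : int
    feature_names_in_ : ndarray of str, when X carries names.

    Notes
    -----
    ``fit(X, y)`` accepts y as a structured (event, time) array, a
    (time, event) tuple, a 2-column (time, event) array, or a DataFrame
    with those columns. ``predict`` returns the linear predictor x'θ
    (a risk score, higher = shorter survival), so the estimator can slot
    into sklearn model selection with concordance-style scorers.
    """

    def __init__(
        self,
        family: str = "hypertabastic",
        n_starts: int = 5,
        max_iter: int = 500,
        gtol: float = 1e-6,
        ftol: float = 1e-10,
    ):
        self.family = family
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.gtol = gtol
        self.ftol = ftol

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        fam = get_family(self.family)
        time, event = _unpack_y(y)
        event = np.asarray(event)
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        event = event.astype(float)
        if np.any(time <= 0) or np.any(~np.isfinite(time)):
            raise ValueError("all times must be positive and finite")

        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X.reshape(-1, 1)
        n, p = X.shape
        if n != time.size:
            raise ValueError("X and y have inconsistent lengths")
        if n < 10:
            raise ValueError("need at least 10 subjects to fit")
        if event.sum() < 1:
            raise ValueError("need at least one observed event to fit")
        if p:
            if np.any(np.ptp(X, axis=0) == 0):
                raise ValueError("constant covariate column in design")
            if np.linalg.matrix_rank(X) < p:
                raise ValueError("collinear covariates: design matrix is rank deficient")
        self.n_features_in_ = p

        def negll(psi):
            params = np.exp(psi[:2])
            theta = psi[2:]
            eta = X @ theta if p else np.zeros(n)
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                val = np.sum(event * (fam.log_hazard(time, params) + eta)) + np.sum(
                    np.exp(eta) * fam.log_sf(time, params)
                )
            if not np.isfinite(val):
                return 1e10
            return -val

        b0 = np.log(fam.init_params(time, event))
        bounds = [(-20.0, 20.0)] * 2 + [(-50.0, 50.0)] * p
        best = None
        for d1, d2 in _START_PERTURBATIONS[: max(1, int(self.n_starts))]:
            psi0 = np.concatenate([[b0[0] + d1, b0[1] + d2], np.zeros(p)])
            res = optimize.minimize(
                negll,
                psi0,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": int(self.max_iter),
                    "gtol": self.gtol,
                    "ftol": self.ftol,
                },
            )
            if best is None or res.fun < best.fun:
                best = res
        psi = best.x
        self.converged_ = bool(best.success) and best.fun < 1e9
        self.n_iter_ = int(best.nit)
        self.log_likelihood_ = -float(best.fun)

        baseline = tuple(np.exp(psi[:2]))
        theta = psi[2:].copy()
        self.baseline_params_ = baseline
        self.coef_ = theta
        names = self._param_names(fam)

        # observed information on the unconstrained scale, delta method to
        # the natural (reporting) scale
        self.status_ = "ok" if self.converged_ else "did not converge"
        H = numeric_hessian(lambda q: -negll(q), psi)
        jac = np.ones(2 + p)
        jac[:2] = baseline
        try:
            cov_psi = np.linalg.inv(-H)
            cov = jac[:, None] * cov_psi * jac[None, :]
            var = np.diag(cov).copy()
            if np.any(var < 0):
                raise np.linalg.LinAlgError("negative variance")
            self.covariance_ = cov
            self.se_ = np.sqrt(var)
        except np.linalg.LinAlgError:
            self.covariance_ = np.full((2 + p, 2 + p), np.nan)
            self.se_ = np.full(2 + p, np.nan)
            self.status_ = "singular information: covariance undefined"
            warnings.warn(
                "observed information is singular; standard errors undefined",
                RuntimeWarning,
                stacklevel=2,
            )
        est = np.concatenate([baseline, theta])
        with np.errstate(divide="ignore", invalid="ignore"):
            self.wald_ = (est / self.se_) ** 2
        self.p_values_ = stats.chi2.sf(self.wald_, df=1)
        self.hazard_ratios_ = np.exp(theta)
        self.param_names_ = names
        return self

    def _param_names(self, fam) -> list[str]:
        if hasattr(self, "feature_names_in_"):
            covs = [str(c) for c in self.feature_names_in_]
        else:
            covs = [f"x{i}" for i in range(self.n_features_in_)]
        return list(fam.param_names) + covs

    # -- prediction --------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise AttributeError("this ParametricPH instance is not fitted yet")

    def _design(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                X = X[[str(c) for c in self.feature_names_in_]]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X.reshape(-1, 1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of features than at fit time")
        return X

    def predict(self, X) -> np.ndarray:
        """Linear predictor x'θ (log relative risk)."""
        self._check_fitted()
        return self._design(X) @ self.coef_

    def predict_survival(self, X, times) -> np.ndarray:
        """S(t|x) on a grid: array of shape (n_samples, n_times)."""
        self._check_fitted()
        fam = get_family(self.family)
        t = np.atleast_1d(np.asarray(times, dtype=float))
        g = np.exp(self.predict(X))
        return np.exp(np.outer(g, fam.log_sf(t, self.baseline_params_)))

    def predict_hazard(self, X, times) -> np.ndarray:
        """h(t|x) on a grid: array of shape (n_samples, n_times)."""
        self._check_fitted()
        fam = get_family(self.family)
        t = np.atleast_1d(np.asarray(times, dtype=float))
        g = np.exp(self.predict(X))
        return np.outer(g, fam.hazard(t, self.baseline_params_))

    def predict_cumulative_hazard(self, X, times) -> np.ndarray:
        self._check_fitted()
        fam = get_family(self.family)
        t = np.atleast_1d(np.asarray(times, dtype=float))
        g = np.exp(self.predict(X))
        return np.outer(g, -fam.log_sf(t, self.baseline_params_))

    def score(self, X, y) -> float:
        """Mean per-subject censored log-likelihood (higher is better)."""
        self._check_fitted()
        time, event = _unpack_y(y)
        X = self._design(X)
        fam = get_family(self.family)
        eta = X @ self.coef_
        ll = np.sum(
            event * (fam.log_hazard(time, self.baseline_params_) + eta)
        ) + np.sum(np.exp(eta) * fam.log_sf(time, self.baseline_params_))
        return float(ll) / time.size

    # -- reporting ---------------------------------------------------------

    def spec_(self) -> PHModelSpec:
        """The fitted model as a PHModelSpec."""
        self._check_fitted()
        fam = get_family(self.family)
        covs = self._param_names(fam)[2:]
        return PHModelSpec(
            family=fam.name,
            baseline_params=self.baseline_params_,
            coefficients=dict(zip(covs, self.coef_)),
        )

    def result_(self) -> FitResult:
        """The fit as an immutable FitResult record."""
        self._check_fitted()
        est = np.concatenate([self.baseline_params_, self.coef_])
        return FitResult(
            spec=self.spec_(),
            param_names=list(self.param_names_),
            estimates=est,
            loglik=self.log_likelihood_,
            covariance=self.covariance_,
            se=self.se_,
            wald=self.wald_,
            p_value=self.p_values_,
            hazard_ratio=self.hazard_ratios_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            n_params=est.size,
            status=self.status_,
        )


def fit_ph(
    data: SurvivalData,
    family: str = "hypertabastic",
    covariates: Sequence[str] | None = None,
    **options,
) -> FitResult:
    """Fit a parametric PH model to ``data`` and return a FitResult.

    ``covariates`` restricts the design to a subset of columns (all by
    default; an empty list fits the baseline-only model). Extra keyword
    options are forwarded to :class:`ParametricPH`.
    """
    cols = data.names if covariates is None else list(covariates)
    est = ParametricPH(family=family, **options)
    est.fit(data.covariates[cols], (data.time, data.event))
    return est.result_()
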