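"""Synthetic breast-cancer-style cohorts for the PH survival model.

Generates cohorts with the statistical structure the analysis assumes:
an age covariate, a binary good/poor gene-signature label (column
``70G``), two continuous gene-signature correlation scores on [−1, 1]
(``CSR`` and ``CERBB``) with a controllable pairwise correlation kept
below the 0.5 selection screen, hypertabastic proportional-hazards event
times drawn by inverse-transform sampling, and two-part right censoring
(an administrative follow-up horizon plus an independent exponential
drop-out time).

The default configuration emulates a 295-subject early-stage
breast-cancer cohort with roughly 20 years of follow-up; the default
true model uses the fitted estimates of the published four-covariate
analysis (α = 0.7247, β = 0.6205; θ = −0.0735 for AGE, 1.199 for 70G,
2.661 for CSR, 1.561 for CERBB).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import HypertabasticParams, _invert_log_sf
from .regression import SurvivalData, fit_ph

__all__ = [
    "CohortConfig",
    "TrueModel",
    "default_true_model",
    "generate_covariates",
    "simulate_event_times",
    "apply_censoring",
    "generate_cohort",
    "recovery_experiment",
]

COVARIATE_NAMES = ("AGE", "70G", "CSR", "CERBB")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults emulate the validation cohort the model was developed on:
    295 subjects, ages centred in the mid-forties (the cohort enrolled
    women under 53), 61% with a poor-prognosis signature, mildly
    correlated signature scores, and right censoring from a 20-year
    administrative horizon plus slow random drop-out.
    """

    n: int = 295
    age_mean: float = 44.0
    age_sd: float = 6.0
    age_range: tuple[float, float] = (25.0, 75.0)
    signature_prevalence: float = 0.61
    score_means: tuple[float, float] = (0.0, 0.0)
    score_sds: tuple[float, float] = (0.25, 0.25)
    score_correlation: float = 0.2
    administrative_horizon: float = 20.0
    random_censor_rate: float = 0.02  # per year
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not 0.0 <= self.signature_prevalence <= 1.0:
            raise ValueError("signature_prevalence must be a probability")
        if not -1.0 < self.score_correlation < 1.0:
            raise ValueError("score_correlation must lie in (-1, 1)")
        if any(s <= 0 for s in self.score_sds) or self.age_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if self.administrative_horizon <= 0:
            raise ValueError("administrative horizon must be positive")
        if self.random_censor_rate < 0:
            raise ValueError("random censoring rate must be non-negative")


@dataclass(frozen=True)
class TrueModel:
    """Data-generating PH model: baseline parameters plus coefficients."""

    baseline: HypertabasticParams
    coefficients: dict[str, float]

    @property
    def names(self) -> list[str]:
        return list(self.coefficients)

    @property
    def theta(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))

    @property
    def param_values(self) -> np.ndarray:
        return np.concatenate(
            [[self.baseline.alpha, self.baseline.beta], self.theta]
        )

    @property
    def param_names(self) -> list[str]:
        return ["alpha", "beta"] + self.names


def default_true_model() -> TrueModel:
    """The published four-covariate estimates as the default truth."""
    return TrueModel(
        baseline=HypertabasticParams(alpha=0.7247, beta=0.6205),
        coefficients={"AGE": -0.0735, "70G": 1.199, "CSR": 2.661, "CERBB": 1.561},
    )


def generate_covariates(config: CohortConfig, seed=None) -> pd.DataFrame:
    """Draw the covariate matrix (AGE, 70G, CSR, CERBB).

    AGE is a truncated normal on ``config.age_range``; 70G is Bernoulli
    with the configured poor-prognosis prevalence; the two scores are
    bivariate normal with the configured correlation, truncated (clipped)
    to [−1, 1]². Reproducible given the seed (``config.seed`` when no
    explicit seed is passed).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=config.n, random_state=rng
    )
    sig = (rng.uniform(size=config.n) < config.signature_prevalence).astype(int)
    s1, s2 = config.score_sds
    r = config.score_correlation
    cov = np.array([[s1 * s1, r * s1 * s2], [r * s1 * s2, s2 * s2]])
    scores = rng.multivariate_normal(config.score_means, cov, size=config.n,
                                     method="cholesky")
    scores = np.clip(scores, -1.0, 1.0)
    return pd.DataFrame(
        {"AGE": age, "70G": sig, "CSR": scores[:, 0], "CERBB": scores[:, 1]}
    )


def simulate_event_times(X: pd.DataFrame, truth: TrueModel, seed=None) -> np.ndarray:
    """Draw PH event times by inverse transform.

    For subject i with relative risk g_i, U ~ Uniform(0,1) and the event
    time solves S0(t)^g_i = U, i.e. ln S0(t) = ln(U)/g_i, inverted
    numerically (the baseline survival has no closed-form inverse).
    """
    rng = np.random.default_rng(seed)
    Xm = X[truth.names].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    g = np.exp(Xm @ truth.theta)
    u = rng.uniform(size=len(g))
    target = np.log(u) / g
    t = _invert_log_sf(target, truth.baseline)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise RuntimeError("event-time inversion produced invalid times")
    return t


def apply_censoring(
    times: np.ndarray, config: CohortConfig, seed=None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Apply two-part right censoring to latent event times.

    The censoring time is min(administrative horizon, exponential
    drop-out with the configured rate); the observed time is the smaller
    of event and censoring time. Returns (observed time, event indicator,
    censored fraction).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("event times must be positive")
    rng = np.random.default_rng(seed)
    if config.random_censor_rate > 0:
        drop = rng.exponential(1.0 / config.random_censor_rate, size=times.size)
    else:
        drop = np.full(times.size, np.inf)
    censor = np.minimum(config.administrative_horizon, drop)
    observed = np.minimum(times, censor)
    event = (times <= censor).astype(int)
    # guard against zero observed times from a degenerate horizon
    observed = np.maximum(observed, 1e-12)
    return observed, event, float(1.0 - event.mean())


def generate_cohort(
    config: CohortConfig | None = None, truth: TrueModel | None = None, seed=None
) -> SurvivalData:
    """Full pipeline: covariates → event times → censoring → SurvivalData.

    Sub-seeds for the three stochastic stages are spawned from one root
    seed (``config.seed`` unless overridden), so a cohort is a pure
    function of (config, truth, seed).
    """
    config = config or CohortConfig()
    truth = truth or default_true_model()
    if seed is None:
        seed = config.seed
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cov, s_time, s_cens = root.spawn(3)
    X = generate_covariates(config, seed=s_cov)
    t_event = simulate_event_times(X, truth, seed=s_time)
    observed, event, _ = apply_censoring(t_event, config, seed=s_cens)
    return SurvivalData(time=observed, event=event, covariates=X)


def recovery_experiment(
    truth: TrueModel | None = None,
    config: CohortConfig | None = None,
    n_values: tuple[int, ...] = (250, 1000, 4000),
    replicates: int = 100,
    seed: int = 0,
    family: str = "hypertabastic",
) -> tuple[pd.DataFrame, list[dict]]:
    """Parameter-recovery experiment: simulate, fit, summarise.

    For each sample size, ``replicates`` cohorts are generated from
    ``truth`` and fitted; the summary reports per-parameter mean bias,
    empirical SD, RMSE, mean estimated SE and the coverage of nominal
    95% Wald intervals. Fit failures are recorded per replicate, never
    silently dropped.

    Returns the summary table and the per-replicate records.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    truth = truth or default_true_model()
    config = config or CohortConfig()
    true_vals = truth.param_values
    pnames = truth.param_names
    z = stats.norm.ppf(0.975)
    rows, records = [], []
    root = np.random.SeedSequence(seed)
    for n in n_values:
        cfg = replace(config, n=int(n))
        ests, ses, ok = [], [], []
        for rep, child in enumerate(root.spawn(replicates)):
            rec: dict = {"n": int(n), "replicate": rep}
            try:
                data = generate_cohort(cfg, truth, seed=child)
                fit = fit_ph(data, family=family, covariates=truth.names)
                rec.update(converged=fit.converged, status=fit.status)
                if fit.converged and np.all(np.isfinite(fit.se)):
                    ests.append(fit.estimates)
                    ses.append(fit.se)
                    ok.append(True)
                else:
                    ok.append(False)
            except Exception as err:  # noqa: BLE001 - per-replicate status
                rec.update(converged=False, status=f"failed: {err}")
                ok.append(False)
            records.append(rec)
        est = np.array(ests)
        se = np.array(ses)
        if not len(est):
            continue
        inside = np.abs(est - true_vals) <= z * se
        for j, name in enumerate(pnames):
            rows.append(
                {
                    "n": int(n),
                    "parameter": name,
                    "truth": true_vals[j],
                    "mean_estimate": est[:, j].mean(),
                    "bias": est[:, j].mean() - true_vals[j],
                    "empirical_sd": est[:, j].std(ddof=1),
                    "mean_se": se[:, j].mean(),
                    "rmse": float(np.sqrt(np.mean((est[:, j] - true_vals[j]) ** 2))),
                    "coverage_95": float(inside[:, j].mean()),
                    "n_fits": len(est),
                }
            )
    return pd.DataFrame(rows), records
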