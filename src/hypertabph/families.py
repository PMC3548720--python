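"""Parametric baseline families for proportional-hazards regression.

Each family exposes the two quantities the censored likelihood needs —
``log_hazard`` and ``log_sf`` of the baseline — on a common two-parameter
surface, plus a moment-style initial guess for the optimiser. All three
families are used inside the PH form h(t|x) = h0(t)·exp(x'θ); for the
log-logistic this is a deliberate departure from its conventional
accelerated-failure-time role, so that all models share one hazard
structure and are compared on equal footing.

Parameterisations:

* hypertabastic: (alpha, beta) as in :mod:`hypertabph.distributions`;
* weibull: h0(t) = lam * k * t**(k-1), params (lam, k);
* loglogistic: h0(t) = (k/lam) (t/lam)**(k-1) / (1 + (t/lam)**k),
  params (lam, k) with lam the scale (median) and k the shape.
"""

from __future__ import annotations

import numpy as np

from . import distributions as htb

__all__ = ["BaselineFamily", "get_family", "FAMILIES"]


class BaselineFamily:
    """Abstract two-parameter baseline hazard family."""

    name: str = ""
    param_names: tuple[str, str] = ("", "")

    def log_hazard(self, t: np.ndarray, params) -> np.ndarray:
        raise NotImplementedError

    def log_sf(self, t: np.ndarray, params) -> np.ndarray:
        raise NotImplementedError

    def hazard(self, t, params):
        return np.exp(self.log_hazard(np.asarray(t, dtype=float), params))

    def sf(self, t, params):
        return np.exp(self.log_sf(np.asarray(t, dtype=float), params))

    def init_params(self, time: np.ndarray, event: np.ndarray) -> tuple[float, float]:
        """Crude but scale-aware starting point for the optimiser."""
        raise NotImplementedError


class HypertabasticFamily(BaselineFamily):
    name = "hypertabastic"
    param_names = ("alpha", "beta")

    def log_hazard(self, t, params):
        return np.asarray(htb.log_baseline_hazard(t, params))

    def log_sf(self, t, params):
        return np.asarray(htb.log_baseline_survival(t, params))

    def init_params(self, time, event):
        # exponential-rate alpha with beta = 1: for beta = 1 the hazard
        # saturates at alpha, so this puts the optimiser on the right scale
        rate = max(event.sum(), 1.0) / time.sum()
        return (rate, 1.0)


class WeibullFamily(BaselineFamily):
    name = "weibull"
    param_names = ("lam", "k")

    def log_hazard(self, t, params):
        lam, k = params
        return np.log(lam) + np.log(k) + (k - 1.0) * np.log(t)

    def log_sf(self, t, params):
        lam, k = params
        return -lam * np.power(t, k)

    def init_params(self, time, event):
        rate = max(event.sum(), 1.0) / time.sum()
        return (rate, 1.0)


class LogLogisticFamily(BaselineFamily):
    name = "loglogistic"
    param_names = ("lam", "k")

    def log_hazard(self, t, params):
        lam, k = params
        logz = k * (np.log(t) - np.log(lam))
        return np.log(k) - np.log(lam) + (k - 1.0) * (np.log(t) - np.log(lam)) - np.logaddexp(0.0, logz)

    def log_sf(self, t, params):
        lam, k = params
        logz = k * (np.log(t) - np.log(lam))
        return -np.logaddexp(0.0, logz)

    def init_params(self, time, event):
        return (float(np.median(time)), 1.0)


FAMILIES: dict[str, BaselineFamily] = {
    f.name: f for f in (HypertabasticFamily(), WeibullFamily(), LogLogisticFamily())
}


def get_family(name) -> BaselineFamily:
    if isinstance(name, BaselineFamily):
        return name
    try:
        return FAMILIES[str(name).lower()]
    except KeyError:
        raise ValueError(
            f"unknown baseline family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None
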