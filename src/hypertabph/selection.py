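"""Model comparison and forward covariate selection.

``compare_models`` fits each requested baseline family (with and without
covariates) on the same data and tabulates −2·log-likelihood and AIC,
ranked by AIC. ``forward_select`` performs stepwise forward selection
with a pairwise-correlation screen: a candidate is never entered if its
absolute Pearson correlation with an already included covariate reaches
the cap (default 0.5), so near-duplicate gene-signature scores cannot
enter the model together.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .regression import FitResult, SurvivalData, fit_ph

__all__ = ["compare_models", "forward_select"]


def compare_models(
    data: SurvivalData,
    families: Sequence[str] = ("hypertabastic", "weibull", "loglogistic"),
    covariates: Sequence[str] | None = None,
    **options,
) -> pd.DataFrame:
    """Fit each family on ``data`` and rank by AIC (ascending).

    Returns one row per family with −2logL, AIC, number of parameters and
    convergence status for the covariate model, plus the −2logL of the
    corresponding null (baseline-only) model. A family that fails to fit
    is kept in the table with a failure status rather than dropped.
    """
    rows = []
    for fam in families:
        row: dict = {"family": str(fam)}
        try:
            full = fit_ph(data, family=fam, covariates=covariates, **options)
            row.update(
                minus_two_loglik=full.minus_two_loglik,
                aic=full.aic,
                n_params=full.n_params,
                converged=full.converged,
                status=full.status,
            )
        except Exception as err:  # noqa: BLE001 - reported, not silenced
            row.update(
                minus_two_loglik=np.nan,
                aic=np.nan,
                n_params=np.nan,
                converged=False,
                status=f"failed: {err}",
            )
            warnings.warn(f"family {fam!r} failed to fit: {err}", RuntimeWarning, stacklevel=2)
        try:
            null = fit_ph(data, family=fam, covariates=[], **options)
            row["minus_two_loglik_null"] = null.minus_two_loglik
        except Exception as err:  # noqa: BLE001
            row["minus_two_loglik_null"] = np.nan
            warnings.warn(
                f"null model for family {fam!r} failed to fit: {err}",
                RuntimeWarning,
                stacklevel=2,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values("aic", na_position="last").reset_index(drop=True)


def forward_select(
    data: SurvivalData,
    candidates: Sequence[str],
    correlation_cap: float = 0.5,
    entry_p: float = 0.05,
    family: str = "hypertabastic",
    **options,
) -> tuple[list[dict], FitResult]:
    """Stepwise forward selection with a pairwise-correlation screen.

    At each step every remaining candidate is screened: if its absolute
    Pearson correlation with any already included covariate is
    ``>= correlation_cap`` it is set aside (recorded in the trace). Each
    surviving candidate is fitted together with the included set, and the
    one with the smallest Wald p-value enters if that p-value is below
    ``entry_p``; ties are broken by smaller AIC. Selection stops when no
    candidate qualifies.

    Returns
    -------
    trace : list of dict
        One record per step with the candidate scores and the action taken.
    result : FitResult
        The final fitted model (baseline-only if nothing was selected).
    """
    missing = [c for c in candidates if c not in data.names]
    if missing:
        raise ValueError(f"candidates not present in data: {missing}")
    included: list[str] = []
    remaining = list(candidates)
    trace: list[dict] = []
    step = 0
    while remaining:
        step += 1
        screened, evaluated = [], []
        for cand in remaining:
            corr = [
                abs(float(np.corrcoef(data.covariates[cand], data.covariates[v])[0, 1]))
                for v in included
            ]
            if corr and max(corr) >= correlation_cap:
                screened.append({"candidate": cand, "max_abs_corr": max(corr)})
                continue
            fit = fit_ph(data, family=family, covariates=included + [cand], **options)
            evaluated.append(
                {
                    "candidate": cand,
                    "p_value": float(fit.p_value[-1]),
                    "aic": fit.aic,
                    "converged": fit.converged,
                }
            )
        entrant = None
        if evaluated:
            evaluated.sort(key=lambda r: (r["p_value"], r["aic"]))
            if evaluated[0]["p_value"] < entry_p:
                entrant = evaluated[0]["candidate"]
        trace.append(
            {
                "step": step,
                "included_before": list(included),
                "screened_out": screened,
                "evaluated": evaluated,
                "entered": entrant,
            }
        )
        if entrant is None:
            break
        included.append(entrant)
        remaining.remove(entrant)
    final = fit_ph(data, family=family, covariates=included, **options)
    return trace, final
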