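"""Regressions of metric discrepancy and detection outcomes on sampling regime.

Two model families over the experiment's results table:

* multiple linear regression (OLS) of a discrepancy measure on
  log(number of individuals), log(observations per individual) and their
  interaction, with the response optionally log-transformed — natural
  logs throughout; count discrepancies use log(1 + x) because zero
  discrepancies occur (configurable via ``zero_offset``);
* logistic regression of a binary outcome (evidence for community
  structure, acceptable R_com) on the untransformed predictors and
  their interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

TERM_NAMES = ("intercept", "n_individuals", "n_obs", "interaction")


@dataclass
class RegressionSummary:
    """Coefficient table plus fit diagnostics for one model."""

    terms: list[tuple[str, float, float, float]]  # (name, coef, se, p)
    r_squared: float | None
    model_kind: str
    transform: str
    converged: bool = True

    def coef(self, name: str) -> float:
        return dict((t[0], t[1]) for t in self.terms)[name]

    def se(self, name: str) -> float:
        return dict((t[0], t[2]) for t in self.terms)[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.terms, columns=["term", "coefficient", "se", "p_value"])

    def report(self) -> str:
        lines = [
            f"{self.model_kind} model ({self.transform})",
            f"{'term':<16}{'coef':>12}{'se':>12}{'p':>12}",
        ]
        for name, coef, se, p in self.terms:
            lines.append(f"{name:<16}{coef:>12.4g}{se:>12.4g}{p:>12.4g}")
        if self.r_squared is not None:
            lines.append(f"R-squared: {self.r_squared:.4f}")
        if not self.converged:
            lines.append("WARNING: fit did not converge")
        return "\n".join(lines)


def _design(results: pd.DataFrame, log_predictors: bool) -> np.ndarray:
    ni = results["n_individuals"].to_numpy(dtype=float)
    no = results["n_obs"].to_numpy(dtype=float)
    if log_predictors:
        ni, no = np.log(ni), np.log(no)
    X = np.column_stack([np.ones_like(ni), ni, no, ni * no])
    for j, name in enumerate(TERM_NAMES):
        if j > 0 and np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor {name!r} has zero variance")
    return X


def fit_discrepancy_model(
    results: pd.DataFrame,
    response: str,
    log_transform: bool = True,
    zero_offset: float = 1.0,
) -> RegressionSummary:
    """OLS of a discrepancy column on (log) sampling-regime predictors.

    With ``log_transform``, the response becomes log(zero_offset + y) for
    the community-count discrepancy (which contains zeros) and log(y)
    otherwise; zeros in a continuous response also fall back to the
    offset form. Predictors are log-transformed alongside the response.
    """
    if response not in results.columns:
        raise ValueError(f"response column {response!r} not in results")
    y = results[response].to_numpy(dtype=float)
    transform = "untransformed"
    if log_transform:
        if response == "delta_n_comm" or np.any(y <= 0):
            y = np.log(zero_offset + y)
            transform = f"log({zero_offset:g} + y), log predictors"
        else:
            y = np.log(y)
            transform = "log(y), log predictors"
    X = _design(results, log_predictors=log_transform)
    fit = sm.OLS(y, X).fit()
    terms = [
        (name, float(fit.params[j]), float(fit.bse[j]), float(fit.pvalues[j]))
        for j, name in enumerate(TERM_NAMES)
    ]
    r2 = float(fit.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0  # constant response: no variance to explain
    return RegressionSummary(
        terms=terms,
        r_squared=r2,
        model_kind="linear",
        transform=transform,
    )


def fit_detection_model(results: pd.DataFrame, response: str) -> RegressionSummary:
    """Logistic regression of a binary outcome on the untransformed regime.

    Raises on a single-class response or on complete separation rather
    than returning a silent degenerate fit.
    """
    if response not in results.columns:
        raise ValueError(f"response column {response!r} not in results")
    y = results[response].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError(f"response {response!r} must be binary 0/1")
    if len(classes) < 2:
        raise ValueError(
            f"response {response!r} has a single class ({classes[0]:g}); "
            "a logistic model cannot be fit"
        )
    X = _design(results, log_predictors=False)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ValueError("logistic fit did not converge (possible separation)")
    terms = [
        (name, float(fit.params[j]), float(fit.bse[j]), float(fit.pvalues[j]))
        for j, name in enumerate(TERM_NAMES)
    ]
    return RegressionSummary(
        terms=terms,
        r_squared=None,
        model_kind="logistic",
        transform="untransformed",
        converged=bool(fit.mle_retvals.get("converged", False)),
    )
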