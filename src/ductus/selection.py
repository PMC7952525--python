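"""Maximum-likelihood logistic regression and Wald backward elimination.

The fit maximises the Bernoulli log-likelihood by iteratively reweighted
least squares (IRLS; Newton-Raphson on the canonical link), converging when
the largest coefficient update falls below 1e-8 or after 50 iterations.
The covariance is the inverse observed information (X' W X)^-1 at the
optimum.  Complete or quasi-complete separation is flagged (not "fixed")
when any coefficient exceeds 30 on the standardized-covariate scale.

Backward elimination starts from the full candidate model and repeatedly
drops the covariate with the largest Wald p-value, refitting after every
removal, until every remaining covariate has p below ``alpha_stay`` (default
0.05, the conventional significance level) or only the intercept remains.
Ties in p are broken toward the smaller squared Wald statistic, then
lexicographic covariate name, so traces are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .closure_model import LogisticModel
from .errors import (
    DegenerateInputError,
    InvalidInputError,
    MissingCovarianceError,
    MissingCovariateError,
    RankDeficiencyError,
    SeparationWarning,
)

__all__ = [
    "fit_logistic",
    "wald_test",
    "backward_eliminate",
    "bernoulli_log_likelihood",
    "EliminationStep",
    "EliminationTrace",
]

_SEPARATION_BOUND = 30.0  # |beta| on standardized covariates


def bernoulli_log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood of binary ``y`` under logit-scale linear predictor."""
    # -log(1 + exp(-eta)) computed stably via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _as_design(
    design: Union[pd.DataFrame, np.ndarray], columns: Optional[Sequence[str]] = None
) -> Tuple[np.ndarray, List[str]]:
    if isinstance(design, pd.DataFrame):
        cols = list(design.columns) if columns is None else list(columns)
        X = design[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cols = [f"x{i}" for i in range(X.shape[1])] if columns is None else list(columns)
    if np.isnan(X).any():
        raise InvalidInputError("design matrix contains missing values")
    return X, cols


def fit_logistic(
    design: Union[pd.DataFrame, np.ndarray],
    outcome: Sequence[float],
    columns: Optional[Sequence[str]] = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    name: str = "fitted-logistic",
) -> LogisticModel:
    """Fit intercept + covariates by IRLS; returns a LogisticModel.

    ``design`` holds the covariates only (the intercept column is added
    internally).  Covariates are used unstandardized so coefficients stay on
    the interpretable clinical scale; standardization is internal to the
    separation check.
    """
    X, cols = _as_design(design, columns)
    y = np.asarray(outcome, dtype=float)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise InvalidInputError("outcome length must match design rows")
    if np.isnan(y).any() or not np.isin(y, (0.0, 1.0)).all():
        raise InvalidInputError("outcome must be binary 0/1 with no missing values")
    n, k = X.shape
    if n < k + 2:
        raise InvalidInputError(f"need at least {k + 2} rows to fit {k} covariates")
    Xd = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise RankDeficiencyError("design matrix (with intercept) is rank deficient")

    beta = np.zeros(k + 1)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = Xd.T * w
        try:
            beta_new = np.linalg.solve(XtW @ Xd, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(f"weighted normal equations singular: {exc}") from exc
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    eta = Xd @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = (Xd.T * w) @ Xd
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError(f"observed information singular: {exc}") from exc
    cov = (cov + cov.T) / 2

    separation = False
    if k:
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        if np.any(np.abs(beta[1:] * scale) > _SEPARATION_BOUND):
            separation = True
            warnings.warn(
                "possible complete or quasi-complete separation: a standardized "
                "coefficient exceeds 30; estimates and SEs are unreliable",
                SeparationWarning,
                stacklevel=2,
            )

    fit_info = {
        "converged": converged,
        "iterations": iterations,
        "log_likelihood": bernoulli_log_likelihood(eta, y),
        "n_obs": n,
        "separation": separation,
    }
    return LogisticModel(
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(cols, beta[1:])},
        covariance=cov,
        fit_info=fit_info,
        name=name,
    )


def wald_test(model: LogisticModel, covariate: str) -> Tuple[float, float]:
    """Squared Wald statistic (beta/SE)^2 and its chi-square(1) p-value."""
    if model.covariance is None:
        raise MissingCovarianceError("Wald test needs a model covariance")
    if covariate not in model.coefficients:
        raise MissingCovariateError(f"unknown covariate {covariate!r}")
    beta = model.coefficients[covariate]
    se = model.standard_error(covariate)
    stat = (beta / se) ** 2
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass(frozen=True)
class EliminationStep:
    removed: str
    p_at_removal: float
    wald_statistic: float
    log_likelihood_after: float


@dataclass
class EliminationTrace:
    """Ordered removals plus the final retained model."""

    steps: List[EliminationStep]
    final_model: LogisticModel
    alpha_stay: float

    @property
    def removed(self) -> List[str]:
        return [s.removed for s in self.steps]

    @property
    def retained(self) -> List[str]:
        return list(self.final_model.coefficients)

    def to_report(self) -> str:
        lines = [f"{'step':>4}  {'removed':<24} {'Wald p':>10} {'logLik after':>14}"]
        for i, s in enumerate(self.steps, start=1):
            lines.append(
                f"{i:>4}  {s.removed:<24} {s.p_at_removal:>10.4f} "
                f"{s.log_likelihood_after:>14.4f}"
            )
        lines.append(f"retained: {', '.join(self.retained) or '(intercept only)'}")
        return "\n".join(lines)


def backward_eliminate(
    design: pd.DataFrame,
    outcome: Sequence[float],
    candidates: Optional[Sequence[str]] = None,
    alpha_stay: float = 0.05,
) -> EliminationTrace:
    """Backward elimination driven by Wald p-values.

    Starts from the full model over ``candidates`` (default: all design
    columns); at each step the single covariate with the largest p is removed
    if p >= ``alpha_stay``, and the model is refitted.
    """
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design, dtype=float))
        design.columns = [f"x{i}" for i in range(design.shape[1])]
    candidates = list(design.columns) if candidates is None else list(candidates)
    missing = [c for c in candidates if c not in design.columns]
    if missing:
        raise InvalidInputError(f"candidates not in design: {missing}")
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("outcome has a single class; nothing to model")

    steps: List[EliminationStep] = []
    current = candidates
    model = fit_logistic(design, y, columns=current) if current else _intercept_only(y)
    while current:
        tests = {c: wald_test(model, c) for c in current}
        # largest p; ties -> smaller Wald statistic, then name
        victim = max(current, key=lambda c: (tests[c][1], -tests[c][0], *_namekey(c)))
        stat, p = tests[victim]
        if p < alpha_stay:
            break
        current = [c for c in current if c != victim]
        model = fit_logistic(design, y, columns=current) if current else _intercept_only(y)
        steps.append(
            EliminationStep(
                removed=victim,
                p_at_removal=p,
                wald_statistic=stat,
                log_likelihood_after=model.fit_info["log_likelihood"],
            )
        )
    return EliminationTrace(steps=steps, final_model=model, alpha_stay=alpha_stay)


def _namekey(name: str):
    # max() picks the largest key; invert character order so that among exact
    # p/statistic ties the lexicographically smallest name is removed first
    return tuple(-ord(ch) for ch in name)


def _intercept_only(y: np.ndarray) -> LogisticModel:
    return fit_logistic(
        pd.DataFrame(index=range(len(y))), y, columns=[], name="intercept-only"
    )
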