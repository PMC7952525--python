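"""Logistic prediction of early spontaneous ductal closure.

The published model combines gestational age (continuous weeks) and the
screening ductal staging score:

    logit(p) = -28.41 + 1.23 * GA_weeks - 0.87 * score

where p is the probability of early spontaneous closure (i.e. that the
infant can be managed conservatively).  The :class:`LogisticModel` container
also holds models fitted in-package (which then carry a covariance matrix
and convergence metadata), so published and refitted models share one
interface and one on-disk JSON format.

Note the published coefficients are printed to two decimals; exp(1.23) =
3.42 while the originally reported odds ratio is 3.44 (the unrounded
coefficient was presumably ~1.235).  All odds-ratio output here is derived
from the stored coefficients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import (
    InvalidInputError,
    MissingCovarianceError,
    MissingCovariateError,
)

__all__ = [
    "LogisticModel",
    "ClosurePrediction",
    "EffectStatement",
    "LIKELY_EARLY_CLOSURE",
    "LIKELY_HSPDA",
    "published_model",
    "closure_probability",
    "odds_ratios",
    "effect_statement",
    "classify",
]

LIKELY_EARLY_CLOSURE = "likely-early-closure"
LIKELY_HSPDA = "likely-hsPDA"


@dataclass
class LogisticModel:
    """Intercept + named coefficients on the logit scale.

    ``covariance`` (optional) is ordered (intercept, *coefficient names in
    insertion order*) and must be symmetric positive semidefinite.
    ``fit_info`` carries convergence metadata for fitted models and is absent
    for fixed published models.
    """

    intercept: float
    coefficients: Dict[str, float]
    covariance: Optional[np.ndarray] = None
    fit_info: Optional[dict] = field(default=None)
    name: str = "logistic"

    def __post_init__(self) -> None:
        if len(set(self.coefficients)) != len(self.coefficients):
            raise InvalidInputError("coefficient names must be unique")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            k = 1 + len(self.coefficients)
            if cov.shape != (k, k):
                raise InvalidInputError(
                    f"covariance must be {k}x{k} (intercept + coefficients)"
                )
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise InvalidInputError("covariance must be symmetric")
            eigvals = np.linalg.eigvalsh((cov + cov.T) / 2)
            if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
                raise InvalidInputError("covariance must be positive semidefinite")
            self.covariance = cov

    # -- parameter order helpers -------------------------------------------

    @property
    def param_names(self) -> Tuple[str, ...]:
        return ("intercept",) + tuple(self.coefficients)

    def standard_error(self, covariate: str) -> float:
        if self.covariance is None:
            raise MissingCovarianceError(
                f"model {self.name!r} carries no covariance; cannot give SE of {covariate!r}"
            )
        try:
            i = self.param_names.index(covariate)
        except ValueError:
            raise MissingCovariateError(f"unknown covariate {covariate!r}") from None
        return float(np.sqrt(self.covariance[i, i]))

    def linear_predictor(self, covariates: Mapping[str, float]) -> float:
        eta = self.intercept
        for name, beta in self.coefficients.items():
            if name not in covariates:
                raise MissingCovariateError(
                    f"covariate {name!r} required by model {self.name!r} is missing"
                )
            eta += beta * float(covariates[name])
        return eta

    # -- serialization ------------------------------------------------------

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "name": self.name,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
        }
        if self.covariance is not None:
            payload["covariance"] = np.asarray(self.covariance).tolist()
        if self.fit_info is not None:
            payload["fit_info"] = {
                k: (v if not isinstance(v, (np.floating, np.integer, np.bool_)) else v.item())
                for k, v in self.fit_info.items()
            }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "LogisticModel":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        payload = json.loads(text)
        cov = payload.get("covariance")
        return cls(
            intercept=float(payload["intercept"]),
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            covariance=None if cov is None else np.asarray(cov, dtype=float),
            fit_info=payload.get("fit_info"),
            name=payload.get("name", "logistic"),
        )


@dataclass(frozen=True)
class ClosurePrediction:
    """Linear predictor, probability and thresholded class for one infant."""

    logit: float
    probability: float
    classification: str


@dataclass(frozen=True)
class EffectStatement:
    """Per-unit odds effect of a covariate, phrased directionally."""

    covariate: str
    kind: str  # "percent-decrease" | "fold-increase" | "no-change"
    value: float

    def __str__(self) -> str:
        if self.kind == "percent-decrease":
            return (
                f"each unit increase in {self.covariate} decreases the odds of "
                f"early spontaneous closure by {self.value:.0f}%"
            )
        if self.kind == "fold-increase":
            return (
                f"each unit increase in {self.covariate} multiplies the odds of "
                f"early spontaneous closure by {self.value:.1f}"
            )
        return f"{self.covariate} has no effect on the odds"


def published_model() -> LogisticModel:
    """The fixed published closure model (no covariance: CIs disabled)."""
    return LogisticModel(
        intercept=-28.41,
        coefficients={"gestational_age_weeks": 1.23, "pda_score": -0.87},
        name="published-closure-model",
    )


def closure_probability(
    model: LogisticModel,
    covariates: Mapping[str, float],
    threshold: float = 0.5,
) -> ClosurePrediction:
    """Probability of early spontaneous closure for one covariate vector."""
    eta = model.linear_predictor(covariates)
    p = float(expit(eta))
    # expit saturates in float; keep the open-interval contract
    p = min(max(p, np.nextafter(0.0, 1.0)), np.nextafter(1.0, 0.0))
    return ClosurePrediction(
        logit=eta, probability=p, classification=classify(p, threshold)
    )


def odds_ratios(
    model: LogisticModel, confidence: Optional[float] = None
) -> Dict[str, Tuple[float, Optional[float], Optional[float]]]:
    """Per-covariate odds ratio exp(beta), with Wald CIs when requested.

    ``confidence`` (e.g. 0.95) requires the model to carry a covariance; for
    the fixed published model CIs are deliberately unavailable rather than
    reconstructed from printed, rounding-inconsistent bounds.
    """
    if confidence is not None and model.covariance is None:
        raise MissingCovarianceError(
            f"model {model.name!r} has no covariance; confidence intervals unavailable"
        )
    out: Dict[str, Tuple[float, Optional[float], Optional[float]]] = {}
    for name, beta in model.coefficients.items():
        if confidence is None:
            out[name] = (math.exp(beta), None, None)
        else:
            if not 0 < confidence < 1:
                raise InvalidInputError("confidence must be in (0, 1)")
            z = norm.ppf(0.5 + confidence / 2)
            se = model.standard_error(name)
            out[name] = (
                math.exp(beta),
                math.exp(beta - z * se),
                math.exp(beta + z * se),
            )
    return out


def effect_statement(model: LogisticModel, covariate: str) -> EffectStatement:
    """Directional per-unit odds effect (percent decrease or fold increase)."""
    if covariate not in model.coefficients:
        raise MissingCovariateError(f"unknown covariate {covariate!r}")
    beta = model.coefficients[covariate]
    if beta < 0:
        return EffectStatement(covariate, "percent-decrease", (1 - math.exp(beta)) * 100)
    if beta > 0:
        return EffectStatement(covariate, "fold-increase", math.exp(beta))
    return EffectStatement(covariate, "no-change", 0.0)


def classify(probability: float, threshold: float = 0.5) -> str:
    """Threshold a closure probability (>= threshold -> likely early closure)."""
    if not 0 <= probability <= 1:
        raise InvalidInputError(f"probability must be in [0, 1], got {probability}")
    if not 0 <= threshold <= 1:
        raise InvalidInputError(f"threshold must be in [0, 1], got {threshold}")
    return LIKELY_EARLY_CLOSURE if probability >= threshold else LIKELY_HSPDA
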