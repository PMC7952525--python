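"""Seedable synthetic preterm cohorts with a two-group ductal structure.

The generator emulates the statistical shape of a screening-echo study
population: a conservatively managed group (``CM``, default n=42) whose
ducts are largely closing, and an ibuprofen-treated group (``IBT``, default
n=21) with hemodynamically significant ducts.  Group membership doubles as
the outcome label (treated = no early spontaneous closure), mirroring the
operational definition used in such studies.

Per-variable marginals are specified by their published group median and
IQR.  Continuous variables use a quantile-spliced normal: a draw u ~ U(0,1)
maps to median + sigma_low * z(u) below the median and median + sigma_high *
z(u) above it, with sigma = (printed quartile distance)/0.6745, then values
are clipped to a physiologic window.  This reproduces the printed median,
q1 and q3 exactly (up to clipping) even when the printed IQR is asymmetric,
which a symmetric truncated normal cannot do.  Ages at closure use a
log-normal.  A zero upper sigma is allowed and yields a ceiling mass at the
median (e.g. the 5-min Apgar, whose printed q3 equals its median).

A single latent severity per infant (standard normal within group) drives
the echo variables through a Gaussian copula with correlation
``latent_correlation`` (default 0.5), inducing realistic co-movement of
diameter, velocity ratio, LPA flow and aortic steal; gestational age and
birth weight load on the *negative* of the same latent.  In the CM group a
closed-duct point mass (diameter = ratio = 0, forward aortic flow) is mixed
in, with weight solved so the group's transductal-diameter quartiles match
the published (0, 0, 1.5) mm; descending-aorta direction is thresholded on
its latent so group reverse-flow prevalences hit the published 5% / 52%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .closure_model import LogisticModel, closure_probability
from .errors import ConfigError, MissingCovariateError
from .staging import StagingScheme, model5_scheme

__all__ = [
    "ContinuousSpec",
    "BinarySpec",
    "DuctSpec",
    "GroupDistributionSpec",
    "SyntheticCohortConfig",
    "default_config",
    "generate_cohort",
    "calibration_report",
    "simulate_outcomes_from_model",
]

_Z75 = norm.ppf(0.75)  # 0.6745 quartile unit


@dataclass(frozen=True)
class ContinuousSpec:
    """Target median/quartiles, distribution family and clipping window."""

    median: float
    q1: float
    q3: float
    lo: float = -math.inf
    hi: float = math.inf
    family: str = "spliced-normal"  # or "lognormal"
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ConfigError(
                f"infeasible quantile targets: q1 {self.q1} <= median {self.median} "
                f"<= q3 {self.q3} violated"
            )
        if not self.lo <= self.q1 and not math.isinf(self.lo):
            raise ConfigError("lower clip bound exceeds q1 target")
        if self.family not in ("spliced-normal", "lognormal"):
            raise ConfigError(f"unknown family {self.family!r}")
        if self.family == "lognormal" and self.q1 <= 0:
            raise ConfigError("lognormal family needs strictly positive quantiles")

    # quantile machinery ----------------------------------------------------

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        if self.family == "lognormal":
            mu = math.log(self.median)
            sigma = (math.log(self.q3) - math.log(self.q1)) / (2 * _Z75)
            x = np.exp(mu + sigma * norm.ppf(q))
        else:
            s_lo = (self.median - self.q1) / _Z75
            s_hi = (self.q3 - self.median) / _Z75
            z = norm.ppf(q)
            x = self.median + np.where(z < 0, s_lo, s_hi) * z
        return np.clip(x, self.lo, self.hi)

    def cdf(self, x: float) -> float:
        if self.family == "lognormal":
            mu = math.log(self.median)
            sigma = (math.log(self.q3) - math.log(self.q1)) / (2 * _Z75)
            return float(norm.cdf((math.log(x) - mu) / sigma))
        s_lo = (self.median - self.q1) / _Z75
        s_hi = (self.q3 - self.median) / _Z75
        if x < self.median:
            return float(norm.cdf((x - self.median) / s_lo)) if s_lo > 0 else 0.0
        if x == self.median:
            return 0.5
        return float(norm.cdf((x - self.median) / s_hi)) if s_hi > 0 else 1.0

    def draw(self, u: np.ndarray) -> np.ndarray:
        """Map standard-normal latents to values (monotone transform)."""
        x = self.ppf(norm.cdf(u))
        return np.round(x) if self.integer else x


@dataclass(frozen=True)
class BinarySpec:
    prevalence: float

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ConfigError(f"prevalence must be in [0, 1], got {self.prevalence}")


@dataclass(frozen=True)
class DuctSpec:
    """Ductal-measurement structure for one group.

    When ``mixture_td_q3`` is set, a closed-duct point mass (diameter and
    Vmax/Vmin both 0, forward descending-aorta flow) is mixed with the open
    components; its weight w solves  w + (1-w) * P_open(td <= q3) = 0.75 so
    the group's published diameter q3 is reproduced.  ``None`` means every
    duct is open (the treated group).
    """

    td_open: ContinuousSpec
    vmax_open: ContinuousSpec
    mixture_td_q3: Optional[float] = None
    mixture_vmax_q3: Optional[float] = None

    @property
    def closed_fraction(self) -> float:
        if self.mixture_td_q3 is None:
            return 0.0
        p_open = self.td_open.cdf(self.mixture_td_q3)
        if p_open >= 0.75:
            raise ConfigError(
                "open-duct diameter component places >= 75% below the mixture q3 "
                "target; the closed-duct weight is not identifiable"
            )
        w = (0.75 - p_open) / (1.0 - p_open)
        if w < 0.5:
            raise ConfigError(
                "closed-duct weight below 0.5 cannot reproduce a zero diameter median"
            )
        return w


@dataclass(frozen=True)
class GroupDistributionSpec:
    """All marginal targets for one management group."""

    continuous: Mapping[str, ContinuousSpec]
    binary: Mapping[str, BinarySpec]
    duct: DuctSpec
    dao_reverse: float
    dao_absent: float
    score_target: Tuple[float, float, float]  # emergent; used by calibration only

    def __post_init__(self) -> None:
        if self.dao_reverse + self.dao_absent > 1:
            raise ConfigError("dao reverse + absent prevalences exceed 1")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_conservative: int = 42
    n_treated: int = 21
    cm: GroupDistributionSpec = None
    ibt: GroupDistributionSpec = None
    latent_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conservative <= 0 or self.n_treated <= 0:
            raise ConfigError("group sizes must be positive")
        if not 0 <= self.latent_correlation < 1:
            raise ConfigError("latent_correlation must be in [0, 1)")


# ---------------------------------------------------------------------------
# Default calibration targets (published per-group medians and IQRs).
#
# Two printed rows have q3 equal to the median, which no continuous
# distribution can satisfy: CM birth weight "1056 (858-1056)" and treated
# cord pH "7.34 (7.31-7.34)".  For these the upper quartile distance is
# mirrored from the lower (q3 = median + (median - q1)); the Apgar ceiling
# (8 with q3 = 8) is kept as a genuine ceiling mass instead.  LPA velocities
# are stored in cm/s (the staging unit); the published table prints m/s.

_CM_CONTINUOUS = {
    "ga_weeks": ContinuousSpec(27.8, 26.7, 28.4, lo=23.0, hi=28.99),
    "birth_weight_g": ContinuousSpec(1056, 858, 1254, lo=400, hi=2000),
    "apgar5": ContinuousSpec(8, 6, 8, lo=0, hi=10, integer=True),
    "cord_ph": ContinuousSpec(7.30, 7.25, 7.36, lo=6.9, hi=7.5),
    "postnatal_age_h": ContinuousSpec(47.5, 24, 48, lo=18, hi=72),
    "lpa_cms": ContinuousSpec(10, 8, 18, lo=0.5, hi=80),
    "la_ao": ContinuousSpec(1.6, 1.2, 1.8, lo=0.7, hi=3.5),
    "lvo_svc_ratio": ContinuousSpec(2.2, 1.5, 2.6, lo=0.5, hi=8),
    "ea_ratio": ContinuousSpec(0.75, 0.7, 1.0, lo=0.3, hi=2.5),
    "svc_mlkgmin": ContinuousSpec(90, 70, 110, lo=20, hi=250),
    "closure_day": ContinuousSpec(5, 2, 15, family="lognormal"),
}

_IBT_CONTINUOUS = {
    "ga_weeks": ContinuousSpec(26.0, 24.6, 26.6, lo=23.0, hi=28.99),
    "birth_weight_g": ContinuousSpec(850, 660, 957, lo=400, hi=2000),
    "apgar5": ContinuousSpec(6, 4.5, 8, lo=0, hi=10, integer=True),
    "cord_ph": ContinuousSpec(7.34, 7.31, 7.37, lo=6.9, hi=7.5),
    "postnatal_age_h": ContinuousSpec(45, 24, 56, lo=18, hi=72),
    "lpa_cms": ContinuousSpec(32, 17, 38, lo=0.5, hi=80),
    "la_ao": ContinuousSpec(1.7, 1.4, 2.0, lo=0.7, hi=3.5),
    "lvo_svc_ratio": ContinuousSpec(2.4, 1.8, 3.5, lo=0.5, hi=8),
    "ea_ratio": ContinuousSpec(0.8, 0.7, 0.84, lo=0.3, hi=2.5),
    "svc_mlkgmin": ContinuousSpec(90, 70, 110, lo=20, hi=250),
    "closure_day": ContinuousSpec(19, 9, 34, family="lognormal"),
}


def _default_cm() -> GroupDistributionSpec:
    return GroupDistributionSpec(
        continuous=dict(_CM_CONTINUOUS),
        binary={"advanced_resuscitation": BinarySpec(15 / 42)},
        duct=DuctSpec(
            td_open=ContinuousSpec(1.6, 1.2, 2.0, lo=0.1, hi=5),
            vmax_open=ContinuousSpec(1.4, 1.1, 1.7, lo=0.05, hi=5),
            mixture_td_q3=1.5,
            mixture_vmax_q3=1.4,
        ),
        dao_reverse=2 / 42,
        dao_absent=0.10,
        score_target=(1, 0, 4),
    )


def _default_ibt() -> GroupDistributionSpec:
    return GroupDistributionSpec(
        continuous=dict(_IBT_CONTINUOUS),
        binary={"advanced_resuscitation": BinarySpec(14 / 21)},
        duct=DuctSpec(
            td_open=ContinuousSpec(2.0, 1.7, 2.6, lo=0.3, hi=6),
            vmax_open=ContinuousSpec(1.5, 1.2, 2.2, lo=0.2, hi=6),
            mixture_td_q3=None,
        ),
        dao_reverse=11 / 21,
        dao_absent=4 / 21,
        score_target=(7, 5, 8.5),
    )


def default_config(
    seed: int = 0,
    n_conservative: int = 42,
    n_treated: int = 21,
    latent_correlation: float = 0.5,
) -> SyntheticCohortConfig:
    """The study-calibrated default configuration (42 CM / 21 treated)."""
    return SyntheticCohortConfig(
        n_conservative=n_conservative,
        n_treated=n_treated,
        cm=_default_cm(),
        ibt=_default_ibt(),
        latent_correlation=latent_correlation,
        seed=seed,
    )


# Columns whose latents load on the shared severity (Gaussian copula).
_ECHO_VARS = ("td", "vmax", "lpa_cms", "dao", "la_ao", "lvo_svc_ratio")
# Perinatal columns loading on the *negative* severity (sicker = less mature).
_NEG_SEVERITY_VARS = ("ga_weeks", "birth_weight_g")


def _correlated_latent(rng: np.random.Generator, severity: np.ndarray, rho: float):
    eps = rng.standard_normal(severity.shape)
    return rho * severity + math.sqrt(1 - rho**2) * eps


def _generate_group(
    rng: np.random.Generator,
    spec: GroupDistributionSpec,
    n: int,
    rho: float,
    label: str,
    scheme: StagingScheme,
) -> pd.DataFrame:
    severity = rng.standard_normal(n)
    cols: Dict[str, np.ndarray] = {}

    for name, cspec in spec.continuous.items():
        if name in _NEG_SEVERITY_VARS:
            u = -_correlated_latent(rng, severity, rho)
        elif name in _ECHO_VARS:
            u = _correlated_latent(rng, severity, rho)
        else:
            u = rng.standard_normal(n)
        cols[name] = cspec.draw(u)

    for name, bspec in spec.binary.items():
        cols[name] = (rng.random(n) < bspec.prevalence).astype(int)

    # ductal measurements: optional closed point mass, then open components
    w = spec.duct.closed_fraction
    q_td = norm.cdf(_correlated_latent(rng, severity, rho))
    closed = q_td < w
    q_open = np.where(closed, 0.5, (q_td - w) / (1.0 - w))  # rescaled open quantile
    td = np.where(closed, 0.0, spec.duct.td_open.ppf(q_open))
    u_vmax = _correlated_latent(rng, severity, rho)
    vmax = np.where(closed, 0.0, spec.duct.vmax_open.draw(u_vmax))
    cols["td_mm"] = td
    cols["vmax_vmin"] = vmax

    # descending-aorta direction: severity-monotone thresholds; reverse and
    # absent prevalences are group totals, so rescale to the open subset
    open_frac = 1.0 - w
    p_rev = min(spec.dao_reverse / open_frac, 1.0)
    p_abs = min(spec.dao_absent / open_frac, 1.0 - p_rev)
    q_dao = norm.cdf(_correlated_latent(rng, severity, rho))
    direction = np.where(
        q_dao > 1.0 - p_rev, "reverse", np.where(q_dao > 1.0 - p_rev - p_abs, "absent", "forward")
    )
    direction = np.where(closed, "forward", direction)
    cols["dao_direction"] = direction

    cols["lvo_mlkgmin"] = cols["lvo_svc_ratio"] * cols["svc_mlkgmin"]

    df = pd.DataFrame(cols)
    df.insert(0, "group", label)

    # staged score (vectorised components)
    total = np.zeros(n, dtype=int)
    staged = {
        "transductal_diameter": df["td_mm"].to_numpy(),
        "ductal_vmax_vmin_ratio": df["vmax_vmin"].to_numpy(),
        "lpa_diastolic_velocity": df["lpa_cms"].to_numpy(),
    }
    for comp in scheme.components:
        if comp.kind == "numeric-binned":
            total += comp.stage_array(staged[comp.variable])
        else:
            total += np.vectorize(comp.categories.__getitem__)(direction)
    df["pda_score"] = total
    return df


def generate_cohort(config: Optional[SyntheticCohortConfig] = None) -> pd.DataFrame:
    """Generate a synthetic two-group cohort; deterministic under its seed.

    Returns a cohort table in the package CSV schema (plus a ``closure_day``
    column); generation metadata is attached in ``DataFrame.attrs``.
    """
    config = config or default_config()
    rng = np.random.default_rng(config.seed)
    scheme = model5_scheme()
    cm = _generate_group(
        rng, config.cm, config.n_conservative, config.latent_correlation, "CM", scheme
    )
    ibt = _generate_group(
        rng, config.ibt, config.n_treated, config.latent_correlation, "IBT", scheme
    )
    df = pd.concat([cm, ibt], ignore_index=True)
    df.insert(0, "infant_id", [f"P{i + 1:04d}" for i in range(len(df))])
    order = [
        "infant_id", "group", "ga_weeks", "birth_weight_g", "apgar5", "cord_ph",
        "advanced_resuscitation", "td_mm", "vmax_vmin", "lpa_cms", "dao_direction",
        "la_ao", "lvo_mlkgmin", "svc_mlkgmin", "ea_ratio", "pda_score",
        "postnatal_age_h", "closure_day",
    ]
    df = df[order]
    df.attrs["seed"] = config.seed
    df.attrs["n_conservative"] = config.n_conservative
    df.attrs["n_treated"] = config.n_treated
    df.attrs["latent_correlation"] = config.latent_correlation
    return df


def calibration_report(
    cohort: pd.DataFrame,
    config: SyntheticCohortConfig,
    tolerance: float = 0.15,
    binary_tolerance: float = 0.10,
    integer_floor: float = 1.0,
) -> pd.DataFrame:
    """Realized vs target per-group summaries, with pass flags.

    Continuous variables pass when median, q1 and q3 are each within
    ``tolerance`` x (target IQR width) of target (absolute floor
    ``integer_floor`` for integer-valued variables such as the staged score
    and the Apgar); binary prevalences use an absolute ``binary_tolerance``.
    """
    from .stats import median_iqr

    cohort = cohort.copy()
    if "lvo_svc_ratio" not in cohort.columns:
        cohort["lvo_svc_ratio"] = cohort["lvo_mlkgmin"] / cohort["svc_mlkgmin"]
    rows = []
    for label, spec in (("CM", config.cm), ("IBT", config.ibt)):
        sub = cohort[cohort["group"] == label]
        targets: Dict[str, Tuple[float, float, float, bool]] = {
            name: (c.median, c.q1, c.q3, c.integer) for name, c in spec.continuous.items()
        }
        # mixture variables: published group quartiles, not the open component's
        if spec.duct.mixture_td_q3 is not None:
            targets["td_mm"] = (0.0, 0.0, spec.duct.mixture_td_q3, False)
            if spec.duct.mixture_vmax_q3 is not None:
                targets["vmax_vmin"] = (0.0, 0.0, spec.duct.mixture_vmax_q3, False)
        else:
            c = spec.duct.td_open
            targets["td_mm"] = (c.median, c.q1, c.q3, False)
            c = spec.duct.vmax_open
            targets["vmax_vmin"] = (c.median, c.q1, c.q3, False)
        targets["pda_score"] = (*spec.score_target, True)
        for name, (t_med, t_q1, t_q3, is_int) in targets.items():
            med, q1, q3 = median_iqr(sub[name].to_numpy(dtype=float))
            tol = tolerance * (t_q3 - t_q1)
            if is_int:
                tol = max(tol, integer_floor * (tolerance / 0.15 if tolerance else 0.0))
            err = max(abs(med - t_med), abs(q1 - t_q1), abs(q3 - t_q3))
            rows.append(
                {
                    "group": label, "variable": name, "kind": "continuous",
                    "target": f"{t_med:g} ({t_q1:g}-{t_q3:g})",
                    "realized": f"{med:g} ({q1:g}-{q3:g})",
                    "max_abs_error": err, "tolerance": tol, "passed": err <= tol,
                }
            )
        prevalences = {name: b.prevalence for name, b in spec.binary.items()}
        prevalences["dao_reverse"] = spec.dao_reverse
        for name, target in prevalences.items():
            if name == "dao_reverse":
                realized = float((sub["dao_direction"] == "reverse").mean())
            else:
                realized = float(sub[name].mean())
            err = abs(realized - target)
            rows.append(
                {
                    "group": label, "variable": name, "kind": "binary",
                    "target": f"{target:.3f}", "realized": f"{realized:.3f}",
                    "max_abs_error": err, "tolerance": binary_tolerance,
                    "passed": err <= binary_tolerance,
                }
            )
    return pd.DataFrame(rows)


def simulate_outcomes_from_model(
    cohort: pd.DataFrame, model: LogisticModel, seed: int
) -> np.ndarray:
    """Bernoulli outcomes drawn from a logistic model's per-infant probability.

    Covariate names are looked up as cohort columns, with
    ``gestational_age_weeks`` mapped onto the schema's ``ga_weeks``.
    """
    aliases = {"gestational_age_weeks": "ga_weeks"}
    rng = np.random.default_rng(seed)
    probs = np.empty(len(cohort))
    colmap = {}
    for name in model.coefficients:
        col = aliases.get(name, name)
        if col not in cohort.columns:
            raise MissingCovariateError(f"cohort lacks column for covariate {name!r}")
        colmap[name] = cohort[col].to_numpy(dtype=float)
    for i in range(len(cohort)):
        probs[i] = closure_probability(
            model, {name: colmap[name][i] for name in colmap}
        ).probability
    return (rng.random(len(cohort)) < probs).astype(int)
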