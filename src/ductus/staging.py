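"""Ordinal staging of ductal disease from screening echocardiography.

The built-in scheme stages four markers of ductal shunt severity and sums
them into a 0-11 total:

===============================  =====  ======  =======  ====
component (units)                  0      1       2        3
===============================  =====  ======  =======  ====
transductal diameter (mm)          0     <1.5   1.5-3     >3
ductal Vmax/Vmin ratio             0     <1.5   1.5-2     >2
antegrade LPA diastolic (cm/s)     0     <30    30-50     >50
descending-aorta diastole        forw.  absent  reverse   --
===============================  =====  ======  =======  ====

Boundary convention: the printed middle ranges are closed on both ends, so a
value sitting exactly on an upper boundary takes the milder of the two
adjacent categories; "<x" bins are open at x and ">y" bins open at y.  This
makes each row a partition of [0, inf).  Alternative schemes (e.g. candidate
score models) can be defined via :func:`load_scheme` from a JSON-compatible
config and compared through the ROC layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .errors import InvalidInputError, MissingMeasurementError, SchemeValidationError
from .hemodynamics import DAO_DIRECTIONS, EchoExam

__all__ = [
    "Bin",
    "StagingComponent",
    "StagingScheme",
    "StagedScore",
    "model5_scheme",
    "stage_component",
    "compute_score",
    "load_scheme",
    "scheme_to_config",
    "builtin_scheme_path",
]


@dataclass(frozen=True)
class Bin:
    """A numeric scoring interval; ``low``/``high`` bounds with closure flags."""

    low: float
    high: float
    low_closed: bool
    high_closed: bool
    score: int

    def contains(self, value: float) -> bool:
        lo_ok = value >= self.low if self.low_closed else value > self.low
        hi_ok = value <= self.high if self.high_closed else value < self.high
        return lo_ok and hi_ok


@dataclass(frozen=True)
class StagingComponent:
    """One staged variable: numeric-binned over [0, inf) or categorical."""

    variable: str
    kind: str  # "numeric-binned" | "categorical"
    bins: tuple = ()
    categories: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "numeric-binned":
            self._validate_bins()
        elif self.kind == "categorical":
            if not self.categories:
                raise SchemeValidationError(
                    f"component {self.variable!r}: categorical component needs categories"
                )
        else:
            raise SchemeValidationError(
                f"component {self.variable!r}: unknown kind {self.kind!r}"
            )

    def _validate_bins(self) -> None:
        bins = sorted(self.bins, key=lambda b: (b.low, not b.low_closed))
        if not bins:
            raise SchemeValidationError(f"component {self.variable!r}: no bins")
        first = bins[0]
        if first.low != 0 or not first.low_closed:
            raise SchemeValidationError(
                f"component {self.variable!r}: bins must start at a closed 0"
            )
        for prev, nxt in zip(bins, bins[1:]):
            if prev.high != nxt.low or prev.high_closed == nxt.low_closed:
                raise SchemeValidationError(
                    f"component {self.variable!r}: gap or overlap between bins at "
                    f"{prev.high} (values such as {self._gap_example(prev, nxt)} "
                    f"are covered by {'both' if prev.high_closed and nxt.low_closed else 'no'} bin)"
                )
        last = bins[-1]
        if not math.isinf(last.high):
            raise SchemeValidationError(
                f"component {self.variable!r}: bins must extend to infinity "
                f"(no bin above {last.high})"
            )
        object.__setattr__(self, "bins", tuple(bins))

    @staticmethod
    def _gap_example(prev: Bin, nxt: Bin) -> float:
        if prev.high == nxt.low:
            return prev.high
        return (prev.high + nxt.low) / 2.0

    @property
    def max_component_score(self) -> int:
        if self.kind == "numeric-binned":
            return max(b.score for b in self.bins)
        return max(self.categories.values())

    def stage(self, value: Union[float, str]) -> int:
        return stage_component(value, self)

    def stage_array(self, values: np.ndarray) -> np.ndarray:
        """Vectorised staging of a numeric array (no categorical support)."""
        if self.kind != "numeric-binned":
            raise InvalidInputError(
                f"component {self.variable!r} is categorical; stage_array needs numeric bins"
            )
        values = np.asarray(values, dtype=float)
        if np.any(values < 0):
            raise InvalidInputError(f"component {self.variable!r}: negative value")
        out = np.full(values.shape, -1, dtype=int)
        for b in self.bins:
            lo = values >= b.low if b.low_closed else values > b.low
            hi = values <= b.high if b.high_closed else values < b.high
            out[lo & hi] = b.score
        return out


@dataclass(frozen=True)
class StagingScheme:
    """An ordered collection of staging components with an additive total."""

    name: str
    components: tuple

    @property
    def max_score(self) -> int:
        return sum(c.max_component_score for c in self.components)

    @property
    def min_score(self) -> int:
        # every built-in component has an attainable 0 category
        mins = []
        for c in self.components:
            if c.kind == "numeric-binned":
                mins.append(min(b.score for b in c.bins))
            else:
                mins.append(min(c.categories.values()))
        return sum(mins)

    def component(self, variable: str) -> StagingComponent:
        for c in self.components:
            if c.variable == variable:
                return c
        raise KeyError(variable)


@dataclass(frozen=True)
class StagedScore:
    """Per-component and total staging result for one exam."""

    per_component: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.per_component.values()):
            raise InvalidInputError("total does not equal the sum of component scores")


def stage_component(value: Union[float, str], component: StagingComponent) -> int:
    """Score a single measurement under one component's rule."""
    if component.kind == "categorical":
        if value not in component.categories:
            raise InvalidInputError(
                f"component {component.variable!r}: unknown category {value!r} "
                f"(expected one of {sorted(component.categories)})"
            )
        return component.categories[value]
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise InvalidInputError(
            f"component {component.variable!r}: non-numeric value {value!r}"
        ) from None
    if not math.isfinite(v) or v < 0:
        raise InvalidInputError(
            f"component {component.variable!r}: value must be finite and >= 0, got {v}"
        )
    for b in component.bins:
        if b.contains(v):
            return b.score
    raise SchemeValidationError(  # unreachable for a validated scheme
        f"component {component.variable!r}: no bin contains {v}"
    )


def compute_score(exam: EchoExam, scheme: Optional[StagingScheme] = None) -> StagedScore:
    """Stage every component of ``scheme`` (default: built-in 0-11 scheme).

    Raises :class:`MissingMeasurementError` if the exam lacks a staged field;
    no imputation is attempted.
    """
    scheme = scheme or model5_scheme()
    per = {}
    for comp in scheme.components:
        value = getattr(exam, comp.variable, None)
        if value is None:
            raise MissingMeasurementError(
                f"exam is missing measurement {comp.variable!r} required by "
                f"scheme {scheme.name!r}"
            )
        per[comp.variable] = stage_component(value, comp)
    return StagedScore(per_component=per, total=sum(per.values()))


def _numeric_component(variable: str, lo: float, hi: float) -> StagingComponent:
    """0 -> 0, (0, lo) -> 1, [lo, hi] -> 2, (hi, inf) -> 3."""
    return StagingComponent(
        variable=variable,
        kind="numeric-binned",
        bins=(
            Bin(0.0, 0.0, True, True, 0),
            Bin(0.0, lo, False, False, 1),
            Bin(lo, hi, True, True, 2),
            Bin(hi, math.inf, False, False, 3),
        ),
    )


def model5_scheme() -> StagingScheme:
    """The built-in four-component ductal disease stage (maximum total 11).

    Transductal diameter in mm, Vmax/Vmin dimensionless, LPA diastolic
    velocity in cm/s, descending-aorta diastolic direction categorical.
    """
    return StagingScheme(
        name="model5",
        components=(
            _numeric_component("transductal_diameter", 1.5, 3.0),
            _numeric_component("ductal_vmax_vmin_ratio", 1.5, 2.0),
            _numeric_component("lpa_diastolic_velocity", 30.0, 50.0),
            StagingComponent(
                variable="dao_flow_direction",
                kind="categorical",
                categories={"forward": 0, "absent": 1, "reverse": 2},
            ),
        ),
    )


# ---------------------------------------------------------------------------
# Scheme (de)serialization


def scheme_to_config(scheme: StagingScheme) -> dict:
    """JSON-compatible description of a scheme (round-trips via load_scheme)."""
    comps = []
    for c in scheme.components:
        if c.kind == "numeric-binned":
            comps.append(
                {
                    "variable": c.variable,
                    "kind": c.kind,
                    "bins": [
                        {
                            "low": b.low,
                            "high": None if math.isinf(b.high) else b.high,
                            "low_closed": b.low_closed,
                            "high_closed": b.high_closed,
                            "score": b.score,
                        }
                        for b in c.bins
                    ],
                }
            )
        else:
            comps.append(
                {"variable": c.variable, "kind": c.kind, "categories": dict(c.categories)}
            )
    return {"name": scheme.name, "components": comps}


def load_scheme(config: Union[Mapping, str, Path]) -> StagingScheme:
    """Build and validate a scheme from a config mapping or JSON file path.

    Rejects bin structures with gaps or overlaps (every numeric component
    must partition [0, inf)).
    """
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = json.load(fh)
    if "name" not in config or "components" not in config:
        raise SchemeValidationError("scheme config needs 'name' and 'components'")
    comps = []
    seen = set()
    for cc in config["components"]:
        variable = cc.get("variable")
        if not variable or variable in seen:
            raise SchemeValidationError(f"missing or duplicate component variable {variable!r}")
        seen.add(variable)
        kind = cc.get("kind", "numeric-binned")
        if kind == "categorical":
            comps.append(
                StagingComponent(
                    variable=variable, kind=kind, categories=dict(cc["categories"])
                )
            )
        else:
            bins = tuple(
                Bin(
                    low=float(b["low"]),
                    high=math.inf if b.get("high") is None else float(b["high"]),
                    low_closed=bool(b.get("low_closed", True)),
                    high_closed=bool(b.get("high_closed", False)),
                    score=int(b["score"]),
                )
                for b in cc["bins"]
            )
            comps.append(StagingComponent(variable=variable, kind=kind, bins=bins))
    return StagingScheme(name=str(config["name"]), components=tuple(comps))


def builtin_scheme_path() -> Path:
    """Path to the shipped JSON config encoding the built-in scheme."""
    return Path(__file__).parent / "data" / "model5.json"
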