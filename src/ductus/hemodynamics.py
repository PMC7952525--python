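"""Derived hemodynamic quantities from neonatal functional echocardiography.

Left ventricular output (LVO) and superior vena cava (SVC) flow are computed
from vessel cross-section, velocity-time integral (VTI) and heart rate,
indexed to body weight:

    LVO  [mL/kg/min] = (d_ao^2 / 4) * pi * VTI_ao * HR / weight
    SVC  [mL/kg/min] = (d_svc_mean^2 / 4) * pi * VTI_svc * HR / weight

with diameters and VTIs in cm (so cm^3 = mL), HR in beats/min and weight in
kg.  The SVC diameter is the arithmetic mean of its maximum and minimum
(the vessel is not circular over the cardiac cycle).  The LVO/SVC ratio and
the mitral E/A ratio are plain quotients.

Averaging over consecutive cardiac cycles (3-5 for SVC diameter, 5-10 for SVC
VTI, 3 for the aortic VTI) happens *before* an :class:`EchoExam` is built, via
:func:`cycle_average`; the exam stores already-averaged values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Optional

from .errors import InvalidInputError

__all__ = [
    "DAO_DIRECTIONS",
    "EchoExam",
    "cycle_average",
    "left_ventricular_output",
    "svc_flow",
    "lvo_svc_ratio",
    "e_a_ratio",
]

#: Allowed categories for descending-aorta diastolic flow direction.
#: ``reverse`` indicates systemic "steal" through the duct.
DAO_DIRECTIONS = ("forward", "absent", "reverse")


def cycle_average(values: Iterable[float]) -> float:
    """Arithmetic mean over consecutive cardiac cycles.

    Parameters
    ----------
    values
        Per-cycle measurements (e.g. 3-5 SVC diameters); must be non-empty.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise InvalidInputError("cycle_average requires at least one measurement")
    return sum(vals) / len(vals)


def _require_nonnegative(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise InvalidInputError(f"{name} must be a finite non-negative number, got {value!r}")
    return value


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise InvalidInputError(f"{name} must be a finite positive number, got {value!r}")
    return value


def left_ventricular_output(
    aortic_root_diameter: float,
    aortic_vti: float,
    heart_rate: float,
    weight: float,
) -> float:
    """Left ventricular output in mL/kg/min.

    ``(d^2/4) * pi * VTI * HR / weight`` with *d* and *VTI* in cm, *HR* in
    beats/min and *weight* in kg.
    """
    d = _require_nonnegative("aortic_root_diameter", aortic_root_diameter)
    vti = _require_nonnegative("aortic_vti", aortic_vti)
    hr = _require_positive("heart_rate", heart_rate)
    wt = _require_positive("weight", weight)
    return (d * d / 4.0) * math.pi * vti * hr / wt


def svc_flow(
    svc_max_diameter: float,
    svc_min_diameter: float,
    svc_vti: float,
    heart_rate: float,
    weight: float,
) -> float:
    """Superior vena cava flow in mL/kg/min, using the mean SVC diameter."""
    dmax = _require_nonnegative("svc_max_diameter", svc_max_diameter)
    dmin = _require_nonnegative("svc_min_diameter", svc_min_diameter)
    if dmin > dmax:
        raise InvalidInputError(
            f"svc_min_diameter ({dmin}) exceeds svc_max_diameter ({dmax})"
        )
    vti = _require_nonnegative("svc_vti", svc_vti)
    hr = _require_positive("heart_rate", heart_rate)
    wt = _require_positive("weight", weight)
    d = (dmax + dmin) / 2.0
    return (d * d / 4.0) * math.pi * vti * hr / wt


def lvo_svc_ratio(lvo: float, svc: float) -> float:
    """LVO / SVC flow ratio; a marker of ductal shunt volume."""
    lvo = _require_nonnegative("lvo", lvo)
    svc = _require_nonnegative("svc", svc)
    if svc == 0:
        from .errors import UndefinedRatioError

        raise UndefinedRatioError("SVC flow is zero; LVO/SVC ratio undefined")
    return lvo / svc


def e_a_ratio(e_wave: float, a_wave: float) -> float:
    """Mitral inflow E/A velocity ratio (diastolic function marker)."""
    e = _require_nonnegative("e_wave", e_wave)
    a = _require_nonnegative("a_wave", a_wave)
    if a == 0:
        from .errors import UndefinedRatioError

        raise UndefinedRatioError("A-wave velocity is zero; E/A ratio undefined")
    return e / a


@dataclass(frozen=True)
class EchoExam:
    """One echocardiographic assessment's raw (cycle-averaged) measurements.

    Units: ``transductal_diameter`` mm; ``lpa_diastolic_velocity``, E/A wave
    velocities cm/s; aortic/SVC diameters and VTIs cm; heart rate beats/min;
    weight kg; postnatal age hours. ``transductal_diameter == 0`` encodes a
    closed duct and forces a zero Vmax/Vmin ratio.

    All fields are optional; validation applies only to the fields present,
    and downstream consumers (staging, flow computation) raise when a field
    they need is missing.
    """

    transductal_diameter: Optional[float] = None
    ductal_vmax_vmin_ratio: Optional[float] = None
    lpa_diastolic_velocity: Optional[float] = None
    dao_flow_direction: Optional[str] = None
    la_ao_ratio: Optional[float] = None
    aortic_root_diameter: Optional[float] = None
    aortic_vti: Optional[float] = None
    svc_max_diameter: Optional[float] = None
    svc_min_diameter: Optional[float] = None
    svc_vti: Optional[float] = None
    heart_rate: Optional[float] = None
    weight: Optional[float] = None
    e_wave_velocity: Optional[float] = None
    a_wave_velocity: Optional[float] = None
    postnatal_age: Optional[float] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "dao_flow_direction":
                continue
            value = getattr(self, f.name)
            if value is not None:
                _require_nonnegative(f.name, value)
        if self.dao_flow_direction is not None and self.dao_flow_direction not in DAO_DIRECTIONS:
            raise InvalidInputError(
                f"dao_flow_direction must be one of {DAO_DIRECTIONS}, "
                f"got {self.dao_flow_direction!r}"
            )
        if self.svc_max_diameter is not None and self.svc_min_diameter is not None:
            if self.svc_min_diameter > self.svc_max_diameter:
                raise InvalidInputError("svc_min_diameter exceeds svc_max_diameter")
        d, r = self.transductal_diameter, self.ductal_vmax_vmin_ratio
        if d is not None and r is not None and (d == 0) != (r == 0):
            raise InvalidInputError(
                "a closed duct (transductal_diameter = 0) must have "
                "ductal_vmax_vmin_ratio = 0, and vice versa"
            )

    # Convenience accessors -------------------------------------------------

    def lvo(self) -> float:
        """LVO in mL/kg/min from this exam's aortic measurements."""
        self._need("aortic_root_diameter", "aortic_vti", "heart_rate", "weight")
        return left_ventricular_output(
            self.aortic_root_diameter, self.aortic_vti, self.heart_rate, self.weight
        )

    def svc(self) -> float:
        """SVC flow in mL/kg/min from this exam's caval measurements."""
        self._need("svc_max_diameter", "svc_min_diameter", "svc_vti", "heart_rate", "weight")
        return svc_flow(
            self.svc_max_diameter,
            self.svc_min_diameter,
            self.svc_vti,
            self.heart_rate,
            self.weight,
        )

    def e_a(self) -> float:
        self._need("e_wave_velocity", "a_wave_velocity")
        return e_a_ratio(self.e_wave_velocity, self.a_wave_velocity)

    def _need(self, *names: str) -> None:
        from .errors import MissingMeasurementError

        for name in names:
            if getattr(self, name) is None:
                raise MissingMeasurementError(f"exam is missing measurement {name!r}")
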