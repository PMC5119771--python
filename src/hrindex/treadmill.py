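"""Treadmill-parameter VO2 prediction equations and handrail corrections.

Large screening studies rarely measure gas exchange; instead they predict
VO2peak from treadmill speed and incline, or from total time on a staged
protocol. This module evaluates such prediction equations and applies the
well-documented handrail-support correction: holding the rail lengthens
test time and inflates time/stage-based predictions by roughly 20-30%.

Coefficients are deliberately *data, not code*: they live in a shipped
JSON registry (``data/equations.json``) keyed by equation name, so the
external-reference constants stay auditable and swappable. Shipped
defaults are the ACSM walking and running equations and a cubic in
Bruce-protocol time. Units: speed in m·min⁻¹, grade as a fraction
(0.10 = 10%), time in minutes, output in mL O2·kg⁻¹·min⁻¹.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import DomainError, RegistryError
from .records import RailSupport

__all__ = [
    "EquationKind", "EquationSpec", "EquationRegistry", "load_registry",
    "vo2_walk", "vo2_run", "vo2_from_protocol_time", "handrail_adjust",
    "mph_to_m_per_min", "kmh_to_m_per_min",
]

#: m·min⁻¹ per mile·h⁻¹ (1 mile = 1609.34 m).
_M_PER_MIN_PER_MPH = 1609.34 / 60.0


def mph_to_m_per_min(mph: float) -> float:
    """Convert a treadmill speed from miles per hour to m·min⁻¹."""
    return mph * _M_PER_MIN_PER_MPH


def kmh_to_m_per_min(kmh: float) -> float:
    """Convert a treadmill speed from km per hour to m·min⁻¹."""
    return kmh * 1000.0 / 60.0


class EquationKind(str, enum.Enum):
    SPEED_GRADE_WALK = "speed_grade_walk"
    SPEED_GRADE_RUN = "speed_grade_run"
    PROTOCOL_TIME_POLY = "protocol_time_poly"


@dataclass(frozen=True)
class EquationSpec:
    """One registered prediction equation.

    ``coefficients`` are ordered: for speed/grade forms the (resting,
    horizontal, vertical) triple; for protocol-time polynomials the
    polynomial coefficients, constant term first.
    """

    name: str
    kind: EquationKind
    coefficients: tuple[float, ...]
    valid_range: dict[str, tuple[float, float]]
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.kind is EquationKind.PROTOCOL_TIME_POLY:
            if len(self.coefficients) < 1:
                raise DomainError(f"equation {self.name!r}: needs >= 1 coefficient")
        elif len(self.coefficients) != 3:
            raise DomainError(
                f"equation {self.name!r}: speed/grade forms take exactly the "
                f"(resting, horizontal, vertical) coefficient triple, "
                f"got {len(self.coefficients)}"
            )


class EquationRegistry:
    """Name-keyed collection of :class:`EquationSpec`."""

    def __init__(self, specs: dict[str, EquationSpec]):
        self._specs = dict(specs)

    def __getitem__(self, name: str) -> EquationSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise RegistryError(
                f"unknown equation {name!r}; available: "
                f"{', '.join(sorted(self._specs))}"
            ) from None

    def __iter__(self):
        return iter(self._specs.values())

    def names(self) -> list[str]:
        return sorted(self._specs)


def load_registry(path: str | Path | None = None) -> EquationRegistry:
    """Load an equation registry from JSON (the packaged default if no path)."""
    if path is None:
        src = resources.files("hrindex.data") / "equations.json"
        raw = json.loads(src.read_text(encoding="utf-8"))
    else:
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
    specs = {
        name: EquationSpec(
            name=name,
            kind=EquationKind(entry["kind"]),
            coefficients=tuple(float(c) for c in entry["coefficients"]),
            valid_range={k: (float(v[0]), float(v[1]))
                         for k, v in entry.get("valid_range", {}).items()},
            source_note=entry.get("source_note", ""),
        )
        for name, entry in raw.items()
    }
    return EquationRegistry(specs)


def _check_speed_grade(speed: float, grade: float) -> None:
    if speed < 0:
        raise DomainError(f"speed must be >= 0 m/min, got {speed!r}")
    if not 0 <= grade <= 0.4:
        raise DomainError(
            f"grade must be a fraction in [0, 0.4] (0.10 = 10%), got {grade!r}"
        )


def _speed_grade(speed: float, grade: float,
                 coeffs: tuple[float, float, float]) -> float:
    resting, horiz, vert = coeffs
    return resting + horiz * speed + vert * speed * grade


def vo2_walk(speed: float, grade: float,
             coefficients: tuple[float, float, float] = (3.5, 0.1, 1.8)) -> float:
    """Predicted walking VO2 (mL O2·kg⁻¹·min⁻¹) from speed and grade.

    ``resting + horizontal*speed + vertical*speed*grade``; at zero speed
    this reduces to the 3.5 mL resting value (1 MET). Speed in m·min⁻¹,
    grade a fraction in [0, 0.4].
    """
    _check_speed_grade(speed, grade)
    return _speed_grade(speed, grade, coefficients)


def vo2_run(speed: float, grade: float,
            coefficients: tuple[float, float, float] = (3.5, 0.2, 0.9)) -> float:
    """Predicted running VO2 (mL O2·kg⁻¹·min⁻¹) from speed and grade.

    Same linear form as :func:`vo2_walk` with the running coefficient
    triple: a larger horizontal cost and roughly half the vertical cost
    (running partially airborne lifts the body less per metre climbed).
    """
    _check_speed_grade(speed, grade)
    return _speed_grade(speed, grade, coefficients)


def vo2_from_protocol_time(spec: EquationSpec, minutes: float) -> float:
    """Predicted VO2 from total time on a staged protocol.

    Evaluates the polynomial in ``minutes`` with ``spec.coefficients``
    (constant term first, Horner scheme). ``minutes`` must lie within the
    spec's declared valid range, over which shipped polynomials are
    monotone nondecreasing.
    """
    if spec.kind is not EquationKind.PROTOCOL_TIME_POLY:
        raise DomainError(f"equation {spec.name!r} is not a protocol-time polynomial")
    lo, hi = spec.valid_range.get("minutes", (float("-inf"), float("inf")))
    if not lo <= minutes <= hi:
        raise DomainError(
            f"time {minutes} min outside valid range [{lo}, {hi}] of {spec.name!r}"
        )
    acc = 0.0
    for c in reversed(spec.coefficients):
        acc = acc * minutes + c
    return acc


def handrail_adjust(vo2_predicted: float, support: RailSupport | str,
                    overprediction_pct: float) -> float:
    """Correct an equation-predicted VO2 for handrail support.

    Rail support inflates the prediction by ``overprediction_pct`` percent;
    the correction divides it back out: ``vo2 / (1 + pct/100)``. Tests with
    support explicitly not permitted are returned unchanged. Exact inverse
    of multiplying by ``1 + pct/100``.
    """
    if not 0 <= overprediction_pct <= 100:
        raise DomainError(
            f"overprediction_pct must lie in [0, 100], got {overprediction_pct!r}"
        )
    if RailSupport(support) is RailSupport.NOT_PERMITTED:
        return vo2_predicted
    return vo2_predicted / (1.0 + overprediction_pct / 100.0)
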