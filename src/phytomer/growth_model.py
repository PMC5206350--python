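"""Closed-form kinetics of phytomer elongation.

A phytomer (the repeating blade/sheath/internode unit of a grass tiller)
elongates along a sigmoidal time course.  This module holds the fitted
curve objects used throughout the package, the piecewise rule that splits
total phytomer length into blade, sheath and internode contributions, and
linear thermal-time conversion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

__all__ = [
    "SigmoidCurve",
    "LinearCurve",
    "PartitionThresholds",
    "CoordinationRuleSet",
    "ThermalTimeSpec",
    "eval_sigmoid",
    "invert_sigmoid",
    "partition_components",
    "thermal_time",
    "default_rules",
]


class InvalidCurveError(ValueError):
    """Raised for non-positive amplitude or scale parameters."""


@dataclass(frozen=True)
class SigmoidCurve:
    """Two/three-parameter logistic ``y = a / (1 + exp((x0 - x) / b))``.

    Parameters
    ----------
    amplitude : float
        Upper asymptote ``a`` (> 0).  1 for curves of fraction of final
        length vs time; may differ from 1 for empirical regressions.
    midpoint : float
        Abscissa ``x0`` at which y = a/2 (units of the abscissa:
        days after tip emergence, or fraction of final length).
    scale : float
        Steepness parameter ``b`` (> 0, same units as the abscissa).
    """

    amplitude: float
    midpoint: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.amplitude > 0):
            raise InvalidCurveError(f"amplitude must be > 0, got {self.amplitude}")
        if not (self.scale > 0):
            raise InvalidCurveError(f"scale must be > 0, got {self.scale}")

    def __call__(self, x):
        return eval_sigmoid(self, x)

    def inverse(self, y: float) -> float:
        return invert_sigmoid(self, y)


@dataclass(frozen=True)
class LinearCurve:
    """Straight line ``y = slope * x + intercept`` on x in [0, 1]."""

    slope: float
    intercept: float

    def __call__(self, x):
        return self.slope * x + self.intercept


def eval_sigmoid(curve: SigmoidCurve, x):
    """Evaluate the logistic curve at ``x`` (scalar or array).

    Always strictly between 0 and the amplitude for finite ``x``, and
    exactly a/2 at the midpoint.
    """
    import numpy as np

    z = (curve.midpoint - np.asarray(x, dtype=float)) / curve.scale
    out = curve.amplitude / (1.0 + np.exp(z))
    if out.ndim == 0:
        return float(out)
    return out


def invert_sigmoid(curve: SigmoidCurve, y: float) -> float:
    """Abscissa at which the curve attains ``y``: ``x0 - b ln(a/y - 1)``.

    Raises
    ------
    ValueError
        If ``y`` is outside the open interval (0, a).
    """
    if not (0.0 < y < curve.amplitude):
        raise ValueError(
            f"y={y} outside the open range (0, {curve.amplitude}) of the curve"
        )
    return curve.midpoint - curve.scale * math.log(curve.amplitude / y - 1.0)


@dataclass(frozen=True)
class PartitionThresholds:
    """Break points of the blade/sheath/internode partition rule.

    All values are fractions of final phytomer length.  ``sheath_onset``:
    below it elongation is blade only.  ``blade_stop_phytomer_fraction``:
    phytomer fraction at which the blade stops elongating, having reached
    ``blade_final_fraction`` of final phytomer length.  ``internode_onset``:
    phytomer fraction at which internode elongation begins (and sheath
    elongation ends).
    """

    sheath_onset: float = 0.50
    blade_stop_phytomer_fraction: float = 0.75
    blade_final_fraction: float = 0.66
    internode_onset: float = 0.80

    def __post_init__(self) -> None:
        ok = (
            0.0
            < self.sheath_onset
            < self.blade_stop_phytomer_fraction
            < self.internode_onset
            < 1.0
        ) and self.blade_final_fraction < self.blade_stop_phytomer_fraction
        if not ok:
            raise ValueError(f"inconsistent partition thresholds: {self}")

    @property
    def sheath_final_fraction(self) -> float:
        """Final sheath share of phytomer length (0.14 by default)."""
        return self.internode_onset - self.blade_final_fraction

    @property
    def internode_final_fraction(self) -> float:
        """Final internode share of phytomer length (0.20 by default)."""
        return 1.0 - self.internode_onset


def partition_components(f, thresholds: PartitionThresholds | None = None):
    """Split fraction-of-final-length ``f`` into (blade, sheath, internode).

    The rule follows the observed elongation sequence: blade only up to
    ``sheath_onset``; blade rising linearly to its final share while the
    sheath takes up the remainder, until the blade stops; sheath only up to
    ``internode_onset``; internode thereafter.  The pieces are continuous
    and conserve ``f`` exactly.  Accepts scalars or numpy arrays.
    """
    import numpy as np

    t = thresholds or PartitionThresholds()
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0 + 1e-12):
        raise ValueError(f"fraction of final length must be in [0, 1], got {f}")
    arr = np.minimum(arr, 1.0)

    # blade share per piece
    w = (arr - t.sheath_onset) / (t.blade_stop_phytomer_fraction - t.sheath_onset)
    blade_mid = t.sheath_onset + w * (t.blade_final_fraction - t.sheath_onset)
    blade = np.where(
        arr <= t.sheath_onset,
        arr,
        np.where(
            arr <= t.blade_stop_phytomer_fraction, blade_mid, t.blade_final_fraction
        ),
    )
    internode = np.maximum(arr - t.internode_onset, 0.0)
    sheath = arr - blade - internode
    if arr.ndim == 0:
        return (float(blade), float(sheath), float(internode))
    return (blade, sheath, internode)


@dataclass(frozen=True)
class ThermalTimeSpec:
    """Constant-temperature degree-day accumulation."""

    air_temperature: float = 25.0
    base_temperature: float = 0.0


def thermal_time(duration_days: float, spec: ThermalTimeSpec) -> float:
    """Degree days accumulated over ``duration_days`` at constant temperature.

    The daily contribution is floored at zero (no negative accumulation
    when air temperature is at or below base temperature).
    """
    if duration_days < 0:
        raise ValueError(f"duration must be >= 0, got {duration_days}")
    per_day = max(spec.air_temperature - spec.base_temperature, 0.0)
    return duration_days * per_day


@dataclass(frozen=True)
class CoordinationRuleSet:
    """The five fitted coordination curves, with their published defaults.

    ``blade_curve``, ``sheath_curve`` and ``internode_curve`` describe
    component contributions vs fraction of final phytomer length;
    ``between_phytomer_curve`` relates fractions of two successive
    phytomers; ``complete_timecourse`` gives fraction of final length vs
    days after tip emergence.
    """

    blade_curve: SigmoidCurve = field(
        default_factory=lambda: SigmoidCurve(0.73, 0.37, 0.17)
    )
    sheath_curve: SigmoidCurve = field(
        default_factory=lambda: SigmoidCurve(0.46, 0.94, 0.13)
    )
    internode_curve: LinearCurve = field(
        default_factory=lambda: LinearCurve(0.04, -0.0063)
    )
    between_phytomer_curve: SigmoidCurve = field(
        default_factory=lambda: SigmoidCurve(1.34, 0.91, 0.24)
    )
    complete_timecourse: SigmoidCurve = field(
        default_factory=lambda: SigmoidCurve(1.0, 1.82, 1.81)
    )

    def to_dict(self) -> dict:
        out: dict[str, dict] = {}
        for name in (
            "blade_curve",
            "sheath_curve",
            "internode_curve",
            "between_phytomer_curve",
            "complete_timecourse",
        ):
            c = getattr(self, name)
            if isinstance(c, SigmoidCurve):
                out[name] = {"a": c.amplitude, "x0": c.midpoint, "b": c.scale}
            else:
                out[name] = {"slope": c.slope, "intercept": c.intercept}
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CoordinationRuleSet":
        kwargs = {}
        for name, params in d.items():
            if "slope" in params:
                kwargs[name] = LinearCurve(params["slope"], params["intercept"])
            else:
                kwargs[name] = SigmoidCurve(params["a"], params["x0"], params["b"])
        return cls(**kwargs)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CoordinationRuleSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_rules() -> CoordinationRuleSet:
    """Rule set carrying the published curve parameters."""
    return CoordinationRuleSet()
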