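"""Strain measurement, cyclic-response summaries, and voltage-strain calibration.

Covers the bench-side arithmetic of the stretcher characterization: radial
strain from electrode-edge point pairs, percent linear strain, per-cycle
max/min/difference summaries of cyclic actuation traces, and ordinary
least-squares fitting of the linear strain-vs-voltage calibration line
(percent strain against kV).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RadiusMeasurement",
    "CalibrationLine",
    "StrainTrace",
    "DEFAULT_CALIBRATION",
    "radius_from_points",
    "radial_strain",
    "linear_strain_percent",
    "summarize_cycles",
    "fit_linear_calibration",
]


@dataclass(frozen=True)
class RadiusMeasurement:
    """Two diametrically opposite electrode-edge points plus the rest radius.

    ``point_a``/``point_b`` are planar coordinates in mm; ``r0`` is the
    pre-actuation electrode radius in mm.
    """

    point_a: tuple[float, float]
    point_b: tuple[float, float]
    r0: float

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")
        if tuple(self.point_a) == tuple(self.point_b):
            raise ValueError("points must be distinct")

    @property
    def radius(self) -> float:
        return radius_from_points(self.point_a, self.point_b)

    @property
    def strain(self) -> float:
        return radial_strain(self.r0, self.radius)


@dataclass(frozen=True)
class CalibrationLine:
    """Linear strain-vs-voltage calibration, percent strain per kV.

    The built-in default is the device's fitted line y = 1.7 x - 0.85
    (x in kV, y in percent strain), valid on 0.5-5 kV.  Evaluation below
    the line's zero crossing would give negative strain; ``evaluate``
    clamps to zero and warns when any voltage falls outside
    ``valid_range``.
    """

    slope: float = 1.7
    intercept: float = -0.85
    valid_range: tuple[float, float] = (0.5, 5.0)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError(f"invalid valid_range {self.valid_range}")

    def evaluate(self, voltage_kv):
        """Percent strain at ``voltage_kv`` (kV), clamped at 0 from below."""
        v = np.asarray(voltage_kv, dtype=float)
        lo, hi = self.valid_range
        if np.any(v < lo) or np.any(v > hi):
            warnings.warn(
                f"voltage outside the calibrated range {self.valid_range} kV; "
                "strain clamped at 0 from below",
                stacklevel=2,
            )
        out = np.maximum(self.slope * v + self.intercept, 0.0)
        return float(out) if out.ndim == 0 else out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "valid_range": list(self.valid_range),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CalibrationLine":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(d["slope"], d["intercept"], tuple(d["valid_range"]))


DEFAULT_CALIBRATION = CalibrationLine()


@dataclass(frozen=True)
class StrainTrace:
    """Uniformly sampled strain (or any scalar) time series with a unit tag."""

    time: np.ndarray
    strain: np.ndarray
    sample_rate: float
    unit: str = "percent"  # "percent" or "fraction"

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "strain", np.asarray(self.strain, dtype=float))
        if self.time.shape != self.strain.shape:
            raise ValueError("time and strain must have the same shape")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.unit not in ("percent", "fraction"):
            raise ValueError(f"unknown unit tag {self.unit!r}")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-12):
                raise ValueError("time grid is not uniform at sample_rate")

    def as_percent(self) -> "StrainTrace":
        if self.unit == "percent":
            return self
        return StrainTrace(self.time, self.strain * 100.0, self.sample_rate, "percent")


def radius_from_points(a: Sequence[float], b: Sequence[float]) -> float:
    """Electrode radius (mm) as half the distance between opposite edge points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = float(np.linalg.norm(a - b))
    if d == 0.0:
        raise ValueError("points are coincident")
    return d / 2.0


def radial_strain(r0: float, r: float) -> float:
    """Engineering radial strain (r - r0) / r0."""
    if r0 <= 0:
        raise ValueError(f"r0 must be positive, got {r0}")
    return (r - r0) / r0


def linear_strain_percent(eps) -> float:
    """Dimensionless strain expressed in percent (eps * 100)."""
    out = np.asarray(eps, dtype=float) * 100.0
    return float(out) if out.ndim == 0 else out


def _cycle_slices(values: np.ndarray) -> list[slice]:
    """Split a cyclic trace at rising mid-level crossings with hysteresis.

    The threshold is the mid-level of the trace with a hysteresis band of
    5% of the range, which keeps the detector stable on drifting square
    waves.  Returns one slice per complete cycle (rising edge to rising
    edge).
    """
    vmin, vmax = float(np.min(values)), float(np.max(values))
    rng = vmax - vmin
    if rng <= 0:
        return []
    mid = 0.5 * (vmin + vmax)
    hyst = 0.05 * rng
    hi_th, lo_th = mid + 0.5 * hyst, mid - 0.5 * hyst

    edges = []
    armed = values[0] < lo_th
    for i in range(1, len(values)):
        v = values[i]
        if armed and v >= hi_th:
            edges.append(i)
            armed = False
        elif not armed and v <= lo_th:
            armed = True
    return [slice(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]


def summarize_cycles(trace: StrainTrace, window_s: float | None = None):
    """Average per-cycle maximum, minimum and their difference.

    Cycles are detected by rising mid-level threshold crossings within the
    trailing ``window_s`` seconds of the trace (the whole trace when
    ``window_s`` is None).  Returns ``(avg_max, avg_min, avg_diff)`` in the
    trace's unit; ``avg_diff`` equals ``avg_max - avg_min`` exactly by
    linearity of the mean.  Raises ``ValueError`` when no complete cycle
    is found.
    """
    values = trace.strain
    time = trace.time
    if window_s is not None:
        mask = time >= time[-1] - window_s
        values = values[mask]
    if values.size == 0:
        raise ValueError("empty analysis window")

    cycles = _cycle_slices(values)
    if not cycles:
        raise ValueError("no complete cycle detected in the window")

    maxima = np.array([np.max(values[s]) for s in cycles])
    minima = np.array([np.min(values[s]) for s in cycles])
    avg_max = float(np.mean(maxima))
    avg_min = float(np.mean(minima))
    return avg_max, avg_min, avg_max - avg_min


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration line plus fit diagnostics."""

    line: CalibrationLine
    r_squared: float
    residual_se: float
    slope_se: float
    intercept_se: float
    n: int

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for the slope from the t distribution."""
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return (
            self.line.slope - tcrit * self.slope_se,
            self.line.slope + tcrit * self.slope_se,
        )


def fit_linear_calibration(
    voltages_kv: Sequence[float],
    strains_percent: Sequence[float],
    valid_range: tuple[float, float] | None = None,
) -> CalibrationFit:
    """Fit the strain-vs-voltage line by unweighted ordinary least squares.

    ``voltages_kv`` in kV, ``strains_percent`` in percent.  Needs at least
    two distinct voltages.  The fitted line's ``valid_range`` defaults to
    the span of the input voltages.
    """
    v = np.asarray(voltages_kv, dtype=float)
    y = np.asarray(strains_percent, dtype=float)
    if v.shape != y.shape:
        raise ValueError("voltages and strains must have equal length")
    if np.unique(v).size < 2:
        raise ValueError("need at least two distinct voltages")

    res = stats.linregress(v, y)
    n = v.size
    resid = y - (res.slope * v + res.intercept)
    dof = max(n - 2, 1)
    residual_se = float(np.sqrt(np.sum(resid**2) / dof))
    if valid_range is None:
        valid_range = (float(np.min(v)), float(np.max(v)))
    line = CalibrationLine(res.slope, res.intercept, valid_range)
    return CalibrationFit(
        line=line,
        r_squared=float(res.rvalue**2),
        residual_se=residual_se,
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        n=n,
    )
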