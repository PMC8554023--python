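"""Double-angle vector algebra for cylindrical astigmatism.

Clinical astigmatism is a cylinder power (diopters) at a meridian (degrees,
TABO convention, half-open interval [0, 180)).  Because a meridian of 180°
is the same meridian as 0°, cylinders do not add componentwise in polar
form.  The standard fix is the double-angle representation: a cylinder
``m @ θ`` maps to the Cartesian vector ``(m·cos 2θ, m·sin 2θ)``, in which
sums, differences and centroids are ordinary vector arithmetic and axes 0°
and 180° coincide.  Every arithmetic operation in this package passes
through this one representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Astigmatism",
    "DoubleAngleVector",
    "MagnitudeStats",
    "to_double_angle",
    "from_double_angle",
    "vector_add",
    "vector_diff",
    "negate",
    "centroid",
    "absolute_error_stats",
]

#: Period of the cylinder axis in degrees (meridians, not full angles).
AXIS_PERIOD = 180.0


@dataclass(frozen=True)
class Astigmatism:
    """A cylinder of ``magnitude`` diopters at ``axis`` degrees.

    The axis is normalized into [0, 180); an input of exactly 180 becomes 0.
    A zero-magnitude cylinder has the canonical axis 0 so that equality is
    well defined.
    """

    magnitude: float
    axis: float = 0.0

    def __post_init__(self) -> None:
        m = float(self.magnitude)
        a = float(self.axis)
        if not math.isfinite(m) or not math.isfinite(a):
            raise ValueError("magnitude and axis must be finite")
        if m < 0:
            raise ValueError(f"cylinder magnitude must be >= 0, got {m}")
        a = a % AXIS_PERIOD
        if m == 0.0:
            a = 0.0
        object.__setattr__(self, "magnitude", m)
        object.__setattr__(self, "axis", a)

    def __str__(self) -> str:  # clinical "D @ degree" notation
        return f"{self.magnitude:.2f} D @ {self.axis:.0f}"

    def isclose(self, other: "Astigmatism", tol: float = 1e-9) -> bool:
        """Closeness in double-angle space (handles the 0/180 wrap)."""
        d = vector_diff(self, other)
        return d.magnitude <= tol


@dataclass(frozen=True)
class DoubleAngleVector:
    """Cartesian double-angle form ``(m·cos 2θ, m·sin 2θ)`` in diopters."""

    x: float
    y: float

    def __add__(self, other: "DoubleAngleVector") -> "DoubleAngleVector":
        return DoubleAngleVector(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "DoubleAngleVector") -> "DoubleAngleVector":
        return DoubleAngleVector(self.x - other.x, self.y - other.y)

    def __neg__(self) -> "DoubleAngleVector":
        return DoubleAngleVector(-self.x, -self.y)


def to_double_angle(a: Astigmatism) -> DoubleAngleVector:
    """Map ``m @ θ`` to ``(m·cos 2θ, m·sin 2θ)``."""
    t = 2.0 * math.radians(a.axis)
    return DoubleAngleVector(a.magnitude * math.cos(t), a.magnitude * math.sin(t))


def from_double_angle(v: DoubleAngleVector) -> Astigmatism:
    """Inverse of :func:`to_double_angle`; the zero vector maps to 0 D @ 0."""
    m = math.hypot(v.x, v.y)
    if m == 0.0:
        return Astigmatism(0.0, 0.0)
    axis = math.degrees(0.5 * math.atan2(v.y, v.x)) % AXIS_PERIOD
    return Astigmatism(m, axis)


def vector_add(a: Astigmatism, b: Astigmatism) -> Astigmatism:
    return from_double_angle(to_double_angle(a) + to_double_angle(b))


def vector_diff(a: Astigmatism, b: Astigmatism) -> Astigmatism:
    return from_double_angle(to_double_angle(a) - to_double_angle(b))


def negate(a: Astigmatism) -> Astigmatism:
    """The additive inverse: same magnitude rotated 90° (axes are meridians)."""
    return from_double_angle(-to_double_angle(a))


def centroid(vs: Sequence[Astigmatism] | Iterable[Astigmatism]) -> Astigmatism:
    """Componentwise mean in double-angle space, converted back to polar.

    By the triangle inequality its magnitude never exceeds the mean input
    magnitude, with equality iff all axes coincide.
    """
    vs = list(vs)
    if not vs:
        raise ValueError("centroid of an empty collection is undefined")
    xs = np.array([to_double_angle(a).x for a in vs])
    ys = np.array([to_double_angle(a).y for a in vs])
    return from_double_angle(DoubleAngleVector(float(xs.mean()), float(ys.mean())))


@dataclass(frozen=True)
class MagnitudeStats:
    """Summary of a distribution of absolute (magnitude-only) errors."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


def absolute_error_stats(vs: Sequence[Astigmatism] | Iterable[Astigmatism]) -> MagnitudeStats:
    """Mean ± SD and median (IQR) of cylinder magnitudes, axes ignored.

    SD uses the n−1 denominator; for a single observation it is NaN.
    """
    mags = np.array([a.magnitude for a in vs], dtype=float)
    if mags.size == 0:
        raise ValueError("absolute_error_stats of an empty collection is undefined")
    sd = float(mags.std(ddof=1)) if mags.size > 1 else float("nan")
    q1, med, q3 = np.percentile(mags, [25.0, 50.0, 75.0])
    return MagnitudeStats(
        n=int(mags.size),
        mean=float(mags.mean()),
        sd=sd,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )
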