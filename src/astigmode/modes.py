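"""Ring/zone keratometric extraction on a sampled corneal power map.

A Scheimpflug-style device reports corneal astigmatism for many analysis
modes: the measurement region is a *ring* (points on a circle of a given
diameter) or a *zone* (all points within that diameter), centered on either
the corneal apex or the pupil center, at diameters of 2, 3, 4 and 5 mm —
sixteen combinations in all.  This module emulates that extraction on a
polar grid of total refractive power samples.

The per-mode astigmatism is obtained by weighted least squares of the
standard keratometric sinusoid

    K(θ) = a0 + a1·cos 2θ + a2·sin 2θ

over the selected samples; cylinder = 2·√(a1² + a2²) (steep minus flat
power) at the steep meridian ½·atan2(a2, a1).  The device's internal
algorithm is proprietary; this sinusoidal fit is the standard keratometric
model and is an emulation, not a device clone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .core import Astigmatism

__all__ = [
    "CornealPowerMap",
    "ModeSpec",
    "ALL_MODES",
    "sample_points",
    "fit_astigmatism",
    "extract_all_modes",
]

GEOMETRIES = ("ring", "zone")
CENTERS = ("apex", "pupil")
DIAMETERS_MM = (2.0, 3.0, 4.0, 5.0)

POWER_MIN_D, POWER_MAX_D = 20.0, 70.0


@dataclass
class CornealPowerMap:
    """Total refractive power sampled on an apex-centered polar grid.

    radii
        Strictly increasing radii in mm, uniform step (≤ 0.1 mm), starting
        at 0 and covering at least 4.5 mm.
    angles_deg
        Uniform meridian grid in degrees covering [0, 360) (step ≤ 1°).
    power
        Array of shape ``(len(radii), len(angles_deg))`` in diopters.
    pupil_offset_mm
        ``(dx, dy)`` of the pupil center relative to the apex, mm, in
        right-eye-view Cartesian coordinates (x = cos θ, y = sin θ).
    pupil_diameter_mm
        Entrance-pupil diameter, mm (carried metadata; not used for
        sampling geometry).
    """

    radii: np.ndarray
    angles_deg: np.ndarray
    power: np.ndarray
    pupil_offset_mm: tuple[float, float] = (0.0, 0.0)
    pupil_diameter_mm: float = 3.0

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.radii.size, self.angles_deg.size):
            raise ValueError(
                f"power shape {self.power.shape} does not match grid "
                f"({self.radii.size}, {self.angles_deg.size})"
            )
        dr = np.diff(self.radii)
        dt = np.diff(self.angles_deg)
        if self.radii.size < 2 or not np.allclose(dr, dr[0]) or dr[0] <= 0:
            raise ValueError("radii must be a uniform, increasing grid")
        if self.angles_deg.size < 3 or not np.allclose(dt, dt[0]) or dt[0] <= 0:
            raise ValueError("angles must be a uniform, increasing grid")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("power map contains non-finite values")
        if self.power.min() <= POWER_MIN_D or self.power.max() >= POWER_MAX_D:
            raise ValueError(
                f"power values outside the physiologic window "
                f"({POWER_MIN_D}, {POWER_MAX_D}) D"
            )

    @property
    def dr(self) -> float:
        return float(self.radii[1] - self.radii[0])

    @property
    def dtheta_deg(self) -> float:
        return float(self.angles_deg[1] - self.angles_deg[0])

    def nearest_angle_index(self, angle_deg: float) -> int:
        return int(round((angle_deg % 360.0) / self.dtheta_deg)) % self.angles_deg.size

    def nearest_radius_index(self, r_mm: float) -> int:
        i = int(round((r_mm - self.radii[0]) / self.dr))
        return min(max(i, 0), self.radii.size - 1)

    def power_at(self, r_mm: float, angle_deg: float) -> float:
        """Power at the grid node nearest to (r, θ) in apex-polar coordinates."""
        return float(self.power[self.nearest_radius_index(r_mm), self.nearest_angle_index(angle_deg)])

    # ---- serialization: long CSV + JSON sidecar ---------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the map as long-format CSV (radius_mm, angle_deg, power_D)
        plus a ``<stem>.json`` sidecar for the pupil metadata."""
        path = Path(path)
        rr, tt = np.meshgrid(self.radii, self.angles_deg, indexing="ij")
        pd.DataFrame(
            {"radius_mm": rr.ravel(), "angle_deg": tt.ravel(), "power_D": self.power.ravel()}
        ).to_csv(path, index=False)
        sidecar = {
            "pupil_offset_mm": list(self.pupil_offset_mm),
            "pupil_diameter_mm": self.pupil_diameter_mm,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CornealPowerMap":
        path = Path(path)
        df = pd.read_csv(path)
        radii = np.sort(df["radius_mm"].unique())
        angles = np.sort(df["angle_deg"].unique())
        power = (
            df.pivot(index="radius_mm", columns="angle_deg", values="power_D")
            .reindex(index=radii, columns=angles)
            .to_numpy()
        )
        if np.isnan(power).any():
            raise ValueError(f"{path}: incomplete polar grid (missing nodes)")
        meta_path = path.with_suffix(".json")
        offset, pupil_d = (0.0, 0.0), 3.0
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            offset = tuple(meta.get("pupil_offset_mm", offset))
            pupil_d = float(meta.get("pupil_diameter_mm", pupil_d))
        return cls(radii, angles, power, offset, pupil_d)


@dataclass(frozen=True)
class ModeSpec:
    """One of the 16 analysis modes: ring|zone × apex|pupil × 2/3/4/5 mm."""

    geometry: str
    center: str
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}")
        if self.center not in CENTERS:
            raise ValueError(f"center must be one of {CENTERS}, got {self.center!r}")
        if float(self.diameter_mm) not in DIAMETERS_MM:
            raise ValueError(f"diameter must be one of {DIAMETERS_MM} mm, got {self.diameter_mm}")
        object.__setattr__(self, "diameter_mm", float(self.diameter_mm))

    @property
    def key(self) -> str:
        """Stable column-key form, e.g. ``zone_apex_3mm``."""
        return f"{self.geometry}_{self.center}_{int(self.diameter_mm)}mm"

    @classmethod
    def from_key(cls, key: str) -> "ModeSpec":
        geometry, center, dia = key.split("_")
        return cls(geometry, center, float(dia.removesuffix("mm")))


def _iter_modes() -> Iterator[ModeSpec]:
    for g in GEOMETRIES:
        for c in CENTERS:
            for d in DIAMETERS_MM:
                yield ModeSpec(g, c, d)


ALL_MODES: tuple[ModeSpec, ...] = tuple(_iter_modes())


def _recenter(cmap: CornealPowerMap, spec: ModeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Radius and meridian of every grid node about the mode's center.

    Exact Euclidean geometry on the existing nodes: powers stay attached to
    their nodes, only the coordinates are re-expressed (no resampling).
    """
    rr, tt = np.meshgrid(cmap.radii, np.radians(cmap.angles_deg), indexing="ij")
    if spec.center == "apex" or cmap.pupil_offset_mm == (0.0, 0.0):
        # no shift: keep the exact grid coordinates (a Cartesian round trip
        # would let rounding split boundary rings across the selection edge)
        return rr, np.degrees(tt)
    x = rr * np.cos(tt) - cmap.pupil_offset_mm[0]
    y = rr * np.sin(tt) - cmap.pupil_offset_mm[1]
    return np.hypot(x, y), np.degrees(np.arctan2(y, x))


def resample_to_pupil(cmap: CornealPowerMap) -> CornealPowerMap:
    """Bilinearly resample the map onto a polar grid centered at the pupil.

    Optional alternative to the default no-resampling recentering; the
    angular coordinate is padded periodically before interpolation.
    """
    angles_pad = np.concatenate([cmap.angles_deg, [cmap.angles_deg[0] + 360.0]])
    power_pad = np.concatenate([cmap.power, cmap.power[:, :1]], axis=1)
    interp = RegularGridInterpolator(
        (cmap.radii, angles_pad), power_pad, bounds_error=False, fill_value=None
    )
    dx, dy = cmap.pupil_offset_mm
    rr, tt = np.meshgrid(cmap.radii, np.radians(cmap.angles_deg), indexing="ij")
    x = rr * np.cos(tt) + dx
    y = rr * np.sin(tt) + dy
    r_src = np.hypot(x, y)
    t_src = np.degrees(np.arctan2(y, x)) % 360.0
    power = interp(np.stack([r_src.ravel(), t_src.ravel()], axis=1)).reshape(rr.shape)
    return CornealPowerMap(
        cmap.radii.copy(), cmap.angles_deg.copy(), power, (0.0, 0.0), cmap.pupil_diameter_mm
    )


def sample_points(
    cmap: CornealPowerMap,
    spec: ModeSpec,
    ring_tolerance_mm: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Select the grid samples a mode analyzes.

    Returns ``(radius, meridian_deg, power, weight)`` arrays, all about the
    mode's center.  Ring mode keeps nodes within ``ring_tolerance_mm``
    (default: half the radial grid step) of the ring radius, weight 1; zone
    mode keeps nodes with recentered radius ≤ diameter/2, weighted by the
    node's polar area element r·Δr·Δθ.
    """
    half = spec.diameter_mm / 2.0
    shift = math.hypot(*cmap.pupil_offset_mm) if spec.center == "pupil" else 0.0
    if half + shift > cmap.radii[-1] + cmap.dr / 2.0:
        raise ValueError(
            f"mode {spec.key}: region (radius {half} mm about the {spec.center}, "
            f"offset {shift:.2f} mm) exceeds the map extent {cmap.radii[-1]} mm"
        )
    r_c, t_c = _recenter(cmap, spec)
    if spec.geometry == "ring":
        tol = cmap.dr / 2.0 if ring_tolerance_mm is None else ring_tolerance_mm
        mask = np.abs(r_c - half) <= tol + 1e-9
        weight = np.ones(cmap.power.shape)
    else:
        mask = r_c <= half + 1e-9
        # area element of each node in its own (original, apex-polar) grid
        rr = np.meshgrid(cmap.radii, cmap.angles_deg, indexing="ij")[0]
        weight = rr * cmap.dr * math.radians(cmap.dtheta_deg)
    return r_c[mask], t_c[mask], cmap.power[mask], weight[mask]


def fit_astigmatism(
    meridians_deg: np.ndarray,
    powers: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[Astigmatism, float]:
    """Weighted least-squares keratometric sinusoid fit.

    Returns the fitted cylinder (2× the sinusoid amplitude, at the steep
    meridian) and the mean power ``a0``.  Requires samples on at least 3
    distinct meridians (mod 180°) or the design is rank deficient.
    """
    meridians_deg = np.asarray(meridians_deg, dtype=float)
    powers = np.asarray(powers, dtype=float)
    if meridians_deg.size == 0:
        raise ValueError("no samples to fit")
    distinct = np.unique(np.round(meridians_deg % 180.0, 6))
    if distinct.size < 3:
        raise ValueError(
            f"rank-deficient keratometric fit: samples span only {distinct.size} "
            "distinct meridians (need >= 3)"
        )
    t2 = 2.0 * np.radians(meridians_deg)
    design = np.column_stack([np.ones_like(t2), np.cos(t2), np.sin(t2)])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        design = design * w[:, None]
        powers = powers * w
    (a0, a1, a2), *_ = np.linalg.lstsq(design, powers, rcond=None)
    magnitude = 2.0 * math.hypot(a1, a2)
    axis = math.degrees(0.5 * math.atan2(a2, a1)) % 180.0
    return Astigmatism(magnitude, axis if magnitude > 0 else 0.0), float(a0)


def extract_mode(
    cmap: CornealPowerMap,
    spec: ModeSpec,
    ring_tolerance_mm: float | None = None,
    interpolation: str = "none",
) -> tuple[Astigmatism, float]:
    """Astigmatism and mean power for a single analysis mode."""
    if interpolation == "bilinear" and spec.center == "pupil":
        cmap = resample_to_pupil(cmap)
        spec = ModeSpec(spec.geometry, "apex", spec.diameter_mm)
    elif interpolation not in ("none", "bilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    _, t_c, p, w = sample_points(cmap, spec, ring_tolerance_mm)
    return fit_astigmatism(t_c, p, w)


def extract_all_modes(
    cmap: CornealPowerMap,
    ring_tolerance_mm: float | None = None,
    interpolation: str = "none",
) -> dict[ModeSpec, Astigmatism]:
    """The 16 per-mode astigmatism values for one map (deterministic)."""
    return {
        spec: extract_mode(cmap, spec, ring_tolerance_mm, interpolation)[0]
        for spec in ALL_MODES
    }
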