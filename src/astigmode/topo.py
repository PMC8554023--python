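"""Bowtie-pattern classification of corneal topography.

Astigmatic corneas show a "bowtie" of two steep lobes on the power map.
Eyes are classified *asymmetric* when any keratoconus-screening marker
exceeds its threshold — inferior–superior index I-S > 1.5 D, superior–
inferior index S-I > 2.5 D, or skewed radial axis index SRAX > 22° (strict
inequalities) — and *symmetric* otherwise.  Symmetric bowties are further
typed by their tip-to-tip diameter: A (small, ≤ 5 mm), B (medium,
5 < d ≤ 7 mm), C (large, > 7 mm), measured here with a 0.25 D power
contrast against the flat meridian, mirroring the clinical reading of a
color map with 0.25 D increments.  Total corneal irregular astigmatism
(μm) is graded mild (< 0.3), moderate (0.3 ≤ v < 0.5) or severe (≥ 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .modes import CornealPowerMap, ModeSpec, sample_points, fit_astigmatism

__all__ = [
    "TopographyIndices",
    "NoBowtieError",
    "compute_indices",
    "classify_symmetry",
    "bowtie_diameter",
    "classify_bowtie_type",
    "classify_irregularity",
    "classify_map",
]

IS_THRESHOLD_D = 1.5
SI_THRESHOLD_D = 2.5
SRAX_THRESHOLD_DEG = 22.0
BOWTIE_CONTRAST_D = 0.25
SMALL_BOWTIE_MM = 5.0
MEDIUM_BOWTIE_MM = 7.0
MIN_RESOLVABLE_CYL_D = 0.05

#: Diameter (mm) of the screening ring on which I-S and SRAX are read.
SCREENING_RING_MM = 5.0


class NoBowtieError(ValueError):
    """Raised when no point on the steep meridian clears the color-step contrast."""


@dataclass(frozen=True)
class TopographyIndices:
    """Asymmetry markers of one map.

    is_index
        Inferior minus superior sagittal power (D) at the two intersections
        of the steep meridian with the 5-mm ring (radius 2.5 mm).  The
        inferior point is the intersection with a downward vertical
        component (y < 0 in right-eye-view coordinates).
    si_index
        Superior minus inferior, i.e. −is_index.
    srax_deg
        Acute angular difference between the steep axes fitted separately
        on the superior and inferior half-rings, in [0, 90].
    steep_axis_deg, cylinder_d
        Whole-ring steep meridian and cylinder at 5 mm.
    applicable
        False when the 5-mm cylinder is below the resolvable floor
        (< 0.05 D): no steep axis exists and the indices are NaN.
    """

    is_index: float
    si_index: float
    srax_deg: float
    steep_axis_deg: float
    cylinder_d: float
    applicable: bool = True


def _acute_meridian_diff(a_deg: float, b_deg: float) -> float:
    d = abs(a_deg - b_deg) % 180.0
    return min(d, 180.0 - d)


def compute_indices(cmap: CornealPowerMap) -> TopographyIndices:
    """I-S, S-I and SRAX from the apex-centered 5-mm ring."""
    spec = ModeSpec("ring", "apex", SCREENING_RING_MM)
    r, t, p, w = sample_points(cmap, spec)
    astig, _ = fit_astigmatism(t, p, w)
    if astig.magnitude < MIN_RESOLVABLE_CYL_D:
        nan = float("nan")
        return TopographyIndices(nan, nan, nan, nan, astig.magnitude, applicable=False)
    phi = astig.axis
    half_r = SCREENING_RING_MM / 2.0
    # superior intersection at meridian phi (sin phi >= 0 for phi in [0,180)),
    # inferior at phi + 180
    p_sup = cmap.power_at(half_r, phi)
    p_inf = cmap.power_at(half_r, phi + 180.0)
    is_index = p_inf - p_sup

    t_full = np.asarray(t) % 360.0
    sup = (t_full > 0.0) & (t_full < 180.0)
    inf = t_full > 180.0
    axis_sup = fit_astigmatism(t[sup], p[sup], w[sup])[0].axis
    axis_inf = fit_astigmatism(t[inf], p[inf], w[inf])[0].axis
    srax = _acute_meridian_diff(axis_sup, axis_inf)
    return TopographyIndices(is_index, -is_index, srax, phi, astig.magnitude)


def classify_symmetry(
    idx: TopographyIndices,
    is_threshold: float = IS_THRESHOLD_D,
    si_threshold: float = SI_THRESHOLD_D,
    srax_threshold: float = SRAX_THRESHOLD_DEG,
) -> str:
    """``"asymmetric"`` iff I-S > 1.5 D or S-I > 2.5 D or SRAX > 22° (strict)."""
    if not idx.applicable:
        return "symmetric"
    if idx.is_index > is_threshold or idx.si_index > si_threshold or idx.srax_deg > srax_threshold:
        return "asymmetric"
    return "symmetric"


def _lobe_extent(cmap: CornealPowerMap, steep_deg: float, contrast: float) -> float:
    """Farthest contiguous radius at which the steep meridian exceeds the
    flat-meridian power at the same radius by at least ``contrast`` D."""
    i_steep = cmap.nearest_angle_index(steep_deg)
    i_flat1 = cmap.nearest_angle_index(steep_deg + 90.0)
    i_flat2 = cmap.nearest_angle_index(steep_deg + 270.0)
    extent = 0.0
    for j, r in enumerate(cmap.radii):
        if r == 0.0:
            continue
        flat = 0.5 * (cmap.power[j, i_flat1] + cmap.power[j, i_flat2])
        if cmap.power[j, i_steep] - flat >= contrast:
            extent = float(r)
        else:
            break
    return extent


def bowtie_diameter(cmap: CornealPowerMap, contrast: float = BOWTIE_CONTRAST_D) -> float:
    """Tip-to-tip bowtie extent (mm) along the steep meridian.

    Sum of the superior and inferior lobe extents, each the farthest
    contiguous radius whose steep-meridian power exceeds the flat-meridian
    power by at least one color step (default 0.25 D).  The steep meridian
    is fitted on the central 2-mm zone — a small bowtie need not reach the
    5-mm screening ring.  Raises :class:`NoBowtieError` when no radius
    clears the contrast.
    """
    r, t, p, w = sample_points(cmap, ModeSpec("zone", "apex", 2.0))
    central, _ = fit_astigmatism(t, p, w)
    if central.magnitude < MIN_RESOLVABLE_CYL_D:
        raise NoBowtieError("no resolvable steep axis: central cylinder below 0.05 D")
    sup = _lobe_extent(cmap, central.axis, contrast)
    inf = _lobe_extent(cmap, central.axis + 180.0, contrast)
    if sup == 0.0 and inf == 0.0:
        raise NoBowtieError(
            f"no bowtie: no point on the steep meridian exceeds the flat "
            f"meridian by the {contrast} D color step"
        )
    return sup + inf


def classify_bowtie_type(diameter_mm: float) -> str:
    """A iff d ≤ 5 mm; B iff 5 < d ≤ 7 mm; C iff d > 7 mm."""
    if not (diameter_mm > 0):
        raise ValueError(f"bowtie diameter must be > 0 mm, got {diameter_mm}")
    if diameter_mm <= SMALL_BOWTIE_MM:
        return "A"
    if diameter_mm <= MEDIUM_BOWTIE_MM:
        return "B"
    return "C"


def classify_irregularity(value_um: float) -> str:
    """Mild < 0.3 μm ≤ moderate < 0.5 μm ≤ severe."""
    if value_um < 0:
        raise ValueError(f"irregular astigmatism must be >= 0 um, got {value_um}")
    if value_um < 0.3:
        return "mild"
    if value_um < 0.5:
        return "moderate"
    return "severe"


def classify_map(
    cmap: CornealPowerMap,
    irregular_um: float | None = None,
    contrast: float = BOWTIE_CONTRAST_D,
) -> dict:
    """Full classification of one map, as a flat column dict.

    Bowtie diameter/type are only assigned for symmetric eyes (the clinical
    subtyping applies to the symmetric group); a missing bowtie is recorded
    as ``bowtie_type = "none"``.
    """
    idx = compute_indices(cmap)
    symmetry = classify_symmetry(idx)
    out = {
        "is_index": idx.is_index,
        "si_index": idx.si_index,
        "srax_deg": idx.srax_deg,
        "symmetry": symmetry,
        "bowtie_diameter_mm": float("nan"),
        "bowtie_type": "",
    }
    if symmetry == "symmetric":
        try:
            d = bowtie_diameter(cmap, contrast)
            out["bowtie_diameter_mm"] = d
            out["bowtie_type"] = classify_bowtie_type(d)
        except NoBowtieError:
            out["bowtie_type"] = "none"
    if irregular_um is not None:
        out["irregularity_grade"] = classify_irregularity(irregular_um)
    return out
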