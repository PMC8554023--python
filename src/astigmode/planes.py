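"""Refractive-plane conversions for residual astigmatism and toric IOL power.

Two conversions bring all cylinders onto the corneal plane, where the
back-calculation of actual corneal astigmatism is performed:

* Spectacle → cornea (vertex formula): a manifest cylinder ``D`` measured at
  vertex distance ``v`` (meters, default 0.012) has corneal-plane power
  ``D / (1 − v·D)``.

* IOL plane → cornea (vergence chain): an add of ``D_IOL`` diopters at the
  IOL plane, an effective lens position ``ELP`` millimeters behind a cornea
  of net power ``K``, changes the corneal-plane power by propagating
  vergences through the aqueous (reduced index 1.336, i.e. 1336 with
  distances in mm)::

      f1 = 1336 / K            # corneal focal distance, mm
      f2 = f1 − ELP            # distance from IOL plane to that focus
      P2 = 1336 / f2           # vergence arriving at the IOL plane
      Pt = P2 + D_IOL          # add the IOL cylinder
      f3 = 1336 / Pt           # new focal distance from the IOL plane
      f4 = f3 + ELP            # referred back to the cornea
      →  1336 / f4 − K         # corneal-plane equivalent of the add

  As ELP → 0 the chain collapses to the identity, and for ELP > 0 the
  corneal-plane effect is smaller than the labelled IOL cylinder (a
  posterior-chamber cylinder is less effective at the cornea).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BiometryContext",
    "residual_to_corneal_plane",
    "corneal_to_spectacle_plane",
    "toric_to_corneal_plane",
    "corneal_cyl_to_iol_plane",
]

#: Reduced index of the aqueous × 1000 (vergences in D, distances in mm).
N_AQUEOUS_MM = 1336.0

#: Default spectacle vertex distance in meters.
DEFAULT_VERTEX_M = 0.012


@dataclass(frozen=True)
class BiometryContext:
    """Per-eye biometry needed for the IOL-plane conversion.

    k_net
        Net corneal power in diopters (Scheimpflug total power).
    elp_mm
        Effective lens position in millimeters, taken from the
        postoperative anterior chamber depth.
    vertex_distance_m
        Spectacle vertex distance in meters (default 12 mm).
    """

    k_net: float
    elp_mm: float
    vertex_distance_m: float = DEFAULT_VERTEX_M

    def __post_init__(self) -> None:
        if not (self.k_net > 0):
            raise ValueError(f"net corneal power must be > 0 D, got {self.k_net}")
        if self.elp_mm < 0:
            raise ValueError(f"ELP must be >= 0 mm, got {self.elp_mm}")
        if not (self.vertex_distance_m > 0):
            raise ValueError("vertex distance must be > 0 m")


def residual_to_corneal_plane(d_residual: float, vertex_distance_m: float = DEFAULT_VERTEX_M) -> float:
    """Vertex-convert a spectacle-plane cylinder (D) to the corneal plane.

    Strictly increasing with ``f(D) > D`` for ``D > 0``; the axis of the
    cylinder is unchanged by the conversion.
    """
    denom = 1.0 - vertex_distance_m * d_residual
    if denom <= 0:
        raise ValueError(
            f"cylinder {d_residual} D is at or beyond the vertex singularity "
            f"1/{vertex_distance_m} D"
        )
    return d_residual / denom


def corneal_to_spectacle_plane(d_corneal: float, vertex_distance_m: float = DEFAULT_VERTEX_M) -> float:
    """Exact inverse of :func:`residual_to_corneal_plane`."""
    return d_corneal / (1.0 + vertex_distance_m * d_corneal)


def _corneal_effect(power_at_iol: float, ctx: BiometryContext) -> float:
    """Corneal-plane power change produced by ``power_at_iol`` D at the IOL plane."""
    f1 = N_AQUEOUS_MM / ctx.k_net
    f2 = f1 - ctx.elp_mm
    if f2 == 0:
        raise ValueError("vergence step f2 = 1336/K - ELP is zero (IOL at the corneal focus)")
    p2 = N_AQUEOUS_MM / f2
    p_tot = p2 + power_at_iol
    if p_tot == 0:
        raise ValueError("vergence step P_tot = 1336/f2 + D_IOL is zero")
    f3 = N_AQUEOUS_MM / p_tot
    f4 = f3 + ctx.elp_mm
    if f4 == 0:
        raise ValueError("vergence step f4 = f3 + ELP is zero")
    return N_AQUEOUS_MM / f4 - ctx.k_net


def toric_to_corneal_plane(
    d_iol: float,
    ctx: BiometryContext,
    method: str = "meridional",
    iol_base_power: float = 0.0,
) -> float:
    """Convert a toric IOL cylinder (D at the IOL plane) to the corneal plane.

    ``method="meridional"`` converts the two principal meridians separately —
    the flat meridian carries ``iol_base_power`` and the steep meridian
    ``iol_base_power + d_iol`` — and returns the difference of their
    corneal-plane effects, which is the optically exact cylinder.
    ``method="scalar"`` plugs the cylinder straight into the vergence chain,
    the common clinical shortcut.  With ``iol_base_power = 0`` the two
    coincide; the axis of the cylinder is unchanged either way.
    """
    if method == "scalar":
        return _corneal_effect(d_iol, ctx)
    if method == "meridional":
        steep = _corneal_effect(iol_base_power + d_iol, ctx)
        flat = _corneal_effect(iol_base_power, ctx)
        return steep - flat
    raise ValueError(f"unknown cylinder conversion method {method!r}")


def corneal_cyl_to_iol_plane(d_corneal: float, ctx: BiometryContext) -> float:
    """Closed-form inverse of the scalar vergence chain.

    Given a desired corneal-plane cylinder effect, return the IOL-plane
    cylinder that produces it.  Used when back-solving the implanted toric
    power from a corneal-plane target.
    """
    f1 = N_AQUEOUS_MM / ctx.k_net
    f2 = f1 - ctx.elp_mm
    if f2 == 0:
        raise ValueError("vergence step f2 = 1336/K - ELP is zero")
    p2 = N_AQUEOUS_MM / f2
    k_plus = ctx.k_net + d_corneal
    if k_plus == 0:
        raise ValueError("target corneal power K + D is zero")
    f4 = N_AQUEOUS_MM / k_plus
    f3 = f4 - ctx.elp_mm
    if f3 == 0:
        raise ValueError("vergence step f3 = 1336/(K+D) - ELP is zero")
    return N_AQUEOUS_MM / f3 - p2
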