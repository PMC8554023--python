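"""Synthetic Scheimpflug-like corneas and toric-IOL cohorts with known truth.

No patient data accompany the study population this package analyzes, so
every pipeline stage is exercised against generated eyes whose ground
truth is known exactly.  The generator emulates:

* a corneal total-power map ``K(r, θ) = K0 + g·r + A(r, θ)·cos 2(θ − φ)``
  on an apex-centered polar grid, where the sinusoid amplitude
  ``A = C(r)/2`` carries a radial cylinder profile (a hard or tapered
  cutoff controls the bowtie extent), an inferior-lobe power offset
  (drives I-S) and a per-lobe axis counter-rotation (drives SRAX);
* a cohort whose drawn marginals follow the study's summary statistics
  (preoperative total corneal refractive power 2.09 ± 0.74 D, SIA
  0.55 ± 0.38 D, pupil diameter 2.69 ± 0.55 mm, …), with magnitudes drawn
  from normals truncated at zero;
* the forward optics of toric IOL implantation: the toric cylinder is
  back-solved from the planning-mode measurement through the vergence
  chain, implanted with a configurable axis error, surgically induced
  astigmatism is applied as a vector at the (temporal) incision meridian,
  and the manifest residual astigmatism is *derived* by exact optical
  composition plus manifest measurement noise — never drawn independently
  — so the noiseless pipeline closes identically.

Because the keratometric fit is linear in the map, adding a radially
uniform SIA term to the map shifts every mode's fitted astigmatism by the
same double-angle vector; postoperative per-mode values are therefore
computed by vector addition rather than by regenerating a postoperative
map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Astigmatism, from_double_angle, to_double_angle, vector_add, vector_diff
from .modes import ALL_MODES, CornealPowerMap, ModeSpec, extract_all_modes
from .planes import (
    BiometryContext,
    corneal_cyl_to_iol_plane,
    corneal_to_spectacle_plane,
    toric_to_corneal_plane,
)

__all__ = [
    "CylProfile",
    "CorneaGenParams",
    "CohortGenParams",
    "generate_cornea",
    "generate_cohort",
]


@dataclass(frozen=True)
class CylProfile:
    """Radial cylinder profile C(r) = cyl0 · mult(r).

    ``mult(r)`` is 1 out to ``cutoff_mm``, falls linearly to 0 over
    ``taper_mm``, and is 0 beyond; ``cutoff_mm = None`` means a constant
    (radius-independent) cylinder.  A hard cutoff (taper 0) makes the
    recovered bowtie diameter exactly ``2·cutoff_mm``.
    """

    cutoff_mm: float | None = None
    taper_mm: float = 0.0

    def multiplier(self, r: np.ndarray | float) -> np.ndarray | float:
        if self.cutoff_mm is None:
            return np.ones_like(np.asarray(r, dtype=float))
        r = np.asarray(r, dtype=float)
        if self.taper_mm <= 0:
            # tolerance absorbs float accumulation in grid construction
            return (r <= self.cutoff_mm + 1e-9).astype(float)
        frac = (r - self.cutoff_mm) / self.taper_mm
        return np.clip(1.0 - frac, 0.0, 1.0)

    def zone_mean_multiplier(self, radius_mm: float) -> float:
        """Area-weighted mean of mult over the disc of the given radius:
        (2/R²)·∫₀ᴿ mult(r)·r dr, in closed form."""
        R = float(radius_mm)
        if R <= 0:
            raise ValueError("zone radius must be > 0")
        c = self.cutoff_mm
        if c is None or R <= c:
            return 1.0
        tau = self.taper_mm
        integral = c * c / 2.0
        if tau > 0:
            b = min(R, c + tau)
            # ∫_c^b (1 − (r−c)/τ)·r dr
            integral += (b * b - c * c) / 2.0 - (
                (b**3 - c**3) / 3.0 - c * (b * b - c * c) / 2.0
            ) / tau
        return 2.0 * integral / (R * R)


@dataclass(frozen=True)
class CorneaGenParams:
    """Parameters of one synthetic corneal power map (all deterministic per seed)."""

    k0: float = 43.5                #: central mean power, D
    cyl0: float = 2.0               #: central cylinder, D
    steep_axis_deg: float = 90.0
    radial_gradient: float = 0.0    #: D/mm applied to the mean power
    profile: CylProfile = field(default_factory=CylProfile)
    lobe_asymmetry: float = 0.0     #: extra D at the inferior steep point (drives I-S)
    lobe_skew_deg: float = 0.0      #: counter-rotation between lobes (drives SRAX)
    noise_sd: float = 0.0           #: per-node measurement noise, D
    pupil_offset_mm: tuple[float, float] = (0.0, 0.0)
    pupil_diameter_mm: float = 2.69
    r_max_mm: float = 4.5
    dr_mm: float = 0.1
    dtheta_deg: float = 1.0
    seed: int = 0


def generate_cornea(p: CorneaGenParams) -> CornealPowerMap:
    """Build the sampled power map for one synthetic cornea."""
    if p.cyl0 < 0 or p.noise_sd < 0:
        raise ValueError("cyl0 and noise_sd must be >= 0")
    radii = np.arange(0.0, p.r_max_mm + p.dr_mm / 2, p.dr_mm)
    angles = np.arange(0.0, 360.0, p.dtheta_deg)
    rr, tt = np.meshgrid(radii, angles, indexing="ij")
    inferior = np.sin(np.radians(tt)) < 0.0

    mult = p.profile.multiplier(rr)
    amplitude = 0.5 * p.cyl0 * mult + p.lobe_asymmetry * mult * inferior
    phi = np.where(
        inferior,
        p.steep_axis_deg + p.lobe_skew_deg / 2.0,
        p.steep_axis_deg - p.lobe_skew_deg / 2.0,
    )
    power = p.k0 + p.radial_gradient * rr + amplitude * np.cos(2.0 * np.radians(tt - phi))
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        power = power + rng.normal(0.0, p.noise_sd, power.shape)
    return CornealPowerMap(radii, angles, power, p.pupil_offset_mm, p.pupil_diameter_mm)


@dataclass(frozen=True)
class CohortGenParams:
    """Study-population parameters for a synthetic toric-IOL cohort.

    ``(mean, sd)`` pairs are drawn from normals truncated at zero (or at
    the stated physiologic bounds); axis distributions default to uniform
    on [0, 180) with an optional with-the-rule concentration.  Residual
    astigmatism and IOL cylinder power are *derived* quantities, not drawn.
    """

    n_eyes: int = 59
    preop_tcrp_d: tuple[float, float] = (2.09, 0.74)
    sia_d: tuple[float, float] = (0.55, 0.38)
    pupil_diameter_mm: tuple[float, float] = (2.69, 0.55)
    elp_mm: tuple[float, float] = (3.18, 0.46)     #: anterior chamber depth proxy
    k_net_d: tuple[float, float] = (43.5, 1.4)
    steep_axis_kappa: float = 0.0                  #: von Mises concentration (0 = uniform)
    wtr_axis_deg: float = 90.0                     #: with-the-rule center when kappa > 0
    incision_meridian_deg: float = 0.0             #: temporal clear corneal incision
    incision_axis_sd_deg: float = 0.0
    anticipated_sia_d: float | None = None         #: planner's SIA estimate (None → the SIA mean)
    iol_axis_error_sd_deg: float = 5.0
    manifest_noise_sd_d: float = 0.25              #: per double-angle component
    map_noise_sd_d: float = 0.1
    pupil_offset_sd_mm: float = 0.15               #: per Cartesian component
    asymmetric_fraction: float = 23.0 / 59.0
    bowtie_type_proportions: tuple[float, float, float] = (6 / 36, 18 / 36, 12 / 36)
    type_cutoff_mm: tuple[float, float, float] = (2.25, 3.0, 4.0)  #: A, B, C lobe cutoffs
    lobe_asymmetry_d: float = 2.0                  #: I-S driver for asymmetric eyes
    lobe_skew_deg: float = 30.0                    #: SRAX driver for asymmetric eyes
    radial_gradient: float = 0.0
    planning_mode: str = "zone_apex_3mm"
    truth_mode: str = "zone_apex_3mm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        for name in ("preop_tcrp_d", "sia_d", "pupil_diameter_mm", "elp_mm", "k_net_d"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, size: int,
                  low: float = 0.0, high: float = np.inf) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_axes(rng: np.random.Generator, p: CohortGenParams, size: int) -> np.ndarray:
    if p.steep_axis_kappa <= 0:
        return rng.uniform(0.0, 180.0, size)
    # concentrate the double angle around 2·wtr_axis
    double = rng.vonmises(np.radians(2.0 * p.wtr_axis_deg), p.steep_axis_kappa, size)
    return (np.degrees(double) / 2.0) % 180.0


def _analytic_modes(cyl0: float, axis: float, profile: CylProfile) -> dict[ModeSpec, Astigmatism]:
    """Closed-form per-mode values for a symmetric, centered cornea.

    Ring at diameter d reads C(d/2); zone reads the area-weighted mean of
    C(r) over the disc.  Apex- and pupil-centered values coincide in this
    shortcut (the full-map path is needed for centration effects).
    """
    out = {}
    for spec in ALL_MODES:
        half = spec.diameter_mm / 2.0
        if spec.geometry == "ring":
            mag = cyl0 * float(profile.multiplier(half))
        else:
            mag = cyl0 * profile.zone_mean_multiplier(half)
        out[spec] = Astigmatism(mag, axis if mag > 0 else 0.0)
    return out


def _gaussian_da_noise(rng: np.random.Generator, a: Astigmatism, sd: float) -> Astigmatism:
    if sd <= 0:
        return a
    v = to_double_angle(a)
    return from_double_angle(
        type(v)(v.x + rng.normal(0.0, sd), v.y + rng.normal(0.0, sd))
    )


def generate_cohort(
    p: CohortGenParams,
    with_maps: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, list[CornealPowerMap]]:
    """Generate one cohort: the observable eye records and the hidden truth.

    ``with_maps=True`` builds a full power map per eye and extracts the 16
    analysis modes numerically (needed for centration, asymmetry and map
    noise to reach the measurements); the default analytic path computes
    the mode values in closed form from each eye's radial profile, which
    is exact for symmetric centered corneas and fast enough for large-n
    calibration runs.

    Returns ``(records, truth)`` DataFrames (plus the map list when
    requested); bit-identical for identical parameters and seed.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_eyes
    cyl0 = _trunc_normal(rng, *p.preop_tcrp_d, n)
    sia_mag = _trunc_normal(rng, *p.sia_d, n)
    pupil_d = _trunc_normal(rng, *p.pupil_diameter_mm, n, low=0.5)
    elp = _trunc_normal(rng, *p.elp_mm, n, low=2.0, high=8.0)
    k_net = _trunc_normal(rng, *p.k_net_d, n, low=30.0, high=60.0)
    steep_axis = _draw_axes(rng, p, n)
    laterality = rng.choice(["OD", "OS"], n)

    asym = rng.uniform(size=n) < p.asymmetric_fraction
    bowtie = rng.choice(["A", "B", "C"], n, p=np.asarray(p.bowtie_type_proportions))
    cutoffs = dict(zip("ABC", p.type_cutoff_mm))
    skew_driven = rng.uniform(size=n) < 0.5   # asymmetric eyes: SRAX- vs I-S-driven
    offsets = rng.normal(0.0, p.pupil_offset_sd_mm, (n, 2))
    iol_axis_err = rng.normal(0.0, p.iol_axis_error_sd_deg, n)
    sia_axis = (
        p.incision_meridian_deg + rng.normal(0.0, p.incision_axis_sd_deg, n)
    ) % 180.0
    map_seeds = rng.integers(0, 2**31 - 1, n)

    plan_spec = ModeSpec.from_key(p.planning_mode)
    truth_spec = ModeSpec.from_key(p.truth_mode)

    records: list[dict] = []
    truths: list[dict] = []
    maps: list[CornealPowerMap] = []

    for i in range(n):
        profile = CylProfile(cutoff_mm=cutoffs[bowtie[i]])
        gen = CorneaGenParams(
            k0=float(k_net[i]),
            cyl0=float(cyl0[i]),
            steep_axis_deg=float(steep_axis[i]),
            radial_gradient=p.radial_gradient,
            profile=profile,
            lobe_asymmetry=p.lobe_asymmetry_d if (asym[i] and not skew_driven[i]) else 0.0,
            lobe_skew_deg=p.lobe_skew_deg if (asym[i] and skew_driven[i]) else 0.0,
            noise_sd=p.map_noise_sd_d,
            pupil_offset_mm=(float(offsets[i, 0]), float(offsets[i, 1])),
            pupil_diameter_mm=float(pupil_d[i]),
            seed=int(map_seeds[i]),
        )
        if with_maps:
            cmap = generate_cornea(gen)
            maps.append(cmap)
            pre_modes = extract_all_modes(cmap)
        else:
            pre_modes = _analytic_modes(gen.cyl0, gen.steep_axis_deg, profile)

        ctx = BiometryContext(k_net=float(k_net[i]), elp_mm=float(elp[i]))
        # planning target: the planning-mode measurement plus the surgeon's
        # anticipated SIA at the incision meridian (as clinical calculators do)
        sia_expected = p.sia_d[0] if p.anticipated_sia_d is None else p.anticipated_sia_d
        a_plan = vector_add(
            pre_modes[plan_spec],
            Astigmatism(sia_expected, p.incision_meridian_deg if sia_expected > 0 else 0.0),
        )
        d_iol = corneal_cyl_to_iol_plane(a_plan.magnitude, ctx) if a_plan.magnitude > 0 else 0.0
        iol_axis = (a_plan.axis + iol_axis_err[i]) % 180.0
        toric_corneal = toric_to_corneal_plane(d_iol, ctx) if d_iol > 0 else 0.0
        toric = Astigmatism(toric_corneal, iol_axis if toric_corneal > 0 else 0.0)

        sia = Astigmatism(float(sia_mag[i]), float(sia_axis[i]) if sia_mag[i] > 0 else 0.0)
        post_truth = vector_add(pre_modes[truth_spec], sia)
        residual_corneal = vector_diff(post_truth, toric)
        residual_obs = _gaussian_da_noise(rng, residual_corneal, p.manifest_noise_sd_d)
        residual_spectacle = Astigmatism(
            corneal_to_spectacle_plane(residual_obs.magnitude), residual_obs.axis
        )

        rec: dict = {"eye_id": f"E{i+1:04d}", "laterality": laterality[i]}
        for spec, a in pre_modes.items():
            rec[f"pre_{spec.key}_mag"] = a.magnitude
            rec[f"pre_{spec.key}_axis"] = a.axis
        rec.update(
            post_mag=post_truth.magnitude,
            post_axis=post_truth.axis,
            residual_mag=residual_spectacle.magnitude,
            residual_axis=residual_spectacle.axis,
            k_net=float(k_net[i]),
            elp_mm=float(elp[i]),
            iol_cylinder=d_iol,
            iol_axis=iol_axis,
            pupil_diameter=float(pupil_d[i]),
        )
        records.append(rec)
        truths.append(
            {
                "eye_id": rec["eye_id"],
                "cyl0": gen.cyl0,
                "steep_axis": gen.steep_axis_deg,
                "true_preop_mag": pre_modes[truth_spec].magnitude,
                "true_preop_axis": pre_modes[truth_spec].axis,
                "sia_mag": sia.magnitude,
                "sia_axis": sia.axis,
                "toric_mag": toric.magnitude,
                "toric_axis": toric.axis,
                "residual_corneal_mag": residual_corneal.magnitude,
                "residual_corneal_axis": residual_corneal.axis,
                "d_iol": d_iol,
                "group": "asymmetric" if asym[i] else bowtie[i],
                "asymmetric": bool(asym[i]),
                "bowtie_type": "" if asym[i] else bowtie[i],
                "cutoff_mm": cutoffs[bowtie[i]],
                "lobe_asymmetry": gen.lobe_asymmetry,
                "lobe_skew_deg": gen.lobe_skew_deg,
                "pupil_dx_mm": gen.pupil_offset_mm[0],
                "pupil_dy_mm": gen.pupil_offset_mm[1],
                "map_seed": gen.seed,
            }
        )

    records_df = pd.DataFrame(records)
    truth_df = pd.DataFrame(truths)
    if with_maps:
        return records_df, truth_df, maps
    return records_df, truth_df


def noiseless(p: CohortGenParams) -> CohortGenParams:
    """A copy of the parameters with every stochastic disturbance removed
    (axis errors, manifest and map noise, centration offsets): the exact-
    optics configuration under which the pipeline must close."""
    return replace(
        p,
        iol_axis_error_sd_deg=0.0,
        incision_axis_sd_deg=0.0,
        manifest_noise_sd_d=0.0,
        map_noise_sd_d=0.0,
        pupil_offset_sd_mm=0.0,
        lobe_asymmetry_d=0.0,
        lobe_skew_deg=0.0,
        asymmetric_fraction=0.0,
        type_cutoff_mm=(None, None, None),
    )
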