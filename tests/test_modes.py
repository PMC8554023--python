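"""Ring/zone × apex/pupil keratometric extraction on sampled power maps."""

import math

import numpy as np
import pytest

from astigmode import (
    ALL_MODES,
    Astigmatism,
    CornealPowerMap,
    ModeSpec,
    extract_all_modes,
    extract_mode,
    fit_astigmatism,
    sample_points,
)
from astigmode.synth import CorneaGenParams, CylProfile, generate_cornea


def toric_map(k0=43.0, cyl=2.0, axis=0.0, **kwargs) -> CornealPowerMap:
    return generate_cornea(CorneaGenParams(k0=k0, cyl0=cyl, steep_axis_deg=axis, **kwargs))


def brute_force_fit(meridians_deg, powers, weights):
    """Grid-search oracle over (magnitude, axis) minimizing weighted SSE."""
    t = np.radians(meridians_deg)
    best = (np.inf, None, None)
    for mag in np.arange(0.0, 4.001, 0.01):
        for ax in np.arange(0.0, 180.0, 0.5):
            model = 0.5 * mag * np.cos(2 * (t - math.radians(ax)))
            resid = powers - powers.mean() - (model - np.average(model, weights=weights))
            sse = float(np.sum(weights * resid**2))
            if sse < best[0]:
                best = (sse, mag, ax)
    return best[1], best[2]


class TestModeSpec:
    def test_sixteen_modes(self):
        assert len(ALL_MODES) == 16
        assert len({m.key for m in ALL_MODES}) == 16

    def test_key_round_trip(self):
        for m in ALL_MODES:
            assert ModeSpec.from_key(m.key) == m

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ModeSpec("annulus", "apex", 3.0)
        with pytest.raises(ValueError):
            ModeSpec("ring", "apex", 6.0)


class TestSamplePoints:
    def test_zone_selects_disc(self):
        m = toric_map()
        r, t, p, w = sample_points(m, ModeSpec("zone", "apex", 2.0))
        assert r.max() <= 1.0 + 1e-12
        assert np.all(w >= 0)

    def test_ring_selects_band(self):
        m = toric_map()
        r, t, p, w = sample_points(m, ModeSpec("ring", "apex", 2.0))
        assert np.all(np.abs(r - 1.0) <= 0.05 + 1e-12)
        assert np.all(w == 1.0)

    def test_pupil_recentering_geometry(self):
        """A node at apex-polar (0.3 mm, 0°) has recentered radius 0 when the
        pupil center sits at (0.3, 0)."""
        m = toric_map(pupil_offset_mm=(0.3, 0.0))
        r, t, p, w = sample_points(m, ModeSpec("zone", "pupil", 2.0))
        assert r.min() == pytest.approx(0.0, abs=1e-12)

    def test_region_outside_map_rejected(self):
        m = toric_map(pupil_offset_mm=(2.5, 0.0))
        with pytest.raises(ValueError, match="zone_pupil_5mm"):
            sample_points(m, ModeSpec("zone", "pupil", 5.0))


class TestFitAstigmatism:
    def test_pure_toric_recovered_exactly(self):
        theta = np.arange(0.0, 360.0, 1.0)
        power = 43.0 + 1.0 * np.cos(2 * np.radians(theta))
        a, mean = fit_astigmatism(theta, power)
        assert a.magnitude == pytest.approx(2.0, abs=1e-9)
        assert a.axis == pytest.approx(0.0, abs=1e-9)
        assert mean == pytest.approx(43.0, abs=1e-9)

    def test_spherical_map_gives_zero(self):
        theta = np.arange(0.0, 360.0, 1.0)
        a, _ = fit_astigmatism(theta, np.full_like(theta, 43.0))
        assert a.magnitude == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="meridians"):
            fit_astigmatism(np.array([0.0, 90.0, 180.0]), np.array([43.0, 44.0, 43.0]))

    def test_noisy_ring_matches_brute_force_oracle(self, rng):
        theta = np.arange(0.0, 360.0, 1.0)
        truth_mag, truth_ax = 1.8, 37.0
        power = (
            43.0
            + 0.5 * truth_mag * np.cos(2 * np.radians(theta - truth_ax))
            + rng.normal(0, 0.1, theta.size)
        )
        w = np.ones_like(theta)
        a, _ = fit_astigmatism(theta, power, w)
        bf_mag, bf_ax = brute_force_fit(theta, power, w)
        assert a.magnitude == pytest.approx(bf_mag, abs=0.01)
        assert min(abs(a.axis - bf_ax), 180 - abs(a.axis - bf_ax)) <= 0.5
        # and within 3 SE of the generating truth (SE of amplitude ~ σ·√(2/n)·2)
        se = 0.1 * math.sqrt(2.0 / theta.size) * 2.0
        assert abs(a.magnitude - truth_mag) < 3 * se


class TestExtractAllModes:
    def test_mode_invariance_on_radially_uniform_toric(self):
        """All 16 modes agree on a radius-independent toric map."""
        m = toric_map(cyl=2.0, axis=70.0, radial_gradient=0.3)
        vals = extract_all_modes(m)
        mags = [a.magnitude for a in vals.values()]
        axes = [a.axis for a in vals.values()]
        assert max(mags) - min(mags) < 1e-6
        assert max(axes) - min(axes) < 0.01

    def test_zone_equals_area_weighted_ring_average(self):
        """For an axis-uniform map, the zone cylinder equals the area-weighted
        mean of ring cylinders over radii ≤ d/2 (numeric-integration oracle)."""
        profile = CylProfile(cutoff_mm=1.5, taper_mm=2.0)
        m = toric_map(cyl=2.0, axis=30.0, profile=profile)
        d = 4.0
        zone, _ = extract_mode(m, ModeSpec("zone", "apex", d))
        radii = m.radii[(m.radii > 0) & (m.radii <= d / 2 + 1e-12)]
        ring_cyls = np.array([2.0 * profile.multiplier(r) for r in radii])
        oracle = float(np.sum(ring_cyls * radii) / np.sum(radii))
        assert zone.magnitude == pytest.approx(oracle, abs=1e-3)

    def test_radial_gradient_makes_ring_exceed_zone(self):
        """With cylinder growing in r, the 4-mm ring reads a larger cylinder
        than the 4-mm zone (which averages smaller radii)."""
        radii = np.arange(0.0, 4.6, 0.1)
        theta = np.arange(0.0, 360.0, 1.0)
        rr, tt = np.meshgrid(radii, theta, indexing="ij")
        cyl = 1.0 + 0.2 * rr
        power = 43.0 + 0.5 * cyl * np.cos(2 * np.radians(tt))
        m = CornealPowerMap(radii, theta, power)
        ring, _ = extract_mode(m, ModeSpec("ring", "apex", 4.0))
        zone, _ = extract_mode(m, ModeSpec("zone", "apex", 4.0))
        assert ring.magnitude > zone.magnitude
        assert ring.magnitude == pytest.approx(1.0 + 0.2 * 2.0, abs=1e-6)

    def test_ring_locality_under_interior_perturbation(self):
        """Perturbing the map strictly inside the ring leaves it unchanged."""
        m = toric_map(cyl=2.0, axis=10.0)
        spec = ModeSpec("ring", "apex", 4.0)
        before, _ = extract_mode(m, spec)
        perturbed = m.power.copy()
        interior = m.radii < 2.0 - m.dr
        perturbed[interior, :] += 1.5
        m2 = CornealPowerMap(m.radii, m.angles_deg, perturbed)
        after, _ = extract_mode(m2, spec)
        assert after.isclose(before, 1e-12)

    def test_pupil_offset_separates_centers_on_asymmetric_map(self):
        """Apex- and pupil-centered values differ when the pupil is displaced
        on an asymmetric cornea, and coincide when the offset is zeroed."""
        kwargs = dict(cyl=2.0, axis=90.0, lobe_asymmetry=1.5,
                      profile=CylProfile(cutoff_mm=2.0, taper_mm=1.0))
        m_off = toric_map(pupil_offset_mm=(0.4, 0.3), **kwargs)
        m_ctr = toric_map(pupil_offset_mm=(0.0, 0.0), **kwargs)
        spec = ModeSpec("zone", "pupil", 3.0)
        apex = extract_mode(m_off, ModeSpec("zone", "apex", 3.0))[0]
        pupil = extract_mode(m_off, spec)[0]
        control = extract_mode(m_ctr, spec)[0]
        assert not pupil.isclose(apex, 1e-3)
        assert control.isclose(extract_mode(m_ctr, ModeSpec("zone", "apex", 3.0))[0], 1e-9)

    def test_bilinear_resampling_close_to_direct_recentering(self):
        m = toric_map(cyl=2.0, axis=45.0, pupil_offset_mm=(0.3, -0.2))
        direct = extract_mode(m, ModeSpec("zone", "pupil", 3.0))[0]
        interp = extract_mode(m, ModeSpec("zone", "pupil", 3.0), interpolation="bilinear")[0]
        assert interp.isclose(direct, 0.05)


class TestMapSerialization:
    def test_csv_round_trip(self, tmp_path):
        m = toric_map(cyl=1.3, axis=65.0, pupil_offset_mm=(0.2, -0.1))
        path = tmp_path / "map.csv"
        m.to_csv(path)
        back = CornealPowerMap.from_csv(path)
        assert np.allclose(back.power, m.power)
        assert back.pupil_offset_mm == pytest.approx(m.pupil_offset_mm)
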