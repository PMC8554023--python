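"""Double-angle algebra: round trips, oracle agreement, magnitude statistics."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from astigmode import (
    Astigmatism,
    DoubleAngleVector,
    absolute_error_stats,
    centroid,
    from_double_angle,
    to_double_angle,
    vector_add,
    vector_diff,
)

magnitudes = st.floats(0.0, 10.0, allow_nan=False)
axes = st.floats(0.0, 180.0, exclude_max=True, allow_nan=False)
astigs = st.builds(Astigmatism, magnitudes, axes)


def as_complex(a: Astigmatism) -> complex:
    """Independent oracle: the cylinder as m·e^{2iθ}."""
    return a.magnitude * cmath.exp(2j * math.radians(a.axis))


def from_complex(z: complex) -> Astigmatism:
    if abs(z) == 0:
        return Astigmatism(0.0)
    return Astigmatism(abs(z), math.degrees(cmath.phase(z) / 2.0) % 180.0)


class TestAstigmatismType:
    def test_axis_normalization_and_canonical_zero(self):
        assert Astigmatism(1.0, 180.0).axis == 0.0
        assert Astigmatism(1.0, 270.0).axis == 90.0
        assert Astigmatism(0.0, 37.0).axis == 0.0

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            Astigmatism(-0.1, 0.0)

    @pytest.mark.parametrize(
        "a, expected",
        [
            (Astigmatism(1.0, 0.0), (1.0, 0.0)),
            (Astigmatism(1.0, 90.0), (-1.0, 0.0)),
            (Astigmatism(2.0, 45.0), (0.0, 2.0)),
        ],
    )
    def test_double_angle_examples(self, a, expected):
        v = to_double_angle(a)
        assert v.x == pytest.approx(expected[0], abs=1e-12)
        assert v.y == pytest.approx(expected[1], abs=1e-12)

    @pytest.mark.parametrize(
        "v, expected",
        [
            (DoubleAngleVector(0.0, 0.0), Astigmatism(0.0)),
            (DoubleAngleVector(-1.0, 0.0), Astigmatism(1.0, 90.0)),
            (DoubleAngleVector(1.0, 1.0), Astigmatism(math.sqrt(2.0), 22.5)),
        ],
    )
    def test_from_double_angle_examples(self, v, expected):
        a = from_double_angle(v)
        assert a.magnitude == pytest.approx(expected.magnitude, abs=1e-12)
        assert a.axis == pytest.approx(expected.axis, abs=1e-9)

    @given(astigs)
    def test_round_trip(self, a):
        b = from_double_angle(to_double_angle(a))
        assert vector_diff(a, b).magnitude < 1e-9

    @given(magnitudes, axes)
    def test_axis_periodicity(self, m, ax):
        v1 = to_double_angle(Astigmatism(m, ax))
        v2 = to_double_angle(Astigmatism(m, ax + 180.0))
        assert math.hypot(v1.x - v2.x, v1.y - v2.y) < 1e-9 * max(m, 1.0)


class TestVectorArithmetic:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (Astigmatism(1, 0), Astigmatism(1, 90), Astigmatism(0)),
            (Astigmatism(1, 30), Astigmatism(0), Astigmatism(1, 30)),
            (Astigmatism(1, 0), Astigmatism(1, 45), Astigmatism(math.sqrt(2), 22.5)),
        ],
    )
    def test_add_examples(self, a, b, expected):
        assert vector_add(a, b).isclose(expected, 1e-9)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (Astigmatism(2, 90), Astigmatism(2, 90), Astigmatism(0)),
            (Astigmatism(1, 90), Astigmatism(1, 0), Astigmatism(2, 90)),
            (Astigmatism(0.5, 10), Astigmatism(0), Astigmatism(0.5, 10)),
        ],
    )
    def test_diff_examples(self, a, b, expected):
        assert vector_diff(a, b).isclose(expected, 1e-9)

    @given(astigs, astigs)
    def test_add_commutes(self, a, b):
        assert vector_add(a, b).isclose(vector_add(b, a), 1e-9)

    def test_complex_oracle_on_random_cases(self, rng):
        """add/diff/centroid agree with the m·e^{2iθ} oracle to 1e-9 D."""
        for _ in range(1000):
            a = Astigmatism(rng.uniform(0, 10), rng.uniform(0, 180))
            b = Astigmatism(rng.uniform(0, 10), rng.uniform(0, 180))
            assert vector_add(a, b).isclose(from_complex(as_complex(a) + as_complex(b)), 1e-9)
            assert vector_diff(a, b).isclose(from_complex(as_complex(a) - as_complex(b)), 1e-9)
        vs = [Astigmatism(rng.uniform(0, 3), rng.uniform(0, 180)) for _ in range(100)]
        oracle = from_complex(sum(as_complex(v) for v in vs) / len(vs))
        assert centroid(vs).isclose(oracle, 1e-9)


class TestCentroid:
    @pytest.mark.parametrize(
        "vs, expected",
        [
            ([Astigmatism(1, 0), Astigmatism(1, 90)], Astigmatism(0)),
            ([Astigmatism(0.19, 148)], Astigmatism(0.19, 148)),
            (
                [Astigmatism(1, 0), Astigmatism(1, 0), Astigmatism(1, 90)],
                Astigmatism(1 / 3, 0),
            ),
        ],
    )
    def test_examples(self, vs, expected):
        assert centroid(vs).isclose(expected, 1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            centroid([])

    def test_triangle_inequality(self, rng):
        """|centroid| <= mean magnitude, equality iff all axes equal."""
        for _ in range(200):
            vs = [Astigmatism(rng.uniform(0, 5), rng.uniform(0, 180)) for _ in range(10)]
            mean_mag = np.mean([v.magnitude for v in vs])
            assert centroid(vs).magnitude <= mean_mag + 1e-12
        same = [Astigmatism(rng.uniform(0.1, 5), 37.0) for _ in range(10)]
        assert centroid(same).magnitude == pytest.approx(
            np.mean([v.magnitude for v in same]), abs=1e-12
        )


class TestAbsoluteErrorStats:
    def test_examples(self):
        s = absolute_error_stats([Astigmatism(0), Astigmatism(0)])
        assert s.mean == 0 and s.median == 0
        s = absolute_error_stats([Astigmatism(1, 0), Astigmatism(3, 90)])
        assert s.mean == pytest.approx(2.0) and s.median == pytest.approx(2.0)
        assert s.sd == pytest.approx(np.std([1, 3], ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            absolute_error_stats([])

    def test_rayleigh_median_of_isotropic_2d_errors(self, rng):
        """Magnitudes of isotropic 2-D N(0, σ²) errors have median σ·√(2 ln 2)."""
        sigma = 0.4
        xy = rng.normal(0, sigma, (20000, 2))
        vs = [
            from_double_angle(DoubleAngleVector(x, y)) for x, y in xy
        ]
        s = absolute_error_stats(vs)
        expected = sigma * math.sqrt(2 * math.log(2))
        assert s.median == pytest.approx(expected, rel=0.05)
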