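"""Geometry construction, electrostatic moments, scaling and normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eccwater import (
    DEFAULT_BOUNDS,
    INITIAL_GUESS,
    PRESETS,
    WaterModelParams,
    build_geometry,
    denormalize_params,
    dipole_moment,
    molecular_moments,
    normalize_params,
    quadrupole_qt,
    scale_charge,
)
from eccwater.units import E_NM_TO_DEBYE, E_NM2_TO_DEBYE_ANGSTROM

from conftest import PUBLISHED_MOMENTS


def random_params(rng: np.random.Generator) -> WaterModelParams:
    lo, hi = DEFAULT_BOUNDS.lower_array(), DEFAULT_BOUNDS.upper_array()
    return WaterModelParams.from_array(lo + rng.random(6) * (hi - lo))


def closed_form_mu(p: WaterModelParams) -> float:
    """Independent closed form: 2 q_H (d_OH cos(θ/2) - d_OM) in e nm -> D."""
    half = math.radians(p.theta) / 2
    return abs(2 * p.q_H * (p.d_OH * math.cos(half) - p.d_OM)) * E_NM_TO_DEBYE


def closed_form_qt(p: WaterModelParams) -> float:
    """Independent closed form: (3/2) q_H (d_OH sin(θ/2))² in e nm² -> D Å."""
    half = math.radians(p.theta) / 2
    return 1.5 * p.q_H * (p.d_OH * math.sin(half)) ** 2 * E_NM2_TO_DEBYE_ANGSTROM


class TestGeometry:
    def test_canonical_frame_placement(self):
        p = PRESETS["eccw2024"]
        g = build_geometry(p)
        half = math.radians(p.theta) / 2
        np.testing.assert_allclose(g.positions[0], [0, 0, 0])
        np.testing.assert_allclose(
            g.positions[1], [p.d_OH * math.sin(half), 0, p.d_OH * math.cos(half)]
        )
        np.testing.assert_allclose(g.positions[2], g.positions[1] * [-1, 1, 1])
        np.testing.assert_allclose(g.positions[3], [0, 0, p.d_OM])

    def test_straight_angle_puts_hydrogens_on_x_axis(self):
        g = build_geometry(INITIAL_GUESS.replace(theta=180.0))
        np.testing.assert_allclose(g.positions[1][2], 0.0, atol=1e-15)
        np.testing.assert_allclose(g.positions[2][2], 0.0, atol=1e-15)

    def test_oh_distance_matches_parameter(self):
        p = PRESETS["tip4p2005"]
        g = build_geometry(p)
        assert np.linalg.norm(g.positions[1]) == pytest.approx(0.09572, abs=1e-12)

    def test_charge_neutrality_is_structural(self, rng):
        for _ in range(50):
            g = build_geometry(random_params(rng))
            assert g.total_charge == 0.0

    @pytest.mark.parametrize("field", ["sigma", "q_H", "d_OH", "theta"])
    def test_nonpositive_parameter_rejected_by_name(self, field):
        with pytest.raises(ValueError, match=field):
            INITIAL_GUESS.replace(**{field: -1.0})
        with pytest.raises(ValueError, match=field):
            INITIAL_GUESS.replace(**{field: float("nan")})


class TestMoments:
    def test_published_moments_reproduced(self, preset_name):
        mu_ref, qt_ref = PUBLISHED_MOMENTS[preset_name]
        m = molecular_moments(PRESETS[preset_name])
        assert m.mu == pytest.approx(mu_ref, abs=1e-3)
        assert m.q_t == pytest.approx(qt_ref, abs=1e-3)

    def test_tensor_evaluation_equals_closed_forms(self, rng):
        # oracle equivalence: full-tensor path vs analytic expressions
        for _ in range(100):
            p = random_params(rng)
            g = build_geometry(p)
            assert dipole_moment(g) == pytest.approx(closed_form_mu(p), rel=1e-10)
            assert quadrupole_qt(g) == pytest.approx(closed_form_qt(p), rel=1e-10)

    def test_dipole_invariant_under_rigid_motion(self, rng):
        g = build_geometry(PRESETS["eccw2024"])
        mu0 = dipole_moment(g)
        for _ in range(25):
            q, r = np.linalg.qr(rng.standard_normal((3, 3)))
            rot = q * np.sign(np.diag(r))
            moved = g.transformed(rot, rng.normal(0, 5.0, 3))
            assert dipole_moment(moved) == pytest.approx(mu0, rel=1e-10)

    def test_qt_independent_of_dummy_distance(self, rng):
        p = random_params(rng)
        values = {quadrupole_qt(build_geometry(p.replace(d_OM=d)))
                  for d in (0.012, 0.015, 0.018)}
        assert max(values) - min(values) < 1e-12

    def test_dipole_strictly_decreasing_in_dummy_distance(self):
        p = PRESETS["eccw2024"]
        mus = [dipole_moment(build_geometry(p.replace(d_OM=d)))
               for d in np.linspace(0.012, 0.018, 7)]
        assert all(a > b for a, b in zip(mus, mus[1:]))

    def test_zero_charge_zero_dipole(self):
        g = build_geometry(INITIAL_GUESS.replace(q_H=1e-300))
        assert dipole_moment(g) == pytest.approx(0.0, abs=1e-250)

    def test_dipole_vanishes_when_charge_centroids_coincide(self):
        p = INITIAL_GUESS
        d_om = p.d_OH * math.cos(math.radians(p.theta) / 2)
        g = build_geometry(p.replace(d_OM=d_om))
        assert dipole_moment(g) == pytest.approx(0.0, abs=1e-12)

    def test_charged_geometry_rejected(self):
        g = build_geometry(INITIAL_GUESS)
        broken = type(g)(labels=g.labels, positions=g.positions,
                         charges=g.charges + 0.1, frame=g.frame)
        with pytest.raises(ValueError, match="net charge"):
            dipole_moment(broken)


class TestChargeScaling:
    def test_water_scaling_factor(self):
        # 1/sqrt(1.78) — the ECC factor for water
        assert scale_charge(1.0, 1.78) == pytest.approx(0.7496, abs=5e-4)

    def test_identity_and_zero(self):
        assert scale_charge(0.75, 1.0) == 0.75
        assert scale_charge(0.0, 3.0) == 0.0

    def test_unphysical_eps_rejected(self):
        with pytest.raises(ValueError):
            scale_charge(1.0, 0.9)


class TestNormalization:
    def test_lower_bound_maps_to_zero(self):
        p = WaterModelParams.from_array(DEFAULT_BOUNDS.lower_array() + 1e-12)
        np.testing.assert_allclose(normalize_params(p), np.zeros(6), atol=1e-9)

    def test_seed_point_sigma_component(self):
        # (0.3150 - 0.3050) / (0.3250 - 0.3050) = 0.5
        assert normalize_params(INITIAL_GUESS)[0] == pytest.approx(0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1 - 1e-9), min_size=6, max_size=6))
    def test_round_trip_identity(self, x):
        x = np.array(x)
        np.testing.assert_allclose(
            normalize_params(denormalize_params(x)), x, atol=1e-9
        )

    def test_out_of_bounds_strict_raises_listing_parameter(self):
        with pytest.raises(ValueError, match="d_OM"):
            normalize_params(PRESETS["tip4pfb"])  # published model outside the box

    def test_out_of_bounds_relaxed_warns(self):
        with pytest.warns(UserWarning, match="d_OH"):
            normalize_params(PRESETS["opc4"], strict=False)
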