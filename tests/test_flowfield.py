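"""Stream function, radial velocity, stagnation points and trapping."""

import numpy as np
import pytest
from scipy.integrate import quad

from ciliapump import (
    CiliaParams,
    PumpState,
    axial_velocity,
    compute_field,
    pumping_integrals,
    radial_velocity,
    stagnation_points,
    stream_function,
    trapping_metrics,
    tube_radius,
)
from ciliapump.errors import ParameterDomainError, ResolutionError
from ciliapump.flowfield import _station
from ciliapump.params import gamma_factor


def _pump(qbar, p):
    return PumpState.from_qbar(qbar, p, pumping_integrals(p))


class TestStreamFunction:
    def test_axis_normalization(self, trapping_pump, casson_params):
        z = np.linspace(0, 1, 17)
        np.testing.assert_allclose(
            stream_function(np.zeros_like(z), z, trapping_pump, casson_params),
            0.0, atol=1e-15,
        )

    def test_newtonian_uniform_tube_analytic(self):
        # q=0 in a uniform tube: w = 1 - 2r^2, psi = r^2/2 - r^4/2
        p = CiliaParams(epsilon=0.0, alpha=0.0, beta=0.4, hp=0.0)
        pump = _pump(1.0, p)  # qbar = 1 -> q = 0
        assert pump.q == pytest.approx(0.0, abs=1e-12)
        r = np.linspace(0, 1, 21)
        np.testing.assert_allclose(
            stream_function(r, 0.3, pump, p), r**2 / 2 - r**4 / 2, atol=1e-12
        )
        assert stream_function(1 / np.sqrt(2), 0.9, pump, p) == pytest.approx(0.125)

    def test_wall_value_is_half_flux(self, trapping_pump, casson_params):
        z = np.linspace(0, 1, 64, endpoint=False)
        psi_wall = stream_function(
            tube_radius(z, casson_params), z, trapping_pump, casson_params
        )
        np.testing.assert_allclose(psi_wall, trapping_pump.q / 2, atol=1e-8)

    def test_matches_numerical_radial_quadrature(self, trapping_pump,
                                                 casson_params):
        p = casson_params
        for z0, r0 in ((0.1, 0.3), (0.45, 0.6), (0.8, 0.2)):
            dpdz = _station(z0, trapping_pump.q, p)[4]
            oracle, _ = quad(lambda r: r * axial_velocity(r, z0, dpdz, p),
                             0.0, r0, points=[p.hp], limit=200)
            assert stream_function(r0, z0, trapping_pump, p) == pytest.approx(
                oracle, rel=1e-9, abs=1e-12
            )

    def test_velocity_recovery(self, trapping_pump, casson_params):
        # (1/r) dpsi/dr reproduces the axial velocity
        dr = 1e-6
        for z0, r0 in ((0.2, 0.35), (0.6, 0.5), (0.9, 0.15)):
            grad = (
                stream_function(r0 + dr, z0, trapping_pump, casson_params)
                - stream_function(r0 - dr, z0, trapping_pump, casson_params)
            ) / (2 * dr * r0)
            dpdz = _station(z0, trapping_pump.q, casson_params)[4]
            assert grad == pytest.approx(
                float(axial_velocity(r0, z0, dpdz, casson_params)), abs=1e-6
            )

    def test_r_beyond_wall_rejected(self, trapping_pump, casson_params):
        with pytest.raises(ParameterDomainError):
            stream_function(1.0, 0.5, trapping_pump, casson_params)


class TestRadialVelocity:
    def test_uniform_tube_no_radial_flow(self):
        p = CiliaParams(epsilon=0.0, alpha=0.0, beta=0.4, hp=0.0)
        pump = _pump(0.5, p)
        zz, rr = np.meshgrid(np.linspace(0, 1, 9), np.linspace(0, 1, 9))
        np.testing.assert_allclose(radial_velocity(rr, zz, pump, p), 0.0,
                                   atol=1e-13)

    def test_axis_limit_zero(self, trapping_pump, casson_params):
        z = np.linspace(0, 1, 11)
        np.testing.assert_allclose(
            radial_velocity(np.zeros_like(z), z, trapping_pump, casson_params),
            0.0, atol=1e-13,
        )

    def test_matches_finite_difference_of_psi(self, trapping_pump,
                                              casson_params):
        dz = 1e-6
        for z0, r0 in ((0.17, 0.4), (0.52, 0.25), (0.83, 0.55)):
            fd = -(
                stream_function(r0, z0 + dz, trapping_pump, casson_params)
                - stream_function(r0, z0 - dz, trapping_pump, casson_params)
            ) / (2 * dz * r0)
            assert radial_velocity(r0, z0, trapping_pump, casson_params) == \
                pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_continuity_residual(self, trapping_pump, casson_params):
        # (1/r) d(ru)/dr + dw/dz ~ 0 on an interior grid, FD spacing 1e-3
        d = 1e-3
        r = np.linspace(0.05, 0.6, 56)
        z = np.linspace(0.05, 0.95, 91)
        zz, rr = np.meshgrid(z, r, indexing="ij")

        def w_of(rr_, zz_):
            dpdz = _station(zz_, trapping_pump.q, casson_params)[4]
            return axial_velocity(rr_.ravel(), zz_.ravel(),
                                  np.asarray(dpdz).ravel(),
                                  casson_params).reshape(rr_.shape)

        du = (
            (rr + d) * radial_velocity(rr + d, zz, trapping_pump, casson_params)
            - (rr - d) * radial_velocity(rr - d, zz, trapping_pump, casson_params)
        ) / (2 * d * rr)
        dw = (w_of(rr, zz + d) - w_of(rr, zz - d)) / (2 * d)
        assert np.max(np.abs(du + dw)) < 1e-4


def test_lab_frame_flow_rate_identity(trapping_pump, casson_params):
    # Q(z) = q + h^2 holds at every station
    for z0 in (0.0, 0.25, 0.6):
        h = float(tube_radius(z0, casson_params))
        dpdz = _station(z0, trapping_pump.q, casson_params)[4]
        lab, _ = quad(
            lambda r: r * (axial_velocity(r, z0, dpdz, casson_params) + 1.0),
            0.0, h, points=[casson_params.hp], limit=200,
        )
        assert 2 * lab == pytest.approx(trapping_pump.q + h * h, rel=1e-8)


class TestStagnation:
    def test_no_stagnation_without_trapping(self):
        # qbar = 0 in a uniform tube: w < 0 everywhere
        p = CiliaParams(epsilon=0.0, alpha=0.0, beta=0.4, hp=0.0)
        assert stagnation_points(_pump(0.0, p), p) == []

    def test_degenerate_zero_line_not_reported(self):
        # uniform tube at qbar = 1: w = 1 - 2r^2 vanishes on the whole line
        # r = 1/sqrt(2); no isolated stagnation points are reported
        p = CiliaParams(epsilon=0.0, alpha=0.0, beta=0.4, hp=0.0)
        pts = stagnation_points(_pump(1.0, p), p)
        assert pts == []

    def test_trapping_regime_has_interior_point(self):
        p = CiliaParams(epsilon=0.25, alpha=0.4, beta=0.4, hp=0.0)
        pts = stagnation_points(_pump(0.95, p), p)
        interior = [(r, z) for r, z in pts if r > 1e-6]
        assert len(interior) >= 1
        # deterministic ordering by z then r
        assert pts == sorted(pts, key=lambda t: (t[1], t[0]))


class TestTrapping:
    def test_uniform_tube_traps_nothing(self):
        p = CiliaParams(epsilon=0.0, alpha=0.0, beta=0.4, hp=0.0)
        tm = trapping_metrics(_pump(0.95, p), p)
        assert tm.n_boluses == 0
        assert tm.total_area == 0.0

    def test_too_coarse_grid_rejected(self, trapping_pump, casson_params):
        with pytest.raises(ResolutionError):
            trapping_metrics(trapping_pump, casson_params, n_r=32, n_z=32)

    def test_bolus_area_nonincreasing_in_plug_width(self):
        areas = []
        for hp in (0.0, 0.01, 0.05, 0.09):
            p = CiliaParams(epsilon=0.25, alpha=0.4, beta=0.4, hp=hp)
            areas.append(trapping_metrics(_pump(0.95, p), p).total_area)
        assert areas[0] > 0  # trapping occurs in the Newtonian panel
        assert np.all(np.diff(areas) <= 1e-12)

    def test_bolus_area_nondecreasing_in_cilia_length(self):
        areas = []
        for eps in (0.05, 0.15, 0.25, 0.35):
            p = CiliaParams(epsilon=eps, alpha=0.4, beta=0.4, hp=0.05)
            areas.append(trapping_metrics(_pump(0.95, p), p).total_area)
        assert np.all(np.diff(areas) >= -1e-12)

    def test_bolus_count_stable_under_refinement(self, trapping_pump,
                                                 casson_params):
        a = trapping_metrics(trapping_pump, casson_params, n_r=301, n_z=301)
        b = trapping_metrics(trapping_pump, casson_params, n_r=401, n_z=401)
        assert a.n_boluses == b.n_boluses
        assert a.total_area == pytest.approx(b.total_area, rel=0.05)


def test_field_container(trapping_pump, casson_params):
    field = compute_field(trapping_pump, casson_params, n_r=101, n_z=101)
    assert field.psi.shape == (101, 101)
    assert np.all(np.isfinite(field.w[field.mask]))
    # wall rows hold the wall psi value
    np.testing.assert_allclose(field.psi[~field.mask], trapping_pump.q / 2)
    frame = field.to_frame()
    assert set(frame.columns) == {"r", "z", "w", "u", "psi"}
    assert len(frame) == int(field.mask.sum())
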