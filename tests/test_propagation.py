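"""Angular-spectrum propagation, focus metrics, bending and layered media."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.constants import c as C0

from mmvital.propagation import (
    AliasingError,
    ApertureField,
    BendState,
    Layer,
    LayerStack,
    bend_aperture,
    focus_metrics,
    matching_sweep,
    propagate_angular_spectrum,
    tmm_reflection,
)

LAM = 5e-3


def gaussian_field(w0=10e-3, n=256, dx=0.5e-3):
    x = (np.arange(n) - n // 2) * dx
    xx, yy = np.meshgrid(x, x)
    return ApertureField(np.exp(-(xx**2 + yy**2) / w0**2), dx, LAM)


class TestAngularSpectrum:
    def test_z_zero_is_identity(self):
        f = gaussian_field()
        out = propagate_angular_spectrum(f, 0.0)
        np.testing.assert_allclose(out.u, f.u, atol=1e-12)

    def test_plane_wave_phase_advance(self):
        n, dx = 64, 1e-3
        f = ApertureField(np.ones((n, n)), dx, LAM)
        z = 0.01
        out = propagate_angular_spectrum(f, z)
        k = 2 * np.pi / LAM
        np.testing.assert_allclose(out.u, np.exp(1j * k * z) * np.ones((n, n)), atol=1e-9)

    def test_gaussian_beam_width_matches_closed_form(self):
        w0 = 10e-3
        zr = np.pi * w0**2 / LAM
        f = gaussian_field(w0=w0, n=512, dx=0.5e-3)
        out = propagate_angular_spectrum(f, zr)
        inten = np.abs(out.u) ** 2
        x, _ = out.axes()
        profile = inten.sum(axis=0)
        w_num = 2 * np.sqrt((profile * x**2).sum() / profile.sum())
        w_theory = w0 * np.sqrt(2)
        assert w_num == pytest.approx(w_theory, rel=0.01)

    def test_power_conserved_for_propagating_field(self):
        f = gaussian_field()
        out = propagate_angular_spectrum(f, 0.12)
        assert out.power == pytest.approx(f.power, rel=1e-6)

    def test_coarse_grid_raises_aliasing_error(self):
        f = ApertureField(np.ones((16, 16)), 3e-3, LAM)  # dx > lambda/2
        with pytest.raises(AliasingError):
            propagate_angular_spectrum(f, 0.01)


class TestBendGeometry:
    def test_zero_angle_no_sag(self, default_layout):
        x, y, sag, phase = bend_aperture(default_layout, BendState(0.0))
        assert np.all(sag == 0) and np.all(phase == 0)

    def test_sag_even_and_edge_maximal(self, default_layout):
        _, _, sag, _ = bend_aperture(default_layout, BendState(25.0))
        np.testing.assert_allclose(sag, sag[:, ::-1], atol=1e-15)
        assert np.argmax(sag[0]) in (0, sag.shape[1] - 1)

    def test_max_sag_matches_chord_geometry(self, default_layout):
        # oracle: R = arc/angle; sag = R(1 - cos(s_max/R)) at the edge element
        _, _, sag, _ = bend_aperture(default_layout, BendState(40.0))
        theta = np.deg2rad(40.0)
        r_c = default_layout.side_length / theta
        s_edge = 18 * default_layout.pitch  # outermost element centre
        expected = r_c * (1 - np.cos(s_edge / r_c))
        assert sag.max() == pytest.approx(expected, rel=1e-12)

    def test_angle_out_of_studied_range_rejected(self):
        with pytest.raises(ValueError):
            BendState(45.0)


class TestFocusMetrics:
    def test_flat_lens_focuses_with_sane_width(self, default_layout):
        m = focus_metrics(default_layout, spacing=0.5e-3, z_step=2e-3)
        assert not m.boundary_peak
        # diffraction-limit scale at the observed peak plane
        limit = 0.886 * default_layout.wavelength * m.peak_z / default_layout.side_length
        assert m.fwhm_x == pytest.approx(limit, rel=0.15)
        assert 0 <= m.on_axis_profile.min() and m.on_axis_profile.max() == 1.0

    def test_bend_zero_equals_flat(self, default_layout):
        kw = dict(spacing=0.5e-3, z_step=2e-3)
        flat = focus_metrics(default_layout, None, **kw)
        zero = focus_metrics(default_layout, BendState(0.0), **kw)
        assert flat.peak_z == zero.peak_z
        assert flat.fwhm_x == pytest.approx(zero.fwhm_x)
        assert flat.snr_db == pytest.approx(zero.snr_db)

    def test_focal_shift_stable_for_small_bends(self, default_layout):
        kw = dict(spacing=0.5e-3, z_step=2e-3)
        for angle in (0.0, 10.0, 20.0):
            bend = BendState(angle) if angle else None
            m = focus_metrics(default_layout, bend, **kw)
            assert abs(m.focal_shift) <= 0.25 * default_layout.focal_length

    def test_snr_degrades_from_10_to_40_degrees(self, default_layout):
        kw = dict(spacing=0.5e-3, z_step=2e-3)
        snr10 = focus_metrics(default_layout, BendState(10.0), **kw).snr_db
        snr40 = focus_metrics(default_layout, BendState(40.0), **kw).snr_db
        assert snr10 >= snr40


class TestTransferMatrix:
    def test_single_interface_fresnel(self):
        r, t = tmm_reflection(LayerStack([], 1.0, 4.0), 60e9)
        assert abs(r) ** 2 == pytest.approx(1 / 9, abs=1e-10)
        assert r.real == pytest.approx(-1 / 3, abs=1e-10)

    def test_identical_half_spaces_no_reflection(self):
        r, t = tmm_reflection(LayerStack([], 2.25, 2.25), 60e9)
        assert abs(r) == pytest.approx(0.0, abs=1e-12)
        assert t == pytest.approx(1.0)

    def test_half_wave_slab_transparent(self):
        lam0 = C0 / 60e9
        slab = Layer("slab", lam0 / (2 * np.sqrt(4.0)), 4.0)
        r, _ = tmm_reflection(LayerStack([slab], 1.0, 1.0), 60e9)
        assert abs(r) == pytest.approx(0.0, abs=1e-10)

    def test_quarter_wave_matching_layer(self):
        lam0 = C0 / 60e9
        eps_m = np.sqrt(48.0)  # n_m = (n1 n2)^(1/2)
        match = Layer("match", lam0 / (4 * eps_m**0.5), eps_m)
        r, _ = tmm_reflection(LayerStack([match], 1.0, 48.0), 60e9)
        assert abs(r) == pytest.approx(0.0, abs=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(
        eps1=st.floats(1.0, 20.0),
        eps2=st.floats(1.0, 20.0),
        d1=st.floats(1e-4, 5e-3),
        d2=st.floats(1e-4, 5e-3),
        eps_out=st.floats(1.0, 50.0),
    )
    def test_lossless_energy_conservation(self, eps1, eps2, d1, d2, eps_out):
        stack = LayerStack([Layer("a", d1, eps1), Layer("b", d2, eps2)], 1.0, eps_out)
        r, t = tmm_reflection(stack, 60e9)
        t_power = np.sqrt(eps_out) / 1.0 * abs(t) ** 2
        assert abs(r) ** 2 + t_power == pytest.approx(1.0, abs=1e-10)

    def test_zero_thickness_layer_rejected(self):
        with pytest.raises(ValueError):
            Layer("bad", 0.0, 2.0)

    def test_tissue_stack_factory_matches_declared_model(self):
        stack = LayerStack.tissue()
        assert [l.name for l in stack.layers] == ["skin", "fat", "muscle", "bone"]
        assert [l.eps_r for l in stack.layers] == [35.0, 9.0, 52.0, 14.0]
        assert [l.thickness for l in stack.layers] == [10e-3, 20e-3, 20e-3, 15e-3]


class TestMatchingSweep:
    def test_single_point_equals_tmm(self):
        template = LayerStack([Layer("m", 1e-3, 2.0)], 1.0, 48.0)
        grid, eps_opt, th_opt = matching_sweep(template, [2.3], [1.1e-3], 60e9)
        r, _ = tmm_reflection(
            LayerStack([Layer("m", 1.1e-3, 2.3)], 1.0, 48.0), 60e9
        )
        assert grid.shape == (1, 1)
        assert grid[0, 0] == pytest.approx(abs(r))
        assert (eps_opt, th_opt) == (2.3, 1.1e-3)

    def test_sweep_finds_quarter_wave_optimum(self):
        # oracle: closed-form single-slab matching n = sqrt(n_out), d = lam/(4n)
        lam0 = C0 / 60e9
        template = LayerStack([Layer("m", 1e-3, 2.0)], 1.0, 48.0)
        eps_vals = np.linspace(4.0, 10.0, 25)
        th_vals = np.linspace(0.2e-3, 0.8e-3, 61)
        grid, eps_opt, th_opt = matching_sweep(template, eps_vals, th_vals, 60e9)
        assert grid.shape == (25, 61)
        assert eps_opt == pytest.approx(np.sqrt(48.0), rel=0.05)
        assert th_opt == pytest.approx(lam0 / (4 * 48.0**0.25), rel=0.05)

    def test_stack_yaml_round_trip(self, tmp_path):
        stack = LayerStack.tissue()
        path = tmp_path / "stack.yaml"
        stack.to_yaml(path)
        back = LayerStack.from_yaml(path)
        assert back.layers == stack.layers
        assert back.exit_eps == stack.exit_eps
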