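"""Overlap coefficient, defocus phase, sensitivity sweep and contrast metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tubeao import (
    contrast_enhancement,
    gaussian_amplitude,
    overlap,
    percentile_projection,
    sensitivity_sweep,
    synth_stack,
)
from tubeao.metrics import DefocusModel, defocus_phase
from tubeao.pattern import PhasePattern
from tubeao.raytracer import pupil_pixel_grid
from tubeao.zernike_ao import zernike_mode

K0 = 2 * np.pi / 0.804
DM = DefocusModel(n=1.33, numerical_aperture=0.8, k0=K0)


def _pattern(phase_fn, shape=(96, 96)):
    px, py = pupil_pixel_grid(shape)
    mask = np.hypot(px, py) <= 1.0
    phase = np.where(mask, phase_fn(px, py), np.nan)
    return PhasePattern(phase=phase, valid_mask=mask, pupil_x=px, pupil_y=py)


AMP = gaussian_amplitude((96, 96), 1.18)


class TestGaussianAmplitude:
    def test_unit_power(self):
        assert np.sum(AMP.amplitude**2) == pytest.approx(1.0, abs=1e-12)

    def test_edge_to_centre_ratio_matches_closed_form(self):
        """A(R)/A(0) = exp(-1/w^2) with w = 1.18 (units of pupil radius)."""
        px, py = pupil_pixel_grid((96, 96))
        r = np.hypot(px, py)
        centre = AMP.amplitude[np.unravel_index(np.argmin(r), r.shape)]
        edge_pix = np.unravel_index(np.argmin(np.abs(r - 1.0) + ~AMP.pupil_mask), r.shape)
        ratio = AMP.amplitude[edge_pix] / centre
        expected = np.exp(-(r[edge_pix] ** 2) / 1.18**2) / np.exp(
            -(r[np.unravel_index(np.argmin(r), r.shape)] ** 2) / 1.18**2
        )
        assert ratio == pytest.approx(expected, rel=1e-9)
        assert np.exp(-1 / 1.18**2) == pytest.approx(0.487, abs=1e-3)

    def test_flat_limit(self):
        big = gaussian_amplitude((64, 64), 1e6)
        vals = big.amplitude[big.pupil_mask]
        assert vals.max() / vals.min() == pytest.approx(1.0, abs=1e-6)


class TestDefocusPhase:
    PX, PY = pupil_pixel_grid((64, 64))

    def test_zero_distance_zero_phase(self):
        np.testing.assert_allclose(
            np.nan_to_num(defocus_phase(DM, self.PX, self.PY, 0.0)), 0.0
        )

    def test_on_axis_value(self):
        phi = defocus_phase(DM, np.array([[0.0]]), np.array([[0.0]]), 2.0)
        assert phi[0, 0] == pytest.approx(2.0 * K0 * 1.33, rel=1e-12)

    def test_na_zero_limit_constant(self):
        dm0 = DefocusModel(n=1.33, numerical_aperture=1e-9, k0=K0)
        phi = defocus_phase(dm0, self.PX, self.PY, 2.0)
        np.testing.assert_allclose(phi, 2.0 * K0 * 1.33, rtol=1e-12)

    def test_monotone_decreasing_in_r(self):
        r = np.linspace(0, 1, 50)
        phi = defocus_phase(DM, r, np.zeros_like(r), 1.0)
        assert np.all(np.diff(phi) < 0)


class TestOverlap:
    def test_identity_gives_unity_at_zero_defocus(self):
        p = _pattern(lambda x, y: 3 * (x**2 - y**2))
        g2, zd = overlap(p, p, AMP, DM)
        assert g2 == pytest.approx(1.0, abs=1e-12)
        assert zd == pytest.approx(0.0, abs=0.2)

    def test_piston_invariance(self):
        p = _pattern(lambda x, y: 3 * (x**2 - y**2))
        q = p.with_phase(p.phase + 2.5)
        g2, _ = overlap(p, q, AMP, DM)
        assert g2 == pytest.approx(1.0, abs=1e-12)

    def test_swap_symmetry_with_reversed_defocus(self):
        p = _pattern(lambda x, y: 2 * x**2 + 0.5 * np.sin(3 * y))
        q = _pattern(lambda x, y: np.cos(2 * x) - y**2)
        g12, z12 = overlap(p, q, AMP, DM)
        g21, z21 = overlap(q, p, AMP, DM)
        assert g12 == pytest.approx(g21, abs=1e-9)
        assert z12 == pytest.approx(-z21, abs=0.11)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        amp_rms = rng.uniform(0.1, 20.0)
        p = _pattern(lambda x, y: np.zeros_like(x), shape=(48, 48))
        q = _pattern(
            lambda x, y: amp_rms * np.sin(rng.uniform(1, 5) * x + rng.uniform(0, 3))
            * np.cos(rng.uniform(1, 5) * y),
            shape=(48, 48),
        )
        amp = gaussian_amplitude((48, 48), 1.18)
        g2, _ = overlap(p, q, amp, DM, zd_scan=np.linspace(-5, 5, 51))
        assert 0.0 <= g2 <= 1.0

    def test_marechal_small_aberration_regime(self):
        """For weak aberrations |gamma|^2 tracks the Strehl ratio exp(-sigma^2)."""
        px, py = pupil_pixel_grid((96, 96))
        for eps in (0.1, 0.2, 0.3):
            aberr = eps * zernike_mode(2, 2, px, py)  # orthogonal to defocus
            p = _pattern(lambda x, y: np.zeros_like(x))
            q = p.with_phase(np.where(p.valid_mask, aberr, np.nan))
            g2, _ = overlap(p, q, AMP, DM)
            w = AMP.amplitude[p.valid_mask] ** 2
            w = w / w.sum()
            phi = aberr[p.valid_mask]
            sigma2 = np.sum(w * phi**2) - np.sum(w * phi) ** 2
            assert g2 == pytest.approx(np.exp(-sigma2), rel=0.02)

    def test_mismatched_grids_rejected(self):
        p = _pattern(lambda x, y: x, shape=(64, 64))
        q = _pattern(lambda x, y: x, shape=(96, 96))
        with pytest.raises(ValueError):
            overlap(p, q, AMP, DM)


class TestSensitivitySweep:
    def test_nominal_value_is_self_overlap(self, small_scene, small_amp):
        from tubeao import compute_correction

        s = small_scene
        f = s.focus_presets["bottom"]
        ref = compute_correction(s.tube, s.objective, s.config, f)
        pts = sensitivity_sweep(
            "outer_radius",
            [s.tube.outer_radius],
            s.tube,
            s.objective,
            s.config,
            f,
            ref,
            small_amp,
        )
        assert pts[0].gamma_squared == pytest.approx(1.0, abs=1e-9)

    def test_local_peak_and_nonphysical_skipped(self, small_scene, small_amp):
        """|gamma|^2 does not increase away from the nominal value; impossible
        geometries yield warning entries instead of raising."""
        from tubeao import compute_correction

        s = small_scene
        f = s.focus_presets["bottom"]
        ref = compute_correction(s.tube, s.objective, s.config, f)
        nominal = s.tube.shell_thickness
        with pytest.warns(UserWarning):
            pts = sensitivity_sweep(
                "shell_thickness",
                [nominal, nominal + 2.0, nominal + 4.0, s.tube.outer_radius + 1],
                s.tube,
                s.objective,
                s.config,
                f,
                ref,
                small_amp,
            )
        g = [p.gamma_squared for p in pts[:3]]
        assert g[0] >= g[1] >= g[2]
        assert not pts[3].valid and np.isnan(pts[3].gamma_squared)


class TestContrastEnhancement:
    def test_equal_stacks_no_background(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(10, 16, 16))
        res = contrast_enhancement(img, img, np.zeros((10, 16, 16)))
        assert res.defined
        assert res.eta_sigma == pytest.approx(1.0, abs=1e-12)

    def test_arithmetic(self):
        """Planted variances 101 / 2 / 1 give eta = sqrt(100/1) = 10."""
        rng = np.random.default_rng(1)
        n = 400_000
        c = rng.normal(0, np.sqrt(101), n)
        u = rng.normal(0, np.sqrt(2), n)
        b = rng.normal(0, 1, n)
        res = contrast_enhancement(c, u, b)
        assert res.eta_sigma == pytest.approx(10.0, rel=0.02)

    def test_undefined_flagged_not_clipped(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 1.0, 20_000)
        weak = rng.normal(0, 0.5, 20_000)  # denominator variance < background
        res = contrast_enhancement(noise, weak, noise + rng.normal(0, 0.1, 20_000))
        assert not res.defined
        assert np.isnan(res.eta_sigma)

    def test_planted_ratio_recovered_from_synthetic_stacks(self):
        corr, unc, bg, truth = synth_stack(
            shape=(74, 64, 64), signal_variance=(4.0, 1.0), background_variance=0.25,
            seed=7,
        )
        res = contrast_enhancement(corr, unc, bg)
        assert res.defined
        assert res.eta_sigma == pytest.approx(truth, rel=0.05)


class TestPercentileProjection:
    def test_q100_is_max_projection(self):
        rng = np.random.default_rng(3)
        stack = rng.normal(size=(20, 8, 8))
        np.testing.assert_allclose(
            percentile_projection(stack, 100), stack.max(axis=0)
        )

    def test_constant_stack(self):
        stack = np.full((5, 4, 4), 2.5)
        np.testing.assert_allclose(percentile_projection(stack, 99.5), 2.5)

    def test_single_bright_plane_suppressed(self):
        """With 74 planes, the 99.5th percentile falls below one bright sample."""
        stack = np.zeros((74, 6, 6))
        stack[40] = 10.0
        proj = percentile_projection(stack, 99.5)
        assert np.all(proj < 10.0)
        np.testing.assert_array_equal(percentile_projection(stack, 100), 10.0)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            percentile_projection(np.zeros((0, 4, 4)), 99.5)
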