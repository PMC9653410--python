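"""Spectrum estimator against a brute-force DFT oracle, Parseval identity,
closed-form sine modes, and the two-regime fixed-slope Helfrich fit."""

import numpy as np
import pytest

from conftest import brute_force_dft_power, make_flat_frame
from memfluct.frames import INNER, OUTER
from memfluct.mechanics import (
    FluctuationSpectrum,
    HeightFieldStack,
    build_height_field,
    compute_spectrum,
    fit_bending_modulus,
    helfrich_intensity,
    membrane_spectrum,
    scale_moduli,
    spectrum_parseval_sum,
)
from memfluct.synthetic import (
    DeformationTemplate,
    FootprintSpec,
    SyntheticSpec,
    apply_deformation_field,
    generate_undulating_membrane,
)


def grid_stack(fields, box=96.0):
    fields = np.asarray(fields, dtype=float)
    if fields.ndim == 2:
        fields = fields[None]
    nx, ny = fields.shape[1:]
    return HeightFieldStack(fields, box, box, box / nx, box / ny, 1.0)


class TestHeightField:
    def test_flat_membrane_yields_zero_field(self, flat_frames):
        stack = build_height_field(flat_frames, grid_bin=8.0)
        assert np.abs(stack.fields).max() < 1e-12

    def test_sine_reproduced_at_bin_centers(self):
        f = make_flat_frame(n_side=32, box=(128.0, 128.0, 120.0))
        k = 2 * np.pi / 128.0
        f.positions[:, 2] += 3.0 * np.sin(k * f.positions[:, 0])
        stack = build_height_field([f], grid_bin=4.0)
        xc = (np.arange(32) + 0.5) * 4.0
        expected = 3.0 * np.sin(k * xc)
        expected -= expected.mean()
        np.testing.assert_allclose(stack.fields[0][:, 0], expected, atol=1e-9)

    def test_deformation_cancels_in_undulation_mode(self, flat_frames):
        """A mirrored elevation/depression pair is a thickness (peristaltic)
        perturbation: it vanishes from the pooled undulation field but
        survives in peristaltic mode."""
        # radius 5 leaves every lattice site in place, so outer and inner
        # bins stay balanced and the mirrored field cancels exactly
        fp = FootprintSpec(center_xy=(64, 64), footprint_radius=5, dimer_id="D1")
        frames = apply_deformation_field(
            flat_frames, [(fp, DeformationTemplate(amplitude=5))]
        )
        und = build_height_field(frames, grid_bin=8.0, leaflet_mode="undulation")
        per = build_height_field(frames, grid_bin=8.0, leaflet_mode="peristaltic")
        assert np.abs(und.fields).max() < 0.3
        assert np.abs(per.fields).max() > 2.0

    def test_sparse_grid_rejected(self, flat_frames):
        with pytest.raises(ValueError, match="sparse"):
            build_height_field(flat_frames, grid_bin=1.0)


class TestSpectrum:
    def test_planted_sine_has_parseval_intensity(self):
        L, a, nx = 96.0, 3.0, 32
        x = (np.arange(nx) + 0.5) * L / nx
        field = a * np.sin(2 * np.pi * 4 * x / L)[:, None] * np.ones((1, nx))
        sp = compute_spectrum(grid_stack(field, L), window_correction=False,
                              q_discard_fraction=0.0)
        q0 = 8 * np.pi / L
        expect = a**2 * L * L / 4
        # the two Hermitian partners of the planted mode each hold a^2 A / 4;
        # degenerate |q| modes along other directions stay empty
        hot = sp.intensity_modes > expect / 100
        assert hot.sum() == 2
        np.testing.assert_allclose(sp.q_modes[hot], q0, rtol=1e-9)
        np.testing.assert_allclose(sp.intensity_modes[hot], expect, rtol=1e-9)

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(51)
        fields = rng.normal(0, 2.0, size=(4, 16, 16))
        fields -= fields.mean(axis=(1, 2), keepdims=True)
        stack = grid_stack(fields, 64.0)
        sp = compute_spectrum(stack, window_correction=False, q_discard_fraction=0.0)
        oracle = brute_force_dft_power(fields, 64.0 * 64.0)
        qx = 2 * np.pi * np.fft.fftfreq(16, d=4.0)
        qg = np.hypot(*np.meshgrid(qx, qx, indexing="ij"))
        # the estimator reports isotropic shells up to the radial Nyquist;
        # compare every mode it keeps against the brute-force value
        keep = (qg > 0) & (qg <= np.pi / 4.0)
        got = {}
        for q, i in zip(sp.q_modes, sp.intensity_modes):
            got.setdefault(round(q, 9), []).append(i)
        for q, p in zip(qg[keep], oracle[keep]):
            assert any(abs(p - i) < 1e-9 * max(p, 1) for i in got[round(q, 9)])

    def test_parseval_identity(self):
        rng = np.random.default_rng(53)
        fields = rng.normal(0, 1.5, size=(6, 24, 24))
        stack = grid_stack(fields, 96.0)
        total = spectrum_parseval_sum(stack)
        variance = np.mean(fields.var(axis=(1, 2)) + fields.mean(axis=(1, 2)) ** 2)
        assert abs(total - variance) < 1e-9

    def test_white_noise_spectrum_is_flat_at_bin_area_level(self):
        rng = np.random.default_rng(55)
        v = 4.0
        fields = rng.normal(0, np.sqrt(v), size=(400, 24, 24))
        fields -= fields.mean(axis=(1, 2), keepdims=True)
        sp = compute_spectrum(grid_stack(fields, 96.0), window_correction=False)
        expect = v * 4.0 * 4.0          # variance times bin area
        assert np.all(np.abs(sp.intensity - expect) < 0.1 * expect)

    def test_equipartition_round_trip(self):
        spec = SyntheticSpec(n_frames=300, seed=57)
        frames = generate_undulating_membrane(spec)
        sp = membrane_spectrum(frames, grid_bin=8.0)
        model = helfrich_intensity(sp.q, spec.bending_modulus)
        low = sp.q <= sp.q[len(sp.q) // 2]
        assert np.all(np.abs(sp.intensity[low] / model[low] - 1.0) < 0.15)


class TestFit:
    def test_noise_free_model_recovered_to_machine_precision(self):
        q = np.geomspace(0.02, 0.5, 25)
        sp = FluctuationSpectrum.from_model(q, bending_modulus=20.0)
        fit = fit_bending_modulus(sp)
        assert fit.bending_modulus_kbt == pytest.approx(20.0, rel=1e-12)
        assert fit.crossover_q == q[-1]           # pure undulation: edge
        assert fit.rss_undulation < 1e-20

    def test_two_regime_model_recovered(self):
        q = np.geomspace(0.005, 2.0, 50)
        K, c = 20.0, 5.0                          # crossover near q = 0.1
        sp = FluctuationSpectrum(
            q, helfrich_intensity(q, K) + c / q**2,
            np.ones_like(q, int), area=np.nan, grid_bin=(np.nan, np.nan),
        )
        fit = fit_bending_modulus(sp)
        assert abs(fit.bending_modulus_kbt - K) / K < 0.05
        assert 0.02 < fit.crossover_q < 0.3
        assert np.isfinite(fit.intercept_protrusion)

    def test_joule_conversion(self):
        q = np.geomspace(0.02, 0.5, 12)
        fit = fit_bending_modulus(
            FluctuationSpectrum.from_model(q, 25.0), temperature=310.0
        )
        assert fit.bending_modulus_joule == pytest.approx(
            25.0 * 1.380649e-23 * 310.0, rel=1e-6
        )

    def test_nonphysical_and_short_spectra_rejected(self):
        q = np.geomspace(0.02, 0.5, 12)
        rising = FluctuationSpectrum(q, q**2, np.ones_like(q, int),
                                     area=np.nan, grid_bin=(np.nan, np.nan))
        with pytest.raises(ValueError, match="increases"):
            fit_bending_modulus(rising)
        with pytest.raises(ValueError, match="shells"):
            fit_bending_modulus(FluctuationSpectrum.from_model(q[:3], 20.0))

    def test_estimate_invariant_under_field_translation_and_rotation(self):
        spec = SyntheticSpec(n_frames=100, seed=59)
        frames = generate_undulating_membrane(spec)
        stack = build_height_field(frames, grid_bin=8.0)
        k0 = fit_bending_modulus(compute_spectrum(stack)).bending_modulus_kbt

        rolled = HeightFieldStack(
            np.roll(stack.fields, (5, 11), axis=(1, 2)),
            stack.box_x, stack.box_y, stack.dx, stack.dy, stack.occupancy,
        )
        k_roll = fit_bending_modulus(compute_spectrum(rolled)).bending_modulus_kbt
        assert k_roll == pytest.approx(k0, rel=1e-9)

        rotated = HeightFieldStack(
            np.rot90(stack.fields, axes=(1, 2)).copy(),
            stack.box_y, stack.box_x, stack.dy, stack.dx, stack.occupancy,
        )
        k_rot = fit_bending_modulus(compute_spectrum(rotated)).bending_modulus_kbt
        assert k_rot == pytest.approx(k0, rel=1e-9)

    def test_consistency_when_doubling_frames(self):
        spec = SyntheticSpec(n_frames=400, seed=61)
        frames = generate_undulating_membrane(spec)
        k1 = fit_bending_modulus(membrane_spectrum(frames[:200], grid_bin=8.0)).bending_modulus_kbt
        k2 = fit_bending_modulus(membrane_spectrum(frames, grid_bin=8.0)).bending_modulus_kbt
        assert abs(k1 - k2) / k2 < 0.10


class TestScaledModuli:
    def test_single_system_scales_to_one(self):
        df = scale_moduli({"only": 17.3})
        assert df["scaled_K"].tolist() == [1.0]

    def test_simple_arithmetic(self):
        df = scale_moduli({"a": 2.0, "b": 4.0}).set_index("system")
        assert df.loc["a", "scaled_K"] == 0.5
        assert df.loc["b", "scaled_K"] == 1.0

    def test_groups_scale_independently(self):
        df = scale_moduli(
            {"a": 2.0, "b": 4.0, "c": 10.0},
            groups={"a": "g1", "b": "g1", "c": "g2"},
        ).set_index("system")
        assert df.loc["b", "scaled_K"] == 1.0
        assert df.loc["c", "scaled_K"] == 1.0
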