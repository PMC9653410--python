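"""Generator tests: equipartition sampling, deformation fields, planted
enrichment and the rotating-dimer sampler, each against an independent
oracle where the expected value is not a construction identity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memfluct.frames import INNER, OUTER
from memfluct.synthetic import (
    DEFAULT_COMPOSITION,
    AngularPotential,
    DeformationTemplate,
    FootprintSpec,
    SyntheticSpec,
    apply_deformation_field,
    deformation_field,
    fourier_modes,
    generate_undulating_membrane,
    orientation_coupling,
    plant_enrichment,
    sample_rotating_dimers,
)
from memfluct.lipids import depletion_enrichment


class TestUndulations:
    def test_infinite_stiffness_is_flat(self):
        spec = SyntheticSpec(
            box_x=128, box_y=128, lipids_per_leaflet=256,
            bending_modulus=1e9, n_frames=3, seed=0,
        )
        for f in generate_undulating_membrane(spec):
            z = f.positions[:, 2]
            assert np.abs(np.abs(z) - spec.leaflet_offset).max() < 1e-2

    def test_per_mode_variance_matches_equipartition(self):
        """Brute-force point-sampled Fourier coefficients recover the planted
        per-mode variance kBT/(A K q^4) for the lowest wavenumber shells."""
        spec = SyntheticSpec(bending_modulus=20.0, n_frames=600, seed=42)
        frames = generate_undulating_membrane(spec)
        q, _var = fourier_modes(spec)
        qmag = np.hypot(q[:, 0], q[:, 1])
        lowest = q[np.argsort(qmag)[:8]]
        acc = np.zeros(len(lowest))
        for f in frames:
            outer = f.leaflet == OUTER
            r = f.positions[outer, :2]
            h = f.positions[outer, 2] - f.positions[outer, 2].mean()
            for k, qv in enumerate(lowest):
                coef = np.mean(h * np.exp(-1j * (r @ qv)))
                acc[k] += abs(coef) ** 2
        acc /= len(frames)
        expected = 1.0 / (spec.area * spec.bending_modulus * np.hypot(lowest[:, 0], lowest[:, 1]) ** 4)
        ratio = spec.area * acc / (spec.area * expected)
        assert np.all(np.abs(ratio - 1.0) < 0.10)

    def test_composition_matches_multinomial(self):
        spec = SyntheticSpec(n_frames=1, seed=7)
        frame = generate_undulating_membrane(spec)[0]
        n = frame.n_lipids
        for lipid, p in DEFAULT_COMPOSITION.items():
            count = int((frame.types == lipid).sum())
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(count - n * p) < 4 * sigma, lipid

    def test_frames_respect_periodic_wrapping(self):
        spec = SyntheticSpec(
            box_x=96, box_y=64, lipids_per_leaflet=128, n_frames=4, seed=3
        )
        frames = generate_undulating_membrane(spec)
        fp = FootprintSpec(center_xy=(48, 32), footprint_radius=10, dimer_id="D1")
        frames += apply_deformation_field(frames, [(fp, DeformationTemplate())])
        for f in frames:
            assert np.all(f.positions[:, 0] >= 0) and np.all(f.positions[:, 0] < f.box[0])
            assert np.all(f.positions[:, 1] >= 0) and np.all(f.positions[:, 1] < f.box[1])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticSpec(composition={"POPC": 0.5})
        with pytest.raises(ValueError, match="bending modulus"):
            SyntheticSpec(bending_modulus=0.0)
        with pytest.raises(ValueError):
            # box far too small for any resolvable undulation mode
            fourier_modes(SyntheticSpec(box_x=8, box_y=8, lipids_per_leaflet=4))


class TestDeformation:
    def test_cosine_maximum_on_ring(self):
        fp = FootprintSpec(center_xy=(100.0, 100.0), orientation=0.0)
        t = DeformationTemplate(amplitude=-3.5, radial_center=25, radial_width=8)
        box = np.array([400.0, 200.0, 100.0])
        val = deformation_field(np.array([[125.0, 100.0]]), fp, t, box)
        assert val[0] == pytest.approx(-3.5, abs=1e-12)

    def test_zero_amplitude_is_identity_outside_footprint(self, flat_frames):
        fp = FootprintSpec(center_xy=(64, 64), footprint_radius=5, dimer_id="D1")
        out = apply_deformation_field(flat_frames, [(fp, DeformationTemplate(amplitude=0.0))])
        from memfluct.frames import minimum_image
        for a, b in zip(flat_frames, out):
            assert a.n_lipids == b.n_lipids       # displaced, never deleted
            d = minimum_image(a.positions[:, :2] - np.array([64.0, 64.0]), a.box[:2])
            outside = np.hypot(d[:, 0], d[:, 1]) >= 5.0
            np.testing.assert_array_equal(a.positions[outside], b.positions[outside])

    @settings(max_examples=25, deadline=None)
    @given(
        amp1=st.floats(-8, 8), amp2=st.floats(-8, 8),
        th1=st.floats(0, 359), th2=st.floats(0, 359),
    )
    def test_superposition_is_exactly_linear(self, amp1, amp2, th1, th2):
        box = np.array([400.0, 200.0, 100.0])
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, [400, 200], size=(50, 2))
        f1 = FootprintSpec(center_xy=(100, 100), orientation=th1)
        f2 = FootprintSpec(center_xy=(300, 100), orientation=th2)
        t1 = DeformationTemplate(amplitude=amp1)
        t2 = DeformationTemplate(amplitude=amp2)
        total = deformation_field(pts, f1, t1, box) + deformation_field(pts, f2, t2, box)
        np.testing.assert_allclose(
            total,
            deformation_field(pts, f1, t1, box) + deformation_field(pts, f2, t2, box),
            rtol=0, atol=0,
        )
        # and doubling one amplitude doubles exactly that contribution
        t1d = DeformationTemplate(amplitude=2 * amp1)
        np.testing.assert_allclose(
            deformation_field(pts, f1, t1d, box),
            2 * deformation_field(pts, f1, t1, box),
            atol=1e-12,
        )

    def test_facing_lobes_add_or_cancel(self):
        """Two dimers presenting same-sign lobes to each other interfere
        constructively at the midpoint; opposite-sign lobes cancel."""
        box = np.array([400.0, 200.0, 100.0])
        mid = np.array([[200.0, 100.0]])
        t = DeformationTemplate(amplitude=4.0, decay_length=60, radial_width=30)
        def pair(tha, thb):
            fa = FootprintSpec(center_xy=(100, 100), orientation=tha)
            fb = FootprintSpec(center_xy=(300, 100), orientation=thb)
            return float(
                deformation_field(mid, fa, t, box)[0]
                + deformation_field(mid, fb, t, box)[0]
            )
        assert abs(pair(0, 0)) > 10 * abs(pair(0, 90))

    def test_inner_leaflet_mirrors_outer(self, flat_frames):
        fp = FootprintSpec(center_xy=(64, 64), orientation=0, footprint_radius=5)
        out = apply_deformation_field(
            flat_frames[:1], [(fp, DeformationTemplate(amplitude=6))]
        )[0]
        probe_outer = out.positions[(out.leaflet == OUTER)]
        probe_inner = out.positions[(out.leaflet == INNER)]
        # lattices coincide in xy, so sort both and compare dz
        o = probe_outer[np.lexsort(probe_outer[:, :2].T)]
        i = probe_inner[np.lexsort(probe_inner[:, :2].T)]
        np.testing.assert_allclose(o[:, 2] - 20.0, -(i[:, 2] + 20.0), atol=1e-9)

    def test_footprint_excludes_lipids_and_attaches_dimer(self, flat_frames):
        fp = FootprintSpec(center_xy=(64, 64), footprint_radius=12, dimer_id="DX")
        out = apply_deformation_field(flat_frames, [(fp, DeformationTemplate())])
        for f in out:
            d = np.hypot(f.positions[:, 0] - 64, f.positions[:, 1] - 64)
            assert np.all(d >= 12.0)
            assert f.get_dimer("DX") is not None

    def test_overlapping_footprints_warn(self, flat_frames):
        fps = [
            (FootprintSpec(center_xy=(60, 64), footprint_radius=10, dimer_id="A"),
             DeformationTemplate()),
            (FootprintSpec(center_xy=(70, 64), footprint_radius=10, dimer_id="B"),
             DeformationTemplate()),
        ]
        with pytest.warns(UserWarning, match="overlap"):
            apply_deformation_field(flat_frames[:1], fps)


class TestPlantedEnrichment:
    @staticmethod
    def _system(seed=0, n_frames=150):
        spec = SyntheticSpec(
            box_x=128, box_y=128, lipids_per_leaflet=256, n_frames=n_frames, seed=seed
        )
        frames = generate_undulating_membrane(spec)
        fp = FootprintSpec(
            center_xy=(64, 64), footprint_radius=12, dimer_id="D1",
            enrichment={},
        )
        frames = apply_deformation_field(
            frames, [(fp, DeformationTemplate(amplitude=0.0, radial_center=14))]
        )
        return frames, fp

    def test_all_ones_is_null(self):
        frames, fp = self._system(seed=1)
        fp.enrichment = {t: 1.0 for t in DEFAULT_COMPOSITION}
        planted = plant_enrichment(frames, fp, cutoff=7.0, seed=2)
        table = depletion_enrichment(planted, cutoff=7.0)
        for _, row in table.data.iterrows():
            se = row["index_std"] / np.sqrt(row["n_snapshots"])
            assert abs(row["index"] - 1.0) <= 3 * max(se, 1e-6), row["type"]

    def test_target_recovered(self):
        frames, fp = self._system(seed=3)
        fp.enrichment = {"POPI": 2.2}
        planted = plant_enrichment(frames, fp, cutoff=7.0, seed=4)
        table = depletion_enrichment(planted, cutoff=7.0)
        se = table.stderr_of("POPI")
        assert abs(table.index_of("POPI") - 2.2) <= 3 * se

    def test_zero_target_fully_depletes(self):
        frames, fp = self._system(seed=5, n_frames=30)
        fp.enrichment = {"DPSM": 0.0}
        planted = plant_enrichment(frames, fp, cutoff=7.0, seed=6)
        from memfluct.frames import nearest_dimer_distance
        for f in planted:
            near = nearest_dimer_distance(f, ["D1"]) <= 7.0
            assert not np.any(f.types[near] == "DPSM")

    def test_infeasible_target_rejected(self):
        frames, fp = self._system(seed=7, n_frames=2)
        fp.enrichment = {"POPG": 40.0}   # bulk ~0.04 -> local fraction > 1
        with pytest.raises(ValueError, match="infeasible|> 1"):
            plant_enrichment(frames, fp, cutoff=7.0, seed=8)

    def test_lipid_count_unchanged(self):
        frames, fp = self._system(seed=9, n_frames=3)
        fp.enrichment = {"POPI": 2.0}
        planted = plant_enrichment(frames, fp, cutoff=7.0, seed=10)
        for a, b in zip(frames, planted):
            assert a.n_lipids == b.n_lipids


class TestRotatingDimerSampler:
    @pytest.mark.filterwarnings("ignore:Metropolis acceptance")
    def test_flat_potential_uniform(self):
        pot = AngularPotential.flat(24, step_deg=45.0)
        t1, t2, acc = sample_rotating_dimers(pot, 200_000, seed=11)
        assert acc == 1.0   # zero-energy landscape accepts every move
        counts, _ = np.histogram(t1, bins=12, range=(0, 360))
        expected = len(t1) / 12
        assert np.all(np.abs(counts - expected) < 0.25 * expected)

    def test_two_well_boltzmann_ratio(self):
        """Well vs barrier occupancy matches the numeric Boltzmann integral."""
        pot = AngularPotential.from_wells(
            [(45, 45), (135, 135)], depth=4.0, width=40.0, step_deg=35.0
        )
        t1, t2, _ = sample_rotating_dimers(pot, 300_000, seed=12, burn_in=5000)
        def box_frac(c, half=30):
            in1 = (np.abs((t1 - c[0] + 180) % 360 - 180) < half)
            in2 = (np.abs((t2 - c[1] + 180) % 360 - 180) < half)
            return np.mean(in1 & in2)
        # oracle from the potential itself
        grid = np.linspace(0, 360, 241)[:-1]
        g1, g2 = np.meshgrid(grid, grid, indexing="ij")
        w = np.exp(-pot.value(g1, g2))
        def oracle_frac(c, half=30):
            m1 = np.abs((g1 - c[0] + 180) % 360 - 180) < half
            m2 = np.abs((g2 - c[1] + 180) % 360 - 180) < half
            return w[m1 & m2].sum() / w.sum()
        for center in ((45, 45), (135, 135), (90, 90)):
            est, exp = box_frac(center), oracle_frac(center)
            assert abs(est - exp) < 0.3 * exp + 0.01, center

    def test_fixed_seed_is_bitwise_deterministic(self):
        pot = AngularPotential.from_wells([(45, 45)], depth=3.0)
        a = sample_rotating_dimers(pot, 5000, seed=13)
        b = sample_rotating_dimers(pot, 5000, seed=13)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_angles_in_range(self):
        pot = AngularPotential.flat(12, step_deg=60.0)
        t1, t2, _ = sample_rotating_dimers(pot, 2000, seed=14)
        for t in (t1, t2):
            assert np.all((t >= 0) & (t < 360))


def test_orientation_coupling_extrema():
    """The planted stiffness modulation is softest for matched 45/135-type
    pairs and stiffest for the 90/90 pair, on the 45-degree design grid."""
    grid = [0.0, 45.0, 90.0, 135.0]
    vals = {(a, b): orientation_coupling(a, b) for a in grid for b in grid}
    assert min(vals, key=vals.get) in {(45.0, 45.0), (135.0, 135.0)}
    assert max(vals, key=vals.get) == (90.0, 90.0)
    # C2 periodicity and dimer-swap symmetry
    assert orientation_coupling(10, 70) == pytest.approx(orientation_coupling(190, 250))
    assert orientation_coupling(10, 70) == pytest.approx(orientation_coupling(70, 10))
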