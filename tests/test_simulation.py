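import numpy as np
import pytest

from vignetta.circular import axial_difference_deg, median_absolute_axial_difference
from vignetta.pyramid import PyramidConfig, build_filter_bank, energy_maps
from vignetta.simulation import (
    ORIENTATIONS_16,
    PRF,
    VoxelMap,
    fit_orientation_cosine,
    orientation_bias_map,
    predict_prf_tuning,
    prf_weights,
    select_scale,
    simulate_orientation_maps,
    simulate_voxel_map,
)
from vignetta.stimuli import (
    AnnulusSpec,
    CarrierSpec,
    ModulatorSpec,
    compose_stimulus,
    make_annulus,
    make_carrier,
    simulation_geometry,
)

from conftest import MID_ECC, SIM_ANNULUS, SIM_CARRIER


@pytest.fixture(scope="module")
def geom96():
    return simulation_geometry(96, 24.0)


@pytest.fixture(scope="module")
def bank96(geom96):
    return build_filter_bank(PyramidConfig(image_shape=geom96.shape))


class TestSimulateVoxelMap:
    def test_uniform_gray_is_zero(self, geom96, bank96):
        vm = simulate_voxel_map([np.full(geom96.shape, 0.5)], bank96, geom96)
        np.testing.assert_allclose(vm.response, 0.0, atol=1e-20)

    def test_empty_set(self, geom96, bank96):
        with pytest.raises(ValueError, match="empty"):
            simulate_voxel_map([], bank96, geom96)

    def test_scale_selection_matches_bruteforce(self, geom96, bank96):
        car = make_carrier(geom96, CarrierSpec(sf_cpd=0.7))
        ann = make_annulus(geom96, AnnulusSpec(2.0, 8.0, 1.0))
        stim = car * ann
        # oracle: loop over scales, total energy per scale from full maps
        totals = [
            energy_maps(stim, bank96)[s].sum() for s in range(bank96.n_scales)
        ]
        assert select_scale([stim], bank96) == int(np.argmax(totals))

    def test_unvignetted_grating_uniform_map(self, geom96, bank96):
        phases = np.arange(8) / 8 * 2 * np.pi
        # integer cycles per image: no wraparound discontinuity (which
        # would itself act as a vignette)
        sf = 16 / (96 * geom96.deg_per_pixel)
        stims = [
            make_carrier(geom96, CarrierSpec(orientation_deg=0.0, sf_cpd=sf,
                                             phase_rad=p))
            for p in phases
        ]
        vm = simulate_voxel_map(stims, bank96, geom96)
        m = 10
        inner = vm.response[m:-m, m:-m]
        assert (inner.max() - inner.min()) / inner.mean() < 0.02


class TestBiasMap:
    def test_zero_for_identical(self, geom96):
        vm = VoxelMap(response=np.random.default_rng(0).random(geom96.shape),
                      scale=0, geometry=geom96)
        bm = orientation_bias_map(vm, vm)
        assert not bm.bias.any()

    def test_antisymmetry(self, geom96):
        rng = np.random.default_rng(1)
        a = VoxelMap(response=rng.random(geom96.shape), scale=0, geometry=geom96)
        b = VoxelMap(response=rng.random(geom96.shape), scale=0, geometry=geom96)
        np.testing.assert_allclose(
            orientation_bias_map(a, b).bias, -orientation_bias_map(b, a).bias
        )

    def test_shape_mismatch(self, geom96):
        a = VoxelMap(response=np.zeros(geom96.shape), scale=0, geometry=geom96)
        b = VoxelMap(response=np.zeros((10, 10)), scale=0, geometry=geom96)
        with pytest.raises(ValueError):
            orientation_bias_map(a, b)

    def test_radial_bias_of_plain_annulus(self, geom96, bank96):
        # classic 5-9 deg annulus, no modulator: vertical-minus-horizontal
        # bias is positive on the vertical meridian, negative on the
        # horizontal meridian (radial preference)
        ann = AnnulusSpec(5.0, 9.0, 1.0)
        maps, _ = simulate_orientation_maps(
            geom96, None, ann, CarrierSpec(sf_cpd=0.5), bank=bank96,
            orientations_deg=np.array([90.0, 0.0]),
            carrier_phases=np.arange(4) / 4 * 2 * np.pi,
        )
        bias = maps[0] - maps[1]
        x, y = geom96.grid_deg()
        r = geom96.eccentricity_deg()
        in_ann = (r > 5.5) & (r < 8.5)
        vertical = in_ann & (np.abs(x) < 1.0)
        horizontal = in_ann & (np.abs(y) < 1.0)
        assert bias[vertical].mean() > 0
        assert bias[horizontal].mean() < 0

    def test_modulators_flip_sign_pattern(self, model_maps, sim_geometry):
        maps_r, maps_a = model_maps["radial"], model_maps["angular"]
        i_v = int(np.argmin(np.abs(ORIENTATIONS_16 - 90.0)))
        x, y = sim_geometry.grid_deg()
        r = sim_geometry.eccentricity_deg()
        ring = (r > MID_ECC - 1) & (r < MID_ECC + 1)
        vert = ring & (np.abs(x) < 0.8)
        horiz = ring & (np.abs(y) < 0.8)
        bias_r = maps_r[i_v] - maps_r[0]
        bias_a = maps_a[i_v] - maps_a[0]
        assert bias_r[vert].mean() > 0 and bias_r[horiz].mean() < 0
        assert bias_a[vert].mean() < 0 and bias_a[horiz].mean() > 0


class TestPRFSampling:
    def test_weights_normalized_and_truncated(self, geom96):
        w = prf_weights(geom96, PRF(2.0, 3.0, 1.0))
        assert w.sum() == pytest.approx(1.0)
        d = np.hypot(*(g - c for g, c in zip(geom96.grid_deg(), (2.0, 3.0))))
        assert not w[d > 4.0].any()

    def test_prf_outside_fov(self, geom96):
        with pytest.raises(ValueError, match="mass"):
            prf_weights(geom96, PRF(100.0, 0.0, 1.0))

    def test_vertical_meridian_flip(self, model_maps, sim_geometry):
        prf = PRF(0.0, 7.0, 1.0)
        t_rad = predict_prf_tuning(model_maps["radial"], prf, sim_geometry)
        t_ang = predict_prf_tuning(model_maps["angular"], prf, sim_geometry)
        assert abs(axial_difference_deg(t_rad.preferred_deg, 90.0)) < 10
        assert abs(axial_difference_deg(t_ang.preferred_deg, 0.0)) < 10

    def test_constant_responses_flagged(self, geom96):
        maps = np.ones((16,) + geom96.shape)
        t = predict_prf_tuning(maps, PRF(0.0, 5.0, 1.0), geom96)
        assert t.amplitude == 0.0
        assert not t.defined


class TestCosineFit:
    def test_matches_least_squares(self):
        rng = np.random.default_rng(5)
        n = 16
        design = np.column_stack(
            [np.ones(n), np.cos(2 * np.pi * np.arange(n) / n),
             np.sin(2 * np.pi * np.arange(n) / n)]
        )
        for _ in range(20):
            r = rng.random(n) * 10
            pref, amp = fit_orientation_cosine(r)
            coef, *_ = np.linalg.lstsq(design, r, rcond=None)
            amp_ls = np.hypot(coef[1], coef[2])
            pref_ls = (np.arctan2(coef[2], coef[1]) / (2 * np.pi) * 180.0) % 180.0
            assert amp == pytest.approx(amp_ls, abs=1e-10)
            d = abs(axial_difference_deg(pref, pref_ls))
            assert d < 1e-10 / max(amp, 1e-12) or d == pytest.approx(0, abs=1e-8)

    def test_pure_cosine(self):
        i = np.arange(16)
        r = 2.0 + 1.5 * np.cos(2 * np.pi * (i - 5) / 16)
        pref, amp = fit_orientation_cosine(r)
        assert amp == pytest.approx(1.5, abs=1e-12)
        assert pref == pytest.approx(5 * 11.25, abs=1e-9)

    def test_flat_flagged(self):
        pref, amp = fit_orientation_cosine(np.full(16, 3.0))
        assert np.isnan(pref) and amp == 0.0


class TestFlipProperties:
    def test_ring_flip_90(self, model_maps, sim_geometry):
        prefs = {"radial": [], "angular": []}
        for beta in np.arange(16) / 16 * 2 * np.pi:
            prf = PRF(MID_ECC * np.cos(beta), MID_ECC * np.sin(beta), 1.0)
            for axis in prefs:
                t = predict_prf_tuning(model_maps[axis], prf, sim_geometry)
                prefs[axis].append(t.preferred_deg)
        flip = median_absolute_axial_difference(
            np.array(prefs["radial"]), np.array(prefs["angular"])
        )
        assert abs(flip - 90.0) <= 10.0

    def test_rotational_equivariance(self, model_maps, sim_geometry):
        # rotating the pRF around the ring shifts radial preference by the
        # same angle (the stimulus family is rotation covariant)
        for axis in ("radial", "angular"):
            base = predict_prf_tuning(
                model_maps[axis], PRF(MID_ECC, 0.0, 1.0), sim_geometry
            ).preferred_deg
            for beta_deg in (45.0, 90.0, 135.0):
                b = np.deg2rad(beta_deg)
                t = predict_prf_tuning(
                    model_maps[axis],
                    PRF(MID_ECC * np.cos(b), MID_ECC * np.sin(b), 1.0),
                    sim_geometry,
                )
                d = axial_difference_deg(t.preferred_deg, base + beta_deg)
                assert abs(d) < 7.0

    def test_orientation_dependence_requires_vignette(self, geom96, bank96):
        # summing across orientation channels: without a vignette the maps
        # are orientation independent; with one they are not
        phases = np.arange(4) / 4 * 2 * np.pi
        m = 10
        sf = 16 / (96 * geom96.deg_per_pixel)  # integer cycles per image
        plain, _ = simulate_orientation_maps(
            geom96, None, AnnulusSpec(0.0, 100.0, 0.0), CarrierSpec(sf_cpd=sf),
            bank=bank96, orientations_deg=np.array([0.0, 90.0]),
            carrier_phases=phases,
        )
        spread_plain = np.abs(plain[0] - plain[1])[m:-m, m:-m].max() / plain.mean()
        vign, _ = simulate_orientation_maps(
            geom96, None, AnnulusSpec(4.0, 8.0, 1.0), CarrierSpec(sf_cpd=sf),
            bank=bank96, orientations_deg=np.array([0.0, 90.0]),
            carrier_phases=phases,
        )
        spread_vign = np.abs(vign[0] - vign[1])[m:-m, m:-m].max() / vign.mean()
        assert spread_plain < 0.02
        assert spread_vign > 5 * spread_plain
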