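"""Simulator: geometry, dye equilibrium, rendering, time-lapse, presets."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import measure

from mitovolt.constants import nernst_kappa_mv
from mitovolt.labels import Compartment
from mitovolt.simulate import (
    GeometryError,
    SimScenario,
    build_geometry,
    equilibrium_dye_map,
    get_preset,
    preset_scenarios,
    render_frame,
    simulate_timelapse,
)
from mitovolt.simulate.dye import potential_map
from mitovolt.simulate.presets import preset_manifest
from mitovolt.simulate.scenario import Event

from conftest import flicker_scenario, wave_scenario


class TestBuildGeometry:
    def test_no_cristae_no_vesicles_label_set(self):
        scenario = SimScenario(n_cristae=0)
        geo = build_geometry(scenario)
        labels = set(np.unique(geo.labels))
        assert labels == {Compartment.CYTOSOL, Compartment.IBM, Compartment.MATRIX}

    def test_crista_components_and_spacing(self):
        # 10 cristae at 0.3 um spacing on a 40 nm grid: 7-8 px apart
        scenario = SimScenario(n_cristae=10, crista_spacing_um=0.3)
        geo = build_geometry(scenario)
        comp = measure.label(geo.labels == Compartment.CRISTA, connectivity=2)
        assert comp.max() == 10
        centers = sorted(
            measure.regionprops(comp), key=lambda r: r.centroid[1]
        )
        gaps = np.diff([r.centroid[1] for r in centers])
        assert np.all((gaps >= 7) & (gaps <= 8))

    def test_vesicle_not_adjacent_to_ibm(self):
        scenario = SimScenario(
            n_cristae=0, vesicles=[(5.0, 0.1, 20.0)]
        )
        geo = build_geometry(scenario)
        vesicle = geo.labels == Compartment.VESICLE
        comp = measure.label(vesicle, connectivity=2)
        assert comp.max() == 1
        halo = ndimage.binary_dilation(vesicle, structure=np.ones((3, 3)))
        assert not (halo & (geo.labels == Compartment.IBM)).any()

    def test_vesicle_overlapping_ibm_rejected(self):
        # vesicle bigger than the tube radius must clash with the ring
        with pytest.raises(GeometryError):
            build_geometry(SimScenario(n_cristae=0, vesicles=[(5.0, 0.5, 20.0)]))

    def test_cristae_overflowing_caps_rejected(self):
        with pytest.raises(GeometryError):
            build_geometry(SimScenario(length_um=2.0, n_cristae=10))

    def test_registry_matches_labels(self):
        geo = build_geometry(SimScenario(n_cristae=5))
        for entry in geo.crista_registry.values():
            for r, c in entry["pixels"]:
                assert geo.labels[r, c] == Compartment.CRISTA


class TestEquilibriumDyeMap:
    def test_zero_potential_constant_one(self):
        scenario = SimScenario(
            n_cristae=0, psi_matrix_mv=0.0, psi_ibm_offset_mv=0.0,
            independent_fraction=0.0,
        )
        geo = build_geometry(scenario)
        conc = equilibrium_dye_map(geo, scenario)
        np.testing.assert_allclose(conc[1], 1.0)

    def test_nernst_ratio_one_decade(self):
        # 61.54 mV at 310.15 K is one decade of concentration
        scenario = SimScenario(
            n_cristae=0, psi_matrix_mv=61.54, psi_ibm_offset_mv=0.0,
            independent_fraction=0.0,
        )
        geo = build_geometry(scenario)
        conc = equilibrium_dye_map(geo, scenario)
        matrix = conc[1][geo.labels == Compartment.MATRIX]
        cyto = conc[1][geo.labels == Compartment.CYTOSOL]
        assert matrix.mean() / cyto.mean() == pytest.approx(10.0, abs=1e-3)

    def test_crista_ibm_ratio_mic10_offset(self):
        # 25.85 mV crista-vs-IBM offset -> concentration ratio exp(25.85/kappa)
        scenario = SimScenario(
            psi_crista_offset_mv=25.85, independent_fraction=0.0
        )
        geo = build_geometry(scenario)
        conc = equilibrium_dye_map(geo, scenario)
        crista = conc[1][geo.labels == Compartment.CRISTA].mean()
        ibm = conc[1][geo.labels == Compartment.IBM].mean()
        expected = np.exp(25.85 / nernst_kappa_mv(scenario.temperature_K))
        assert crista / ibm == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(2.63, abs=0.01)

    def test_structural_channel_follows_density(self):
        scenario = SimScenario(n_cristae=3)
        geo = build_geometry(scenario)
        conc = equilibrium_dye_map(geo, scenario)
        dens = scenario.membrane_density_struct
        assert conc[0][geo.labels == Compartment.CRISTA].mean() == pytest.approx(
            dens["crista"]
        )
        assert conc[0][geo.labels == Compartment.MATRIX].mean() == pytest.approx(
            dens["matrix"]
        )

    def test_independent_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimScenario(independent_fraction=1.0)
        with pytest.raises(ValueError):
            SimScenario(independent_fraction=-0.1)

    def test_per_crista_offset_length_checked(self):
        with pytest.raises(ValueError):
            SimScenario(n_cristae=3, per_crista_offsets_mv=[1.0, 2.0])


class TestRenderFrame:
    def test_noise_free_is_blur_only(self):
        scenario = SimScenario(n_cristae=0)
        geo = build_geometry(scenario)
        conc = equilibrium_dye_map(geo, scenario)
        rendered = render_frame(conc, scenario, noise_free=True)
        sigma = scenario.psf_sigma_px
        expected = ndimage.gaussian_filter(conc[1], sigma, mode="nearest")
        np.testing.assert_allclose(
            rendered[1], expected * scenario.photons_per_unit, rtol=1e-12
        )

    def test_blur_preserves_constant(self):
        scenario = SimScenario(n_cristae=0)
        const = np.full((2, 40, 40), 3.7)
        out = render_frame(const, scenario, noise_free=True)
        np.testing.assert_allclose(out[1], 3.7 * scenario.photons_per_unit)

    def test_same_seed_bit_identical(self):
        scenario = SimScenario(n_cristae=2, n_frames=2)
        a, _ = simulate_timelapse(scenario)
        b, _ = simulate_timelapse(scenario)
        assert a.pixels.tobytes() == b.pixels.tobytes()

    def test_nonfinite_concentration_rejected(self):
        scenario = SimScenario(n_cristae=0)
        bad = np.full((2, 10, 10), np.nan)
        with pytest.raises(ValueError):
            render_frame(bad, scenario)

    def test_psf_narrower_than_pixel_rejected(self):
        scenario = SimScenario(n_cristae=0, psf_fwhm_nm=140.0, pixel_size_nm=40.0)
        scenario.psf_fwhm_nm = 20.0  # bypass constructor to hit render check
        with pytest.raises(ValueError):
            render_frame(np.ones((2, 10, 10)), scenario)


class TestSimulateTimelapse:
    def test_no_events_noise_free_frames_identical(self):
        scenario = SimScenario(n_cristae=4, n_frames=4)
        stack, _ = simulate_timelapse(scenario, noise_free=True)
        for t in range(1, 4):
            np.testing.assert_array_equal(stack.pixels[t], stack.pixels[0])

    def test_full_flicker_plateau_fraction(self):
        # full-depth flicker with bound fraction 0.15: ~15% of the crista
        # FI remains at the plateau (85% potential-dependent loss)
        scenario = flicker_scenario(depth=1.0, independent_fraction=0.15)
        stack, truth = simulate_timelapse(scenario, noise_free=True)
        crista = truth.label_map[0] == Compartment.CRISTA
        pot = stack.channel("potentiometric")
        baseline = pot[0][crista].mean()
        plateau = pot[12][crista].mean()  # 12 s: inside the 9-16 s event
        assert plateau / baseline == pytest.approx(0.15, abs=0.02)

    def test_wave_has_intermediate_frames(self):
        # 5 um/s front on a 14 um phantom at 0.3 s/frame: several frames
        # with the near half depolarized and the far half still polarized
        scenario = wave_scenario(5.0, frame_interval_s=0.3, n_frames=20)
        stack, truth = simulate_timelapse(scenario, noise_free=True)
        mito = truth.label_map[0] >= 2
        cols = np.nonzero(mito.any(axis=0))[0]
        mid = (cols.min() + cols.max()) // 2
        near = mito.copy(); near[:, mid:] = False
        far = mito.copy(); far[:, :mid] = False
        pot = stack.channel("potentiometric")
        base_near = pot[0][near].mean()
        base_far = pot[0][far].mean()
        n_intermediate = sum(
            pot[t][near].mean() < 0.5 * base_near
            and pot[t][far].mean() > 0.9 * base_far
            for t in range(stack.n_frames)
        )
        assert n_intermediate >= 2

    def test_partial_event_targets_only_some_cristae(self):
        scenario = get_preset("control", seed=0)
        scenario.n_frames = 4
        scenario.events = [
            Event(
                kind="partial_depolarization", t_start_s=1.0, t_end_s=2.0,
                depth=1.0, target_crista_ids=[0, 3],
            )
        ]
        _, truth = simulate_timelapse(scenario, noise_free=True)
        psi_event = truth.true_psi_map[2]  # frame at t=1.0 s
        reg = truth.crista_registry
        for cid, entry in reg.items():
            r, c = entry["pixels"][len(entry["pixels"]) // 2]
            if cid in (0, 3):
                assert psi_event[r, c] == 0.0
            else:
                assert psi_event[r, c] > 100.0

    def test_unknown_target_crista_rejected(self):
        scenario = get_preset("control", seed=0)
        scenario.n_frames = 4
        scenario.events = [
            Event(kind="partial_depolarization", t_start_s=0.0, t_end_s=1.0,
                  depth=1.0, target_crista_ids=[99])
        ]
        with pytest.raises(ValueError):
            simulate_timelapse(scenario)

    def test_event_validation(self):
        with pytest.raises(ValueError):
            Event(kind="flicker", t_start_s=5.0, t_end_s=3.0).validate(10.0, 10.0)
        with pytest.raises(ValueError):
            Event(kind="wave", t_start_s=0.0, t_end_s=1.0, site_um=50.0,
                  speed_um_per_s=5.0).validate(10.0, 10.0)

    def test_ground_truth_shapes_match(self):
        scenario = SimScenario(n_cristae=3, n_frames=3)
        stack, truth = simulate_timelapse(scenario)
        assert truth.label_map.shape == stack.pixels[:, 0].shape
        assert truth.true_psi_map.shape == stack.pixels[:, 0].shape


class TestInvariants:
    def test_monotone_crista_intensity_with_offset(self):
        ratios = []
        for offset in (2.0, 8.0, 16.0):
            scenario = SimScenario(
                psi_crista_offset_mv=offset, independent_fraction=0.0, n_frames=1
            )
            stack, truth = simulate_timelapse(scenario, noise_free=True)
            pot = stack.channel("potentiometric")[0]
            crista = pot[truth.label_map[0] == Compartment.CRISTA].mean()
            ibm = pot[truth.label_map[0] == Compartment.IBM].mean()
            ratios.append(crista / ibm)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_conservation_flat_density_no_events(self):
        scenario = SimScenario(
            n_cristae=5, n_frames=4,
            membrane_density_struct={k: 0.5 for k in
                                     ("background", "cytosol", "matrix",
                                      "ibm", "crista", "vesicle")},
        )
        stack, _ = simulate_timelapse(scenario, noise_free=True)
        totals = stack.pixels.sum(axis=(1, 2, 3))
        np.testing.assert_allclose(totals, totals[0], rtol=1e-12)


class TestPresets:
    def test_control_ground_truth_offset(self):
        scenario = get_preset("control")
        assert scenario.psi_crista_offset_mv == pytest.approx(10.11)
        assert not scenario.vesicles

    def test_dko_vesicle_offset(self):
        scenario = get_preset("opa1_drp1_dko")
        assert scenario.vesicles[0][2] == pytest.approx(39.55)

    def test_mic10_vesicle_offset(self):
        scenario = get_preset("mic10_ko")
        assert scenario.vesicles[0][2] == pytest.approx(25.85)

    def test_fccp_below_control(self):
        presets = preset_scenarios()
        assert (
            presets["fccp"].psi_crista_offset_mv
            < presets["control"].psi_crista_offset_mv
        )

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            get_preset("nocodazole")

    def test_manifest_is_serializable(self):
        import json

        manifest = preset_manifest()
        text = json.dumps(manifest)
        assert "control" in manifest and "10.11" in text

    def test_ko_presets_have_fewer_cristae(self):
        presets = preset_scenarios()
        for name in ("mic13_ko", "mic60_ko", "opa1_ko", "mic10_ko"):
            assert presets[name].n_cristae < presets["control"].n_cristae


class TestScenarioSerialization:
    def test_json_round_trip(self, tmp_path):
        scenario = get_preset("mic10_ko", seed=7)
        scenario.events = [Event(kind="flicker", t_start_s=0.5, t_end_s=1.5)]
        path = tmp_path / "scenario.json"
        scenario.to_json(path)
        loaded = SimScenario.from_json(path)
        assert loaded.to_dict() == scenario.to_dict()
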