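"""Tracking, flicker detection/decomposition, variability, waves."""

import numpy as np
import pytest

from mitovolt import dynamics
from mitovolt.config import RunConfig
from mitovolt.dynamics import (
    FlickerEvent,
    analyze_wave,
    crista_variability,
    decompose_flicker,
    detect_flicker,
    detect_partial_depolarization,
    track_cristae,
)
from mitovolt.labels import Compartment
from mitovolt.pipeline import analyze_stack
from mitovolt.simulate import get_preset, simulate_timelapse
from mitovolt.simulate.scenario import Event

from conftest import flicker_scenario, run_preset, wave_scenario

FAST_CFG = RunConfig(subtract_background=False)  # phantoms have flat background


class TestTrackCristae:
    def test_static_detections_single_tracks(self):
        positions = [np.array([1.0, 2.0, 3.0])] * 5
        tracks = track_cristae(positions)
        assert len(tracks) == 3
        for tr in tracks:
            assert tr.frames == list(range(5))
            assert len(set(tr.positions_um)) == 1

    def test_slow_drift_single_monotone_track(self):
        positions = [np.array([1.0 + 0.04 * t]) for t in range(8)]
        tracks = track_cristae(positions, max_jump_um=0.15)
        assert len(tracks) == 1
        assert np.all(np.diff(tracks[0].positions_um) > 0)

    def test_jump_beyond_limit_starts_new_track(self):
        positions = [np.array([1.0]), np.array([1.5])]
        tracks = track_cristae(positions, max_jump_um=0.15)
        assert len(tracks) == 2

    def test_gap_tolerance(self):
        positions = [np.array([1.0]), np.array([]), np.array([1.02])]
        tracks = track_cristae(positions, max_gap=2)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 2]

    def test_crossing_resolved_by_total_displacement(self):
        # two detections approach within max_jump; assignment minimizes
        # total displacement, keeping the track order stable
        positions = [np.array([1.00, 1.10]), np.array([1.02, 1.08])]
        tracks = track_cristae(positions, max_jump_um=0.15)
        assert len(tracks) == 2
        assert tracks[0].positions_um == [1.00, 1.02]
        assert tracks[1].positions_um == [1.10, 1.08]

    def test_values_carried(self):
        positions = [np.array([1.0]), np.array([1.0])]
        values = [np.array([5.0]), np.array([6.0])]
        tracks = track_cristae(positions, values_per_frame=values)
        assert tracks[0].values == [5.0, 6.0]
        assert tracks[0].mean_value == pytest.approx(5.5)


class TestDetectFlicker:
    def test_constant_trace_no_events(self):
        assert detect_flicker(np.full(20, 100.0)) == []

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_flicker(np.ones(5))

    def test_simulated_flicker_depth(self):
        scenario = flicker_scenario(seed=2, depth=1.0, independent_fraction=0.15)
        stack, truth = simulate_timelapse(scenario)
        trace = dynamics.mito_trace(stack, truth.label_map[0] >= 2)
        events = detect_flicker(trace, frame_interval_s=1.0)
        assert len(events) == 1
        assert events[0].depth_fraction == pytest.approx(0.85, abs=0.03)
        assert events[0].t_depol_s == pytest.approx(9.0, abs=1.0)
        assert events[0].t_repol_s == pytest.approx(16.0, abs=1.0)

    def test_two_sequential_flickers_ordered(self):
        scenario = flicker_scenario(seed=3, n_frames=40)
        scenario.events = [
            Event(kind="flicker", t_start_s=8.0, t_end_s=13.0, depth=1.0),
            Event(kind="flicker", t_start_s=25.0, t_end_s=30.0, depth=1.0),
        ]
        stack, truth = simulate_timelapse(scenario)
        trace = dynamics.mito_trace(stack, truth.label_map[0] >= 2)
        events = detect_flicker(trace, frame_interval_s=1.0)
        assert len(events) == 2
        assert events[0].t_depol_s < events[1].t_depol_s


class TestDecomposeFlicker:
    def test_arithmetic(self):
        event = FlickerEvent(
            mito_id=0, t_depol_s=3, t_repol_s=6, depth_fraction=0.85,
            independent_fraction_est=0.15, plateau_frames=[3, 4, 5],
        )
        crista = np.array([100.0, 100, 100, 15, 15, 15, 100])
        matrix = np.array([60.0, 60, 60, 15, 15, 15, 60])
        out = decompose_flicker(crista, matrix, event)
        assert out["crista_independent"] == pytest.approx(15.0)
        assert out["crista_dependent"] == pytest.approx(85.0)
        assert out["plateau_mismatch_frac"] == pytest.approx(0.0)

    def test_simulated_plateaus_agree(self):
        scenario = flicker_scenario(seed=4, depth=1.0, independent_fraction=0.15)
        stack, truth = simulate_timelapse(scenario)
        crista = dynamics.mito_trace(
            stack, truth.label_map[0] == Compartment.CRISTA
        )
        matrix = dynamics.mito_trace(
            stack, truth.label_map[0] == Compartment.MATRIX
        )
        trace = dynamics.mito_trace(stack, truth.label_map[0] >= 2)
        event = detect_flicker(trace, frame_interval_s=1.0)[0]
        out = decompose_flicker(crista, matrix, event)
        assert out["plateau_mismatch_frac"] < 0.05

    def test_short_event_flagged(self):
        event = FlickerEvent(0, 1, 2, 0.9, 0.1, plateau_frames=[1])
        with pytest.raises(ValueError):
            decompose_flicker(np.ones(5), np.ones(5), event)


class TestCristaVariability:
    def test_closed_form_offsets(self):
        # offsets {5,5,12,12} have SD 3.5; 1 mV jitter inflates slightly
        rng = np.random.default_rng(0)
        base = np.array([5.0, 5.0, 12.0, 12.0])
        values = base[:, None] + rng.normal(0, 1.0, size=(4, 50))
        sd_within, sd_between = crista_variability(values)
        assert sd_within.mean() == pytest.approx(1.0, abs=0.2)
        assert 3.3 <= sd_between <= 4.2
        assert sd_between > sd_within.mean()

    def test_identical_constant_tracks(self):
        values = np.full((3, 6), 7.0)
        sd_within, sd_between = crista_variability(values)
        assert np.all(sd_within == 0) and sd_between == 0

    def test_single_track_rejected(self):
        with pytest.raises(ValueError):
            crista_variability(np.ones((1, 10)))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            crista_variability(np.ones((3, 3)))


@pytest.fixture(scope="module")
def partial_run():
    scenario = get_preset("control", seed=3)
    scenario.n_frames = 12
    scenario.frame_interval_s = 1.0
    scenario.events = [
        Event(kind="partial_depolarization", t_start_s=5.0, t_end_s=9.0,
              depth=1.0, target_crista_ids=[2, 4])
    ]
    stack, truth = simulate_timelapse(scenario)
    results = analyze_stack(stack, FAST_CFG)
    return (
        results["crista_tracks"]
        .pivot(index="track_id", columns="frame", values="delta_psi_cr_ibm_mv")
        .to_numpy()
    )


@pytest.fixture(scope="module")
def fast_wave():
    scenario = wave_scenario(5.0, frame_interval_s=0.3, n_frames=40, seed=1)
    stack, _ = simulate_timelapse(scenario)
    results = analyze_stack(stack, FAST_CFG, stop_after="preprocess")
    return stack, results["objects"][0]


class TestPartialDepolarization:
    def test_exact_target_set_recovered(self, partial_run):
        out = detect_partial_depolarization(partial_run, event_frames=[5, 6, 7, 8])
        assert out["depolarized_ids"] == [2, 4]
        assert out["contrast_mv"] > 20.0

    def test_no_event_all_polarized(self, partial_run):
        out = detect_partial_depolarization(
            partial_run, event_frames=[2, 3], baseline_frames=[0, 1]
        )
        assert out["depolarized_ids"] == []

    def test_full_depth_flicker_all_depolarized(self):
        scenario = flicker_scenario(seed=5, depth=1.0, n_frames=20)
        stack, truth = simulate_timelapse(scenario)
        results = analyze_stack(stack, FAST_CFG)
        values = (
            results["crista_tracks"]
            .pivot(index="track_id", columns="frame", values="delta_psi_cr_ibm_mv")
            .to_numpy()
        )
        out = detect_partial_depolarization(values, event_frames=list(range(10, 15)))
        assert out["polarized_ids"] == []


class TestAnalyzeWave:
    def test_speed_recovered(self, fast_wave):
        stack, obj = fast_wave
        event = analyze_wave(stack, obj, site_um=0.5, t0_frame=5)
        assert event.speed_um_per_s == pytest.approx(5.0, abs=1.0)
        assert event.wave_class == "wavelike"

    def test_front_monotone(self, fast_wave):
        stack, obj = fast_wave
        event = analyze_wave(stack, obj, site_um=0.5, t0_frame=5)
        assert np.all(np.diff(event.front_position_um) >= -1e-9)

    def test_first_frame_asymmetry(self, fast_wave):
        # just after onset: distal still polarized, proximal depolarized
        stack, obj = fast_wave
        event = analyze_wave(stack, obj, site_um=0.5, t0_frame=5)
        assert event.distal_fi[7] >= 0.9
        assert event.proximal_fi[7] <= 0.5

    def test_slow_frames_classified_instantaneous(self):
        scenario = wave_scenario(5.0, frame_interval_s=5.0, n_frames=12, seed=1)
        stack, _ = simulate_timelapse(scenario)
        results = analyze_stack(stack, FAST_CFG, stop_after="preprocess")
        event = analyze_wave(stack, results["objects"][0], site_um=0.5, t0_frame=5)
        assert event.wave_class == "instantaneous"

    def test_global_drop_instantaneous(self):
        scenario = get_preset("control", seed=2, length_um=12.0)
        scenario.n_frames = 15
        scenario.frame_interval_s = 0.3
        scenario.events = [
            Event(kind="flicker", t_start_s=1.5, t_end_s=4.5, depth=1.0)
        ]
        stack, _ = simulate_timelapse(scenario)
        results = analyze_stack(stack, FAST_CFG, stop_after="preprocess")
        event = analyze_wave(stack, results["objects"][0], site_um=0.5, t0_frame=5)
        assert event.wave_class == "instantaneous"
        # proximal and distal collapse together on the first post-event frame
        assert abs(event.proximal_fi[6] - event.distal_fi[6]) < 0.2

    def test_onset_outside_series_rejected(self, fast_wave):
        stack, obj = fast_wave
        with pytest.raises(ValueError):
            analyze_wave(stack, obj, site_um=0.5, t0_frame=100)
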