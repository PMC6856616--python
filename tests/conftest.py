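"""Shared fixtures: simulated phantoms and full pipeline runs."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from mitovolt.config import RunConfig
from mitovolt.pipeline import analyze_stack
from mitovolt.simulate import get_preset, simulate_timelapse
from mitovolt.simulate.scenario import Event, SimScenario

logging.getLogger("mitovolt").setLevel(logging.ERROR)


def run_preset(name: str, seed: int, config: RunConfig | None = None, **overrides):
    """Simulate one preset and run the full pipeline on it."""
    scenario = get_preset(name, seed=seed, **overrides)
    stack, truth = simulate_timelapse(scenario)
    results = analyze_stack(stack, config or RunConfig())
    return scenario, stack, truth, results


def per_crista_estimates(results) -> np.ndarray:
    """Time-averaged per-crista potential-vs-IBM estimates (mV), by track."""
    tracks = results["crista_tracks"]
    return (
        tracks.groupby("track_id")["delta_psi_cr_ibm_mv"].mean().to_numpy()
    )


def wave_scenario(
    speed_um_per_s: float,
    frame_interval_s: float = 0.3,
    n_frames: int = 40,
    seed: int = 0,
    depth: float = 1.0,
    site_um: float = 0.5,
) -> SimScenario:
    onset = 5 * frame_interval_s
    return SimScenario(
        name="wave",
        length_um=14.0,
        n_cristae=20,
        crista_spacing_um=0.4,
        n_frames=n_frames,
        frame_interval_s=frame_interval_s,
        rng_seed=seed,
        events=[
            Event(
                kind="wave",
                t_start_s=onset,
                t_end_s=n_frames * frame_interval_s,
                depth=depth,
                site_um=site_um,
                speed_um_per_s=speed_um_per_s,
            )
        ],
    )


def flicker_scenario(
    seed: int = 0,
    depth: float = 1.0,
    independent_fraction: float = 0.15,
    n_frames: int = 30,
) -> SimScenario:
    scenario = get_preset("control", seed=seed)
    scenario.independent_fraction = independent_fraction
    scenario.n_frames = n_frames
    scenario.frame_interval_s = 1.0
    scenario.events = [
        Event(kind="flicker", t_start_s=9.0, t_end_s=16.0, depth=depth)
    ]
    return scenario


def position_errors(detected: np.ndarray, truth: np.ndarray, axis_length: float) -> np.ndarray:
    """Per-crista |detected - true| position errors (um), sorted matching.

    The analysis axis may be oriented either way along the mitochondrion,
    so the orientation with the smaller total error is used.
    """
    if len(detected) != len(truth):
        raise AssertionError(f"count mismatch: {len(detected)} vs {len(truth)}")
    d = np.sort(np.asarray(detected, dtype=float))
    t = np.sort(np.asarray(truth, dtype=float))
    fwd = np.abs(d - t)
    rev = np.abs(np.sort(axis_length - d) - t)
    return fwd if fwd.sum() <= rev.sum() else rev


@pytest.fixture(scope="session")
def control_run():
    """Control phantom (seed 1) + full pipeline results."""
    return run_preset("control", seed=1)


@pytest.fixture(scope="session")
def control_run_noise_free():
    scenario = get_preset("control", seed=1)
    stack, truth = simulate_timelapse(scenario, noise_free=True)
    results = analyze_stack(stack, RunConfig())
    return scenario, stack, truth, results


@pytest.fixture(scope="session")
def mic10_run():
    return run_preset("mic10_ko", seed=1)


@pytest.fixture(scope="session")
def fccp_run():
    return run_preset("fccp", seed=1)


@pytest.fixture(scope="session")
def control_batch():
    """Per-crista estimates and detection metrics over many control seeds.

    Shared by the parameter-recovery and detection acceptance tests to
    avoid re-simulating.  Returns a list of dicts, one per seed.
    """
    out = []
    for seed in range(1, 21):
        scenario, stack, truth, results = run_preset("control", seed=seed)
        sites = results["per_object"][0]["cristae"]
        out.append(
            dict(
                seed=seed,
                estimates=per_crista_estimates(results),
                detected_positions=np.array(
                    [s.axial_position_um for s in sites]
                ),
                true_positions=truth.crista_positions_um(),
                label_map=results["per_object"][0]["label_map"],
                truth_labels=truth.label_map[0],
                true_offset=scenario.psi_crista_offset_mv,
            )
        )
    return out
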