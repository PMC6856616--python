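"""Time-resolved analysis: tracking, flicker, variability, waves."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .compartments import axial_profile
from .preprocess import MitoObject

logger = logging.getLogger("mitovolt")

_BIG = 1e9  # forbidden-assignment cost


# -- crista tracking ------------------------------------------------------

@dataclass
class CristaTrack:
    """One crista followed across frames."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    detection_indices: list[int] = field(default_factory=list)
    positions_um: list[float] = field(default_factory=list)
    values: list[float] = field(default_factory=list)  # e.g. dpsi_cr_ibm per frame

    @property
    def mean_value(self) -> float:
        return float(np.nanmean(self.values)) if self.values else float("nan")

    @property
    def sd_over_time(self) -> float:
        v = np.asarray(self.values, dtype=float)
        v = v[np.isfinite(v)]
        return float(v.std(ddof=1)) if len(v) > 1 else float("nan")


def track_cristae(
    positions_per_frame: list[np.ndarray],
    max_jump_um: float = 0.15,
    max_gap: int = 2,
    values_per_frame: list[np.ndarray] | None = None,
) -> list[CristaTrack]:
    """Link per-frame axial detections into tracks.

    Frame-to-frame matching minimizes total axial displacement (optimal
    assignment), with links beyond ``max_jump_um`` forbidden.  Tracks
    missing for more than ``max_gap`` frames are closed; unmatched
    detections start new tracks.  Output is ordered by first position.
    """
    tracks: list[CristaTrack] = []
    active: list[CristaTrack] = []
    for t, positions in enumerate(positions_per_frame):
        positions = np.asarray(positions, dtype=float)
        order = np.argsort(positions)
        positions = positions[order]
        vals = None
        if values_per_frame is not None:
            vals = np.asarray(values_per_frame[t], dtype=float)[order]
        active = [tr for tr in active if t - tr.frames[-1] <= max_gap]
        assigned = np.full(len(positions), -1, dtype=int)
        if active and len(positions):
            cost = np.abs(
                np.array([tr.positions_um[-1] for tr in active])[:, None]
                - positions[None, :]
            )
            cost = np.where(cost <= max_jump_um, cost, _BIG)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < _BIG:
                    assigned[c] = r
        for j, pos in enumerate(positions):
            if assigned[j] >= 0:
                tr = active[assigned[j]]
            else:
                tr = CristaTrack(track_id=len(tracks))
                tracks.append(tr)
                active.append(tr)
            tr.frames.append(t)
            tr.detection_indices.append(int(order[j]))
            tr.positions_um.append(float(pos))
            if vals is not None:
                tr.values.append(float(vals[j]))
    tracks.sort(key=lambda tr: (tr.positions_um[0], tr.frames[0]))
    for i, tr in enumerate(tracks):
        tr.track_id = i
    return tracks


# -- flicker --------------------------------------------------------------

@dataclass
class FlickerEvent:
    """A transient whole-organelle depolarization/repolarization."""

    mito_id: int
    t_depol_s: float
    t_repol_s: float
    depth_fraction: float            # potential-dependent FI loss
    independent_fraction_est: float  # plateau / baseline
    plateau_frames: list[int]
    affected_crista_ids: list[int] = field(default_factory=list)


def detect_flicker(
    trace: np.ndarray,
    frame_interval_s: float = 1.0,
    drop_threshold: float = 0.5,
    recovery_threshold: float = 0.8,
    mito_id: int = 0,
) -> list[FlickerEvent]:
    """Detect flicker events on a whole-mitochondrion intensity trace.

    An event starts when the trace falls below ``drop_threshold`` x
    baseline and counts only if the trace later recovers above
    ``recovery_threshold`` x baseline.  Depth is the fractional FI loss at
    the event plateau; what remains is the potential-independent signal
    estimate.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < 10:
        raise ValueError("flicker detection needs >= 10 frames")
    # baseline from frames near the trace top (robust to long events)
    top = trace >= recovery_threshold * trace.max()
    baseline = float(np.median(trace[top]))
    below = trace < drop_threshold * baseline
    events: list[FlickerEvent] = []
    i = 0
    while i < len(trace):
        if not below[i]:
            i += 1
            continue
        j = i
        while j < len(trace) and below[j]:
            j += 1
        recovered = np.nonzero(trace[j:] >= recovery_threshold * baseline)[0]
        if len(recovered):
            plateau = float(trace[i:j].mean())
            events.append(
                FlickerEvent(
                    mito_id=mito_id,
                    t_depol_s=i * frame_interval_s,
                    t_repol_s=(j + recovered[0]) * frame_interval_s,
                    depth_fraction=1.0 - plateau / baseline,
                    independent_fraction_est=plateau / baseline,
                    plateau_frames=list(range(i, j)),
                )
            )
        i = j
    return events


def decompose_flicker(
    crista_trace: np.ndarray,
    matrix_trace: np.ndarray,
    event: FlickerEvent,
) -> dict[str, float]:
    """Split compartment traces into potential-dependent and -independent
    components using the depolarized plateau.

    The independent component is the mean plateau FI; the dependent
    component is baseline minus plateau.  Also reports the crista/matrix
    plateau mismatch relative to the crista baseline (should be small when
    the bound-dye pool is shared).
    """
    if len(event.plateau_frames) < 2:
        raise ValueError("event too short to decompose (< 2 plateau frames)")
    crista_trace = np.asarray(crista_trace, dtype=float)
    matrix_trace = np.asarray(matrix_trace, dtype=float)
    pre = [f for f in range(len(crista_trace)) if f < event.plateau_frames[0]]
    if not pre:
        raise ValueError("no pre-event frames to estimate baselines")
    out = {}
    for name, trace in (("crista", crista_trace), ("matrix", matrix_trace)):
        baseline = float(trace[np.array(pre)].mean())
        plateau = float(trace[np.array(event.plateau_frames)].mean())
        out[f"{name}_baseline"] = baseline
        out[f"{name}_independent"] = plateau
        out[f"{name}_dependent"] = baseline - plateau
    out["plateau_mismatch_frac"] = abs(
        out["crista_independent"] - out["matrix_independent"]
    ) / out["crista_baseline"]
    return out


# -- within- vs between-crista variability --------------------------------

def crista_variability(
    values: np.ndarray,
) -> tuple[np.ndarray, float]:
    """(sd over time per crista, mean per-frame sd across cristae).

    ``values`` is (n_tracks, n_frames) of per-crista potential estimates.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need >= 2 tracks")
    if values.shape[1] < 5:
        raise ValueError("need >= 5 frames per track")
    sd_within = values.std(axis=1, ddof=1)
    sd_between = float(values.std(axis=0, ddof=1).mean())
    return sd_within, sd_between


def detect_partial_depolarization(
    values: np.ndarray,
    event_frames: list[int],
    baseline_frames: list[int] | None = None,
    fraction: float = 0.3,
) -> dict[str, object]:
    """Split cristae into depolarized vs polarized sets during an event.

    A crista counts as depolarized when its potential during the event
    falls below ``fraction`` of its own pre-event baseline.  Reports the
    mean potential contrast between the two sets during the event.
    """
    values = np.asarray(values, dtype=float)
    event_frames = list(event_frames)
    if baseline_frames is None:
        baseline_frames = [f for f in range(values.shape[1]) if f < min(event_frames)]
    if not baseline_frames:
        raise ValueError("no baseline frames before the event")
    baseline = np.nanmean(values[:, baseline_frames], axis=1)
    during = np.nanmean(values[:, event_frames], axis=1)
    # a during-event value below the bound-dye floor comes out missing;
    # that is itself evidence of depolarization
    depolarized = np.isnan(during) | (during < fraction * baseline)
    contrast = float(
        during[~depolarized].mean() - during[depolarized].mean()
    ) if depolarized.any() and (~depolarized).any() else float("nan")
    return {
        "depolarized_ids": sorted(np.nonzero(depolarized)[0].tolist()),
        "polarized_ids": sorted(np.nonzero(~depolarized)[0].tolist()),
        "contrast_mv": contrast,
    }


# -- laser-induced depolarization waves -----------------------------------

@dataclass
class WaveEvent:
    """Quantified depolarization front after a localized perturbation."""

    mito_id: int
    site_um: float
    t0_s: float
    times_s: np.ndarray
    front_position_um: np.ndarray  # per post-onset frame
    speed_um_per_s: float
    wave_class: str  # wavelike | instantaneous | none
    proximal_fi: np.ndarray  # normalized to pre-event baseline
    distal_fi: np.ndarray


def analyze_wave(
    stack,
    mito: MitoObject,
    site_um: float,
    t0_frame: int,
    front_fraction: float = 0.5,
    proximal_um: float = 1.0,
    distal_um: float = 10.0,
    baseline_frames: int = 5,
    potentiometric_channel: str = "potentiometric",
    resolve_orientation: bool = True,
) -> WaveEvent:
    """Quantify a depolarization wave from a perturbation at ``site_um``.

    Front position per frame is the farthest arclength distance from the
    site over which the profile has contiguously fallen below
    ``front_fraction`` of its pre-event baseline; speed is a least-squares
    fit of front position vs time over frames with a partial front.
    Class: instantaneous if >= 90% of the axis is depolarized within one
    frame of onset; wavelike if the advancing front spans >= 2 frames;
    none otherwise.  For objects shorter than ``distal_um`` the distal
    band falls back to >= 0.6 x axis length from the site.
    """
    frames = stack.channel(potentiometric_channel)
    if not 0 <= t0_frame < len(frames):
        raise ValueError("onset frame outside the series")
    if t0_frame < 1:
        raise ValueError("need at least one pre-onset frame for baselines")
    profiles = []
    arclength = None
    for frame in frames:
        arclength, prof = axial_profile(frame, mito, band_halfwidth_px=2)
        profiles.append(prof)
    profiles = np.array(profiles)
    pre = profiles[max(0, t0_frame - baseline_frames) : t0_frame]
    baseline = pre.mean(axis=0)
    baseline = np.maximum(baseline, 1e-12)
    norm = profiles / baseline

    length = float(arclength[-1])
    if resolve_orientation and t0_frame + 1 < len(frames):
        # the analysis axis may be oriented either way; pick the site
        # coordinate whose neighborhood depolarizes first
        probe = norm[min(t0_frame + 1, len(frames) - 1)]
        cands = [site_um, length - site_um]
        scores = []
        for cand in cands:
            near = np.abs(arclength - cand) <= max(proximal_um, 0.5)
            scores.append(probe[near].mean() if near.any() else np.inf)
        site_um = cands[int(np.argmin(scores))]

    d = np.abs(arclength - site_um)
    order = np.argsort(d)
    d_sorted = d[order]
    d_max = float(d_sorted[-1])

    post = range(t0_frame, len(frames))
    fronts = []
    for t in post:
        below = norm[t][order] < front_fraction
        front = 0.0
        for dist, b in zip(d_sorted, below):
            if not b:
                break
            front = float(dist)
        fronts.append(front)
    fronts = np.asarray(fronts)
    times = (np.arange(t0_frame, len(frames)) - t0_frame) * stack.frame_interval_s

    partial = (fronts > 0.05 * d_max) & (fronts < 0.9 * d_max)
    if partial.sum() >= 2:
        t_fit, f_fit = times[partial], fronts[partial]
        speed = float(np.polyfit(t_fit, f_fit, 1)[0])
    else:
        speed = float("nan")

    # classification
    frac_depol_first = float((norm[min(t0_frame + 1, len(frames) - 1)] < front_fraction).mean())
    if frac_depol_first >= 0.9:
        wave_class = "instantaneous"
    elif partial.sum() >= 2:
        wave_class = "wavelike"
    else:
        wave_class = "none"

    proximal = d <= proximal_um
    distal_cut = distal_um if d_max >= distal_um else 0.6 * length
    distal = d >= distal_cut
    if not distal.any():
        logger.warning("distal band empty (object too short); using farthest 10%%")
        distal = d >= 0.9 * d_max
    proximal_fi = norm[:, proximal].mean(axis=1)
    distal_fi = norm[:, distal].mean(axis=1)

    return WaveEvent(
        mito_id=mito.id,
        site_um=float(site_um),
        t0_s=t0_frame * stack.frame_interval_s,
        times_s=times,
        front_position_um=fronts,
        speed_um_per_s=speed,
        wave_class=wave_class,
        proximal_fi=proximal_fi,
        distal_fi=distal_fi,
    )


def mito_trace(stack, mask: np.ndarray, channel: str = "potentiometric") -> np.ndarray:
    """Per-frame mean intensity over a fixed pixel mask."""
    frames = stack.channel(channel)
    return np.array([float(f[mask].mean()) for f in frames])
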