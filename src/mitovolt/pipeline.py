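"""End-to-end analysis orchestration used by the CLI and tests."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import compartments, dynamics, potentials, preprocess
from .config import RunConfig
from .io import FrameStack
from .labels import Compartment

logger = logging.getLogger("mitovolt")

STRUCTURAL = "structural"
POTENTIOMETRIC = "potentiometric"


def analyze_stack(
    stack: FrameStack,
    config: RunConfig | None = None,
    stop_after: str | None = None,
) -> dict[str, object]:
    """Run preprocess -> compartments -> potentials -> dynamics.

    Returns a dict with the four standard tables (morphometrics,
    potentials, crista_tracks, events) plus per-object intermediates under
    ``objects``.  ``stop_after`` in {"preprocess", "compartments"} truncates
    the pipeline.
    """
    cfg = config or RunConfig()
    struct = stack.channel(STRUCTURAL if STRUCTURAL in stack.channel_names else stack.channel_names[0])
    pot = stack.channel(
        POTENTIOMETRIC if POTENTIOMETRIC in stack.channel_names else stack.channel_names[-1]
    )

    if cfg.subtract_background:
        if cfg.background_radius_px < min(struct.shape[1:]):
            struct = np.stack(
                [preprocess.subtract_background(f, cfg.background_radius_px) for f in struct]
            )
            pot = np.stack(
                [preprocess.subtract_background(f, cfg.background_radius_px) for f in pot]
            )
        else:
            logger.warning("image smaller than rolling-ball radius; skipping background subtraction")

    struct_mean = struct.mean(axis=0)
    pot_mean = pot.mean(axis=0)

    objects = preprocess.segment_mitochondria(
        struct_mean,
        stack.pixel_size_nm,
        min_area_um2=cfg.min_area_um2,
        discard_edge=cfg.discard_edge_objects,
    )
    morph_rows = []
    for obj in objects:
        preprocess.refine_boundary(obj, struct_mean)
        try:
            obj.axis = preprocess.extract_axis(obj, stack.pixel_size_nm)
        except ValueError:
            logger.warning("object %d skipped (too small to skeletonize)", obj.id)
            obj.axis = None
        morph_rows.append(
            dict(
                frame=-1,
                mito_id=obj.id,
                area_um2=obj.area_um2,
                perimeter_um=obj.perimeter_um,
                circularity=obj.circularity,
                aspect_ratio=obj.aspect_ratio,
                axis_length_um=obj.axis.length_um if obj.axis else float("nan"),
            )
        )
    results: dict[str, object] = {
        "morphometrics": pd.DataFrame(morph_rows),
        "objects": objects,
    }
    if stop_after == "preprocess":
        return results

    # rebuild a background-subtracted stack for downstream measurement
    sub_stack = FrameStack(
        pixels=np.stack([struct, pot], axis=1),
        pixel_size_nm=stack.pixel_size_nm,
        frame_interval_s=stack.frame_interval_s,
        channel_names=[STRUCTURAL, POTENTIOMETRIC],
    )

    potential_rows, track_rows, event_rows = [], [], []
    per_object = {}
    for obj in objects:
        if obj.axis is None or len(obj.axis.points) < 3:
            continue
        assignment = compartments.axis_assignment(obj)
        arclength, profile = compartments.axial_profile(
            struct_mean, obj, band_halfwidth_px=cfg.band_halfwidth_px,
            assignment=assignment,
        )
        # end caps are all membrane: exclude roughly half the tube width
        width_um = obj.area_um2 / max(obj.axis.length_um, 1e-6)
        cristae = compartments.detect_cristae(
            arclength, profile,
            min_prominence_frac=cfg.min_prominence_frac,
            min_spacing_nm=cfg.min_spacing_nm,
            mito_id=obj.id,
            end_margin_um=max(cfg.end_margin_um, 0.55 * width_um),
        )
        # vesicles first, on a crista-free map (vesicles are bright in both
        # channels and would otherwise be claimed by crista bands)
        base_map = compartments.classify_pixels(
            obj, [], assignment=assignment, ibm_shell_px=cfg.ibm_shell_px,
        )
        base_map = compartments.detect_vesicles(
            pot_mean, base_map, stack.pixel_size_nm,
            intensity_factor=cfg.vesicle_intensity_factor,
            min_area_um2=cfg.vesicle_min_area_um2,
        )
        vesicle_mask = base_map == Compartment.VESICLE
        cristae = compartments.filter_cristae_near_vesicles(
            cristae, vesicle_mask, obj, assignment
        )
        label_map = compartments.classify_pixels(
            obj, cristae, assignment=assignment,
            ibm_shell_px=cfg.ibm_shell_px,
            band_halfwidth_px=cfg.band_halfwidth_px,
        )
        label_map[vesicle_mask] = Compartment.VESICLE
        per_object[obj.id] = dict(
            cristae=cristae, label_map=label_map, arclength=arclength,
            profile=profile,
        )
        if stop_after == "compartments":
            continue

        table = potentials.compartment_potentials(
            sub_stack, obj, cristae, label_map,
            reference_mode=cfg.reference_mode,
            temperature_K=cfg.temperature_K,
            independent_fraction=cfg.independent_fraction,
            psf_fwhm_nm=cfg.psf_fwhm_nm,
            restore_contrast=cfg.restore_contrast,
        )
        potential_rows.append(table)

        cr_ibm = potentials.delta_psi_cr_ibm(
            sub_stack, obj, cristae, label_map,
            temperature_K=cfg.temperature_K,
            independent_fraction=cfg.independent_fraction,
            psf_fwhm_nm=cfg.psf_fwhm_nm,
            restore_contrast=cfg.restore_contrast,
            adjacent_window_um=cfg.adjacent_window_um,
        )
        for _, row in cr_ibm.iterrows():
            track_rows.append(
                dict(
                    mito_id=obj.id,
                    track_id=int(row["crista_id"]),
                    frame=int(row["frame"]),
                    axial_position_um=row["axial_position_um"],
                    delta_psi_cr_ibm_mv=row["delta_psi_cr_ibm_mv"],
                )
            )

        if stack.n_frames >= 10:
            trace = dynamics.mito_trace(sub_stack, obj.mask)
            for k, ev in enumerate(
                dynamics.detect_flicker(
                    trace,
                    frame_interval_s=stack.frame_interval_s,
                    drop_threshold=cfg.flicker_drop_threshold,
                    recovery_threshold=cfg.flicker_recovery_threshold,
                    mito_id=obj.id,
                )
            ):
                event_rows.append(
                    dict(
                        mito_id=obj.id, event_id=k, kind="flicker",
                        t_start_s=ev.t_depol_s, t_end_s=ev.t_repol_s,
                        depth=ev.depth_fraction, speed_um_per_s=float("nan"),
                        wave_class="",
                    )
                )

    results["per_object"] = per_object
    if stop_after == "compartments":
        return results
    results["potentials"] = (
        pd.concat(potential_rows, ignore_index=True) if potential_rows else pd.DataFrame()
    )
    results["crista_tracks"] = pd.DataFrame(track_rows)
    results["events"] = pd.DataFrame(event_rows)
    return results


def tables_only(results: dict[str, object]) -> dict[str, pd.DataFrame]:
    """Drop non-table intermediates for serialization."""
    return {k: v for k, v in results.items() if isinstance(v, pd.DataFrame)}
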