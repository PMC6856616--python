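"""Sub-organelle labeling: cristae, IBM, matrix, detached vesicles."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.stats import pearsonr
from skimage import measure

from .labels import Compartment
from .preprocess import MitoObject

logger = logging.getLogger("mitovolt")


@dataclass
class CristaSite:
    """One detected crista: an axial peak expanded to a transverse band."""

    id: int
    mito_id: int
    axial_position_um: float     # sub-pixel (parabolic refinement)
    peak_index: int              # axis vertex index of the peak
    prominence: float
    band_indices: tuple[np.ndarray, np.ndarray] = field(default=None)  # (rows, cols)

    @property
    def n_pixels(self) -> int:
        return 0 if self.band_indices is None else len(self.band_indices[0])


def axis_assignment(mito: MitoObject) -> np.ndarray:
    """Nearest axis-vertex index for every object pixel (full-frame int map).

    Pixels outside the object get -1.
    """
    if mito.axis is None:
        raise ValueError("extract_axis must run before axis_assignment")
    tree = cKDTree(mito.axis.points)
    rows, cols = np.nonzero(mito.mask)
    _, idx = tree.query(np.column_stack([rows, cols]))
    out = np.full(mito.mask.shape, -1, dtype=int)
    out[rows, cols] = idx
    return out


def axial_profile(
    frame: np.ndarray,
    mito: MitoObject,
    band_halfwidth_px: int = 2,
    assignment: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity in transverse bands along the long axis.

    Returns (arclength_um, intensity), one sample per axis vertex; each
    sample averages object pixels whose nearest axis vertex lies within
    ``band_halfwidth_px`` vertices of the sample point.
    """
    if mito.axis is None or len(mito.axis.points) < 3:
        raise ValueError("axis must be extracted and have >= 3 points")
    if assignment is None:
        assignment = axis_assignment(mito)
    values = np.asarray(frame, dtype=float)[mito.mask]
    idx = assignment[mito.mask]
    n = len(mito.axis.points)
    sums = np.bincount(idx, weights=values, minlength=n)
    counts = np.bincount(idx, minlength=n)
    if band_halfwidth_px > 0:
        kernel = np.ones(2 * band_halfwidth_px + 1)
        sums = np.convolve(sums, kernel, mode="same")
        counts = np.convolve(counts, kernel, mode="same")
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    # fill the rare empty vertex from neighbors
    if np.isnan(profile).any():
        good = ~np.isnan(profile)
        profile = np.interp(np.arange(n), np.nonzero(good)[0], profile[good])
    return mito.axis.arclength_um.copy(), profile


def detect_cristae(
    arclength_um: np.ndarray,
    profile: np.ndarray,
    min_prominence_frac: float = 0.1,
    min_spacing_nm: float = 120.0,
    mito_id: int = 0,
    end_margin_um: float = 0.4,
) -> list[CristaSite]:
    """Local-maximum crista detection on a structural-channel profile.

    Prominence threshold is relative to the profile dynamic range; spacing
    converts ``min_spacing_nm`` using the axis step.  Peaks within
    ``end_margin_um`` of either axis end are discarded (the rounded end
    caps are all membrane and produce spurious maxima).  Equal-height
    plateaus resolve to their leftmost index; positions are refined
    sub-pixel by a parabolic fit and reported in um along the axis.
    """
    profile = np.asarray(profile, dtype=float)
    dynamic_range = float(profile.max() - profile.min())
    if dynamic_range <= 0:
        return []
    step_um = float(np.median(np.diff(arclength_um)))
    distance = max(1, int(round(min_spacing_nm / 1000.0 / step_um)))
    peaks, props = find_peaks(
        profile,
        prominence=min_prominence_frac * dynamic_range,
        distance=distance,
        plateau_size=(1, None),
    )
    # leftmost index on plateaus
    peaks = props["left_edges"]
    sites = []
    total = arclength_um[-1]
    for i, p in enumerate(peaks):
        pos = arclength_um[p]
        if pos < end_margin_um or pos > total - end_margin_um:
            continue
        if 0 < p < len(profile) - 1:
            denom = profile[p - 1] - 2 * profile[p] + profile[p + 1]
            if denom < 0:
                shift = 0.5 * (profile[p - 1] - profile[p + 1]) / denom
                shift = float(np.clip(shift, -0.5, 0.5))
                pos = float(np.interp(p + shift, np.arange(len(arclength_um)),
                                      arclength_um))
        sites.append(
            CristaSite(
                id=len(sites),
                mito_id=mito_id,
                axial_position_um=float(pos),
                peak_index=int(p),
                prominence=float(props["prominences"][i]),
            )
        )
    logger.info("mito %d: %d cristae detected", mito_id, len(sites))
    return sites


def classify_pixels(
    mito: MitoObject,
    cristae: list[CristaSite],
    assignment: np.ndarray | None = None,
    ibm_shell_px: int = 1,
    band_halfwidth_px: int = 1,
) -> np.ndarray:
    """Partition the frame into compartment labels.

    Object boundary shell -> IBM; crista bands (axis vertices within
    ``band_halfwidth_px`` of each peak) -> crista, including the shell
    pixels capping each crista column (excluded from IBM so that IBM
    measurements are not crista-contaminated); remaining interior ->
    matrix; everything outside the object -> cytosol.  Fills each site's
    ``band_indices`` in place.
    """
    if assignment is None:
        assignment = axis_assignment(mito)
    labels = np.full(mito.mask.shape, Compartment.CYTOSOL, dtype=np.uint8)
    interior = ndimage.binary_erosion(
        mito.mask, structure=ndimage.generate_binary_structure(2, 1),
        iterations=ibm_shell_px,
    )
    shell = mito.mask & ~interior
    labels[interior] = Compartment.MATRIX
    labels[shell] = Compartment.IBM

    if cristae:
        peak_idx = np.array([c.peak_index for c in cristae])
        idx = assignment[mito.mask]
        rows, cols = np.nonzero(mito.mask)
        # nearest peak and axial distance in axis vertices
        d = np.abs(idx[:, None] - peak_idx[None, :])
        nearest = np.argmin(d, axis=1)
        dist = d[np.arange(len(idx)), nearest]
        in_band = dist <= band_halfwidth_px
        at_center = dist == 0
        is_shell = shell[rows, cols]
        # interior band pixels plus shell pixels capping the exact peak column
        crista_sel = (in_band & ~is_shell) | (at_center & is_shell)
        labels[rows[crista_sel], cols[crista_sel]] = Compartment.CRISTA
        for k, site in enumerate(cristae):
            sel = crista_sel & (nearest == k)
            site.band_indices = (rows[sel], cols[sel])
    # invariant: compartment labels partition the object pixels
    inside = labels != Compartment.CYTOSOL
    assert np.array_equal(inside, mito.mask), "labels must partition the object"
    return labels


def detect_vesicles(
    frame_potentiometric: np.ndarray,
    label_map: np.ndarray,
    pixel_size_nm: float,
    intensity_factor: float = 2.0,
    min_area_um2: float = 0.01,
) -> np.ndarray:
    """Relabel bright matrix-interior blobs (not touching IBM) as vesicles.

    Candidates are matrix pixels with FI >= ``intensity_factor`` times the
    median matrix FI; connected components below ``min_area_um2`` or with
    any pixel 8-adjacent to an IBM pixel are rejected.  Returns the
    updated label map (modified in place).
    """
    frame = np.asarray(frame_potentiometric, dtype=float)
    matrix = label_map == Compartment.MATRIX
    if not matrix.any():
        return label_map
    median_fi = float(np.median(frame[matrix]))
    candidates = matrix & (frame >= intensity_factor * max(median_fi, 1e-12))
    ibm_halo = ndimage.binary_dilation(
        label_map == Compartment.IBM, structure=np.ones((3, 3))
    )
    px_um = pixel_size_nm / 1000.0
    min_area_px = min_area_um2 / px_um**2
    comp = measure.label(candidates, connectivity=2)
    n_kept = 0
    for region in measure.regionprops(comp):
        mask = comp == region.label
        if region.area < min_area_px:
            continue
        if (mask & ibm_halo).any():
            continue  # adjacency rule: attached structures are not vesicles
        # refine to the half-max footprint; the true (pre-blur) extent is
        # recovered downstream by fitting a disk against the PSF model
        peak = float(frame[mask].max())
        grow = mask | (ndimage.binary_dilation(mask, iterations=3) & matrix)
        refined = grow & (frame >= 0.5 * (peak + median_fi))
        refined = ndimage.binary_fill_holes(refined)
        if refined.sum() < min_area_px or (refined & ibm_halo).any():
            continue
        label_map[refined] = Compartment.VESICLE
        n_kept += 1
    logger.info("vesicle detection: %d kept", n_kept)
    return label_map


def filter_cristae_near_vesicles(
    cristae: list[CristaSite],
    vesicle_mask: np.ndarray,
    mito: MitoObject,
    assignment: np.ndarray,
    margin_um: float = 0.08,
) -> list[CristaSite]:
    """Drop crista detections that coincide with a detached vesicle.

    Vesicles are bright in the structural channel too, so they register as
    spurious axial peaks; any site whose position falls within a vesicle's
    axial extent (plus margin) is removed and ids are renumbered.
    """
    if not vesicle_mask.any():
        return cristae
    idx = assignment[vesicle_mask]
    arc = mito.axis.arclength_um
    lo = arc[idx.min()] - margin_um
    hi = arc[idx.max()] + margin_um
    kept = [c for c in cristae if not lo <= c.axial_position_um <= hi]
    n_dropped = len(cristae) - len(kept)
    if n_dropped:
        logger.info("dropped %d crista detections overlapping vesicles", n_dropped)
    for i, c in enumerate(kept):
        c.id = i
    return kept


def profile_correlation(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Pearson correlation of two equal-length axial profiles.

    Returns NaN (reported as missing) when either profile has zero
    variance.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(pearsonr(a, b)[0])
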