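"""Nernstian conversion of dye intensities into per-compartment potentials.

Potential differences follow delta_psi = kappa * ln(FI_a / FI_b) with
kappa = RT/F (mV).  Because sub-resolution membranes are mixed with their
surroundings by the PSF, raw band means underestimate true contrast; the
module therefore offers a calibrated contrast restoration: per-compartment
indicator images built from the detected geometry are blurred with the
known PSF and the resulting linear mixing system is solved for the
underlying compartment concentrations.  This is a geometric calibration
against the imaging model, not deconvolution of the image.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats

from .compartments import CristaSite, axis_assignment
from .constants import DEFAULT_TEMPERATURE_K, nernst_kappa_mv
from .labels import Compartment
from .preprocess import MitoObject

logger = logging.getLogger("mitovolt")


# -- elementary conversions ----------------------------------------------

def nernst_delta_psi(
    fi_a: float, fi_b: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Potential of a vs b in mV: kappa * ln(fi_a / fi_b).

    Positive means compartment a is more polarized than b.
    """
    if not fi_a > 0:
        raise ValueError(f"fi_a must be positive, got {fi_a}")
    if not fi_b > 0:
        raise ValueError(f"fi_b must be positive, got {fi_b}")
    # log difference (not log of ratio) keeps antisymmetry exact in floats
    return nernst_kappa_mv(temperature_K) * float(np.log(fi_a) - np.log(fi_b))


def correct_independent_fraction(fi: float, fi_independent: float) -> float:
    """Remove the potential-independent bound-dye signal.

    Returns ``fi - fi_independent``; if the correction would be
    non-positive the value is flagged missing (NaN) and logged.
    """
    if fi_independent < 0:
        raise ValueError("fi_independent must be non-negative")
    if fi_independent >= fi:
        logger.warning(
            "independent fraction %.3g >= signal %.3g; value flagged missing",
            fi_independent, fi,
        )
        return float("nan")
    return float(fi - fi_independent)


# -- contrast restoration (geometric unmixing) ---------------------------

@dataclass
class UnmixingModel:
    """Linear PSF-mixing model m = A c over compartment unknowns."""

    keys: list[str]                      # unknown names, order of columns
    A: np.ndarray                        # (n_measurements, n_unknowns)
    measure_masks: dict[str, np.ndarray]  # key -> boolean pixel set

    def unmix(self, frame: np.ndarray) -> dict[str, float]:
        """Solve for compartment concentrations from one frame."""
        m = np.array(
            [float(np.asarray(frame)[self.measure_masks[k]].mean())
             for k in self.keys]
        )
        c, *_ = np.linalg.lstsq(self.A, m, rcond=None)
        return dict(zip(self.keys, c))


def _fractional_column(
    interior: np.ndarray, col_sub: float
) -> np.ndarray:
    """Unit-mass 1-px transverse line at a sub-pixel column position."""
    out = np.zeros(interior.shape, dtype=float)
    c0 = int(np.floor(col_sub))
    frac = col_sub - c0
    for c, w in ((c0, 1.0 - frac), (c0 + 1, frac)):
        if w > 0 and 0 <= c < interior.shape[1]:
            out[:, c] = np.where(interior[:, c], w, 0.0)
    return out


def _fit_vesicle_disk(
    frame: np.ndarray,
    vmask: np.ndarray,
    interior: np.ndarray,
    ring: np.ndarray,
    sigma_px: float,
) -> np.ndarray:
    """Recover the pre-blur vesicle footprint by disk fitting.

    Scans candidate disk radii around the detected half-max component and
    keeps the one whose blurred two-region model (disk vs surroundings)
    best explains the local pixel values in the least-squares sense.
    """
    rows, cols = np.nonzero(vmask)
    cy, cx = rows.mean(), cols.mean()
    r_half = np.sqrt(vmask.sum() / np.pi)
    yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
    dist = np.hypot(yy - cy, xx - cx)
    window = dist <= r_half + 4.0 * sigma_px + 2.0
    exterior = ~(interior | ring)
    m = np.asarray(frame, dtype=float)[window]
    best = None
    for radius in np.arange(max(1.0, r_half - 1.5), r_half + 3.01, 0.25):
        disk = (dist <= radius) & interior
        basis = [disk, interior & ~disk, ring, exterior]
        A = np.stack(
            [ndimage.gaussian_filter(b.astype(float), sigma_px, mode="nearest")[window]
             for b in basis],
            axis=1,
        )
        coef, *_ = np.linalg.lstsq(A, m, rcond=None)
        resid = float(((A @ coef - m) ** 2).sum())
        if best is None or resid < best[0]:
            best = (resid, disk)
    return best[1]


def build_unmixing_model(
    mito: MitoObject,
    cristae: list[CristaSite],
    psf_sigma_px: float,
    label_map: np.ndarray,
    vesicle_masks: list[np.ndarray] | None = None,
    ibm_shell_px: int = 1,
    reference_frame: np.ndarray | None = None,
) -> UnmixingModel:
    """Build the blur-mixing matrix from detected geometry.

    Model: cytosol fills the exterior; the IBM is a 1-shell ring on the
    object boundary; each crista is a 1-px transverse line at its detected
    sub-pixel position; each vesicle is a disk fitted to its detected
    component; the matrix is the remaining interior.  Membranes modeled
    1 px wide, so recovered crista/vesicle values are line concentrations
    on that convention.
    """
    mask = mito.mask
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(mask, structure=cross, iterations=ibm_shell_px)
    ring = mask & ~interior

    indicators: dict[str, np.ndarray] = {}
    indicators["cytosol"] = (~mask).astype(float)
    indicators["ibm"] = ring.astype(float)

    axis = mito.axis
    crista_ind = np.zeros(mask.shape, dtype=float)
    for site in cristae:
        col_sub = float(
            np.interp(site.axial_position_um, axis.arclength_um, axis.points[:, 1])
        )
        ind = _fractional_column(interior, col_sub)
        indicators[f"crista:{site.id}"] = ind
        crista_ind += ind

    vesicle_ind = np.zeros(mask.shape, dtype=float)
    vesicle_disks: list[np.ndarray] = []
    for j, vmask in enumerate(vesicle_masks or []):
        if reference_frame is not None:
            disk = _fit_vesicle_disk(
                reference_frame, vmask, interior, ring, psf_sigma_px
            )
        else:
            rows, cols = np.nonzero(vmask)
            cy, cx = rows.mean(), cols.mean()
            radius = np.sqrt(vmask.sum() / np.pi)
            yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
            disk = (np.hypot(yy - cy, xx - cx) <= radius) & interior
        vesicle_disks.append(disk)
        indicators[f"vesicle:{j}"] = disk.astype(float)
        vesicle_ind += disk

    matrix_ind = np.clip(
        interior.astype(float) - crista_ind - (vesicle_ind > 0), 0.0, 1.0
    )
    indicators["matrix"] = matrix_ind

    blurred = {
        k: ndimage.gaussian_filter(v, sigma=psf_sigma_px, mode="nearest")
        for k, v in indicators.items()
    }

    measure_masks: dict[str, np.ndarray] = {
        "cytosol": ~ndimage.binary_dilation(
            mask, iterations=max(3, int(np.ceil(3 * psf_sigma_px)))
        ),
        "ibm": label_map == Compartment.IBM,
        "matrix": label_map == Compartment.MATRIX,
    }
    for site in cristae:
        m = np.zeros(mask.shape, dtype=bool)
        if site.band_indices is not None:
            m[site.band_indices] = True
        measure_masks[f"crista:{site.id}"] = m
    for j, disk in enumerate(vesicle_disks):
        measure_masks[f"vesicle:{j}"] = disk

    keys = list(indicators)
    empty = [k for k in keys if not measure_masks[k].any()]
    for k in empty:
        logger.warning("unmixing: empty measurement set for %s; dropped", k)
        keys.remove(k)
    A = np.array(
        [[float(blurred[kk][measure_masks[k]].mean()) for kk in keys] for k in keys]
    )
    return UnmixingModel(keys=keys, A=A, measure_masks=measure_masks)


# -- tables ---------------------------------------------------------------

REFERENCE_MODES = ("cytosol", "mito_mean", "adjacent_IBM")


def _corrected_concentrations(
    model: UnmixingModel,
    frame: np.ndarray,
    mito_mask: np.ndarray,
    independent_fraction: float,
) -> dict[str, float]:
    """Unmix one frame and remove the bound-dye term from inside unknowns."""
    conc = model.unmix(frame)
    indep = independent_fraction * float(np.asarray(frame)[mito_mask].mean())
    out = {}
    for k, v in conc.items():
        if k == "cytosol":
            out[k] = v
        else:
            out[k] = correct_independent_fraction(v, indep) if indep > 0 else v
    return out


def compartment_potentials(
    stack,
    mito: MitoObject,
    cristae: list[CristaSite],
    label_map: np.ndarray,
    reference_mode: str = "mito_mean",
    potentiometric_channel: str = "potentiometric",
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    independent_fraction: float = 0.05,
    psf_fwhm_nm: float = 140.0,
    restore_contrast: bool = True,
    vesicle_masks: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-compartment potentials vs the chosen reference, one row per
    compartment per frame.

    With ``restore_contrast`` (default) compartment concentrations come
    from the PSF unmixing model; otherwise raw label-mean intensities are
    used (biased toward 0 for sub-resolution membranes).
    """
    if reference_mode not in REFERENCE_MODES:
        raise ValueError(f"reference_mode must be one of {REFERENCE_MODES}")
    frames = stack.channel(potentiometric_channel)
    kappa = nernst_kappa_mv(temperature_K)
    mito_mask = mito.mask
    if vesicle_masks is None:
        vesicle_masks = _vesicle_components(label_map)
    model = None
    if restore_contrast:
        sigma_px = psf_fwhm_nm / 2.3548 / stack.pixel_size_nm
        model = build_unmixing_model(
            mito, cristae, sigma_px, label_map, vesicle_masks=vesicle_masks,
            reference_frame=frames.mean(axis=0),
        )

    rows = []
    for t, frame in enumerate(frames):
        if restore_contrast:
            conc = _corrected_concentrations(
                model, frame, mito_mask, independent_fraction
            )
        else:
            conc = _raw_concentrations(
                frame, label_map, cristae, vesicle_masks, mito_mask,
                independent_fraction,
            )
        ref = _reference_value(conc, reference_mode, frame, mito_mask, label_map)
        if not ref or not np.isfinite(ref) or ref <= 0:
            logger.warning("frame %d: non-positive reference FI; skipped", t)
            continue
        for key, value in conc.items():
            if key == "cytosol":
                continue
            comp, _, obj = key.partition(":")
            delta = (
                kappa * np.log(value / ref)
                if np.isfinite(value) and value > 0
                else float("nan")
            )
            rows.append(
                dict(
                    mito_id=mito.id,
                    object_id=int(obj) if obj else -1,
                    compartment=comp,
                    frame=t,
                    mean_fi=value,
                    reference_mode=reference_mode,
                    delta_psi_mv=delta,
                    temperature_K=temperature_K,
                )
            )
    return pd.DataFrame(rows)


def _vesicle_components(label_map: np.ndarray) -> list[np.ndarray]:
    from skimage import measure as _measure

    comp = _measure.label(label_map == Compartment.VESICLE, connectivity=2)
    return [comp == lab for lab in range(1, comp.max() + 1)]


def _raw_concentrations(
    frame, label_map, cristae, vesicle_masks, mito_mask, independent_fraction
):
    frame = np.asarray(frame, dtype=float)
    indep = independent_fraction * float(frame[mito_mask].mean())
    out = {}
    cyto = label_map == Compartment.CYTOSOL
    out["cytosol"] = float(np.median(frame[cyto])) if cyto.any() else float("nan")
    for comp, code in (("matrix", Compartment.MATRIX), ("ibm", Compartment.IBM)):
        sel = label_map == code
        if sel.any():
            out[comp] = correct_independent_fraction(float(frame[sel].mean()), indep)
    for site in cristae:
        if site.band_indices is not None and len(site.band_indices[0]):
            out[f"crista:{site.id}"] = correct_independent_fraction(
                float(frame[site.band_indices].mean()), indep
            )
    for j, vmask in enumerate(vesicle_masks or []):
        out[f"vesicle:{j}"] = correct_independent_fraction(
            float(frame[vmask].mean()), indep
        )
    return out


def _reference_value(conc, reference_mode, frame, mito_mask, label_map):
    if reference_mode == "cytosol":
        return conc.get("cytosol")
    if reference_mode == "adjacent_IBM":
        return conc.get("ibm")
    # mito_mean: average FI over the whole mitochondrion
    return float(np.asarray(frame)[mito_mask].mean())


def delta_psi_cr_ibm(
    stack,
    mito: MitoObject,
    cristae: list[CristaSite],
    label_map: np.ndarray,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    independent_fraction: float = 0.05,
    psf_fwhm_nm: float = 140.0,
    restore_contrast: bool = True,
    adjacent_window_um: float = 0.25,
    potentiometric_channel: str = "potentiometric",
) -> pd.DataFrame:
    """Per-crista potential vs adjacent IBM, per frame.

    Restored mode (default): kappa * ln(c_crista / c_IBM) from the
    unmixing model.  Raw mode: kappa * ln(FI_crista / FI_IBM_adjacent)
    where adjacent IBM pixels lie within ``adjacent_window_um`` of the
    crista along the axis; cristae with no adjacent IBM are flagged NaN.
    """
    frames = stack.channel(potentiometric_channel)
    kappa = nernst_kappa_mv(temperature_K)
    rows = []
    if restore_contrast:
        sigma_px = psf_fwhm_nm / 2.3548 / stack.pixel_size_nm
        model = build_unmixing_model(
            mito, cristae, sigma_px, label_map,
            vesicle_masks=_vesicle_components(label_map),
            reference_frame=frames.mean(axis=0),
        )
        for t, frame in enumerate(frames):
            conc = _corrected_concentrations(
                model, frame, mito.mask, independent_fraction
            )
            c_ibm = conc.get("ibm", float("nan"))
            for site in cristae:
                c_cr = conc.get(f"crista:{site.id}", float("nan"))
                ok = np.isfinite(c_cr) and np.isfinite(c_ibm) and c_cr > 0 and c_ibm > 0
                rows.append(
                    dict(
                        mito_id=mito.id,
                        crista_id=site.id,
                        frame=t,
                        axial_position_um=site.axial_position_um,
                        delta_psi_cr_ibm_mv=(
                            kappa * np.log(c_cr / c_ibm) if ok else float("nan")
                        ),
                    )
                )
        return pd.DataFrame(rows)

    # raw mode: adjacent-IBM window along the axis
    assignment = axis_assignment(mito)
    arclength = mito.axis.arclength_um
    ibm_mask = label_map == Compartment.IBM
    ibm_idx = assignment[ibm_mask]
    ibm_pos = arclength[ibm_idx]
    ibm_vals_rc = np.nonzero(ibm_mask)
    for t, frame in enumerate(frames):
        frame = np.asarray(frame, dtype=float)
        indep = independent_fraction * float(frame[mito.mask].mean())
        for site in cristae:
            near = np.abs(ibm_pos - site.axial_position_um) <= adjacent_window_um
            if not near.any():
                logger.warning("crista %d has no adjacent IBM pixels", site.id)
                value = float("nan")
            else:
                fi_ibm = correct_independent_fraction(
                    float(frame[ibm_vals_rc[0][near], ibm_vals_rc[1][near]].mean()),
                    indep,
                )
                fi_cr = correct_independent_fraction(
                    float(frame[site.band_indices].mean()), indep
                )
                value = (
                    kappa * np.log(fi_cr / fi_ibm)
                    if np.isfinite(fi_cr) and np.isfinite(fi_ibm)
                    else float("nan")
                )
            rows.append(
                dict(
                    mito_id=mito.id,
                    crista_id=site.id,
                    frame=t,
                    axial_position_um=site.axial_position_um,
                    delta_psi_cr_ibm_mv=value,
                )
            )
    return pd.DataFrame(rows)


# -- group statistics -----------------------------------------------------

def group_compare(
    values_by_group: dict[str, np.ndarray],
    per_experiment_ids: dict[str, np.ndarray] | None = None,
    equal_variance: bool = True,
) -> pd.DataFrame:
    """Two-tailed two-sample t-tests between groups.

    Values are first averaged within independent experiments (per the
    provided experiment ids; absent ids treat each value as its own
    experiment), then compared pairwise with Student's t-test (pooled
    variance by default; Welch with ``equal_variance=False``).
    """
    means = {}
    for group, values in values_by_group.items():
        values = np.asarray(values, dtype=float)
        if per_experiment_ids is not None and group in per_experiment_ids:
            ids = np.asarray(per_experiment_ids[group])
            means[group] = np.array(
                [values[ids == u].mean() for u in np.unique(ids)]
            )
        else:
            means[group] = values
        if len(means[group]) < 2:
            raise ValueError(
                f"group {group!r} has fewer than 2 independent experiments"
            )
    rows = []
    for a, b in itertools.combinations(means, 2):
        x, y = means[a], means[b]
        t, p = stats.ttest_ind(x, y, equal_var=equal_variance)
        df = (
            len(x) + len(y) - 2
            if equal_variance
            else _welch_df(x, y)
        )
        rows.append(
            dict(
                group_a=a, group_b=b,
                mean_a=float(x.mean()), mean_b=float(y.mean()),
                n_a=len(x), n_b=len(y),
                t=float(t), df=float(df), p=float(p),
            )
        )
    return pd.DataFrame(rows)


def _welch_df(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    return (vx + vy) ** 2 / (
        vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1)
    )
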