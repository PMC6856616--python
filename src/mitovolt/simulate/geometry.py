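"""Rasterize scenario geometry into a compartment label map.

The mitochondrion is drawn as a horizontal capsule (stadium shape):
a rectangle of ``length - width`` capped with two half-disks.  Membranes
(IBM ring, transverse crista bands, vesicle rims) are drawn one pixel
wide; optical blur later gives them their apparent width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import ndimage

from ..labels import Compartment
from .scenario import SimScenario


class GeometryError(ValueError):
    """Scenario geometry does not fit or violates placement rules."""


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class Geometry:
    """Rasterized scenario geometry plus object registries."""

    labels: np.ndarray  # (H, W) uint8 Compartment codes
    crista_registry: dict[int, dict[str, Any]]
    vesicle_registry: dict[int, dict[str, Any]]
    axis_x0_um: float  # axial coordinate origin (left capsule tip), image um
    axis_y_um: float  # capsule axis row, image um
    mito_mask: np.ndarray  # (H, W) bool, all mitochondrial pixels

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _capsule_mask(shape: tuple[int, int], x0: float, x1: float, yc: float,
                  radius: float) -> np.ndarray:
    """Pixels within ``radius`` of the axis segment [(x0, yc), (x1, yc)]."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    xc = np.clip(xx, x0, x1)
    dist = np.hypot(xx - xc, yy - yc)
    return dist <= radius


def build_geometry(scenario: SimScenario) -> Geometry:
    """Draw the capsule, IBM ring, crista bands and vesicles.

    Raises
    ------
    GeometryError
        If cristae fall outside the straight section of the capsule or a
        vesicle overlaps/touches the IBM ring.
    """
    px = scenario.pixel_size_um
    H = int(round((scenario.width_um + 2 * scenario.margin_um) / px))
    W = int(round((scenario.length_um + 2 * scenario.margin_um) / px))
    yc = (H - 1) / 2.0
    radius_px = scenario.width_um / 2.0 / px
    # axial coordinate 0 um sits at the left capsule tip
    x_left = scenario.margin_um / px
    x_right = x_left + scenario.length_um / px
    # segment endpoints are the cap centers
    seg_x0 = x_left + radius_px
    seg_x1 = x_right - radius_px
    if seg_x1 < seg_x0:
        raise GeometryError("length_um must exceed width_um")

    labels = np.full((H, W), Compartment.CYTOSOL, dtype=np.uint8)
    mito = _capsule_mask((H, W), seg_x0, seg_x1, yc, radius_px)
    if mito[0].any() or mito[-1].any() or mito[:, 0].any() or mito[:, -1].any():
        raise GeometryError("capsule overflows the canvas; increase margin_um")
    labels[mito] = Compartment.MATRIX

    ring = mito & ~ndimage.binary_erosion(mito, structure=_CROSS)
    labels[ring] = Compartment.IBM

    # transverse cristae, centered on the capsule midpoint
    crista_registry: dict[int, dict[str, Any]] = {}
    n = scenario.n_cristae
    if n > 0:
        mid = scenario.length_um / 2.0
        positions = mid + (np.arange(n) - (n - 1) / 2.0) * scenario.crista_spacing_um
        half_w = scenario.width_um / 2.0
        if positions[0] < half_w or positions[-1] > scenario.length_um - half_w:
            raise GeometryError(
                "cristae extend into the capsule end caps; reduce n_cristae "
                "or crista_spacing_um"
            )
        for i, pos in enumerate(positions):
            col = int(round(x_left + pos / px))
            band = mito[:, col] & ~ring[:, col]
            labels[band, col] = Compartment.CRISTA
            rows = np.nonzero(band)[0]
            crista_registry[i] = {
                "axial_position_um": float(pos),
                "pixels": [(int(r), int(col)) for r in rows],
            }

    # detached vesicles (must stay clear of the IBM ring)
    vesicle_registry: dict[int, dict[str, Any]] = {}
    ring_halo = ndimage.binary_dilation(ring, structure=np.ones((3, 3)))
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    for j, (pos, radius_um, psi_offset) in enumerate(scenario.vesicles):
        cx = x_left + pos / px
        disk = np.hypot(xx - cx, yy - yc) <= radius_um / px
        if not disk.any():
            raise GeometryError(f"vesicle {j} smaller than one pixel")
        if not mito[disk].all():
            raise GeometryError(f"vesicle {j} extends outside the mitochondrion")
        if (disk & ring_halo).any():
            raise GeometryError(f"vesicle {j} overlaps or touches the IBM ring")
        if (labels[disk] == Compartment.CRISTA).any():
            raise GeometryError(f"vesicle {j} overlaps a crista band")
        labels[disk] = Compartment.VESICLE
        rr, cc = np.nonzero(disk)
        vesicle_registry[j] = {
            "axial_position_um": float(pos),
            "radius_um": float(radius_um),
            "psi_offset_mv": float(psi_offset),
            "pixels": [(int(r), int(c)) for r, c in zip(rr, cc)],
        }

    return Geometry(
        labels=labels,
        crista_registry=crista_registry,
        vesicle_registry=vesicle_registry,
        axis_x0_um=x_left * px,
        axis_y_um=yc * px,
        mito_mask=mito,
    )
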