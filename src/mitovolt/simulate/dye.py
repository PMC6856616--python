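"""Equilibrium dye distributions from the potential field.

The potentiometric probe is a monovalent cation partitioning according to
the Nernst relation: C(pixel) = C_cyto * exp(psi / kappa), with psi in mV
(positive = hyperpolarized vs cytosol) and kappa = RT/F.  On top of the
potential-dependent pool, a small potential-independent bound pool is
modeled as a spatially uniform term inside the mitochondrion, frozen at
its pre-event (baseline) magnitude: ``independent_fraction`` times the
baseline mean mitochondrial signal.  During a full depolarization this
pool is what remains, and it is the same at cristae and matrix.
"""

from __future__ import annotations

import numpy as np

from ..constants import nernst_kappa_mv
from ..labels import Compartment
from .geometry import Geometry
from .scenario import SimScenario

_LABEL_NAMES = {
    Compartment.BACKGROUND: "background",
    Compartment.CYTOSOL: "cytosol",
    Compartment.MATRIX: "matrix",
    Compartment.IBM: "ibm",
    Compartment.CRISTA: "crista",
    Compartment.VESICLE: "vesicle",
}


def potential_map(geometry: Geometry, scenario: SimScenario) -> np.ndarray:
    """Baseline per-pixel potential (mV vs cytosol).

    Matrix = psi_matrix; IBM = matrix + IBM offset; crista i = IBM +
    crista offset + per-crista deviation; vesicle = IBM + vesicle offset.
    """
    labels = geometry.labels
    psi = np.zeros(labels.shape, dtype=float)
    psi[labels == Compartment.MATRIX] = scenario.psi_matrix_mv
    psi_ibm = scenario.psi_matrix_mv + scenario.psi_ibm_offset_mv
    psi[labels == Compartment.IBM] = psi_ibm
    offsets = scenario.crista_offsets()
    for cid, entry in geometry.crista_registry.items():
        for r, c in entry["pixels"]:
            if labels[r, c] == Compartment.CRISTA:
                psi[r, c] = psi_ibm + offsets[cid]
    for entry in geometry.vesicle_registry.values():
        for r, c in entry["pixels"]:
            psi[r, c] = psi_ibm + entry["psi_offset_mv"]
    return psi


def structural_map(geometry: Geometry, scenario: SimScenario) -> np.ndarray:
    """Structural-channel dye density (potential independent)."""
    out = np.zeros(geometry.labels.shape, dtype=float)
    for code, name in _LABEL_NAMES.items():
        out[geometry.labels == code] = scenario.membrane_density_struct.get(name, 0.0)
    return out


def equilibrium_dye_map(
    geometry: Geometry,
    scenario: SimScenario,
    psi: np.ndarray | None = None,
    baseline_psi: np.ndarray | None = None,
) -> np.ndarray:
    """Two-channel concentration map (channel 0 structural, 1 potentiometric).

    Parameters
    ----------
    psi
        Current potential field in mV; defaults to the baseline field.
    baseline_psi
        Pre-event field used to freeze the bound (potential-independent)
        dye pool; defaults to ``psi``.

    Cytosol concentration is normalized to 1.
    """
    if psi is None:
        psi = potential_map(geometry, scenario)
    if baseline_psi is None:
        baseline_psi = psi
    if not np.all(np.isfinite(psi)):
        raise ValueError("potential field contains non-finite values")
    kappa = nernst_kappa_mv(scenario.temperature_K)
    mito = geometry.mito_mask
    f = scenario.independent_fraction

    pot = np.exp(psi / kappa)
    if f > 0:
        baseline_mean = float(np.exp(baseline_psi[mito] / kappa).mean())
        pot = np.where(mito, (1.0 - f) * pot + f * baseline_mean, pot)

    return np.stack([structural_map(geometry, scenario), pot])
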