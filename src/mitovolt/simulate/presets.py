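"""Named simulation scenarios for the experimental conditions.

Per-compartment potential offsets (crista vs IBM, vesicle vs IBM) use
published point estimates; geometry, absolute matrix polarization, pixel
size and noise levels are plausible defaults for Airyscan-class live-cell
imaging and are not measured quantities.
"""

from __future__ import annotations

import copy
from typing import Any

from .scenario import SimScenario

#: Crista-vs-IBM potential offset (mV) for untreated cells.
CONTROL_CR_IBM_MV = 10.11
#: Vesicle-vs-IBM offset (mV) for Mic10-knockout detached vesicles.
MIC10_VESICLE_MV = 25.85
#: Vesicle-vs-IBM offset (mV) for Opa1&Drp1 double-knockout vesicles.
OPA1_DRP1_VESICLE_MV = 39.55

_PRESET_PARAMS: dict[str, dict[str, Any]] = {
    # elongated tubule, regularly spaced cristae, ~10 mV crista offset
    "control": dict(
        psi_crista_offset_mv=CONTROL_CR_IBM_MV,
    ),
    # ATP-synthase inhibition: hyperpolarized, larger crista offset
    "oligomycin": dict(
        psi_matrix_mv=155.0,
        psi_crista_offset_mv=16.0,
    ),
    # protonophore: potentials collapse toward zero, fragmented geometry
    "fccp": dict(
        psi_matrix_mv=40.0,
        psi_ibm_offset_mv=3.0,
        psi_crista_offset_mv=3.0,
        length_um=3.0,
        width_um=1.2,
        n_cristae=4,
    ),
    # MICOS / Opa1 loss: fewer cristae, crista offset near zero
    "mic13_ko": dict(psi_crista_offset_mv=1.5, n_cristae=5),
    "mic60_ko": dict(psi_crista_offset_mv=1.5, n_cristae=5),
    "opa1_ko": dict(psi_crista_offset_mv=1.5, n_cristae=5),
    # Mic10 loss: crista offset near zero plus a hyperpolarized vesicle
    "mic10_ko": dict(
        psi_crista_offset_mv=1.5,
        n_cristae=5,
        vesicles=[(2.5, 0.15, MIC10_VESICLE_MV)],
    ),
    # Opa1&Drp1 double loss: strongly hyperpolarized detached vesicle
    "opa1_drp1_dko": dict(
        psi_crista_offset_mv=1.5,
        n_cristae=4,
        vesicles=[(2.5, 0.18, OPA1_DRP1_VESICLE_MV)],
    ),
}


def preset_names() -> list[str]:
    return list(_PRESET_PARAMS)


def get_preset(name: str, seed: int = 0, **overrides: Any) -> SimScenario:
    """Build one named scenario; ``overrides`` replace any scenario field."""
    if name not in _PRESET_PARAMS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(_PRESET_PARAMS)}"
        )
    params = copy.deepcopy(_PRESET_PARAMS[name])
    params.update(overrides)
    return SimScenario(name=name, rng_seed=seed, **params)


def preset_scenarios(seed: int = 0) -> dict[str, SimScenario]:
    """All named presets, keyed by name."""
    return {name: get_preset(name, seed=seed) for name in _PRESET_PARAMS}


def preset_manifest() -> dict[str, dict[str, Any]]:
    """Machine-readable parameter manifest (JSON-serializable)."""
    return {name: get_preset(name).to_dict() for name in _PRESET_PARAMS}
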