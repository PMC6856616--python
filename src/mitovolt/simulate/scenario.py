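"""Scenario description, event model and ground-truth containers."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

from ..constants import DEFAULT_TEMPERATURE_K

EVENT_KINDS = ("flicker", "wave", "partial_depolarization")

#: Relative structural-dye density per compartment label name.  Membranes
#: (IBM, crista, vesicle) bind far more lipophilic structural dye than the
#: matrix; cytosol carries a small unbound background.
DEFAULT_STRUCT_DENSITY = {
    "background": 0.0,
    "cytosol": 0.05,
    "matrix": 0.25,
    "ibm": 0.8,
    "crista": 1.0,
    "vesicle": 1.0,
}


@dataclass
class Event:
    """A transient potential perturbation applied during the time-lapse.

    kind:
        ``flicker`` scales the whole-organelle potential toward zero for
        the duration of the event; ``wave`` depolarizes behind a front
        advancing from ``site_um`` at ``speed_um_per_s`` (irreversible);
        ``partial_depolarization`` depresses only ``target_crista_ids``.
    depth:
        Fraction of the potential lost (1.0 = full depolarization).
    """

    kind: str
    t_start_s: float
    t_end_s: float
    depth: float = 1.0
    site_um: float | None = None
    speed_um_per_s: float | None = None
    target_crista_ids: list[int] | None = None

    def validate(self, duration_s: float, length_um: float) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.t_start_s < self.t_end_s:
            raise ValueError("event requires t_start_s < t_end_s")
        if self.t_end_s > duration_s + 1e-9:
            raise ValueError(
                f"event ends at {self.t_end_s} s but series lasts {duration_s} s"
            )
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("event depth must lie in [0, 1]")
        if self.kind == "wave":
            if self.site_um is None or self.speed_um_per_s is None:
                raise ValueError("wave events need site_um and speed_um_per_s")
            if not 0.0 <= self.site_um <= length_um:
                raise ValueError("wave site must lie within the mitochondrion")
            if self.speed_um_per_s <= 0:
                raise ValueError("wave speed must be positive")
        if self.kind == "partial_depolarization" and not self.target_crista_ids:
            raise ValueError("partial_depolarization needs target_crista_ids")


@dataclass
class SimScenario:
    """Full generative description of one phantom time-lapse.

    Potentials follow the convention: positive mV = hyperpolarized relative
    to cytosol; offsets add (crista potential = matrix + IBM offset +
    crista offset + per-crista deviation).
    """

    name: str = "custom"
    # geometry
    length_um: float = 10.0
    width_um: float = 0.9
    n_cristae: int = 10
    crista_spacing_um: float = 0.3
    margin_um: float = 1.0
    # potentials (positive = polarized)
    psi_matrix_mv: float = 140.0
    psi_ibm_offset_mv: float = 10.0
    psi_crista_offset_mv: float = 10.11
    per_crista_offsets_mv: list[float] | None = None
    psi_crista_jitter_mv: float = 0.0  # per-frame random crista fluctuation
    # vesicles: (axial position um from left tip, radius um, psi offset vs IBM)
    vesicles: list[tuple[float, float, float]] = field(default_factory=list)
    # dye model
    independent_fraction: float = 0.05
    membrane_density_struct: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRUCT_DENSITY)
    )
    temperature_K: float = DEFAULT_TEMPERATURE_K
    # optics / noise
    pixel_size_nm: float = 40.0
    psf_fwhm_nm: float = 140.0
    photons_per_unit: float = 3.0          # potentiometric channel gain
    struct_photons_per_unit: float = 300.0  # structural channel gain
    read_noise_sd: float = 1.0
    # time
    frame_interval_s: float = 0.5
    n_frames: int = 5
    events: list[Event] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.events = [
            Event(**e) if isinstance(e, dict) else e for e in self.events
        ]
        self.vesicles = [tuple(v) for v in self.vesicles]
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        for name in ("length_um", "width_um", "crista_spacing_um", "pixel_size_nm",
                     "psf_fwhm_nm", "photons_per_unit", "struct_photons_per_unit",
                     "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cristae < 0:
            raise ValueError("n_cristae must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.independent_fraction < 1.0:
            raise ValueError("independent_fraction must lie in [0, 1)")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        if self.per_crista_offsets_mv is not None and len(
            self.per_crista_offsets_mv
        ) != self.n_cristae:
            raise ValueError(
                "per_crista_offsets_mv length must equal n_cristae"
            )
        for pos, radius, _ in self.vesicles:
            if radius <= 0:
                raise ValueError("vesicle radius must be positive")
            if not 0 < pos < self.length_um:
                raise ValueError("vesicle position must lie inside the capsule")
        for ev in self.events:
            ev.validate(self.duration_s, self.length_um)

    # -- derived quantities ---------------------------------------------

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_nm / 2.3548 / self.pixel_size_nm

    def crista_offsets(self) -> np.ndarray:
        """Per-crista potential offsets vs IBM (base offset + deviations)."""
        base = np.full(self.n_cristae, self.psi_crista_offset_mv, dtype=float)
        if self.per_crista_offsets_mv is not None:
            base = base + np.asarray(self.per_crista_offsets_mv, dtype=float)
        return base

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimScenario":
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimScenario":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Simulator truth emitted alongside the rendered stack."""

    label_map: np.ndarray  # (T, H, W) uint8, Compartment codes
    true_psi_map: np.ndarray  # (T, H, W) float32, mV
    crista_registry: dict[int, dict[str, Any]]  # id -> position/pixels
    vesicle_registry: dict[int, dict[str, Any]]
    event_log: list[dict[str, Any]]
    axis_x0_um: float  # axial coordinate of the left capsule tip (image x, um)

    def crista_positions_um(self) -> np.ndarray:
        return np.array(
            [self.crista_registry[k]["axial_position_um"]
             for k in sorted(self.crista_registry)]
        )
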