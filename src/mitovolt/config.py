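"""Run configuration: every stage tunable in one serializable object."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .constants import DEFAULT_TEMPERATURE_K


@dataclass
class RunConfig:
    """All pipeline tunables with documented defaults.

    Serializes losslessly to JSON/YAML; the config plus the input stack
    fully determine the outputs.
    """

    # preprocess
    background_radius_px: int = 50          # rolling-ball radius
    subtract_background: bool = True
    min_area_um2: float = 0.2               # object size filter
    discard_edge_objects: bool = True
    # compartments
    band_halfwidth_px: int = 1              # crista band half-width (axial)
    min_prominence_frac: float = 0.1        # peak prominence vs dynamic range
    min_spacing_nm: float = 120.0           # minimum crista spacing
    end_margin_um: float = 0.4              # discard peaks near the end caps
    ibm_shell_px: int = 1                   # IBM boundary shell thickness
    vesicle_intensity_factor: float = 2.0   # vs median matrix FI
    vesicle_min_area_um2: float = 0.01
    # potentials
    reference_mode: str = "adjacent_IBM"    # cytosol | mito_mean | adjacent_IBM
    temperature_K: float = DEFAULT_TEMPERATURE_K
    independent_fraction: float = 0.05      # bound-dye correction default
    psf_fwhm_nm: float = 140.0              # for contrast restoration
    restore_contrast: bool = True
    adjacent_window_um: float = 0.25        # adjacent-IBM axial window
    equal_variance_ttest: bool = True
    # dynamics
    max_jump_um: float = 0.15               # crista tracking
    max_gap_frames: int = 2
    flicker_drop_threshold: float = 0.5
    flicker_recovery_threshold: float = 0.8
    partial_depol_fraction: float = 0.3
    wave_front_fraction: float = 0.5        # of baseline
    wave_proximal_um: float = 1.0
    wave_distal_um: float = 10.0
    baseline_frames: int = 5
    # misc
    seed: int = 0
    extra: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yaml", ".yml")
            else json.loads(text)
        )
        return cls(**data)
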