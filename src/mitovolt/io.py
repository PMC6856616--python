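"""Image/table IO: calibrated stacks, result tables, LUT renders."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from matplotlib.colors import LinearSegmentedColormap

logger = logging.getLogger("mitovolt")

DEFAULT_PIXEL_SIZE_NM = 40.0
DEFAULT_FRAME_INTERVAL_S = 0.5

#: Stable column schemas for the CSV outputs.
TABLE_SCHEMAS = {
    "morphometrics": [
        "frame", "mito_id", "area_um2", "perimeter_um", "circularity",
        "aspect_ratio", "axis_length_um",
    ],
    "potentials": [
        "mito_id", "object_id", "compartment", "frame", "mean_fi",
        "reference_mode", "delta_psi_mv", "temperature_K",
    ],
    "crista_tracks": [
        "mito_id", "track_id", "frame", "axial_position_um",
        "delta_psi_cr_ibm_mv",
    ],
    "events": [
        "mito_id", "event_id", "kind", "t_start_s", "t_end_s", "depth",
        "speed_um_per_s", "wave_class",
    ],
}


@dataclass
class FrameStack:
    """Calibrated multi-channel time-lapse: pixels indexed (t, c, y, x)."""

    pixels: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be 4D (t, channel, y, x), got {self.pixels.shape}"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.pixels.shape[1])]
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError("channel_names length mismatch with channel axis")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_nm and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def channel(self, name: str) -> np.ndarray:
        """(t, y, x) view of one channel by name."""
        return self.pixels[:, self.channel_names.index(name)]


def write_stack(stack: FrameStack, out_dir: str | Path, name: str = "stack") -> Path:
    """Write a multi-page TIFF (t, c, y, x interleaved) + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / f"{name}.tif"
    tifffile.imwrite(tiff_path, stack.pixels.astype(np.float32), imagej=False)
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "frame_interval_s": stack.frame_interval_s,
        "channel_names": stack.channel_names,
        "axes": "TCYX",
    }
    (out_dir / f"{name}.json").write_text(json.dumps(meta, indent=2))
    return tiff_path


def read_stack(path: str | Path, metadata_path: str | Path | None = None) -> FrameStack:
    """Read a TIFF stack with optional JSON metadata sidecar.

    Arrays are coerced to (t, channel, y, x): 2D input becomes one frame,
    one channel; 3D input is treated as a single-channel time series.
    Missing calibration falls back to defaults with a logged warning.
    """
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None, None]
    elif pixels.ndim == 3:
        pixels = pixels[:, None]
    elif pixels.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with shape {pixels.shape}")

    if metadata_path is None:
        candidate = path.with_suffix(".json")
        metadata_path = candidate if candidate.exists() else None
    meta = {}
    if metadata_path is not None:
        meta = json.loads(Path(metadata_path).read_text())
    if "pixel_size_nm" not in meta:
        logger.warning(
            "no pixel_size_nm metadata for %s; defaulting to %.0f nm",
            path, DEFAULT_PIXEL_SIZE_NM,
        )
    if "frame_interval_s" not in meta:
        logger.warning(
            "no frame_interval_s metadata for %s; defaulting to %.2f s",
            path, DEFAULT_FRAME_INTERVAL_S,
        )
    return FrameStack(
        pixels=pixels,
        pixel_size_nm=float(meta.get("pixel_size_nm", DEFAULT_PIXEL_SIZE_NM)),
        frame_interval_s=float(meta.get("frame_interval_s", DEFAULT_FRAME_INTERVAL_S)),
        channel_names=list(meta.get("channel_names", [])),
    )


def write_ground_truth(truth, out_dir: str | Path, name: str = "truth") -> None:
    """Label TIFF + JSON registry for simulator ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / f"{name}_labels.tif", truth.label_map.astype(np.uint8))
    registry = {
        "axis_x0_um": truth.axis_x0_um,
        "cristae": {
            str(k): {kk: vv for kk, vv in v.items() if kk != "pixels"}
            for k, v in truth.crista_registry.items()
        },
        "vesicles": {
            str(k): {kk: vv for kk, vv in v.items() if kk != "pixels"}
            for k, v in truth.vesicle_registry.items()
        },
        "events": truth.event_log,
    }
    (out_dir / f"{name}_registry.json").write_text(json.dumps(registry, indent=2))


def write_tables(
    results: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write result tables as CSV with stable schemas plus a run manifest.

    Unknown table names are written as-is; known names are reindexed to
    their documented column schema (mV values rounded to 2 decimals).
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in results.items():
        if name in TABLE_SCHEMAS:
            df = df.reindex(columns=TABLE_SCHEMAS[name])
        df = df.copy()
        for col in df.columns:
            if col.endswith("_mv"):
                df[col] = df[col].astype(float).round(2)
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    manifest = {"software_version": __version__, "config": config or {},
                "tables": sorted(results)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return written


#: Pseudo-color scale: blue (dimmest) -> green -> red -> white (brightest).
LUT_CMAP = LinearSegmentedColormap.from_list(
    "mitovolt_lut",
    [(0.0, 0.1, 0.9), (0.0, 0.8, 0.2), (0.9, 0.1, 0.0), (1.0, 1.0, 1.0)],
)


def render_lut(
    frame: np.ndarray,
    scale: tuple[float, float] | None = None,
) -> np.ndarray:
    """Map a scalar frame to RGB with the white->red->green->blue LUT.

    The maximum (or the upper scale bound) maps to white, the minimum to
    blue.  ``scale=(lo, hi)`` fixes the mapping across frames; default is
    per-frame min/max.  Returns a (H, W, 3) float array in [0, 1].
    """
    frame = np.asarray(frame, dtype=float)
    if scale is None:
        lo, hi = float(frame.min()), float(frame.max())
    else:
        lo, hi = scale
    if hi <= lo:  # constant frame: single mid-scale color
        norm = np.full(frame.shape, 0.5)
    else:
        norm = np.clip((frame - lo) / (hi - lo), 0.0, 1.0)
    return LUT_CMAP(norm)[..., :3]


def save_lut_png(
    frame: np.ndarray,
    path: str | Path,
    scale: tuple[float, float] | None = None,
) -> None:
    """Render a frame through the LUT and write a PNG with a legend bar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = render_lut(frame, scale=scale)
    fig, ax = plt.subplots(figsize=(6, 6 * rgb.shape[0] / max(rgb.shape[1], 1)))
    ax.imshow(rgb)
    ax.set_axis_off()
    sm = plt.cm.ScalarMappable(cmap=LUT_CMAP)
    sm.set_clim(*(scale or (float(frame.min()), float(frame.max()))))
    fig.colorbar(sm, ax=ax, fraction=0.04, label="FI")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
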