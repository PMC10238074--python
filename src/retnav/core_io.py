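"""Domain types and file I/O shared by the whole pipeline.

Conventions
-----------
* OCT axes are (repeat r [optional], slow y, fast x, depth z); depth z
  increases away from the vitreous, so the inner retina sits at low z and
  the RPE at high z.  All indices are 0-based; en face coordinates are in
  micrometres with the origin at the volume corner.
* Volumes are stored as multi-page 32-bit float TIFF, one B-scan (z, x) per
  page, pages ordered (repeat, y)-major, with a JSON sidecar
  ``<name>.meta.json`` carrying pitches, repeat count and axis order.
* SLO stacks are multi-page TIFF ordered (time, channel)-major with a
  sidecar carrying pixel pitch, timestamps and frame rate; channel 0 is the
  red (tdTomato) PMT channel and channel 1 the green (GFP / photoconverted)
  channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from retnav._log import get_logger

log = get_logger("core_io")

RED, GREEN = 0, 1


class SidecarError(IOError):
    """Missing or inconsistent JSON sidecar."""


def _sidecar_path(path: Path) -> Path:
    stem = path.stem if path.suffix else path.name
    return path.with_name(stem + ".meta.json")


# --------------------------------------------------------------------- types


@dataclass
class OCTVolume:
    """Reconstructed OCT intensity volume (not raw spectra).

    voxels has axes (y, x, z) or (r, y, x, z) when repeated B-scans are
    present; pitches are micrometres per voxel.
    """

    voxels: np.ndarray
    pitch_x: float
    pitch_y: float
    pitch_z: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (3, 4):
            raise ValueError(f"voxels must be 3D or 4D, got ndim={self.voxels.ndim}")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        for name in ("pitch_x", "pitch_y", "pitch_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if min(self.voxels.shape) < 1:
            raise ValueError("all axis lengths must be >= 1")

    @property
    def has_repeats(self) -> bool:
        return self.voxels.ndim == 4

    @property
    def n_repeats(self) -> int:
        return self.voxels.shape[0] if self.has_repeats else 1

    @property
    def shape_yxz(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape[-3:])

    @property
    def n_frames(self) -> int:
        """Total acquired B-scan frames (positions x repeats)."""
        return self.n_repeats * self.voxels.shape[-3]


@dataclass
class SLOSequence:
    """Two-channel SLO frame time series, axes (t, channel, row, col)."""

    frames: np.ndarray
    pitch: float
    timestamps: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must have axes (t, channel, row, col)")
        if self.frames.shape[1] != 2:
            raise ValueError(
                f"exactly two channels (red, green) required, got {self.frames.shape[1]}"
            )
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pitch <= 0 or self.frame_rate <= 0:
            raise ValueError("pitch and frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def red(self) -> np.ndarray:
        return self.frames[:, RED]

    def green(self) -> np.ndarray:
        return self.frames[:, GREEN]


@dataclass(frozen=True)
class LaserParams:
    """Photocoagulation pulse train: power (mW), duration (ms), repeats, inter-pulse interval (ms)."""

    power: float
    duration: float
    repeats: int = 1
    interval: float = 0.0

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be > 0 mW")
        if self.duration <= 0:
            raise ValueError("duration must be > 0 ms")
        if not isinstance(self.repeats, (int, np.integer)) or self.repeats < 1:
            raise ValueError("repeats must be an integer >= 1")
        if self.interval < 0:
            raise ValueError("interval must be >= 0 ms")

    @property
    def energy_mj(self) -> float:
        """Total delivered energy in mJ (power x duration x repeats)."""
        return self.power * self.duration * self.repeats / 1000.0


VALID_SURFACES = ("RPE", "OPL")


@dataclass
class SurfaceMap:
    """Per-(y, x) depth index (voxels) of a named retinal surface."""

    name: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in VALID_SURFACES:
            raise ValueError(f"surface name must be one of {VALID_SURFACES}")
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise ValueError("depth map must be 2D (y, x)")
        if np.any(self.depth < 0):
            raise ValueError("depth indices must be >= 0")

    def validate_extent(self, z_extent: int) -> None:
        if np.any(self.depth >= z_extent):
            raise ValueError(f"surface depth exceeds z extent {z_extent}")


def check_surface_order(opl: SurfaceMap, rpe: SurfaceMap) -> None:
    """OPL must be strictly inner to (above, lower z than) the RPE everywhere."""
    if opl.depth.shape != rpe.depth.shape:
        raise ValueError("surface maps have mismatched shapes")
    if not np.all(opl.depth < rpe.depth):
        raise ValueError("OPL surface must lie strictly above the RPE at every (y, x)")


# ----------------------------------------------------------------- volume io


def write_volume(vol: OCTVolume, path: str | Path) -> Path:
    path = Path(path)
    vx = vol.voxels if vol.has_repeats else vol.voxels[None]
    r, y, x, z = vx.shape
    pages = np.ascontiguousarray(
        vx.transpose(0, 1, 3, 2).reshape(r * y, z, x).astype(np.float32)
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "kind": "oct_volume",
        "axis_order": "(repeat, y, x, z); pages (repeat, y)-major, each page (z, x)",
        "repeats": r,
        "shape_yxz": [y, x, z],
        "pitch_x_um": vol.pitch_x,
        "pitch_y_um": vol.pitch_y,
        "pitch_z_um": vol.pitch_z,
        "has_repeat_axis": vol.has_repeats,
        "meta": vol.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    log.info("write_volume: %s shape=%s repeats=%d", path, (y, x, z), r)
    return path


def read_volume(path: str | Path) -> OCTVolume:
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise SidecarError(f"missing sidecar for {path}: expected {sc_path}")
    sc = json.loads(sc_path.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    r = int(sc["repeats"])
    y, x, z = (int(v) for v in sc["shape_yxz"])
    if pages.shape != (r * y, z, x):
        raise SidecarError(
            f"shape mismatch: sidecar promises {r}x{y} pages of (z={z}, x={x}), "
            f"file holds {pages.shape}"
        )
    vx = pages.reshape(r, y, z, x).transpose(0, 1, 3, 2)
    if not sc.get("has_repeat_axis", True):
        vx = vx[0]
    return OCTVolume(
        voxels=vx,
        pitch_x=float(sc["pitch_x_um"]),
        pitch_y=float(sc["pitch_y_um"]),
        pitch_z=float(sc["pitch_z_um"]),
        meta=sc.get("meta", {}),
    )


# --------------------------------------------------------------- sequence io


def write_sequence(seq: SLOSequence, path: str | Path) -> Path:
    path = Path(path)
    t, c, h, w = seq.frames.shape
    pages = np.ascontiguousarray(seq.frames.reshape(t * c, h, w).astype(np.float32))
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "kind": "slo_sequence",
        "axis_order": "(t, channel, row, col); pages (t, channel)-major",
        "channels": ["red", "green"],
        "n_frames": t,
        "shape_rc": [h, w],
        "pitch_um": seq.pitch,
        "frame_rate_hz": seq.frame_rate,
        "timestamps_s": seq.timestamps.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    log.info("write_sequence: %s frames=%d shape=%s", path, t, (h, w))
    return path


def read_sequence(path: str | Path) -> SLOSequence:
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise SidecarError(f"missing sidecar for {path}: expected {sc_path}")
    sc = json.loads(sc_path.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    t = int(sc["n_frames"])
    n_ch = len(sc["channels"])
    if n_ch != 2:
        raise SidecarError(f"exactly two channels required, sidecar lists {sc['channels']}")
    h, w = (int(v) for v in sc["shape_rc"])
    if pages.shape != (t * n_ch, h, w):
        raise SidecarError(
            f"shape mismatch: sidecar promises {t * n_ch} pages of ({h}, {w}), "
            f"file holds {pages.shape}"
        )
    return SLOSequence(
        frames=pages.reshape(t, n_ch, h, w),
        pitch=float(sc["pitch_um"]),
        timestamps=np.asarray(sc["timestamps_s"], dtype=float),
        frame_rate=float(sc["frame_rate_hz"]),
    )


# ------------------------------------------------------------ tables & masks


def write_landmarks(df, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_landmarks(path: str | Path):
    import pandas as pd

    df = pd.read_csv(path)
    required = {"vx", "vy", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark table missing columns: {sorted(missing)}")
    return df


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a 2D boolean mask as PNG (uint8 0/255) or single-page TIFF."""
    path = Path(path)
    arr = (np.asarray(mask, dtype=bool)).astype(np.uint8) * 255
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        tifffile.imwrite(path, arr)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        arr = tifffile.imread(path)
    if arr.ndim == 3:  # collapse RGB(A)
        arr = arr[..., 0]
    return arr > 0


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, default=_json_default))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
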