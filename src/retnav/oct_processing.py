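"""OCT volume processing: repeat averaging, surface detection, flattening,
layer-bounded en face projection.

Repeated B-scans acquired at each slow-axis position are averaged; the RPE
is detected per A-scan as the intensity maximum after axial median
filtering, the OPL as the strongest local maximum within a configured
distance band inner to the RPE; volumes are digitally flattened by shifting
each A-scan so the reference surface sits at its median depth; en face views
reduce the half-open depth slab [top, bottom) per (y, x), mean by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from retnav._log import get_logger
from retnav.core_io import OCTVolume, SurfaceMap, check_surface_order

log = get_logger("oct_processing")

#: pluggable denoiser applied to the averaged volume; identity by default.
#: (hook for fancier multi-frame denoising; plain repeat averaging is the
#: method of record here.)
Denoiser = Callable[[np.ndarray], np.ndarray]


def average_repeats(volume: OCTVolume, denoiser: Denoiser | None = None) -> OCTVolume:
    """Voxelwise arithmetic mean over the repeat axis (identity if r = 1)."""
    if not volume.has_repeats:
        vox = volume.voxels.astype(np.float32)
    else:
        vox = volume.voxels.mean(axis=0, dtype=np.float64).astype(np.float32)
    if denoiser is not None:
        vox = np.asarray(denoiser(vox), dtype=np.float32)
    log.info("average_repeats: r=%d -> shape %s", volume.n_repeats, vox.shape)
    return OCTVolume(
        voxels=vox,
        pitch_x=volume.pitch_x,
        pitch_y=volume.pitch_y,
        pitch_z=volume.pitch_z,
        meta=dict(volume.meta) | {"averaged_repeats": volume.n_repeats},
    )


def detect_surface(
    volume: OCTVolume,
    name: str = "RPE",
    smoothing_um: float = 60.0,
    axial_median_vox: int = 3,
    opl_min_sep_um: float = 40.0,
    opl_max_sep_um: float = 200.0,
    peak_snr: float = 3.0,
    max_bad_fraction: float = 0.05,
) -> SurfaceMap:
    """Per-(y, x) depth of the RPE (global axial maximum) or OPL.

    The OPL is the strongest local maximum between ``opl_min_sep_um`` and
    ``opl_max_sep_um`` inner to the detected RPE.  A-scans whose peak does
    not exceed ``peak_snr`` times the volume median count as failures; more
    than ``max_bad_fraction`` of failures raises.
    """
    if volume.has_repeats:
        raise ValueError("detect_surface expects an averaged volume (no repeat axis)")
    vox = volume.voxels
    ny, nx, nz = vox.shape
    filt = ndimage.median_filter(vox, size=(1, 1, axial_median_vox))
    noise = float(np.median(filt))

    rpe_idx = np.argmax(filt, axis=2)
    peaks = np.take_along_axis(filt, rpe_idx[..., None], axis=2)[..., 0]
    bad = peaks <= peak_snr * max(noise, 1e-12)
    frac = float(bad.mean())
    if frac > max_bad_fraction:
        raise ValueError(
            f"no peak above noise floor in {frac:.1%} of A-scans "
            f"(limit {max_bad_fraction:.0%}); volume may be featureless"
        )

    # vessel shadows can dim the RPE below inner layers for isolated A-scans;
    # re-snap outliers to the strongest peak near the laterally
    # median-smoothed surface
    win0 = max(int(round(2 * smoothing_um / volume.pitch_x)) | 1, 3)
    guide = ndimage.median_filter(rpe_idx.astype(float), size=(win0, win0))
    refine = max(int(round(30.0 / volume.pitch_z)), 3)
    z = np.arange(nz)
    near = np.abs(z[None, None, :] - guide[..., None]) <= refine
    rpe_idx = np.argmax(np.where(near, filt, -np.inf), axis=2)

    if name == "RPE":
        depth = rpe_idx.astype(float)
    elif name == "OPL":
        min_sep = max(int(round(opl_min_sep_um / volume.pitch_z)), 1)
        max_sep = max(int(round(opl_max_sep_um / volume.pitch_z)), min_sep + 1)
        lo = np.clip(rpe_idx - max_sep, 0, nz - 1)
        hi = np.clip(rpe_idx - min_sep, 0, nz - 1)
        in_band = (z[None, None, :] >= lo[..., None]) & (z[None, None, :] <= hi[..., None])
        if not np.all(in_band.any(axis=2)):
            raise ValueError("OPL search band empty for some A-scans; RPE too shallow")
        banded = np.where(in_band, filt, -np.inf)
        depth = np.argmax(banded, axis=2).astype(float)
    else:
        raise ValueError(f"unknown surface {name!r}")

    win = max(int(round(smoothing_um / volume.pitch_x)) | 1, 1)  # odd window
    depth = ndimage.median_filter(depth, size=(win, win))
    log.info("detect_surface: %s median depth %.1f vox (smoothing %d px)",
             name, float(np.median(depth)), win)
    return SurfaceMap(name=name, depth=depth)


@dataclass
class FlattenResult:
    volume: OCTVolume
    shifts: np.ndarray  # integer axial shift applied per (y, x)
    valid: np.ndarray  # bool (y, x, z): False where zero padding was inserted
    target_depth: int


def flatten(volume: OCTVolume, reference: SurfaceMap) -> FlattenResult:
    """Shift each A-scan (zero-padded, never wrapped) so ``reference`` sits at
    its median depth; returns the shift map for exact invertibility."""
    if volume.has_repeats:
        raise ValueError("flatten expects an averaged volume")
    vox = volume.voxels
    ny, nx, nz = vox.shape
    if reference.depth.shape != (ny, nx):
        raise ValueError("reference surface does not match volume (y, x) shape")
    target = int(round(float(np.median(reference.depth))))
    shifts = target - np.round(reference.depth).astype(int)  # positive -> deeper

    out, valid = apply_axial_shifts(vox, shifts)
    log.info("flatten: target depth %d vox, shift range [%d, %d]",
             target, int(shifts.min()), int(shifts.max()))
    flat = OCTVolume(
        voxels=out,
        pitch_x=volume.pitch_x,
        pitch_y=volume.pitch_y,
        pitch_z=volume.pitch_z,
        meta=dict(volume.meta) | {"flattened_to": target},
    )
    return FlattenResult(volume=flat, shifts=shifts, valid=valid, target_depth=target)


def apply_axial_shifts(vox: np.ndarray, shifts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shift each A-scan by its (y, x) integer shift with zero fill; returns
    (shifted volume, validity mask)."""
    ny, nx, nz = vox.shape
    out = np.zeros_like(vox)
    valid = np.zeros((ny, nx, nz), dtype=bool)
    for s in np.unique(shifts):
        sel = shifts == s
        if s == 0:
            out[sel] = vox[sel]
            valid[sel] = True
        elif s > 0:
            out[sel, s:] = vox[sel][:, : nz - s]
            valid[sel, s:] = True
        else:
            out[sel, :s] = vox[sel][:, -s:]
            valid[sel, :s] = True
    return out, valid


def unflatten(result: FlattenResult) -> OCTVolume:
    """Invert a flatten by applying the negated shifts (padding stays zero)."""
    vox, _ = apply_axial_shifts(result.volume.voxels, -result.shifts)
    return OCTVolume(
        voxels=vox,
        pitch_x=result.volume.pitch_x,
        pitch_y=result.volume.pitch_y,
        pitch_z=result.volume.pitch_z,
        meta=dict(result.volume.meta),
    )


_REDUCERS = {"mean": np.nanmean, "max": np.nanmax, "sum": np.nansum}


def enface_projection(
    volume: OCTVolume,
    top: "SurfaceMap | np.ndarray",
    bottom: "SurfaceMap | np.ndarray",
    reducer: str = "mean",
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Reduce the half-open depth slab [top, bottom) per (y, x).

    ``top`` must be strictly above ``bottom`` everywhere (lower depth index);
    either bound may be a SurfaceMap or a bare (y, x) depth array.
    ``valid`` optionally masks padded voxels from a flatten.
    """
    if volume.has_repeats:
        raise ValueError("enface_projection expects an averaged volume")
    if reducer not in _REDUCERS:
        raise ValueError(f"reducer must be one of {sorted(_REDUCERS)}")
    top_d = top.depth if isinstance(top, SurfaceMap) else np.asarray(top, dtype=float)
    bot_d = bottom.depth if isinstance(bottom, SurfaceMap) else np.asarray(bottom, dtype=float)
    if not np.all(top_d < bot_d):
        raise ValueError("top surface must lie strictly above bottom surface everywhere")
    vox = volume.voxels.astype(float)
    ny, nx, nz = vox.shape
    z = np.arange(nz)
    t = np.round(top_d).astype(int)
    b = np.round(bot_d).astype(int)
    in_slab = (z[None, None, :] >= t[..., None]) & (z[None, None, :] < b[..., None])
    if valid is not None:
        in_slab &= valid
    stack = np.where(in_slab, vox, np.nan)
    with np.errstate(invalid="ignore"):
        img = _REDUCERS[reducer](stack, axis=2)
    log.info("enface_projection: reducer=%s slab median thickness %.1f vox",
             reducer, float(np.median(b - t)))
    return img


def inner_outer_projections(
    volume: OCTVolume, opl: SurfaceMap, rpe: SurfaceMap, reducer: str = "mean",
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Inner projection: [inner limit, OPL); outer projection: [OPL, RPE+1)."""
    check_surface_order(opl, rpe)
    ny, nx = opl.depth.shape
    inner = enface_projection(volume, np.zeros((ny, nx)), opl, reducer=reducer, valid=valid)
    below = np.minimum(rpe.depth + 1, volume.shape_yxz[2])  # exclusive bound
    outer = enface_projection(volume, opl, below, reducer=reducer, valid=valid)
    return inner, outer
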