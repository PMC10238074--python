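"""Standard synthetic benchmarks built on the phantom.

These assemble the phantom, OCT processing and ground-truth plumbing into
the datasets used to exercise the segmentation protocol: a lesion benchmark
of small flattened volumes with exact labels, and the 5-level power
titration series (4 x 100 ms pulses at 10-50 mW) for dose-monotonicity
checks.
"""

from __future__ import annotations

import numpy as np

from retnav.core_io import LaserParams, OCTVolume
from retnav.lesion_segmentation import SegmentationDataset
from retnav.oct_processing import apply_axial_shifts, average_repeats, detect_surface, flatten
from retnav.phantom import PhantomParams, apply_lesion, generate_retina_volume, small_params


def _benchmark_params(seed: int, n_y: int = 5) -> PhantomParams:
    return small_params(shape=(n_y, 64, 128), seed=seed)


def make_lesioned_volume(
    params: PhantomParams,
    sites_energy: list[tuple[tuple[float, float], float]],
    crop_z: int = 64,
) -> tuple[OCTVolume, np.ndarray]:
    """Phantom volume with lesions applied, averaged and flattened on the
    detected RPE; the ground-truth mask is shifted identically.

    After flattening, the volume is cropped to a ``crop_z``-voxel band ending
    one outer-retina layer below the RPE, which contains the whole lesion
    response (RPE-anchored, growing inward at most to the OPL).
    """
    vol, truth = generate_retina_volume(params)
    for site, energy_mj in sites_energy:
        laser = LaserParams(power=energy_mj * 1000.0, duration=1.0, repeats=1)
        vol, truth = apply_lesion(vol, site, laser, params, truth)
    avg = average_repeats(vol)
    rpe = detect_surface(avg, "RPE")
    flat = flatten(avg, rpe)
    mask, _ = apply_axial_shifts(truth.lesion_mask.astype(np.float32), flat.shifts)
    mask = mask > 0.5
    nz = flat.volume.shape_yxz[2]
    if crop_z and crop_z < nz:
        below_rpe = max(int(round(24.0 / params.pitch_z)), 4)
        z1 = min(nz, flat.target_depth + below_rpe)
        z0 = max(0, z1 - crop_z)
        cropped = OCTVolume(
            voxels=flat.volume.voxels[:, :, z0:z1],
            pitch_x=flat.volume.pitch_x,
            pitch_y=flat.volume.pitch_y,
            pitch_z=flat.volume.pitch_z,
            meta=dict(flat.volume.meta) | {"z_crop": [int(z0), int(z1)]},
        )
        return cropped, mask[:, :, z0:z1]
    return flat.volume, mask


def make_benchmark_dataset(n_volumes: int = 12, seed: int = 0) -> SegmentationDataset:
    """Small flattened lesion volumes (5 B-scans each) with exact labels.

    Lesion site varies per volume over the field centre; per-site dose
    follows the titration protocol used for the segmentation study (4 x
    100 ms pulses at a power drawn from 10-50 mW, i.e. 4-20 mJ).
    """
    rng = np.random.default_rng(seed)
    volumes, masks = [], []
    for i in range(n_volumes):
        params = _benchmark_params(seed=seed * 1000 + i)
        fov_x = params.shape[1] * params.pitch_x
        fov_y = params.shape[0] * params.pitch_y
        site = (
            float(rng.uniform(0.35 * fov_x, 0.65 * fov_x)),
            float(rng.uniform(0.3 * fov_y, 0.7 * fov_y)),
        )
        laser = LaserParams(power=float(rng.uniform(10.0, 50.0)), **TITRATION_PULSE)
        v, m = make_lesioned_volume(params, [(site, laser.energy_mj)])
        volumes.append(v)
        masks.append(m)
    return SegmentationDataset(volumes=volumes, masks=masks)


TITRATION_POWERS_MW = (10.0, 20.0, 30.0, 40.0, 50.0)
TITRATION_PULSE = dict(duration=100.0, repeats=4)


def make_titration_series(
    seed: int = 0, n_y: int = 32
) -> tuple[list[OCTVolume], list[np.ndarray], list[float]]:
    """5-level power titration: one centred lesion per volume from 4 x 100 ms
    pulses at 10, 20, 30, 40, 50 mW (4-20 mJ)."""
    volumes, masks, energies = [], [], []
    for i, power in enumerate(TITRATION_POWERS_MW):
        params = small_params(shape=(n_y, 64, 128), seed=seed * 100 + i)
        fov_x = params.shape[1] * params.pitch_x
        fov_y = params.shape[0] * params.pitch_y
        laser = LaserParams(power=power, **TITRATION_PULSE)
        v, m = make_lesioned_volume_with_laser(params, (fov_x / 2, fov_y / 2), laser)
        volumes.append(v)
        masks.append(m)
        energies.append(laser.energy_mj)
    return volumes, masks, energies


def make_lesioned_volume_with_laser(
    params: PhantomParams, site: tuple[float, float], laser: LaserParams
) -> tuple[OCTVolume, np.ndarray]:
    return make_lesioned_volume(params, [(site, laser.energy_mj)])
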