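"""Automated OCT lesion segmentation: training protocol, inference, metrics.

A compact 2D U-Net segments laser lesions on flattened B-scan cross-sections
(the repository's phantom supplies exactly labelled volumes; a manual
annotation table can substitute for real data).  The training protocol
follows the platform's study design: an 80/20 train/validation split for
hyperparameter work, k-fold (5 or 10) cross-validation for performance
estimation, cross-entropy (+ optional soft-Dice) loss, per-epoch validation
Dice logging with best-checkpoint selection, trained up to a configured
epoch budget.  Dice overlap validates segmentations; degenerate conventions
are explicit: empty-vs-empty Dice is 1.0, empty-vs-nonempty 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from retnav._log import get_logger
from retnav._unet import Adam, UNet2D, bce_dice_loss
from retnav.core_io import OCTVolume

log = get_logger("lesion_segmentation")


# ----------------------------------------------------------------- protocol


@dataclass
class SegmentationDataset:
    """Shape-aligned (flattened volume, ground-truth mask) pairs."""

    volumes: list[OCTVolume]
    masks: list[np.ndarray]  # bool (y, x, z)

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.masks):
            raise ValueError("one mask per volume required")
        for v, m in zip(self.volumes, self.masks):
            if v.shape_yxz != tuple(np.shape(m)):
                raise ValueError("volume and mask shapes differ")

    def __len__(self) -> int:
        return len(self.volumes)

    def bscans(self, indices) -> tuple[np.ndarray, np.ndarray]:
        """Stack B-scans (z, x) and their label slices from selected volumes."""
        imgs, labs = [], []
        for i in indices:
            v = self.volumes[i].voxels  # (y, x, z)
            m = self.masks[i]
            for y in range(v.shape[0]):
                imgs.append(v[y].T)  # (z, x)
                labs.append(m[y].T)
        return np.asarray(imgs, dtype=np.float32), np.asarray(labs, dtype=bool)


@dataclass(frozen=True)
class SegmenterConfig:
    depth: int = 4
    base_channels: int = 16
    patch: int = 128
    lr: float = 3e-3
    batch: int = 8
    epochs: int = 50
    dice_weight: float = 0.5
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.patch % (2**self.depth) != 0:
            raise ValueError(
                f"patch size {self.patch} must be divisible by 2^depth = {2**self.depth}"
            )


#: desk-scale preset used for the synthetic benchmark (small phantom B-scans)
FAST_CONFIG = SegmenterConfig(depth=3, base_channels=8, patch=64, epochs=12, batch=8)


def split_dataset(n: int, train_fraction: float = 0.8, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split: round(fraction * n) train, remainder validation."""
    if not 0 < train_fraction <= 1:
        raise ValueError("train fraction must be in (0, 1]")
    n_train = int(round(train_fraction * n))
    if n_train >= n:
        n_train = min(n_train, n)
        if n - n_train == 0:
            raise ValueError("validation split is empty; lower the train fraction")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def make_folds(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """k near-equal seeded folds partitioning range(n)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


# ----------------------------------------------------------------- training


def _normalize(imgs: np.ndarray) -> np.ndarray:
    mu = imgs.mean(axis=(1, 2), keepdims=True)
    sd = imgs.std(axis=(1, 2), keepdims=True)
    return (imgs - mu) / np.maximum(sd, 1e-6)


def _pad_to_multiple(arr: np.ndarray, mult: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = arr.shape[-2:]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        pad = [(0, 0)] * (arr.ndim - 2) + [(0, ph), (0, pw)]
        arr = np.pad(arr, pad, mode="reflect")
    return arr, (h, w)


@dataclass
class TrainedSegmenter:
    net: UNet2D
    config: SegmenterConfig
    log: pd.DataFrame
    best_val_dice: float


def train_segmenter(
    dataset: SegmentationDataset,
    config: SegmenterConfig = FAST_CONFIG,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
) -> TrainedSegmenter:
    """Train B-scan-wise; log per-epoch loss and validation Dice; return the
    best-validation-Dice checkpoint (final state if no validation split)."""
    if train_idx is None and val_idx is None:
        train_idx, val_idx = split_dataset(len(dataset), 0.8, config.seed)
    train_idx = np.asarray(train_idx, dtype=int)
    imgs, labs = dataset.bscans(train_idx)
    if len(imgs) == 0:
        raise ValueError("empty training split")
    if not labs.any():
        raise ValueError("training data contains no positive (lesion) voxels")
    mult = 2**config.depth
    imgs, _ = _pad_to_multiple(_normalize(imgs), mult)
    labs, _ = _pad_to_multiple(labs, mult)

    net = UNet2D(depth=config.depth, base=config.base_channels, seed=config.seed)
    opt = Adam(net.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)

    val_vols = [dataset.volumes[i] for i in val_idx] if val_idx is not None else []
    val_masks = [dataset.masks[i] for i in val_idx] if val_idx is not None else []

    records = []
    best_state, best_dice = net.copy_state(), -1.0
    n = len(imgs)
    decay_at = max(int(np.ceil(2 * config.epochs / 3)), 1)
    for epoch in range(config.epochs):
        # step decay stabilizes the final state at the default Adam rate
        opt.lr = config.lr * (0.3 if epoch >= decay_at else 1.0)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch):
            sel = order[start : start + config.batch]
            x = imgs[sel][:, None]
            t = labs[sel]
            logits = net.forward(x)
            loss, dldz = bce_dice_loss(logits, t, config.dice_weight)
            net.backward(dldz)
            opt.step()
            losses.append(loss)
        val_dice = np.nan
        if val_vols:
            dices = [
                dice(segment(TrainedSegmenter(net, config, pd.DataFrame(), 0.0), v)[1], m)
                for v, m in zip(val_vols, val_masks)
            ]
            val_dice = float(np.mean(dices))
            if val_dice > best_dice:
                best_dice, best_state = val_dice, net.copy_state()
        records.append({"epoch": epoch, "loss": float(np.mean(losses)), "val_dice": val_dice})
        log.info("train_segmenter: epoch %d loss %.4f val_dice %s",
                 epoch, records[-1]["loss"],
                 f"{val_dice:.3f}" if np.isfinite(val_dice) else "n/a")
    if val_vols:
        net.load_state_dict(best_state)
    else:
        best_dice = float("nan")
    return TrainedSegmenter(
        net=net, config=config, log=pd.DataFrame(records), best_val_dice=best_dice
    )


def segment(
    model: TrainedSegmenter, volume: OCTVolume, batch: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Per-B-scan inference stitched into (probability volume, binary mask)."""
    if volume.has_repeats:
        raise ValueError("segment expects an averaged volume")
    vox = volume.voxels
    ny, nx, nz = vox.shape
    imgs = _normalize(vox.transpose(0, 2, 1).astype(np.float32))  # (y, z, x)
    mult = 2**model.config.depth
    padded, (h, w) = _pad_to_multiple(imgs, mult)
    probs = np.empty_like(padded)
    for start in range(0, ny, batch):
        probs[start : start + batch] = model.net.predict_proba(
            padded[start : start + batch][:, None]
        )
    probs = probs[:, :h, :w].transpose(0, 2, 1)  # back to (y, x, z)
    mask = probs > model.config.threshold
    log.info("segment: %d B-scans, %.3f%% voxels above threshold",
             ny, 100 * float(mask.mean()))
    return probs, mask


# ------------------------------------------------------------------ metrics


def save_segmenter(model: TrainedSegmenter, outdir) -> None:
    """Persist config (JSON), weights (NPZ) and the training log (CSV)."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(asdict(model.config), indent=1))
    np.savez(outdir / "weights.npz", **model.net.state_dict())
    model.log.to_csv(outdir / "training_log.csv", index=False)


def load_segmenter(indir) -> TrainedSegmenter:
    import json
    from pathlib import Path

    indir = Path(indir)
    cfg = SegmenterConfig(**json.loads((indir / "config.json").read_text()))
    net = UNet2D(depth=cfg.depth, base=cfg.base_channels, seed=cfg.seed)
    with np.load(indir / "weights.npz") as data:
        net.load_state_dict(dict(data))
    log_path = indir / "training_log.csv"
    train_log = pd.read_csv(log_path) if log_path.exists() else pd.DataFrame()
    best = float(train_log["val_dice"].max()) if "val_dice" in train_log else float("nan")
    return TrainedSegmenter(net=net, config=cfg, log=train_log, best_val_dice=best)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have identical shapes")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def cross_validate(
    dataset: SegmentationDataset, config: SegmenterConfig = FAST_CONFIG, k: int = 5
) -> dict:
    """k-fold cross-validation; every volume is evaluated exactly once."""
    folds = make_folds(len(dataset), k, config.seed)
    fold_rows, vol_rows = [], []
    for f, held in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(dataset)), held)
        try:
            model = train_segmenter(dataset, replace(config, seed=config.seed + f),
                                    train_idx=train_idx, val_idx=None)
        except ValueError as exc:
            raise ValueError(f"fold {f}: {exc}") from exc
        dices = []
        for i in held:
            _, mask = segment(model, dataset.volumes[i])
            d = dice(mask, dataset.masks[i])
            dices.append(d)
            vol_rows.append({"fold": f, "volume": int(i), "dice": d})
        fold_rows.append({"fold": f, "n_volumes": len(held), "mean_dice": float(np.mean(dices))})
    folds_df = pd.DataFrame(fold_rows)
    result = {
        "folds": folds_df,
        "per_volume": pd.DataFrame(vol_rows),
        "mean_dice": float(folds_df["mean_dice"].mean()),
        "sd_dice": float(folds_df["mean_dice"].std(ddof=1)) if k > 1 else 0.0,
    }
    log.info("cross_validate: k=%d mean Dice %.3f +/- %.3f",
             k, result["mean_dice"], result["sd_dice"])
    return result


def lesion_metrics(mask: np.ndarray, pitches: tuple[float, float, float]) -> pd.DataFrame:
    """Per-lesion table under 26-connectivity: volume, en face area, max axial
    thickness, centroid.  ``pitches`` = (pitch_y, pitch_x, pitch_z) um."""
    mask = np.asarray(mask, dtype=bool)
    py, px, pz = pitches
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    rows = []
    for i in range(1, n + 1):
        sel = labels == i
        count = int(sel.sum())
        footprint = sel.any(axis=2)
        thickness = float(sel.sum(axis=2).max() * pz)
        cy, cx, cz = ndimage.center_of_mass(sel)
        rows.append(
            {
                "id": i,
                "volume_um3": count * px * py * pz,
                "area_um2": int(footprint.sum()) * px * py,
                "thickness_um": thickness,
                "centroid_x_um": (cx + 0.5) * px,
                "centroid_y_um": (cy + 0.5) * py,
                "centroid_z_um": (cz + 0.5) * pz,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "volume_um3", "area_um2", "thickness_um",
            "centroid_x_um", "centroid_y_um", "centroid_z_um",
        ],
    )


#: en face overlap image classes
OVERLAP_NONE, OVERLAP_MANUAL, OVERLAP_AUTO, OVERLAP_BOTH = 0, 1, 2, 3


def compare_manual_auto(manual: np.ndarray, auto: np.ndarray) -> dict:
    """Overlap report: Dice, per-lesion matched pairs, en face class image
    (0 none, 1 manual-only, 2 auto-only, 3 overlap)."""
    manual = np.asarray(manual, dtype=bool)
    auto = np.asarray(auto, dtype=bool)
    if manual.shape != auto.shape:
        raise ValueError("masks must have identical shapes")
    d = dice(manual, auto)
    axes = 2 if manual.ndim == 3 else None
    m2d = manual.any(axis=axes) if axes else manual
    a2d = auto.any(axis=axes) if axes else auto
    overlap_img = np.zeros(m2d.shape, dtype=np.uint8)
    overlap_img[m2d & ~a2d] = OVERLAP_MANUAL
    overlap_img[~m2d & a2d] = OVERLAP_AUTO
    overlap_img[m2d & a2d] = OVERLAP_BOTH

    struct = np.ones((3,) * manual.ndim, dtype=bool)
    m_lab, m_n = ndimage.label(manual, structure=struct)
    a_lab, a_n = ndimage.label(auto, structure=struct)
    pairs = []
    for i in range(1, m_n + 1):
        hit = a_lab[(m_lab == i) & auto]
        if hit.size:
            j = int(np.bincount(hit).argmax())
            pairs.append((i, j, dice(m_lab == i, a_lab == j)))
    return {
        "dice": d,
        "n_manual": m_n,
        "n_auto": a_n,
        "matched_pairs": pairs,
        "overlap_image": overlap_img,
    }
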