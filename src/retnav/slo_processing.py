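"""SLO frame-stack quality control, registration/averaging, and tdTomato
photoconversion quantification.

Frames with significant respiratory motion are rejected by a robust gate on
the normalized cross-correlation score against the median frame combined
with a displacement limit; surviving frames are rigidly registered on the
red channel by sub-pixel phase correlation and averaged NaN-aware.  The
photoconversion index is the bounded ratio p = G' / (G' + R), where G' is
the green signal above the pre-lesion baseline and R the remaining red
signal -- stable where the red channel is fully converted away (R -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from retnav._log import get_logger
from retnav.core_io import GREEN, RED, SLOSequence

log = get_logger("slo_processing")


@dataclass
class MotionQC:
    kept: np.ndarray  # indices of retained frames
    rejected: np.ndarray
    scores: np.ndarray  # NCC score per frame
    displacements: np.ndarray  # |shift| px per frame


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom) if denom > 0 else 1.0


def reject_motion_frames(
    seq: SLOSequence,
    max_displacement_px: float = 10.0,
    mad_gate: float = 3.0,
) -> MotionQC:
    """Flag respiratory-motion frames against the stack median frame.

    Per-frame score = normalized cross-correlation with the median red-channel
    frame after phase-correlation alignment; a frame is rejected when its
    score falls below median(scores) - ``mad_gate`` * MAD(scores) or its
    estimated displacement exceeds ``max_displacement_px``.
    """
    n = seq.n_frames
    if n < 5:
        raise ValueError(f"need at least 5 frames for motion QC, got {n}")
    red = seq.red().astype(float)
    ref = np.median(red, axis=0)

    scores = np.empty(n)
    disps = np.empty(n)
    for t in range(n):
        shift = estimate_shift(ref, red[t], upsample=4)
        disps[t] = float(np.hypot(*shift))
        aligned = ndimage.shift(red[t], shift, order=1, mode="nearest")
        scores[t] = _ncc(aligned, ref)

    med = np.median(scores)
    mad = np.median(np.abs(scores - med))
    gate = med - mad_gate * max(mad, 1e-12)
    reject = (scores < gate) | (disps > max_displacement_px)
    kept = np.nonzero(~reject)[0]
    rejected = np.nonzero(reject)[0]
    if len(kept) == 0:
        raise ValueError("all frames rejected by motion QC")
    log.info("reject_motion_frames: kept %d / %d (score gate %.4f, max disp %.1f px)",
             len(kept), n, gate, max_displacement_px)
    return MotionQC(kept=kept, rejected=rejected, scores=scores, displacements=disps)


def estimate_shift(reference: np.ndarray, moving: np.ndarray, upsample: int = 20) -> np.ndarray:
    """Sub-pixel rigid translation (row, col) aligning ``moving`` to ``reference``.

    Cross-correlation on mean-subtracted images (the DC term otherwise biases
    the peak toward zero lag) with upsampled-DFT sub-pixel refinement.
    """
    ref = np.asarray(reference, float)
    mov = np.asarray(moving, float)
    shift, _, _ = phase_cross_correlation(
        ref - ref.mean(), mov - mov.mean(),
        upsample_factor=upsample, normalization=None,
    )
    return np.asarray(shift, dtype=float)


def register_and_average(seq: SLOSequence, kept: np.ndarray | None = None) -> np.ndarray:
    """Register kept frames on the red channel and average both channels.

    Translation is estimated once per frame by sub-pixel phase correlation
    against the first kept frame and applied identically to both channels;
    the mean is NaN-aware so border pixels lost to shifting are masked, not
    zero-diluted.  Returns a (2, rows, cols) averaged frame.
    """
    kept = np.arange(seq.n_frames) if kept is None else np.asarray(kept, dtype=int)
    if len(kept) == 0:
        raise ValueError("no frames to average")
    frames = seq.frames[kept].astype(float)
    if len(kept) == 1:
        return frames[0]
    ref = frames[0, RED]
    acc = np.zeros_like(frames[0])
    cnt = np.zeros_like(frames[0])
    for i in range(len(kept)):
        shift = estimate_shift(ref, frames[i, RED]) if i else np.zeros(2)
        for c in (RED, GREEN):
            moved = ndimage.shift(frames[i, c], shift, order=1, mode="constant", cval=np.nan)
            good = ~np.isnan(moved)
            acc[c][good] += moved[good]
            cnt[c][good] += 1
    with np.errstate(invalid="ignore"):
        out = acc / cnt
    log.info("register_and_average: %d frames", len(kept))
    return out


@dataclass
class PhotoconversionMap:
    """Per-pixel conversion index p = G' / (G' + R) in [0, 1]; NaN where the
    total signal G' + R is below the noise floor."""

    p: np.ndarray
    valid: np.ndarray
    noise_floor: float

    def lesion_mean(self, mask: np.ndarray) -> float:
        sel = np.asarray(mask, bool) & self.valid
        return float(np.nanmean(self.p[sel])) if sel.any() else float("nan")


def photoconversion_map(
    pre: np.ndarray, post: np.ndarray, noise_floor: float = 1.0
) -> PhotoconversionMap:
    """Quantify red -> green photoconversion between co-registered averaged frames.

    ``pre`` and ``post`` are (2, rows, cols) frames in the same geometry.
    G' = max(post_green - pre_green, 0); p = G' / (G' + post_red) where the
    denominator reaches ``noise_floor``, NaN sentinel elsewhere.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 3 or pre.shape[0] != 2:
        raise ValueError("pre and post must be (2, rows, cols) frames of equal shape")
    g_prime = np.clip(post[GREEN] - pre[GREEN], 0, None)
    denom = g_prime + post[RED]
    valid = denom >= noise_floor
    p = np.full(denom.shape, np.nan)
    p[valid] = g_prime[valid] / denom[valid]
    log.info("photoconversion_map: %.1f%% pixels valid, mean p %.3f",
             100 * valid.mean(), float(np.nanmean(p)) if valid.any() else float("nan"))
    return PhotoconversionMap(p=p, valid=valid, noise_floor=noise_floor)


def lesion_localize_slo(
    pmap: PhotoconversionMap,
    pitch_um: float,
    threshold: float = 0.5,
    min_area_px: int = 4,
) -> np.ndarray:
    """Centroids (x_um, y_um) of connected regions with p > threshold."""
    hot = np.where(pmap.valid, pmap.p > threshold, False)
    labels, n = ndimage.label(hot)
    cents = []
    for i in range(1, n + 1):
        sel = labels == i
        if sel.sum() < min_area_px:
            continue
        r, c = np.nonzero(sel)
        w = pmap.p[sel]
        cents.append(
            (
                (np.average(c, weights=w) + 0.5) * pitch_um,
                (np.average(r, weights=w) + 0.5) * pitch_um,
            )
        )
    log.info("lesion_localize_slo: %d lesion(s) above p > %.2f", len(cents), threshold)
    return np.asarray(cents).reshape(-1, 2)
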