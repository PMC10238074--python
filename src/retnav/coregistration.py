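"""OCT-SLO co-registration via grid landmarks and a 2D polynomial unwarp.

The same grid target is imaged in both modalities; blob landmarks are
detected with sub-pixel intensity-weighted centroiding, matched by mutual
nearest neighbours after a coarse similarity pre-alignment on the grid
corners, and a bivariate polynomial unwarp (stored SLO pixel -> OCT en face
micrometres; OCT is the canonical frame because lesion plans live there) is
least-squares fitted.  Resampling uses inverse mapping with bilinear
interpolation and a NaN sentinel outside the mapped domain so downstream
averaging can mask correctly.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.transform import estimate_transform

from retnav._log import get_logger
from retnav._poly import Poly2DMap, fit_poly2d
from retnav.core_io import read_json, write_json

log = get_logger("coregistration")


class UnwarpTransform(Poly2DMap):
    """Polynomial map from SLO pixel (x=col, y=row) to OCT en face um."""

    def save(self, path) -> None:
        write_json(self.to_dict() | {"kind": "unwarp_transform"}, path)

    @classmethod
    def load(cls, path) -> "UnwarpTransform":
        return cls.from_dict(read_json(path))


def detect_grid_landmarks(
    image: np.ndarray,
    expected_spacing: float,
    min_prominence: float = 0.2,
    min_landmarks: int = 6,
) -> np.ndarray:
    """Sub-pixel (row, col) centroids of grid nodes, sorted row-major.

    Local maxima at least half a spacing apart and ``min_prominence`` of the
    dynamic range above the background are refined by intensity-weighted
    centroiding in a window of one spacing after local background
    subtraction.
    """
    image = np.asarray(image, dtype=float)
    smoothed = ndimage.gaussian_filter(image, sigma=max(expected_spacing / 10.0, 0.8))
    bg = float(np.median(smoothed))  # prominence gate on the searched image
    dyn = float(smoothed.max()) - bg
    if dyn <= 0:
        raise ValueError("image has no landmarks above background")
    peaks = peak_local_max(
        smoothed,
        min_distance=max(int(round(expected_spacing / 2)), 1),
        threshold_abs=bg + min_prominence * dyn,
        exclude_border=False,
    )
    if len(peaks) < min_landmarks:
        raise ValueError(f"only {len(peaks)} landmark(s) detected, need >= {min_landmarks}")

    half = max(int(round(expected_spacing / 2)), 2)
    cents = []
    for r0, c0 in peaks:
        r1, r2 = max(r0 - half, 0), min(r0 + half + 1, image.shape[0])
        c1, c2 = max(c0 - half, 0), min(c0 + half + 1, image.shape[1])
        win = image[r1:r2, c1:c2] - image[r1:r2, c1:c2].min()
        win = np.clip(win - 0.2 * win.max(), 0, None)  # suppress background noise bias
        tot = win.sum()
        if tot <= 0:
            continue
        rr = np.arange(r1, r2)[:, None]
        cc = np.arange(c1, c2)[None, :]
        cents.append(((rr * win).sum() / tot, (cc * win).sum() / tot))
    pts = np.asarray(cents)
    order = np.lexsort((pts[:, 1], np.round(pts[:, 0] / (expected_spacing / 2.0))))
    pts = pts[order]
    log.info("detect_grid_landmarks: %d landmarks (spacing %.1f px)", len(pts), expected_spacing)
    return pts


def _extreme_corners(pts: np.ndarray) -> np.ndarray:
    """Four corner points: extremes of (r + c) and (r - c)."""
    s, d = pts.sum(axis=1), pts[:, 0] - pts[:, 1]
    idx = [int(np.argmin(s)), int(np.argmax(d)), int(np.argmax(s)), int(np.argmin(d))]
    return pts[idx]


def match_landmarks(
    points_a: np.ndarray, points_b: np.ndarray, max_residual_frac: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Mutual-nearest-neighbour correspondences after coarse corner pre-alignment.

    Returns (idx_a, idx_b) index arrays; unmatched points are dropped with a
    logged count.  ``max_residual_frac`` rejects pairs farther apart (after
    pre-alignment) than that fraction of the median nearest-neighbour
    spacing of set B.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if len(a) < 4 or len(b) < 4:
        raise ValueError("need at least 4 points per set to match")
    tform = estimate_transform("similarity", _extreme_corners(a)[:, ::-1], _extreme_corners(b)[:, ::-1])
    a_in_b = tform(a[:, ::-1])[:, ::-1]

    tree_b = cKDTree(b)
    tree_a = cKDTree(a_in_b)
    d_ab, nn_ab = tree_b.query(a_in_b)
    _, nn_ba = tree_a.query(b)
    mutual = nn_ba[nn_ab] == np.arange(len(a))

    spacing = np.median(tree_b.query(b, k=2)[0][:, 1])
    ok = mutual & (d_ab <= max_residual_frac * spacing)
    idx_a = np.nonzero(ok)[0]
    idx_b = nn_ab[idx_a]
    dropped = len(a) - len(idx_a)
    if dropped:
        log.info("match_landmarks: dropped %d unmatched point(s)", dropped)
    return idx_a, idx_b


def fit_unwarp(
    src_points: np.ndarray, dst_points: np.ndarray, degree: int = 3
) -> UnwarpTransform:
    """Fit the SLO (x, y) px -> OCT (x, y) um polynomial from correspondences."""
    base = fit_poly2d(np.asarray(src_points, float), np.asarray(dst_points, float), degree)
    t = UnwarpTransform(
        degree=base.degree,
        coeffs_x=base.coeffs_x,
        coeffs_y=base.coeffs_y,
        rms_residual=base.rms_residual,
        domain=base.domain,
        meta={"source": "slo_px", "target": "oct_um"},
    )
    log.info("fit_unwarp: degree=%d n=%d rms=%.4g", degree, len(src_points), t.rms_residual)
    return t


def apply_unwarp(
    image: np.ndarray,
    transform: Poly2DMap,
    out_shape: tuple[int, int],
    out_pitch: float = 1.0,
    in_pitch: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Resample ``image`` onto the output grid by inverse mapping.

    ``transform`` maps *output* (x, y) coordinates (pixel index times
    ``out_pitch``) to *input* coordinates (pixel index times ``in_pitch``);
    bilinear interpolation, NaN sentinel outside the input, and the covered
    fraction of output pixels are returned.
    """
    nr, nc = out_shape
    xx, yy = np.meshgrid(np.arange(nc) * out_pitch, np.arange(nr) * out_pitch, indexing="xy")
    src = transform(np.stack([xx.ravel(), yy.ravel()], axis=-1)) / in_pitch
    cols = src[:, 0].reshape(nr, nc)
    rows = src[:, 1].reshape(nr, nc)
    out = ndimage.map_coordinates(
        np.asarray(image, dtype=float), [rows, cols], order=1, mode="constant", cval=np.nan
    )
    coverage = float(np.mean(~np.isnan(out)))
    log.info("apply_unwarp: out_shape=%s coverage=%.3f", out_shape, coverage)
    return out, coverage


def coregister_grid(
    oct_image: np.ndarray,
    slo_image: np.ndarray,
    oct_pitch: float,
    oct_spacing_px: float,
    slo_spacing_px: float,
    degree: int = 3,
    min_prominence: float = 0.2,
) -> tuple[UnwarpTransform, dict]:
    """End-to-end grid pipeline: detect -> match -> fit SLO px -> OCT um."""
    pts_oct = detect_grid_landmarks(oct_image, oct_spacing_px, min_prominence)
    pts_slo = detect_grid_landmarks(slo_image, slo_spacing_px, min_prominence)
    idx_slo, idx_oct = match_landmarks(pts_slo, pts_oct)
    slo_xy = pts_slo[idx_slo][:, ::-1]  # (row, col) -> (x, y)
    oct_xy_um = (pts_oct[idx_oct][:, ::-1] + 0.5) * oct_pitch
    t = fit_unwarp(slo_xy, oct_xy_um, degree=degree)
    info = {
        "n_oct": len(pts_oct),
        "n_slo": len(pts_slo),
        "n_matched": len(idx_oct),
        "rms_um": t.rms_residual,
    }
    return t, info
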