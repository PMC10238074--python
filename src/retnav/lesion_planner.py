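"""Lesion plan generation and compilation to a calibrated firing schedule.

Plans live in en face OCT coordinates (micrometres).  Patch plans raster a
row-major grid with centre pitch (1 - overlap) x spot diameter -- "50% spot
overlap" therefore means adjacent spot centres are half a diameter apart --
anchored at the treatment-mask bounding box offset by one spot radius.  A
site is kept iff its full spot disc lies inside the treatment mask and
intersects no exclusion pixel (conservative keep rule; ``allow_partial``
relaxes the inside requirement).  Masks are pixel grids with pixel centres
at (index + 0.5) x pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from retnav._log import get_logger
from retnav.calibration import CalibrationModel, invert_map
from retnav.core_io import LaserParams

log = get_logger("lesion_planner")

DEFAULT_SPOT_UM = 50.0  # retinal spot diameter; config-exposed


@dataclass
class LesionPlan:
    sites: list[tuple[tuple[float, float], LaserParams]]  # ((x_um, y_um), laser)
    spot_diameter: float = DEFAULT_SPOT_UM
    overlap: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.spot_diameter <= 0:
            raise ValueError("spot diameter must be > 0")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def positions(self) -> np.ndarray:
        return np.asarray([p for p, _ in self.sites], dtype=float).reshape(-1, 2)

    def to_dict(self) -> dict:
        return {
            "spot_diameter_um": self.spot_diameter,
            "overlap": self.overlap,
            "provenance": self.provenance,
            "sites": [
                {
                    "x_um": p[0],
                    "y_um": p[1],
                    "power_mw": l.power,
                    "duration_ms": l.duration,
                    "repeats": l.repeats,
                    "interval_ms": l.interval,
                }
                for p, l in self.sites
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LesionPlan":
        sites = [
            (
                (s["x_um"], s["y_um"]),
                LaserParams(s["power_mw"], s["duration_ms"], int(s["repeats"]), s["interval_ms"]),
            )
            for s in d["sites"]
        ]
        return cls(
            sites=sites,
            spot_diameter=d["spot_diameter_um"],
            overlap=d["overlap"],
            provenance=d.get("provenance", {}),
        )


def _mask_value_at(mask: np.ndarray, x_um: float, y_um: float, pitch: float) -> bool:
    r = int(y_um / pitch)
    c = int(x_um / pitch)
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        return False
    return bool(mask[r, c])


def _disc_pixels(
    mask_shape: tuple[int, int], x_um: float, y_um: float, radius_um: float, pitch: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of pixels whose centres lie within ``radius_um`` of the site."""
    nr, nc = mask_shape
    r_lo = max(int(np.floor((y_um - radius_um) / pitch - 0.5)), 0)
    r_hi = min(int(np.ceil((y_um + radius_um) / pitch - 0.5)) + 1, nr)
    c_lo = max(int(np.floor((x_um - radius_um) / pitch - 0.5)), 0)
    c_hi = min(int(np.ceil((x_um + radius_um) / pitch - 0.5)) + 1, nc)
    if r_hi <= r_lo or c_hi <= c_lo:
        return np.empty(0, int), np.empty(0, int)
    rr = np.arange(r_lo, r_hi)
    cc = np.arange(c_lo, c_hi)
    cy = (rr + 0.5) * pitch
    cx = (cc + 0.5) * pitch
    inside = (cy[:, None] - y_um) ** 2 + (cx[None, :] - x_um) ** 2 <= radius_um**2
    ri, ci = np.nonzero(inside)
    return rr[ri], cc[ci]


def spot_fits(
    treatment: np.ndarray,
    exclusion: np.ndarray | None,
    x_um: float,
    y_um: float,
    radius_um: float,
    pitch: float,
    allow_partial: bool = False,
) -> bool:
    """Keep rule on the pixel grid: every pixel whose centre lies within the
    spot radius must exist and be treatment (unless ``allow_partial``, then
    only the centre pixel must be treatment), and none may be exclusion."""
    nr, nc = treatment.shape
    r_lo = int(np.floor((y_um - radius_um) / pitch - 0.5))
    r_hi = int(np.ceil((y_um + radius_um) / pitch - 0.5)) + 1
    c_lo = int(np.floor((x_um - radius_um) / pitch - 0.5))
    c_hi = int(np.ceil((x_um + radius_um) / pitch - 0.5)) + 1
    rr = np.arange(r_lo, r_hi)
    cc = np.arange(c_lo, c_hi)
    cy = (rr + 0.5) * pitch
    cx = (cc + 0.5) * pitch
    inside = (cy[:, None] - y_um) ** 2 + (cx[None, :] - x_um) ** 2 <= radius_um**2
    ri, ci = np.nonzero(inside)
    ri, ci = rr[ri], cc[ci]
    if len(ri) == 0:
        return False
    out_of_image = (ri < 0) | (ri >= nr) | (ci < 0) | (ci >= nc)
    ok_r, ok_c = ri[~out_of_image], ci[~out_of_image]
    if exclusion is not None and len(ok_r) and exclusion[ok_r, ok_c].any():
        return False
    if allow_partial:
        return _mask_value_at(treatment, x_um, y_um, pitch)
    if out_of_image.any():
        return False
    return bool(treatment[ok_r, ok_c].all())


def plan_focal(
    sites: list[tuple[float, float]],
    laser: LaserParams,
    treatment_mask: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
    pitch: float = 1.0,
    spot_diameter: float = DEFAULT_SPOT_UM,
) -> LesionPlan:
    """Plan individual focal lesions at explicit sites, validated against masks."""
    for x, y in sites:
        if exclusion_mask is not None and _mask_value_at(exclusion_mask, x, y, pitch):
            raise ValueError(f"site ({x:.1f}, {y:.1f}) um lies inside the exclusion mask")
        if treatment_mask is not None and not _mask_value_at(treatment_mask, x, y, pitch):
            raise ValueError(f"site ({x:.1f}, {y:.1f}) um lies outside the treatment mask")
    plan = LesionPlan(
        sites=[((float(x), float(y)), laser) for x, y in sites],
        spot_diameter=spot_diameter,
        overlap=0.0,
        provenance={"kind": "focal"},
    )
    log.info("plan_focal: %d site(s)", plan.n_sites)
    return plan


def quadrant_layout(
    centre: tuple[float, float],
    eccentricities_um: tuple[float, ...] = (150.0, 250.0, 350.0),
) -> list[tuple[float, float]]:
    """Preset focal layout: lesions aligned nasal-temporal and inferior-superior,
    3 per quadrant at the given eccentricities (12 sites by default)."""
    cx, cy = centre
    sites = []
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):  # temporal, nasal, superior, inferior
        for e in eccentricities_um:
            sites.append((cx + dx * e, cy + dy * e))
    return sites


def plan_patch(
    treatment_mask: np.ndarray,
    exclusion_mask: np.ndarray | None,
    laser: LaserParams,
    spot_diameter: float = DEFAULT_SPOT_UM,
    overlap: float = 0.5,
    pitch: float = 1.0,
    allow_partial: bool = False,
    serpentine: bool = False,
) -> LesionPlan:
    """Raster-fill a treatment area with spots at (1 - overlap) x diameter pitch.

    Row-major ordering (serpentine optional); the grid is anchored at the
    treatment-mask bounding box corner offset by one spot radius, so plans
    are translation-covariant with the mask.
    """
    treatment_mask = np.asarray(treatment_mask, dtype=bool)
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != treatment_mask.shape:
            raise ValueError("treatment and exclusion masks must share geometry")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = (1 - overlap) * spot_diameter
    radius = spot_diameter / 2.0

    rows, cols = np.nonzero(treatment_mask)
    sites: list[tuple[tuple[float, float], LaserParams]] = []
    if len(rows):
        y0, y1 = (rows.min() + 0.5) * pitch, (rows.max() + 0.5) * pitch
        x0, x1 = (cols.min() + 0.5) * pitch, (cols.max() + 0.5) * pitch
        ys = np.arange(y0 + radius, y1 - radius + 1e-9, step)
        xs = np.arange(x0 + radius, x1 - radius + 1e-9, step)
        for j, y in enumerate(ys):
            xs_row = xs if (not serpentine or j % 2 == 0) else xs[::-1]
            for x in xs_row:
                if spot_fits(treatment_mask, exclusion_mask, x, y, radius, pitch, allow_partial):
                    sites.append(((float(x), float(y)), laser))
    if not sites:
        log.warning("plan_patch: no site fits (spot %.0f um may exceed the mask)", spot_diameter)
    plan = LesionPlan(
        sites=sites,
        spot_diameter=spot_diameter,
        overlap=overlap,
        provenance={"kind": "patch", "pitch_um": step, "serpentine": serpentine},
    )
    log.info("plan_patch: %d site(s), pitch %.1f um, overlap %.0f%%",
             plan.n_sites, step, 100 * overlap)
    return plan


def compile_schedule(
    plan: LesionPlan, model: CalibrationModel, settle_ms: float = 1.0
) -> pd.DataFrame:
    """Compile a plan into a timed, calibrated firing schedule.

    One row per pulse: site index, galvo voltages from Newton inversion of
    the calibration, pulse index, onset (ms), duration, power.  Within a
    site consecutive onsets are separated by duration + interval; sites are
    separated by ``settle_ms``.
    """
    rows = []
    t = 0.0
    failures = []
    for i, (pos, laser) in enumerate(plan.sites):
        try:
            v = invert_map(model, np.asarray(pos, dtype=float))
        except Exception as exc:
            failures.append((i, pos, str(exc)))
            continue
        for k in range(laser.repeats):
            rows.append(
                {
                    "site": i,
                    "vx": float(v[0]),
                    "vy": float(v[1]),
                    "pulse": k,
                    "onset_ms": t,
                    "duration_ms": laser.duration,
                    "power_mw": laser.power,
                }
            )
            t += laser.duration + (laser.interval if k < laser.repeats - 1 else 0.0)
        t += settle_ms
    if failures:
        detail = "; ".join(f"site {i} at {p}" for i, p, _ in failures)
        raise ValueError(f"{len(failures)} site(s) outside the calibration image: {detail}")
    sched = pd.DataFrame(
        rows, columns=["site", "vx", "vy", "pulse", "onset_ms", "duration_ms", "power_mw"]
    )
    log.info("compile_schedule: %d pulse(s) over %d site(s), total on-time %.0f ms",
             len(sched), plan.n_sites, float(sched["duration_ms"].sum()) if len(sched) else 0.0)
    return sched


def coverage_report(
    plan: LesionPlan, treatment_mask: np.ndarray, pitch: float = 1.0
) -> tuple[float, np.ndarray]:
    """Fraction of treatment pixels within one spot radius of >= 1 site, plus
    the gap map (treatment pixels left uncovered)."""
    treatment_mask = np.asarray(treatment_mask, dtype=bool)
    covered = np.zeros_like(treatment_mask)
    radius = plan.spot_diameter / 2.0
    for (x, y), _ in plan.sites:
        ri, ci = _disc_pixels(treatment_mask.shape, x, y, radius, pitch)
        covered[ri, ci] = True
    n_treat = int(treatment_mask.sum())
    frac = float((covered & treatment_mask).sum() / n_treat) if n_treat else 0.0
    gap = treatment_mask & ~covered
    log.info("coverage_report: %.1f%% of treatment area covered", 100 * frac)
    return frac, gap
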