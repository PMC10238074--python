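"""Galvanometer voltage-to-retinal-position calibration.

Laser pulses delivered to a grid target at several rotational orientations
leave lesions whose positions, measured on OCT, are paired with the
commanded scan voltages.  A full tensor-product bivariate polynomial (default
degree 3) is least-squares fitted per output axis; targeting inverts the map
with damped Newton iteration seeded from a dense forward-sampled grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from retnav._log import get_logger
from retnav._poly import FitError, InversionError, Poly2DMap, fit_poly2d
from retnav.core_io import read_json, write_json

__all__ = [
    "CalibrationModel",
    "fit_voltage_map",
    "map_voltage",
    "invert_map",
    "targeting_report",
    "FitError",
    "InversionError",
]

log = get_logger("calibration")

DEFAULT_DEGREE = 3


class CalibrationModel(Poly2DMap):
    """2D polynomial voltage (V) -> retinal position (um) map.

    ``coeffs_x[i, j]`` multiplies ``vx^i * vy^j``; ``domain`` is the voltage
    bounding box of the fitted pairs.
    """

    def save(self, path) -> None:
        write_json(self.to_dict() | {"kind": "calibration_model"}, path)

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        return cls.from_dict(read_json(path))


def fit_voltage_map(
    voltages: np.ndarray, positions: np.ndarray, degree: int = DEFAULT_DEGREE
) -> CalibrationModel:
    """Least-squares fit of commanded voltages (n, 2) to observed positions (n, 2) um."""
    base = fit_poly2d(np.asarray(voltages, float), np.asarray(positions, float), degree)
    model = CalibrationModel(
        degree=base.degree,
        coeffs_x=base.coeffs_x,
        coeffs_y=base.coeffs_y,
        rms_residual=base.rms_residual,
        domain=base.domain,
    )
    log.info("fit_voltage_map: degree=%d n=%d rms=%.4g um", degree, len(voltages),
             model.rms_residual)
    return model


def fit_from_landmarks(df: pd.DataFrame, degree: int = DEFAULT_DEGREE) -> CalibrationModel:
    """Fit from a landmark table with columns vx, vy, x_um, y_um (any rotations pooled)."""
    return fit_voltage_map(df[["vx", "vy"]].to_numpy(), df[["x_um", "y_um"]].to_numpy(), degree)


def map_voltage(model: CalibrationModel, voltage) -> np.ndarray:
    """Forward-evaluate the calibration at one voltage pair or an (n, 2) array."""
    voltage = np.asarray(voltage, dtype=float)
    outside = ~model.in_domain(voltage)
    if np.any(outside):
        log.warning("map_voltage: %d voltage(s) outside fitted domain %s",
                    int(np.sum(outside)), model.domain)
    return model(voltage)


def invert_map(
    model: CalibrationModel, target, tol: float = 0.1, max_iter: int = 100
) -> np.ndarray:
    """Voltage v with |map_voltage(v) - target| <= tol um (damped Newton)."""
    return model.invert(np.asarray(target, dtype=float), tol=tol, max_iter=max_iter)


def targeting_report(model: CalibrationModel, voltages, positions) -> dict:
    """Residual statistics of the model on held-out (voltage, position) pairs."""
    voltages = np.atleast_2d(np.asarray(voltages, dtype=float))
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(voltages) == 0:
        raise ValueError("held-out pair set is empty")
    if voltages.shape != positions.shape:
        raise ValueError("voltages and positions must have matching shapes")
    pred = model(voltages)
    err = np.linalg.norm(pred - positions, axis=-1)
    table = pd.DataFrame(
        {
            "vx": voltages[:, 0],
            "vy": voltages[:, 1],
            "x_um": positions[:, 0],
            "y_um": positions[:, 1],
            "x_pred_um": pred[:, 0],
            "y_pred_um": pred[:, 1],
            "residual_um": err,
        }
    )
    report = {
        "rms_um": float(np.sqrt(np.mean(err**2))),
        "max_um": float(err.max()),
        "n": int(len(err)),
        "table": table,
    }
    log.info("targeting_report: n=%d rms=%.4g um max=%.4g um",
             report["n"], report["rms_um"], report["max_um"])
    return report
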