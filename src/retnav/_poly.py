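"""Bivariate tensor-product polynomial maps R^2 -> R^2.

Shared machinery for the voltage->position calibration and the SLO->OCT
unwarp transform: least-squares fitting on a conditioning-scaled basis with
coefficients reported in the natural monomial basis, forward evaluation,
analytic Jacobians, and damped-Newton inversion seeded from a dense forward
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

from retnav._log import get_logger

log = get_logger("poly")


class FitError(ValueError):
    """Raised when a polynomial fit is underdetermined or rank deficient."""


class InversionError(RuntimeError):
    """Raised when Newton inversion fails or the target is outside the map image."""


def _shift_matrix(degree: int, a: float, b: float) -> np.ndarray:
    """Matrix M with M[k, j] = coefficient of v^j in (a*v + b)^k."""
    m = np.zeros((degree + 1, degree + 1))
    for k in range(degree + 1):
        pk = npoly.polypow([b, a], k) if k > 0 else np.array([1.0])
        m[k, : len(pk)] = pk
    return m


@dataclass
class Poly2DMap:
    """Polynomial map (u, v) -> (x, y) with full (degree+1)^2 tensor terms.

    Coefficient grids are in the natural monomial basis:
    x = sum_ij coeffs_x[i, j] * u^i * v^j (and likewise y).
    """

    degree: int
    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    rms_residual: float
    domain: tuple[float, float, float, float]  # (u_min, u_max, v_min, v_max)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs_x = np.asarray(self.coeffs_x, dtype=float)
        self.coeffs_y = np.asarray(self.coeffs_y, dtype=float)
        n = self.degree + 1
        if self.coeffs_x.shape != (n, n) or self.coeffs_y.shape != (n, n):
            raise ValueError(
                f"coefficient grids must be {(n, n)}, got "
                f"{self.coeffs_x.shape} / {self.coeffs_y.shape}"
            )
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")
        u0, u1, v0, v1 = self.domain
        if not (u1 > u0 and v1 > v0):
            raise ValueError("degenerate domain")

    # ------------------------------------------------------------------ eval
    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        u, v = pts[..., 0], pts[..., 1]
        x = npoly.polyval2d(u, v, self.coeffs_x)
        y = npoly.polyval2d(u, v, self.coeffs_y)
        return np.stack([x, y], axis=-1)

    def in_domain(self, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        u0, u1, v0, v1 = self.domain
        mu = margin * (u1 - u0)
        mv = margin * (v1 - v0)
        return (
            (pts[..., 0] >= u0 - mu)
            & (pts[..., 0] <= u1 + mu)
            & (pts[..., 1] >= v0 - mv)
            & (pts[..., 1] <= v1 + mv)
        )

    def jacobian(self, pts: np.ndarray) -> np.ndarray:
        """Analytic Jacobian d(x,y)/d(u,v), shape (..., 2, 2)."""
        pts = np.asarray(pts, dtype=float)
        u, v = pts[..., 0], pts[..., 1]
        dxu = npoly.polyval2d(u, v, npoly.polyder(self.coeffs_x, axis=0))
        dxv = npoly.polyval2d(u, v, npoly.polyder(self.coeffs_x, axis=1))
        dyu = npoly.polyval2d(u, v, npoly.polyder(self.coeffs_y, axis=0))
        dyv = npoly.polyval2d(u, v, npoly.polyder(self.coeffs_y, axis=1))
        jac = np.empty(u.shape + (2, 2))
        jac[..., 0, 0], jac[..., 0, 1] = dxu, dxv
        jac[..., 1, 0], jac[..., 1, 1] = dyu, dyv
        return jac

    # -------------------------------------------------------------- inversion
    def _seed_grid(self, n: int = 50) -> tuple[np.ndarray, np.ndarray]:
        u0, u1, v0, v1 = self.domain
        uu, vv = np.meshgrid(np.linspace(u0, u1, n), np.linspace(v0, v1, n), indexing="ij")
        seeds = np.stack([uu.ravel(), vv.ravel()], axis=-1)
        return seeds, self(seeds)

    def invert(
        self,
        target: np.ndarray,
        tol: float = 0.1,
        max_iter: int = 100,
        domain_margin: float = 0.25,
    ) -> np.ndarray:
        """Solve map(p) = target by damped Newton from a dense-grid seed.

        Raises InversionError if the target lies outside the image of the
        domain (detected as divergence outside the extended domain) or the
        residual fails to reach ``tol`` within ``max_iter`` iterations.
        """
        target = np.asarray(target, dtype=float)
        single = target.ndim == 1
        tgt = np.atleast_2d(target)
        seeds, fwd = self._seed_grid()
        d2 = ((fwd[None, :, :] - tgt[:, None, :]) ** 2).sum(axis=-1)
        p = seeds[np.argmin(d2, axis=1)].copy()

        res = self(p) - tgt
        rnorm = np.linalg.norm(res, axis=-1)
        for _ in range(max_iter):
            if np.all(rnorm <= tol):
                break
            jac = self.jacobian(p)
            try:
                step = np.linalg.solve(jac, res[..., None])[..., 0]
            except np.linalg.LinAlgError as exc:  # singular Jacobian
                raise InversionError(f"singular Jacobian during inversion: {exc}") from exc
            lam = np.ones(len(p))
            for _ in range(20):  # damping: halve until residual decreases
                cand = p - lam[:, None] * step
                cres = self(cand) - tgt
                cnorm = np.linalg.norm(cres, axis=-1)
                worse = (cnorm > rnorm) & (rnorm > tol)
                if not np.any(worse):
                    break
                lam[worse] *= 0.5
            p, res, rnorm = cand, cres, cnorm

        if np.any(rnorm > tol):
            raise InversionError(
                f"inversion did not converge: max residual {float(rnorm.max()):.4g} "
                f"after {max_iter} iterations (tol {tol})"
            )
        inside = self.in_domain(p, margin=domain_margin)
        if not np.all(inside):
            raise InversionError(
                f"{int((~inside).sum())} target(s) map outside the calibrated domain image"
            )
        return p[0] if single else p

    # ------------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coeffs_x": self.coeffs_x.tolist(),
            "coeffs_y": self.coeffs_y.tolist(),
            "rms_residual": self.rms_residual,
            "domain": list(self.domain),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Poly2DMap":
        return cls(
            degree=int(d["degree"]),
            coeffs_x=np.asarray(d["coeffs_x"], dtype=float),
            coeffs_y=np.asarray(d["coeffs_y"], dtype=float),
            rms_residual=float(d["rms_residual"]),
            domain=tuple(d["domain"]),
            meta=d.get("meta", {}),
        )


def fit_poly2d(src: np.ndarray, dst: np.ndarray, degree: int) -> Poly2DMap:
    """Least-squares tensor-product polynomial fit src -> dst.

    The design matrix is built on coordinates affinely scaled to [-1, 1]^2
    for conditioning; the returned coefficients are converted back to the
    natural monomial basis of the unscaled source coordinates.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.ndim != 2 or src.shape[1] != 2 or src.shape != dst.shape:
        raise ValueError("src and dst must both be (n, 2) arrays")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    n_coef = (degree + 1) ** 2
    n = len(src)
    if n < n_coef:
        raise FitError(
            f"underdetermined fit: degree {degree} needs at least {n_coef} "
            f"point pairs per axis, got {n}"
        )

    u0, u1 = src[:, 0].min(), src[:, 0].max()
    v0, v1 = src[:, 1].min(), src[:, 1].max()
    if u1 <= u0 or v1 <= v0:
        raise FitError("source points are collinear (degenerate bounding box)")
    mu, hu = (u0 + u1) / 2, (u1 - u0) / 2
    mv, hv = (v0 + v1) / 2, (v1 - v0) / 2
    us = (src[:, 0] - mu) / hu
    vs = (src[:, 1] - mv) / hv

    design = npoly.polyvander2d(us, vs, [degree, degree])  # (n, (d+1)^2)
    rank = np.linalg.matrix_rank(design)
    if rank < n_coef:
        raise FitError(
            f"rank-deficient design matrix (rank {rank} < {n_coef}): "
            "grid points do not constrain all polynomial terms"
        )
    sol, _, _, _ = np.linalg.lstsq(design, dst, rcond=None)
    cx_s = sol[:, 0].reshape(degree + 1, degree + 1)
    cy_s = sol[:, 1].reshape(degree + 1, degree + 1)

    # convert from scaled basis ((u-mu)/hu, (v-mv)/hv) to natural monomials
    m_u = _shift_matrix(degree, 1.0 / hu, -mu / hu)
    m_v = _shift_matrix(degree, 1.0 / hv, -mv / hv)
    cx = m_u.T @ cx_s @ m_v
    cy = m_u.T @ cy_s @ m_v

    resid = design @ sol - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    model = Poly2DMap(
        degree=degree,
        coeffs_x=cx,
        coeffs_y=cy,
        rms_residual=rms,
        domain=(float(u0), float(u1), float(v0), float(v1)),
    )
    log.info("fit_poly2d: degree=%d n=%d rms=%.4g", degree, n, rms)
    return model
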