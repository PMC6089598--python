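"""Low-level polygon and 2x2 tensor utilities.

All polygon routines expect an (n, 2) float array of vertices in µm,
ordered around the boundary (either winding); closing vertex optional.
Tensor routines operate on real 2x2 matrices; SPD = symmetric positive
definite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "polygon_area",
    "polygon_centroid",
    "polygon_second_moments",
    "shape_matrix",
    "sym",
    "spd_sqrt",
    "spd_log",
    "spd_transport",
    "polar_rotation",
    "real_logm",
    "interior_angle",
    "fit_affine",
]


def _closed(poly: np.ndarray) -> np.ndarray:
    poly = np.asarray(poly, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (n>=3, 2) array")
    if not np.allclose(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[0]])
    return poly


def polygon_area(poly: np.ndarray) -> float:
    """Unsigned shoelace area (µm²)."""
    p = _closed(poly)
    x, y = p[:-1, 0], p[:-1, 1]
    xn, yn = p[1:, 0], p[1:, 1]
    return abs(np.sum(x * yn - xn * y)) / 2.0


def _signed_terms(poly: np.ndarray):
    p = _closed(poly)
    x, y = p[:-1, 0], p[:-1, 1]
    xn, yn = p[1:, 0], p[1:, 1]
    a = x * yn - xn * y
    return x, y, xn, yn, a


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area centroid of the polygon (µm)."""
    x, y, xn, yn, a = _signed_terms(poly)
    area2 = np.sum(a)
    if area2 == 0:
        raise ValueError("degenerate polygon has zero area")
    cx = np.sum((x + xn) * a) / (3.0 * area2)
    cy = np.sum((y + yn) * a) / (3.0 * area2)
    return np.array([cx, cy])


def polygon_second_moments(poly: np.ndarray) -> np.ndarray:
    """Area-normalised second central moment matrix M (µm²).

    M is the covariance of a uniform density over the polygon interior;
    for an ellipse with semi-axes (a, b), eigenvalues are (a²/4, b²/4).
    """
    x, y, xn, yn, a = _signed_terms(poly)
    area2 = np.sum(a)
    if area2 == 0:
        raise ValueError("degenerate polygon has zero area")
    cx = np.sum((x + xn) * a) / (3.0 * area2)
    cy = np.sum((y + yn) * a) / (3.0 * area2)
    exx = np.sum(a * (x * x + x * xn + xn * xn)) / (6.0 * area2)
    eyy = np.sum(a * (y * y + y * yn + yn * yn)) / (6.0 * area2)
    exy = np.sum(a * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)) / (12.0 * area2)
    m = np.array([[exx - cx * cx, exy - cx * cy], [exy - cx * cy, eyy - cy * cy]])
    return m


def shape_matrix(poly: np.ndarray) -> np.ndarray:
    """Best-fit-ellipse shape matrix Q = 2·M^(1/2) (µm).

    Eigenvalues of Q are the semi-axis lengths of the moment-equivalent
    ellipse, eigenvectors its axes.
    """
    return 2.0 * spd_sqrt(polygon_second_moments(poly))


def sym(a: np.ndarray) -> np.ndarray:
    return (a + a.T) / 2.0


def _eigh_fn(m: np.ndarray, fn) -> np.ndarray:
    w, v = np.linalg.eigh(sym(m))
    return (v * fn(w)) @ v.T


def spd_sqrt(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(sym(m))
    if np.any(w < -1e-12):
        raise ValueError("matrix is not positive semi-definite")
    return (v * np.sqrt(np.clip(w, 0, None))) @ v.T


def spd_log(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(sym(m))
    if np.any(w <= 0):
        raise ValueError("matrix is not positive definite")
    return (v * np.log(w)) @ v.T


def spd_transport(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Unique SPD map F with F·M1·F = M2.

    This is the rotation-free (symmetric) linear map carrying the ellipse
    of second-moment matrix M1 onto that of M2.
    """
    r = spd_sqrt(m1)
    rinv = np.linalg.inv(r)
    inner = spd_sqrt(r @ m2 @ r)
    return rinv @ inner @ rinv


def polar_rotation(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polar decomposition A = R·U; returns (R, U) with U SPD, R rotation."""
    u = spd_sqrt(a.T @ a)
    r = a @ np.linalg.inv(u)
    # project onto the nearest rotation to kill round-off drift
    uu, _, vv = np.linalg.svd(r)
    r = uu @ vv
    if np.linalg.det(r) < 0:
        uu[:, -1] *= -1
        r = uu @ vv
    return r, u


def real_logm(a: np.ndarray) -> np.ndarray:
    """Principal real logarithm of a 2x2 matrix with positive determinant."""
    from scipy.linalg import logm

    out = logm(np.asarray(a, float))
    if np.iscomplexobj(out):
        if np.abs(out.imag).max() > 1e-8:
            raise ValueError("matrix has no principal real logarithm")
        out = out.real
    return out


def interior_angle(poly: np.ndarray, point: np.ndarray, atol: float = 1e-6) -> float:
    """Interior angle (degrees) of the polygon at its vertex nearest `point`.

    Raises if the nearest vertex is further than `atol` would suggest a
    match only when ``strict``-ly needed; callers pass vertices they know
    belong to the polygon boundary, so proximity is informational.
    """
    p = np.asarray(poly, dtype=float)
    if np.allclose(p[0], p[-1]):
        p = p[:-1]
    d = np.linalg.norm(p - np.asarray(point, dtype=float), axis=1)
    i = int(np.argmin(d))
    n = len(p)
    v_prev = p[(i - 1) % n] - p[i]
    v_next = p[(i + 1) % n] - p[i]
    nu = np.linalg.norm(v_prev) * np.linalg.norm(v_next)
    if nu == 0:
        raise ValueError("degenerate edge at vertex")
    c = np.clip(np.dot(v_prev, v_next) / nu, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def fit_affine(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares affine map y ≈ A·x + b for point sets (n, 2).

    Returns (A, b). Requires n >= 3 non-collinear points for A to be
    determined; the caller checks conditioning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    xc = x - xm
    yc = y - ym
    a, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    a = a.T
    b = ym - a @ xm
    return a, b
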