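"""Severity-manifold characterization: 2-d layout, conic fit, traversal.

The hidden-layer embedding is projected to the plane with UMAP (Euclidean
metric, seeded layout).  The resulting point cloud is then summarized by
the best-fitting curve among a scanned conic family — parabolas in both
orientations, the general algebraic conic (ellipse/hyperbola), and a total
least-squares line — scored by mean squared Sampson distance, the
first-order approximation to orthogonal (geometric) distance.  Samples are
projected onto the fitted curve and ordered by arc length, so cumulative
counts of severe vs less-severe patients can be read off while traversing
the manifold from one end to the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nets import EmbeddingMatrix

__all__ = ["umap_project", "ConicFit", "fit_conic", "traverse"]


def umap_project(e: EmbeddingMatrix | np.ndarray, seed: int = 0,
                 n_neighbors: int = 15, min_dist: float = 0.1) -> np.ndarray:
    """Seeded 2-d UMAP layout of an embedding (L2 metric)."""
    values = e.values if isinstance(e, EmbeddingMatrix) else np.asarray(e, float)
    n = values.shape[0]
    if n < 10:
        raise ValueError(
            f"only {n} samples: too few for a meaningful manifold layout "
            "(need >= 10)")
    if n_neighbors >= n:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be below the sample count {n}; "
            "pass a smaller n_neighbors")
    import umap  # deferred: numba-backed import is expensive

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, metric="euclidean",
                            n_neighbors=n_neighbors, min_dist=min_dist,
                            random_state=seed)
        return np.asarray(reducer.fit_transform(values), dtype=float)


# ---------------------------------------------------------------------------
# conic family fit


@dataclass
class ConicFit:
    """Best curve from the scanned conic family.

    ``kind`` ∈ {parabola_x, parabola_y, line, conic}; ``coefficients`` for a
    parabola_x are (a, b, c) of x = a + b·y + c·y²; for parabola_y of
    y = a + b·x + c·x²; for a line (x0, y0, dx, dy) point + unit direction;
    for a general conic the 6-vector (A, B, C, D, E, F) of
    A x² + B xy + C y² + D x + E y + F = 0.  ``mse`` is the mean squared
    Sampson distance; ``arc`` the per-sample arc-length coordinate of its
    projection onto the curve; ``errors`` the mse of every scanned
    candidate.
    """

    kind: str
    coefficients: np.ndarray
    mse: float
    arc: np.ndarray
    errors: dict
    _polyline: np.ndarray = None


def _sampson_parabola(points, coef, axis: str):
    a, b, c = coef
    if axis == "x":
        u, v = points[:, 0], points[:, 1]   # x = f(y)
    else:
        u, v = points[:, 1], points[:, 0]   # y = f(x)
    f = u - (a + b * v + c * v * v)
    grad2 = 1.0 + (b + 2.0 * c * v) ** 2
    return f * f / grad2


def _fit_parabola(points, axis: str):
    if axis == "x":
        u, v = points[:, 0], points[:, 1]
    else:
        u, v = points[:, 1], points[:, 0]
    design = np.column_stack([np.ones_like(v), v, v * v])
    coef, *_ = np.linalg.lstsq(design, u, rcond=None)
    return coef, float(np.mean(_sampson_parabola(points, coef, axis)))


def _fit_line(points):
    center = points.mean(axis=0)
    centered = points - center
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    normal = vt[1]
    resid = centered @ normal
    coef = np.array([center[0], center[1], direction[0], direction[1]])
    return coef, float(np.mean(resid * resid))


def _fit_general_conic(points):
    x, y = points[:, 0], points[:, 1]
    design = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    _, _, vt = np.linalg.svd(design, full_matrices=False)
    coef = vt[-1]
    A, B, C, D, E, _ = coef
    fx = 2 * A * x + B * y + D
    fy = B * x + 2 * C * y + E
    f = design @ coef
    grad2 = fx * fx + fy * fy
    ok = grad2 > 1e-30
    if not ok.all():
        return coef, np.inf
    return coef, float(np.mean(f * f / grad2))


def _polyline(kind, coef, points, n_dense=2000):
    """Dense sampling of the fitted curve spanning the data range."""
    pad = 0.1
    if kind == "parabola_x":
        lo, hi = points[:, 1].min(), points[:, 1].max()
        span = (hi - lo) or 1.0
        t = np.linspace(lo - pad * span, hi + pad * span, n_dense)
        a, b, c = coef
        return np.column_stack([a + b * t + c * t * t, t])
    if kind == "parabola_y":
        lo, hi = points[:, 0].min(), points[:, 0].max()
        span = (hi - lo) or 1.0
        t = np.linspace(lo - pad * span, hi + pad * span, n_dense)
        a, b, c = coef
        return np.column_stack([t, a + b * t + c * t * t])
    if kind == "line":
        x0, y0, dx, dy = coef
        proj = (points - [x0, y0]) @ np.array([dx, dy])
        lo, hi = proj.min(), proj.max()
        span = (hi - lo) or 1.0
        t = np.linspace(lo - pad * span, hi + pad * span, n_dense)
        return np.column_stack([x0 + t * dx, y0 + t * dy])
    # general conic: trace the zero set over a padded bounding box by
    # solving the quadratic in y column-wise (both branches)
    A, B, C, D, E, F = coef
    lo, hi = points[:, 0].min(), points[:, 0].max()
    span = (hi - lo) or 1.0
    xs = np.linspace(lo - pad * span, hi + pad * span, n_dense // 2)
    pts = []
    for xv in xs:
        aa, bb, cc = C, B * xv + E, A * xv * xv + D * xv + F
        if abs(aa) < 1e-14:
            if abs(bb) > 1e-14:
                pts.append((xv, -cc / bb))
            continue
        disc = bb * bb - 4 * aa * cc
        if disc >= 0:
            r = np.sqrt(disc)
            pts.append((xv, (-bb - r) / (2 * aa)))
            pts.append((xv, (-bb + r) / (2 * aa)))
    if not pts:
        return None
    return np.asarray(pts)


def _arc_coordinates(polyline, points):
    """Arc-length coordinate of each point's nearest polyline vertex."""
    seg = np.diff(polyline, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    d2 = ((points[:, None, :] - polyline[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    return cum[nearest]


def fit_conic(points: np.ndarray) -> ConicFit:
    """Scan the conic family and keep the minimum-error curve.

    Collinear input degrades the quadratic fits; in that case a total
    least-squares line is returned directly with a warning.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("expected an (n, 2) coordinate array")
    if points.shape[0] < 6:
        raise ValueError("need at least 6 points for the conic family")

    line_coef, line_err = _fit_line(points)
    centered = points - points.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        warnings.warn("points are collinear; falling back to a line fit",
                      stacklevel=2)
        poly = _polyline("line", line_coef, points)
        return ConicFit("line", line_coef, line_err,
                        _arc_coordinates(poly, points),
                        {"line": line_err}, poly)

    candidates = {"line": (line_coef, line_err)}
    for axis, kind in (("x", "parabola_x"), ("y", "parabola_y")):
        coef, err = _fit_parabola(points, axis)
        candidates[kind] = (coef, err)
    coef, err = _fit_general_conic(points)
    candidates["conic"] = (coef, err)

    errors = {k: e for k, (c, e) in candidates.items()}
    best = min(candidates, key=lambda k: candidates[k][1])
    coef, err = candidates[best]
    poly = _polyline(best, coef, points)
    if poly is None or len(poly) < 2:  # conic zero set missed the box
        best = min((k for k in candidates if k != "conic"),
                   key=lambda k: candidates[k][1])
        coef, err = candidates[best]
        poly = _polyline(best, coef, points)
    order = np.argsort(poly[:, 0], kind="stable") if best == "conic" else None
    if order is not None:
        poly = poly[order]
    return ConicFit(best, np.asarray(coef, float), err,
                    _arc_coordinates(poly, points), errors, poly)


def traverse(fit: ConicFit, points: np.ndarray, severe) -> pd.DataFrame:
    """Cumulative severe / less-severe counts along the projected manifold.

    Samples are ordered by their arc-length coordinate on the fitted curve
    (endpoint A = smallest arc value, endpoint B = largest); `severe` is a
    boolean/0-1 array marking bad-prognosis cases.
    """
    points = np.asarray(points, dtype=float)
    severe = np.asarray(severe).astype(int)
    if len(severe) != len(points) or len(points) != len(fit.arc):
        raise ValueError("points, severity labels and fit must align")
    order = np.argsort(fit.arc, kind="stable")
    sv = severe[order]
    return pd.DataFrame({
        "sample_index": order,
        "arc": fit.arc[order],
        "cum_severe": np.cumsum(sv),
        "cum_less_severe": np.cumsum(1 - sv),
    })
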