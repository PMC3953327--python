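"""Gradient-descent polynomial fitting of local curve segments.

Near a gap, the visible part of a boundary curve is traced backward from
the open endpoint and a low-order polynomial model of its shape is
learned by per-sample (or small-batch) gradient descent on the vertical
fitting error. The fitted model later supervises the gap-closing walker
by scoring how far a candidate pixel strays from the expected curve
trend.

Coordinates: pixels are (row, col); for the fitting math the abscissa x
is the column and the ordinate y the row, with axes exchanged when the
traced segment is more vertical than horizontal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CurveModel",
    "FitConfig",
    "InsufficientSupportError",
    "trace_curve_segment",
    "orient_axes",
    "poly_eval",
    "fit_cost",
    "fit_gradient_step",
    "fit_curve",
    "fit_segment",
]


class InsufficientSupportError(ValueError):
    """Raised when a traced segment is too short to support the model."""


@dataclass(frozen=True)
class CurveModel:
    """Polynomial curve model y = theta_0 + theta_1 x + ... in an oriented frame.

    ``axis_swapped`` records whether x and y were exchanged during
    fitting (done for near-vertical segments so the curve stays
    function-like); ``pixel_distance`` undoes the swap transparently.
    """

    theta: tuple[float, ...]
    axis_swapped: bool = False

    @property
    def degree(self) -> int:
        return len(self.theta) - 1

    def __call__(self, x: float) -> float:
        return poly_eval(self, x)

    def pixel_distance(self, row: float, col: float) -> float:
        """Vertical-distance fit cost of an image pixel to the model curve."""
        x, y = (float(col), float(row))
        if self.axis_swapped:
            x, y = y, x
        return abs(y - poly_eval(self, x))


@dataclass(frozen=True)
class FitConfig:
    """Parameters of segment tracing and gradient-descent fitting.

    theta_dim is the dimension of the coefficient vector (3 = quadratic
    basis 1, x, x^2); neighborhood caps how many pixels are traced back
    from the endpoint and ignore_near_gap drops the pixels nearest the
    gap, whose positions are least reliable.
    """

    theta_dim: int = 3
    alpha_lr: float = 0.1
    episodes: int = 10
    neighborhood: int = 15
    ignore_near_gap: int = 2
    theta_tol: float = 1e-3
    batch_size: int = 5
    mode: str = "instant"

    def __post_init__(self):
        if self.theta_dim < 1 or self.neighborhood < 1 or self.episodes < 1:
            raise ValueError("theta_dim, neighborhood and episodes must be positive")
        if not (0 <= self.ignore_near_gap < self.neighborhood):
            raise ValueError("ignore_near_gap must be < neighborhood")
        if self.mode not in ("instant", "batch"):
            raise ValueError("mode must be 'instant' or 'batch'")
        if self.alpha_lr <= 0 or self.theta_tol <= 0 or self.batch_size < 1:
            raise ValueError("alpha_lr, theta_tol and batch_size must be positive")


_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def trace_curve_segment(boundary_map, endpoint, cfg: FitConfig) -> list[tuple[int, int]]:
    """Walk back from an open endpoint along its curve arm.

    Follows marked 8-neighbours away from the endpoint, stopping at a
    branch point (two or more unvisited marked neighbours), after
    ``cfg.neighborhood`` pixels, or at the arm's end. The
    ``cfg.ignore_near_gap`` pixels closest to the endpoint are dropped
    and the remainder is returned ordered farthest-first.
    """
    b = np.asarray(boundary_map) != 0
    r0, c0 = endpoint
    if not b[r0, c0]:
        raise ValueError(f"endpoint {endpoint} is not a marked pixel")
    h, w = b.shape
    visited = {(r0, c0)}
    walk = [(r0, c0)]
    cur = (r0, c0)
    while len(walk) < cfg.neighborhood:
        r, c = cur
        nxt = [
            (r + dr, c + dc)
            for dr, dc in _NEIGH8
            if 0 <= r + dr < h and 0 <= c + dc < w
            and b[r + dr, c + dc] and (r + dr, c + dc) not in visited
        ]
        if len(nxt) != 1:  # dead end or branch point
            break
        cur = nxt[0]
        visited.add(cur)
        walk.append(cur)
    if len(walk) < cfg.ignore_near_gap + cfg.theta_dim:
        raise InsufficientSupportError(
            f"segment of {len(walk)} px cannot support a {cfg.theta_dim}-coefficient "
            f"model after ignoring {cfg.ignore_near_gap} px near the gap"
        )
    kept = walk[cfg.ignore_near_gap:]
    return kept[::-1]


def orient_axes(points: np.ndarray) -> tuple[np.ndarray, bool]:
    """Exchange x and y when the point set is taller than it is wide.

    Keeps the segment function-like (one y per x) for polynomial
    fitting; ties break toward no swap. ``points`` is an (n, 2) array of
    (x, y) pairs.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need an (n>=2, 2) array of points")
    x_extent = pts[:, 0].max() - pts[:, 0].min()
    y_extent = pts[:, 1].max() - pts[:, 1].min()
    if y_extent > x_extent:
        return pts[:, ::-1].copy(), True
    return pts.copy(), False


def poly_eval(model: CurveModel, x: float):
    """Evaluate the polynomial (constant term first) by Horner's scheme."""
    acc = 0.0
    for coef in reversed(model.theta):
        acc = acc * x + coef
    return acc


def fit_cost(point, model: CurveModel) -> float:
    """Vertical distance |y - model(x)| of an oriented-frame point."""
    x, y = point
    return abs(y - poly_eval(model, x))


def fit_gradient_step(theta: np.ndarray, point, alpha_lr: float) -> np.ndarray:
    """One stochastic-gradient update of theta toward a sample point.

    theta' = theta + alpha_lr * (y - G.theta) * G with basis
    G = (1, x, x^2, ...).
    """
    theta = np.asarray(theta, dtype=float)
    x, y = point
    g = np.power(float(x), np.arange(theta.size))
    residual = float(y) - float(g @ theta)
    return theta + alpha_lr * residual * g


def _sample_gradient(theta: np.ndarray, x: float, y: float) -> np.ndarray:
    g = np.power(x, np.arange(theta.size))
    return (y - float(g @ theta)) * g


def fit_curve(points, cfg: FitConfig | None = None) -> CurveModel:
    """Fit a polynomial curve model to oriented sample points.

    Orientation (axis swap for near-vertical segments) and an internal
    affine normalisation for numerical conditioning happen first: x is
    rescaled to [0, 1] and y is shifted and divided by the same span, so
    residuals and slopes are O(1) and the descent converges within few
    passes regardless of where in the image the segment lies. Gradient
    descent then loops over the points in their given order for up to
    ``cfg.episodes`` passes, instantly per sample or in mean batches of
    ``cfg.batch_size``, stopping early once a full pass moves no
    coefficient by more than ``cfg.theta_tol``. Coefficients are mapped
    back to the unscaled frame before returning. Deterministic: no
    randomness is involved.
    """
    if cfg is None:
        cfg = FitConfig()
    pts, swapped = orient_axes(np.asarray(points, dtype=float))
    if pts.shape[0] < cfg.theta_dim:
        raise InsufficientSupportError(
            f"{pts.shape[0]} points cannot determine {cfg.theta_dim} coefficients"
        )
    x = pts[:, 0]
    y = pts[:, 1]
    x0 = x.min()
    span = max(x.max() - x0, 1.0)
    u = (x - x0) / span
    y0 = y.mean()
    v = (y - y0) / span

    theta = np.zeros(cfg.theta_dim)
    for _ in range(cfg.episodes):
        theta_start = theta.copy()
        if cfg.mode == "instant":
            for ui, vi in zip(u, v):
                theta = theta + cfg.alpha_lr * _sample_gradient(theta, ui, vi)
        else:
            batch = np.zeros_like(theta)
            count = 0
            for ui, vi in zip(u, v):
                batch += _sample_gradient(theta, ui, vi)
                count += 1
                if count == cfg.batch_size:
                    theta = theta + cfg.alpha_lr * batch / count
                    batch[:] = 0.0
                    count = 0
            if count:
                theta = theta + cfg.alpha_lr * batch / count
        if np.max(np.abs(theta - theta_start)) < cfg.theta_tol:
            break

    # undo the normalisation: y = y0 + span * p((x - x0)/span)
    p_u = np.polynomial.Polynomial(theta)
    p_x = p_u(np.polynomial.Polynomial([-x0 / span, 1.0 / span])) * span + y0
    coef = np.zeros(cfg.theta_dim)
    coef[: len(p_x.coef)] = p_x.coef[: cfg.theta_dim]
    return CurveModel(theta=tuple(float(c) for c in coef), axis_swapped=swapped)


def fit_segment(pixels, cfg: FitConfig | None = None) -> CurveModel:
    """Fit a curve model to traced (row, col) pixels.

    Convenience wrapper mapping image coordinates to the fitting frame
    (x = col, y = row) before calling :func:`fit_curve`.
    """
    pix = np.asarray(pixels, dtype=float)
    xy = pix[:, ::-1]  # (col, row) = (x, y)
    return fit_curve(xy, cfg)
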