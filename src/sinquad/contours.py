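"""Closed planar contours and their sign-coded local descriptors.

A contour is an ordered sequence of ``(x, y)`` points in pixel coordinates,
implicitly closed (the first point is *not* repeated at the end) and analyzed
counterclockwise.  The y axis points up (mathematical convention); contours
traced from image arrays must be flipped on ingest (see :mod:`sinquad.io`).

The local shape descriptor is the four-component characteristic vector

    c(u) = [c_t, c_c, c_x, c_y]

where ``c_t`` is the sign of the first derivative dy/dx of the contour viewed
locally as the graph of a function, ``c_c`` the sign of the second derivative,
and ``c_x``, ``c_y`` the signs of the coordinate increments along the
traversal.  Signs are quantized with a sub-pixel tolerance; a vanishing
denominator of the derivative (vertical tangent) is encoded as ``"V"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("sinquad")

#: Default arc-length step (px) for resampling and finite differences.  The
#: same value is the minimal primitive length.
DEFAULT_STEP = 5.0
#: Sub-pixel sign-quantization floor (px): a coordinate difference smaller in
#: magnitude than this counts as zero.
DEFAULT_TOL = 0.5
#: Curvature floor (px^2) on the cross product of consecutive step vectors;
#: below it the second derivative counts as zero (straight run).
DEFAULT_CURV_TOL = 0.5

_SIGNS = ("+", "-", "0", "V")


@dataclass(frozen=True)
class CharVector:
    """Sign-coded characteristic vector ``[c_t, c_c, c_x, c_y]``.

    ``c_t`` and ``c_c`` take values in ``{+, -, 0, V}``; the increment signs
    ``c_x`` and ``c_y`` never take the value ``V``.
    """

    c_t: str
    c_c: str
    c_x: str
    c_y: str

    def __post_init__(self) -> None:
        for name in ("c_t", "c_c"):
            if getattr(self, name) not in _SIGNS:
                raise ValueError(f"{name} must be one of {_SIGNS}")
        for name in ("c_x", "c_y"):
            if getattr(self, name) not in ("+", "-", "0"):
                raise ValueError(f"{name} must be one of ('+', '-', '0')")

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.c_t, self.c_c, self.c_x, self.c_y)

    def __str__(self) -> str:  # compact form used in debug logs / reports
        return "".join(self.as_tuple())


class Contour:
    """A closed, implicitly-cyclic polyline in pixel coordinates.

    Parameters
    ----------
    points : array-like of shape (n, 2)
        Ordered vertices.  A trailing vertex equal to the first one is
        dropped (implicit closure).  At least 3 distinct vertices required.
    """

    def __init__(self, points) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must have shape (n, 2)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour points must be finite")
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(np.unique(np.round(pts, 9), axis=0)) < 3:
            raise ValueError("contour needs at least 3 distinct points")
        self._points = pts

    # -- basic geometry -----------------------------------------------------

    @property
    def points(self) -> np.ndarray:
        return self._points

    def __len__(self) -> int:
        return len(self._points)

    @property
    def signed_area(self) -> float:
        """Shoelace signed area; positive for counterclockwise order."""
        x, y = self._points[:, 0], self._points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def is_ccw(self) -> bool:
        return self.signed_area > 0

    @property
    def perimeter(self) -> float:
        d = np.roll(self._points, -1, axis=0) - self._points
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    # -- transforms (used by invariance tests and fixtures) -----------------

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self._points + np.array([dx, dy]))

    def scaled(self, k: float, about=(0.0, 0.0)) -> "Contour":
        about = np.asarray(about, dtype=float)
        return Contour((self._points - about) * k + about)

    def rotated(self, degrees: float, about=(0.0, 0.0)) -> "Contour":
        t = np.deg2rad(degrees)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        about = np.asarray(about, dtype=float)
        return Contour((self._points - about) @ rot.T + about)

    def __repr__(self) -> str:
        return f"Contour(n={len(self)}, area={self.signed_area:.1f})"


def normalize_orientation(contour: Contour) -> Contour:
    """Return the contour in counterclockwise order, keeping the start point.

    Raises ``ValueError`` for degenerate (zero-area) input.
    """
    area = contour.signed_area
    if abs(area) < 1e-9:
        raise ValueError("degenerate contour: zero enclosed area")
    if area > 0:
        return contour
    pts = contour.points
    logger.debug("normalize_orientation: reversing clockwise contour")
    # reverse while keeping the first vertex first
    return Contour(np.vstack([pts[:1], pts[1:][::-1]]))


def resample_contour(contour: Contour, step: float = DEFAULT_STEP) -> Contour:
    """Resample the closed polyline at (near-)uniform arc-length spacing.

    The number of points is ``round(perimeter / step)`` so the realized
    spacing equals the perimeter divided by that count — within 1% of
    ``step`` whenever the perimeter is at least a few steps long.  The first
    point of the input is kept as the first sample (traversal anchor).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    perim = contour.perimeter
    if perim < 3 * step - 1e-9:
        raise ValueError(
            f"contour too small for step: perimeter {perim:.2f} < 3*{step}"
        )
    pts = contour.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    n = int(round(perim / step))
    targets = np.linspace(0.0, perim, n, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return Contour(np.column_stack([x, y]))


def _sign(value: float, tol: float) -> str:
    if abs(value) < tol:
        return "0"
    return "+" if value > 0 else "-"


def char_vector_from_window(
    p_prev: np.ndarray,
    p: np.ndarray,
    p_next: np.ndarray,
    tol: float = DEFAULT_TOL,
    curv_tol: float = DEFAULT_CURV_TOL,
) -> CharVector:
    """Characteristic vector from a three-point stencil ``p_prev, p, p_next``.

    Increments use the forward difference ``p_next - p``; the derivative
    signs use the central window.  The second-derivative sign is taken from
    the cross product of the two step vectors (left turn/right turn) mapped
    back to the sign of y'' of the locally-parameterized graph.
    """
    d_fwd = p_next - p
    c_x = _sign(d_fwd[0], tol)
    c_y = _sign(d_fwd[1], tol)

    dx_c = p_next[0] - p_prev[0]
    dy_c = p_next[1] - p_prev[1]
    if abs(dx_c) < tol:
        c_t = "V"
        c_c = "V"  # the graph-of-a-function denominator vanishes
        return CharVector(c_t, c_c, c_x, c_y)
    if abs(dy_c) < tol:
        c_t = "0"
    else:
        c_t = "+" if (dy_c * dx_c) > 0 else "-"

    d_in = p - p_prev
    cross = d_in[0] * d_fwd[1] - d_in[1] * d_fwd[0]
    if abs(cross) < curv_tol:
        c_c = "0"
    else:
        ypp = cross if dx_c > 0 else -cross  # sign of y'' along increasing x
        c_c = "+" if ypp > 0 else "-"
    return CharVector(c_t, c_c, c_x, c_y)


def characteristic_vectors(
    contour: Contour,
    tol: float = DEFAULT_TOL,
    curv_tol: float = DEFAULT_CURV_TOL,
) -> list[CharVector]:
    """Characteristic vector at every point of a resampled contour (cyclic)."""
    pts = contour.points
    prev = np.roll(pts, 1, axis=0)
    nxt = np.roll(pts, -1, axis=0)
    return [
        char_vector_from_window(prev[i], pts[i], nxt[i], tol, curv_tol)
        for i in range(len(pts))
    ]


def characteristic_vector(
    contour: Contour,
    index: int,
    tol: float = DEFAULT_TOL,
    curv_tol: float = DEFAULT_CURV_TOL,
) -> CharVector:
    """Characteristic vector at one point (index wraps cyclically)."""
    pts = contour.points
    i = index % len(pts)
    return char_vector_from_window(
        pts[i - 1], pts[i], pts[(i + 1) % len(pts)], tol, curv_tol
    )


def open_char_vectors(
    points,
    tol: float = DEFAULT_TOL,
    curv_tol: float = DEFAULT_CURV_TOL,
) -> list[CharVector]:
    """Characteristic vectors at the interior points of an *open* curve.

    Used for ideal primitive fixtures, which are open arcs/segments rather
    than closed contours.  Returns one vector per interior point
    (indices ``1 .. n-2``).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    return [
        char_vector_from_window(pts[i - 1], pts[i], pts[i + 1], tol, curv_tol)
        for i in range(1, len(pts) - 1)
    ]
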