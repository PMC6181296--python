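"""Parametric fixture generators: ideal primitives, four-lobe rosettes, and
vertebra-like contours with a controlled lower-corner lesion.

The vertebra template is a slightly tapered rounded quadrilateral, tilted by
-20 degrees so that every straight edge direction lies strictly inside one
Cartesian quadrant.  The lower-anterior corner is built as an explicit
vertex between two straight flanks whose interior angle equals the designed
angle alpha; because the generated path *starts* at that vertex and
arc-length resampling keeps the first point, the encoder's measured alpha
equals the designed alpha exactly (the two chords at the switch lie wholly
on the flanks).

Lesion severity maps linearly to alpha (obtuse when healthy, acute when
advanced).  Above ``HOOK_ONSET`` a hook-shaped dip is inserted on the lower
edge, adding the ``430.341`` token pair to the lower-contour key; above
``NOTCH_ONSET`` a step notch on the lower right edge adds ``140.411``,
which makes the key atypical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contours import Contour
from .language import PrimitiveClass

logger = logging.getLogger("sinquad")

#: Whole-contour tilt (degrees): keeps edge directions off the axes.
TILT_DEG = -20.0

#: Designed interior angle at the lesion corner for severity 0 and 0.8.
ALPHA_HEALTHY = 156.0
ALPHA_ADVANCED = 65.0

#: Severity above which the hook dip appears (key gains "430.341").
HOOK_ONSET = 0.35
#: Severity above which the right-edge step notch appears (key atypical).
NOTCH_ONSET = 0.8

# Untilted edge directions (degrees).  The right/left edges are not exactly
# vertical: the small taper emulates the narrower upper vertebral margin.
_RIGHT_DIR = 96.5
_TOP_DIR = 180.0
_LEFT_DIR = 266.7

_FLANK = 8.0    # straight flank length on each side of the lesion vertex
_B2 = 18.0      # lower-edge run between the hook and the lesion corner
_RHO_C = 4.0    # blend radius at the lesion-corner connectors
_RHO_H = 3.0    # blend radius of the hook dip
_RHO_N = 3.0    # blend radius of the step notch


def design_alpha(severity: float) -> float:
    """Designed lesion-corner angle (degrees) for a lesion severity.

    Linear from ``ALPHA_HEALTHY`` at severity 0 to ``ALPHA_ADVANCED`` at
    severity 0.8; continues linearly above 0.8.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("lesion_severity must be in [0, 1]")
    return ALPHA_HEALTHY - (ALPHA_HEALTHY - ALPHA_ADVANCED) * severity / 0.8


@dataclass(frozen=True)
class VertebraParams:
    """Geometry and lesion parameters of one synthetic vertebra contour."""

    width: float = 100.0
    height: float = 70.0
    corner_radius: float = 12.0
    lesion_severity: float = 0.0
    lesion_corner: str = "lower-anterior"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lesion_severity <= 1.0:
            raise ValueError("lesion_severity must be in [0, 1]")
        if self.lesion_corner != "lower-anterior":
            raise ValueError(
                "only the lower-anterior lesion corner is supported"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.width < 60 or self.height < 50:
            raise ValueError("vertebra body too small: width >= 60, height >= 50")
        if not 6.0 <= self.corner_radius < min(self.width, self.height) / 2:
            raise ValueError(
                "corner_radius must be in [6, min(width, height)/2)"
            )


def _dir(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([np.cos(t), np.sin(t)])


class _PathBuilder:
    """Turtle-style dense polyline builder (straight runs and arcs)."""

    DS = 0.5  # dense sampling interval (px)

    def __init__(self, start=(0.0, 0.0), heading: float = 0.0) -> None:
        self.pos = np.asarray(start, dtype=float).copy()
        self.heading = float(heading)
        self.points: list[np.ndarray] = [self.pos.copy()]

    def line(self, length: float) -> None:
        if length < 0:
            raise ValueError("line length must be non-negative")
        if length == 0:
            return
        d = _dir(self.heading)
        start = self.pos.copy()
        n = max(1, int(np.ceil(length / self.DS)))
        for k in range(1, n + 1):
            self.points.append(start + d * (length * k / n))
        self.pos = self.points[-1].copy()

    def arc_to(self, radius: float, target_heading: float) -> None:
        """Circular arc turning the heading to ``target_heading`` (absolute
        degrees; the sign of the sweep decides left/right turn)."""
        sweep = target_heading - self.heading
        if abs(sweep) < 1e-12:
            self.heading = target_heading
            return
        a = self.heading
        if sweep > 0:
            center = self.pos + radius * _dir(a + 90.0)
            offset = -90.0
        else:
            center = self.pos + radius * _dir(a - 90.0)
            offset = 90.0
        arclen = radius * abs(np.deg2rad(sweep))
        n = max(2, int(np.ceil(arclen / self.DS)))
        for k in range(1, n + 1):
            d = a + sweep * k / n
            self.points.append(center + radius * _dir(d + offset))
        self.pos = self.points[-1].copy()
        self.heading = target_heading

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points)


def _vertebra_path(p: VertebraParams) -> np.ndarray:
    """Untilted dense path, starting exactly at the lesion vertex.

    The lower and right edge lengths are unknowns solved from loop closure
    (two scalars, two equations); every other piece is fixed by the params.
    """
    alpha = design_alpha(p.lesion_severity)
    gamma = (180.0 - alpha) / 2.0
    radius = p.corner_radius
    top_len = p.width - 2.0 * radius
    left_len = p.height - 2.0 * radius
    hook = p.lesion_severity > HOOK_ONSET
    notch = p.lesion_severity > NOTCH_ONSET
    c_len = 10.0 + 8.0 * (p.lesion_severity - HOOK_ONSET) / (1.0 - HOOK_ONSET - 0.2)

    def run(bottom_len: float, right_len: float) -> _PathBuilder:
        t = _PathBuilder((0.0, 0.0), 20.0 + gamma)
        t.line(_FLANK)                    # outgoing lesion flank
        t.arc_to(_RHO_C, _RIGHT_DIR)
        if notch:
            t.line(8.0)                   # lower right edge before the notch
            t.arc_to(_RHO_N, -30.0)       # into the step notch (concave)
            t.line(10.0)
            t.arc_to(_RHO_N, _RIGHT_DIR)  # out of the notch (convex)
        t.line(right_len)
        t.arc_to(radius, _TOP_DIR)        # upper posterior corner
        t.line(top_len)
        t.arc_to(radius, _LEFT_DIR)       # upper anterior corner
        t.line(left_len)
        t.arc_to(radius, 360.0)           # lower posterior corner
        t.line(bottom_len)
        if hook:
            t.arc_to(_RHO_H, 270.0)       # into the hook (concave)
            t.line(c_len)                 # hook cliff, straight down
            t.arc_to(_RHO_H, 375.0)       # around the hook tip (convex)
            t.line(1.3 * c_len)           # rising tail
            t.arc_to(_RHO_H, 360.0)
            t.line(_B2)
        t.arc_to(_RHO_C, 380.0 - gamma)   # connector into the lesion vertex
        t.line(_FLANK)                    # incoming lesion flank, ends at V
        return t

    probe = run(0.0, 0.0)
    basis = np.column_stack([_dir(360.0), _dir(_RIGHT_DIR)])
    bottom_len, right_len = np.linalg.solve(basis, -probe.pos)
    if bottom_len < 10.0 or right_len < 8.0:
        raise ValueError(
            "invalid geometry: solved edge lengths too short "
            f"(bottom {bottom_len:.1f}, right {right_len:.1f}); "
            "increase width/height or reduce lesion_severity/corner_radius"
        )
    path = run(float(bottom_len), float(right_len))
    closure = float(np.linalg.norm(path.pos))
    if closure > 1e-6:
        raise AssertionError(f"path failed to close (residual {closure:.2e})")
    return path.as_array()


def _apply_radial_noise(
    pts: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth radial perturbation: Fourier modes k = 1..3 over arc length.

    Low-order modes keep the perturbation gentle at the 5-px chord scale
    (unlike i.i.d. pixel noise), so sign quantization absorbs it.
    """
    if noise_sd <= 0:
        return pts
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = s / (s[-1] + np.linalg.norm(pts[0] - pts[-1]))
    amp = noise_sd * np.sqrt(2.0 / 3.0)
    field = np.zeros(len(pts))
    for k in (1, 2, 3):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        field += amp * np.cos(2.0 * np.pi * k * t + phase)
    centroid = pts.mean(axis=0)
    radial = pts - centroid
    norms = np.linalg.norm(radial, axis=1)
    norms[norms == 0] = 1.0
    return pts + field[:, None] * radial / norms[:, None]


def generate_vertebra(params: VertebraParams) -> Contour:
    """Closed counterclockwise vertebra-like contour per the parameters.

    The first point of the returned contour is the lesion vertex, so the
    pipeline's resampling anchors a sample exactly there and the measured
    lesion angle equals :func:`design_alpha` of the severity (up to the
    noise perturbation).
    """
    pts = _vertebra_path(params)
    contour = Contour(pts).rotated(TILT_DEG, about=(0.0, 0.0))
    rng = np.random.default_rng(params.seed)
    noisy = _apply_radial_noise(contour.points, params.noise_sd, rng)
    out = Contour(noisy)
    if not out.is_ccw:
        raise AssertionError("generator produced a clockwise contour")
    return out


@dataclass(frozen=True)
class CohortItem:
    """One labeled cohort member."""

    contour: Contour
    label: str  # "healthy" | "pathological"
    severity: float
    seed: int


def generate_cohort(
    n_healthy: int,
    n_path: int,
    severity_range: tuple[float, float] = (0.62, 0.8),
    seed: int = 0,
    noise_sd: float = 0.5,
    params: VertebraParams | None = None,
) -> list[CohortItem]:
    """Reproducible labeled cohort of synthetic vertebra contours.

    Healthy members have severity 0; pathological members draw their
    severity uniformly from ``severity_range``.  The default range keeps
    the designed lesion angles on the syndesmophyte-membership plateau
    with margin for the noise perturbation, so generating labels and
    classifier decisions can be compared one-to-one.
    """
    if n_healthy < 0 or n_path < 0:
        raise ValueError("cohort counts must be non-negative")
    lo, hi = severity_range
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError("severity_range must satisfy 0 <= lo <= hi <= 1")
    base = params if params is not None else VertebraParams()
    rng = np.random.default_rng(seed)
    items: list[CohortItem] = []
    for _ in range(n_healthy):
        child = int(rng.integers(2**31))
        p = VertebraParams(
            width=base.width, height=base.height,
            corner_radius=base.corner_radius,
            lesion_severity=0.0, noise_sd=noise_sd, seed=child,
        )
        items.append(CohortItem(generate_vertebra(p), "healthy", 0.0, child))
    for _ in range(n_path):
        sev = float(rng.uniform(lo, hi))
        child = int(rng.integers(2**31))
        p = VertebraParams(
            width=base.width, height=base.height,
            corner_radius=base.corner_radius,
            lesion_severity=sev, noise_sd=noise_sd, seed=child,
        )
        items.append(CohortItem(generate_vertebra(p), "pathological", sev, child))
    logger.debug(
        "generate_cohort: %d healthy + %d pathological (seed %d)",
        n_healthy, n_path, seed,
    )
    return items


# -- ideal primitive fixtures ------------------------------------------------

#: Travel direction (degrees) of the ideal axis-aligned fragment per quadrant
#: convention (the direction entered under counterclockwise traversal).
_AXIS_DIR = {1: 0.0, 2: 90.0, 3: 180.0, 4: 270.0}


def generate_primitive_fixture(
    cls: PrimitiveClass, length: float = 40.0, step: float = 5.0
) -> np.ndarray:
    """Open ideal curve whose interior characteristic vectors classify to
    the requested primitive class.

    Geometry index 1: oblique straight segment at the quadrant's diagonal;
    2/3: constant-curvature arcs with positive/negative second-derivative
    sign; 4: axis-aligned straight run.  Points are spaced ``step`` apart,
    matching the resampling convention.
    """
    if length < 3 * step:
        raise ValueError("fixture length must be at least 3 steps")
    i, j = cls.i, cls.j
    n = int(round(length / step)) + 1
    base = 90.0 * (j - 1)
    if i == 1:
        d = _dir(base + 45.0)
        return np.array([d * step * k for k in range(n)])
    if i == 4:
        d = _dir(_AXIS_DIR[j])
        return np.array([d * step * k for k in range(n)])
    # Arcs: the second-derivative sign of the locally-parameterized graph is
    # sign(cross) * sign(dx); a left-turning arc gives c_c = "+" exactly in
    # the quadrants where x increases (1 and 4).
    left_turn = (i == 2) == (j in (1, 4))
    start_dir = base + 20.0 if left_turn else base + 70.0
    end_dir = base + 70.0 if left_turn else base + 20.0
    radius = length / np.deg2rad(50.0)
    sweep_step = np.rad2deg(step / radius) * (1 if left_turn else -1)
    pts = []
    pos = np.zeros(2)
    if left_turn:
        center = pos + radius * _dir(start_dir + 90.0)
        offset = -90.0
    else:
        center = pos + radius * _dir(start_dir - 90.0)
        offset = 90.0
    for k in range(n):
        d = start_dir + sweep_step * k
        pts.append(center + radius * _dir(d + offset))
    final_dir = start_dir + sweep_step * (n - 1)
    if abs(final_dir - end_dir) > 15.0:
        raise AssertionError("arc fixture left its quadrant window")
    return np.asarray(pts)


# -- closed analytic fixtures ------------------------------------------------

def generate_circle(
    radius: float = 100.0, center=(0.0, 0.0), n_dense: int = 1440
) -> Contour:
    """Counterclockwise circle (dense polyline)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    th = np.linspace(0.0, 2.0 * np.pi, n_dense, endpoint=False)
    c = np.asarray(center, dtype=float)
    return Contour(np.column_stack([c[0] + radius * np.cos(th),
                                    c[1] + radius * np.sin(th)]))


def generate_rosette(
    radius: float = 80.0, eps: float = 0.25, n_dense: int = 2400
) -> Contour:
    """Four-lobe rosette r(theta) = R (1 - eps cos 4 theta).

    For eps above ~1/16 the four dips are concave: the travel direction
    retreats across a quadrant boundary and re-advances at each dip, giving
    twelve direction switches — an advance/retreat/advance triple per
    quadrant boundary — with convexity bits 1, 0, 1.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0.08 <= eps <= 0.45:
        raise ValueError("eps must be in [0.08, 0.45] for the 12-switch shape")
    th = np.linspace(0.0, 2.0 * np.pi, n_dense, endpoint=False)
    r = radius * (1.0 - eps * np.cos(4.0 * th))
    return Contour(np.column_stack([r * np.cos(th), r * np.sin(th)]))
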