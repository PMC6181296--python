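"""Generalized shape-language segmentation and key encoding.

A resampled counterclockwise contour is partitioned into *primitives* —
maximal runs of points sharing the same characteristic vector.  Each
primitive belongs to one of sixteen classes ``p_ij`` where ``j`` is the
Cartesian quadrant of the travel direction and ``i`` encodes the local
geometry (oblique line, arc of either curvature sign, axis-aligned line).
Runs of primitives in the same quadrant form *sinquads*; the transition
points between sinquads are the *switches* — the characteristic points of
the contour.  The contour as a whole is encoded by its *key*: one
three-character token per switch, two quadrant digits plus a convexity bit,
joined with dots (e.g. ``341.430.341.411``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .contours import (
    DEFAULT_CURV_TOL,
    DEFAULT_TOL,
    CharVector,
    Contour,
    characteristic_vectors,
)

logger = logging.getLogger("sinquad")

#: Quadrant of the travel direction from the increment signs.
QUADRANT_OF_INCREMENTS = {
    ("+", "+"): 1,
    ("-", "+"): 2,
    ("-", "-"): 3,
    ("+", "-"): 4,
}

#: Convention for an axis-aligned direction considered in isolation: the
#: quadrant it *enters* under counterclockwise (left-turning) traversal.
QUADRANT_OF_AXIS = {
    ("+", "0"): 1,
    ("0", "+"): 2,
    ("-", "0"): 3,
    ("0", "-"): 4,
}

#: Sign of dy/dx for an interior (non-axis) direction in each quadrant.
_SLOPE_SIGN = {1: "+", 2: "-", 3: "+", 4: "-"}


def _build_primitive_table() -> dict[tuple[str, str, str, str], tuple[int, int]]:
    """The sixteen-row lookup ``(c_t, c_c, c_x, c_y) -> (i, j)``.

    Geometry index ``i``: 1 oblique straight run, 2 arc with y'' > 0,
    3 arc with y'' < 0, 4 axis-aligned run.  Shipped as data so the
    numbering can be adjusted without touching the classifier code; every
    ideal straight segment or constant-curvature quarter arc of class
    ``s_ij`` lands in ``p_ij``.
    """
    table: dict[tuple[str, str, str, str], tuple[int, int]] = {}
    for (sx, sy), j in QUADRANT_OF_INCREMENTS.items():
        t = _SLOPE_SIGN[j]
        table[(t, "0", sx, sy)] = (1, j)
        table[(t, "+", sx, sy)] = (2, j)
        table[(t, "-", sx, sy)] = (3, j)
    table[("0", "0", "+", "0")] = (4, 1)  # horizontal, heading +x
    table[("V", "V", "0", "+")] = (4, 2)  # vertical, heading +y
    table[("0", "0", "-", "0")] = (4, 3)  # horizontal, heading -x
    table[("V", "V", "0", "-")] = (4, 4)  # vertical, heading -y
    assert len(table) == 16
    return table


PRIMITIVE_TABLE = _build_primitive_table()


@dataclass(frozen=True, order=True)
class PrimitiveClass:
    """Bi-index of a primitive: geometry type ``i`` and quadrant ``j``."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i not in (1, 2, 3, 4) or self.j not in (1, 2, 3, 4):
            raise ValueError("primitive indices must be in 1..4")

    def __str__(self) -> str:
        return f"p{self.i}{self.j}"


def classify_primitive(char: CharVector, quadrant: int | None = None) -> PrimitiveClass:
    """Classify a characteristic vector into one of the 16 classes.

    ``quadrant`` overrides the direction quadrant for points whose increment
    is axis-aligned but which belong, by context, to a neighbouring sinquad
    (see :func:`resolve_quadrants`).  Classification is total: vectors not in
    the shipped table fall back to the same rules evaluated directly.
    """
    key = char.as_tuple()
    if key in PRIMITIVE_TABLE and quadrant is None:
        i, j = PRIMITIVE_TABLE[key]
        return PrimitiveClass(i, j)
    j = quadrant if quadrant is not None else _quadrant_of(char)
    if char.c_t in ("0", "V"):
        i = 4
    elif char.c_c == "0":
        i = 1
    elif char.c_c == "+":
        i = 2
    else:
        i = 3
    return PrimitiveClass(i, j)


def _quadrant_of(char: CharVector) -> int:
    inc = (char.c_x, char.c_y)
    if inc in QUADRANT_OF_INCREMENTS:
        return QUADRANT_OF_INCREMENTS[inc]
    if inc in QUADRANT_OF_AXIS:
        return QUADRANT_OF_AXIS[inc]
    raise ValueError("zero increment: point does not move")


def resolve_quadrants(chars: list[CharVector]) -> list[int]:
    """Per-point direction quadrant with axis-aligned runs absorbed.

    A point whose increment is axis-aligned (``c_x`` or ``c_y`` equal to
    ``"0"``) inherits the quadrant of the nearest preceding point with a
    non-degenerate increment (cyclically), so horizontal/vertical runs do
    not fragment sinquads and every switch stays at the point where the
    direction actually changes quadrant.  If the whole contour is
    axis-aligned, the isolated-direction convention applies instead.
    """
    n = len(chars)
    quads = [0] * n
    defined = []
    for k, ch in enumerate(chars):
        inc = (ch.c_x, ch.c_y)
        if inc in QUADRANT_OF_INCREMENTS:
            quads[k] = QUADRANT_OF_INCREMENTS[inc]
            defined.append(k)
    if not defined:
        logger.debug("resolve_quadrants: fully axis-aligned contour")
        return [_quadrant_of(ch) for ch in chars]
    # look-behind fill (cyclic)
    last = defined[-1]
    q = quads[last]
    for off in range(n):
        k = (last + off) % n
        if quads[k]:
            q = quads[k]
        else:
            quads[k] = q
    return quads


def _runs_cyclic(labels: list) -> list[tuple[int, int]]:
    """Maximal cyclic runs of equal labels as ``(start, length)`` pairs.

    Runs are returned in traversal order; the first run starts at the first
    label change at or after index 0 (so a run wrapping past index 0 is
    reported once, starting at its true beginning).
    """
    n = len(labels)
    if n == 0:
        return []
    if all(l == labels[0] for l in labels):
        return [(0, n)]
    start = 0
    while labels[start - 1] == labels[start]:
        start -= 1  # walk back into the wrap; bounded because not all equal
    start %= n
    runs = []
    run_start, run_len = start, 1
    for off in range(1, n):
        k = (start + off) % n
        if labels[k] == labels[run_start]:
            run_len += 1
        else:
            runs.append((run_start, run_len))
            run_start, run_len = k, 1
    runs.append((run_start, run_len))
    return runs


def merge_short_runs(labels: list, min_len: int, prefer: dict | None = None) -> list:
    """Merge cyclic runs shorter than ``min_len`` into a neighbouring run.

    The neighbour whose preference key (``prefer[label]``, e.g. the quadrant
    of a primitive class) matches the short run's is chosen first; otherwise
    the longer neighbour wins (the following one on a tie).  Applied
    iteratively until no short run remains.  With ``min_len == 1`` this is a
    no-op, matching the convention that the minimal primitive length equals
    one resampling step.
    """
    labels = list(labels)
    if min_len <= 1:
        return labels
    while True:
        runs = _runs_cyclic(labels)
        if len(runs) <= 1:
            return labels
        short = [r for r in runs if r[1] < min_len]
        if not short:
            return labels
        start, length = min(short, key=lambda r: r[1])
        idx = runs.index((start, length))
        prev_run = runs[idx - 1]
        next_run = runs[(idx + 1) % len(runs)]
        lab = labels[start]
        key = prefer.get(lab) if prefer else None
        prev_key = prefer.get(labels[prev_run[0]]) if prefer else None
        next_key = prefer.get(labels[next_run[0]]) if prefer else None
        if prefer and (prev_key == key) != (next_key == key):
            target = prev_run if prev_key == key else next_run
        else:
            target = prev_run if prev_run[1] > next_run[1] else next_run
        new_label = labels[target[0]]
        logger.debug(
            "merge_short_runs: run %r (len %d) -> %r", lab, length, new_label
        )
        n = len(labels)
        for off in range(length):
            labels[(start + off) % n] = new_label


@dataclass(frozen=True)
class Primitive:
    """Maximal constant-characteristic fragment of the resampled contour."""

    cls: PrimitiveClass
    start: int
    length: int
    char: CharVector

    def indices(self, n: int) -> list[int]:
        return [(self.start + k) % n for k in range(self.length)]


@dataclass(frozen=True)
class Sinquad:
    """Maximal run of consecutive primitives sharing a quadrant."""

    quadrant: int
    primitives: tuple[Primitive, ...]

    @property
    def start(self) -> int:
        return self.primitives[0].start

    @property
    def length(self) -> int:
        return sum(p.length for p in self.primitives)


@dataclass(frozen=True)
class Switch:
    """Characteristic point between two consecutive sinquads."""

    index: int  # first contour point of the new sinquad
    position: tuple[float, float]
    from_quadrant: int
    to_quadrant: int
    convexity: int = field(default=1)

    @property
    def token(self) -> str:
        return f"{self.from_quadrant}{self.to_quadrant}{self.convexity}"


def segment_primitives(
    contour: Contour,
    tol: float = DEFAULT_TOL,
    curv_tol: float = DEFAULT_CURV_TOL,
    min_primitive_steps: int = 1,
) -> list[Primitive]:
    """Partition a resampled counterclockwise contour into primitives.

    Every contour point belongs to exactly one primitive (cyclically);
    primitives are maximal in their characteristic vector.  Runs shorter
    than ``min_primitive_steps`` (in resampling steps = points) are merged,
    preferring the neighbour in the same quadrant.
    """
    chars = characteristic_vectors(contour, tol, curv_tol)
    quads = resolve_quadrants(chars)
    point_labels = [(chars[k].as_tuple(), quads[k]) for k in range(len(chars))]
    prefer = {lab: lab[1] for lab in point_labels}
    point_labels = merge_short_runs(point_labels, min_primitive_steps, prefer)
    runs = _runs_cyclic(point_labels)
    if len(runs) < 2:
        raise ValueError("contour shorter than two primitives")
    prims = []
    for start, length in runs:
        char_t, quad = point_labels[start]
        char = CharVector(*char_t)
        prims.append(
            Primitive(classify_primitive(char, quadrant=quad), start, length, char)
        )
    return prims


def biquad_convexity(switch_index: int, contour: Contour) -> int:
    """Convexity bit of the biquad transition at a contour point.

    1 iff the cross product of the incoming and outgoing step vectors at the
    point is positive (left turn under counterclockwise traversal); a zero
    cross product counts as convex with a logged warning.
    """
    pts = contour.points
    n = len(pts)
    s = switch_index % n
    d_in = pts[s] - pts[s - 1]
    d_out = pts[(s + 1) % n] - pts[s]
    cross = d_in[0] * d_out[1] - d_in[1] * d_out[0]
    if cross > 0:
        return 1
    if cross == 0:
        logger.warning(
            "biquad_convexity: degenerate tangency at point %d; treating as convex", s
        )
        return 1
    return 0


def build_sinquads(
    primitives: list[Primitive], contour: Contour
) -> tuple[list[Sinquad], list[Switch]]:
    """Group primitives into sinquads and emit one switch per transition.

    The switch position is the first contour point of the incoming sinquad —
    the shared boundary point where the travel direction changes quadrant.
    A contour confined to a single direction quadrant is rejected (a closed
    curve must wind through all four).
    """
    if not primitives:
        raise ValueError("empty primitive partition")
    groups: list[list[Primitive]] = []
    for prim in primitives:
        if groups and groups[-1][0].cls.j == prim.cls.j:
            groups[-1].append(prim)
        else:
            groups.append([prim])
    if len(groups) > 1 and groups[0][0].cls.j == groups[-1][0].cls.j:
        groups[-1].extend(groups.pop(0))  # cyclic wrap: same quadrant
    if len(groups) < 2:
        raise ValueError(
            "contour confined to a single direction quadrant; not a closed curve"
        )
    sinquads = [Sinquad(g[0].cls.j, tuple(g)) for g in groups]
    switches = []
    pts = contour.points
    for k, sq in enumerate(sinquads):
        prev_sq = sinquads[k - 1]
        idx = sq.start
        switches.append(
            Switch(
                index=idx,
                position=(float(pts[idx][0]), float(pts[idx][1])),
                from_quadrant=prev_sq.quadrant,
                to_quadrant=sq.quadrant,
                convexity=biquad_convexity(idx, contour),
            )
        )
    return sinquads, switches


# -- keys -------------------------------------------------------------------

_TOKEN_RE = re.compile(r"^[1-4][1-4][01]$")


@dataclass(frozen=True)
class Key:
    """Dot-separated sequence of biquad tokens, e.g. ``341.430.341.411``."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        for tok in self.tokens:
            if not _TOKEN_RE.match(tok):
                raise ValueError(f"malformed key token: {tok!r}")
            if tok[0] == tok[1]:
                raise ValueError(f"token quadrants must differ: {tok!r}")

    def __str__(self) -> str:
        return ".".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def rotated(self, k: int) -> "Key":
        k %= len(self.tokens)
        return Key(self.tokens[k:] + self.tokens[:k])


def parse_key(text: str) -> Key:
    """Parse the dot-separated key dialect; rejects malformed tokens."""
    if not text:
        raise ValueError("empty key")
    return Key(tuple(text.split(".")))


def encode_key(sinquads: list[Sinquad], switches: list[Switch]) -> Key:
    """Emit one token per switch, in traversal order."""
    if len(switches) != len(sinquads):
        raise ValueError("switch count must equal sinquad count on a closed contour")
    return Key(tuple(sw.token for sw in switches))


def canonicalize_key(key: Key) -> Key:
    """Cyclic rotation starting at the first ``34``-token.

    Keys in the vertebra domain conventionally begin at the 3->4 switch; if
    no token starts with ``34`` the lexicographically smallest rotation is
    used.  Callers with contour context should pre-rotate the switch list to
    the anchor point (topmost, then leftmost) before encoding, so "first"
    is geometrically well-defined when several ``34`` tokens exist.
    """
    for k, tok in enumerate(key.tokens):
        if tok.startswith("34"):
            return key.rotated(k)
    rotations = [key.rotated(k) for k in range(len(key.tokens))]
    return min(rotations, key=str)


#: Keys of healthy vertebrae or vertebrae with early pathological changes.
TYPICAL_KEYS = frozenset({"341.411", "341.430.341.411"})


def match_equivalence_class(key: Key | str) -> str:
    """Coarse routing of a canonicalized key: ``typical`` or ``atypical``.

    Typical keys describe healthy vertebrae or early pathological changes
    and are refined by the fuzzy stage; every other key (including ones
    never seen before) is atypical and maps to serious pathological changes.
    """
    text = str(key)
    return "typical" if text in TYPICAL_KEYS else "atypical"
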