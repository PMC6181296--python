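"""Hierarchical contour classification: key routing, alpha, fuzzy refinement.

The classifier proceeds in two levels.  First the contour is encoded into
its key; if the clinically relevant portion of the key (the switches in the
lower half of the contour, where syndesmophytes of the lower vertebral
margin manifest) is one of the typical strings ``341.411`` or
``341.430.341.411``, the vertebra is healthy or carries early changes and
is refined by the fuzzy stage on the angle alpha at the 4->1 switch.  Any
other key means serious pathological changes and short-circuits the fuzzy
stage.

Why a *clinical* key: a simple closed counterclockwise contour's direction
winds through all four quadrants, so its full cyclic key necessarily chains
through every quadrant (the upper contour contributes 1->2 and 2->3
switches).  The typical strings describe only the lower portion of the
outline; restricting the token sequence to the lower-margin run — from the
first 3->4 switch up to, but excluding, the first switch entering
quadrant 2 — recovers exactly those strings for rounded-quadrilateral
vertebra bodies while the full cyclic key remains available for general
shape analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contours import (
    DEFAULT_CURV_TOL,
    DEFAULT_STEP,
    DEFAULT_TOL,
    Contour,
    normalize_orientation,
    resample_contour,
)
from .fuzzy import ClassConfig, FuzzyResult, default_class_configs
from .language import (
    Key,
    Primitive,
    Sinquad,
    Switch,
    build_sinquads,
    canonicalize_key,
    encode_key,
    match_equivalence_class,
    segment_primitives,
)

logger = logging.getLogger("sinquad")

FINAL_HEALTHY = "healthy"
FINAL_SYN = "syndesmophyte"
FINAL_SERIOUS = "serious"


@dataclass(frozen=True)
class SwitchAngles:
    """Angles at the characteristic switches of the lower contour.

    ``alpha`` is the interior angle between the last minimal (one-step)
    primitive of the 4-sinquad and the first minimal primitive of the
    1-sinquad; ``beta`` the analogous angle at the 3->4 switch.  ``beta``
    is reported for completeness but drives no decision rule.
    """

    alpha: float | None
    beta: float | None


@dataclass(frozen=True)
class ContourEncoding:
    """Full provenance of the syntactic stage for one contour."""

    contour: Contour  # resampled, counterclockwise
    primitives: list[Primitive]
    sinquads: list[Sinquad]
    switches: list[Switch]  # anchored at the topmost-then-leftmost point
    key: Key  # full cyclic key, canonicalized
    clinical_key: Key  # lower-half switches only

    @property
    def key_str(self) -> str:
        return str(self.key)

    @property
    def clinical_key_str(self) -> str:
        return str(self.clinical_key)


@dataclass(frozen=True)
class Diagnosis:
    """Outcome of the hierarchical classifier for one contour."""

    key: str
    clinical_key: str
    coarse: str  # "typical" | "atypical"
    angles: SwitchAngles
    fuzzy: FuzzyResult | None
    final: str  # healthy | syndesmophyte | serious
    class_id: str

    @property
    def alpha(self) -> float | None:
        return self.angles.alpha

    def to_dict(self) -> dict:
        return {
            "class_id": self.class_id,
            "key": self.key,
            "clinical_key": self.clinical_key,
            "coarse": self.coarse,
            "alpha": self.angles.alpha,
            "beta": self.angles.beta,
            "fuzzy": self.fuzzy.to_dict() if self.fuzzy else None,
            "final": self.final,
        }


def _anchor_switches(switches: list[Switch], contour: Contour) -> list[Switch]:
    """Rotate the switch list to start after the topmost-then-leftmost point.

    This gives keys a deterministic, geometry-based token order before
    canonicalization (and breaks ties between multiple ``34`` tokens).
    """
    pts = contour.points
    order = np.lexsort((pts[:, 0], -pts[:, 1]))  # topmost, then leftmost
    anchor = int(order[0])
    n = len(pts)
    offsets = [((sw.index - anchor) % n, k) for k, sw in enumerate(switches)]
    offsets.sort()
    return [switches[k] for _, k in offsets]


def clinical_switches(switches: list[Switch], contour: Contour | None = None) -> list[Switch]:
    """Switches along the lower contour margin, in traversal order.

    The lesion considered by the decision rules sits at the lower vertebral
    margin, which the traversal covers from the switch where the direction
    first turns into quadrant 4 (the posterior-inferior 3->4 switch) until
    it turns up past vertical into quadrant 2 (the anterior-superior 1->2
    switch).  The input must be anchored at the topmost point (see
    :func:`_anchor_switches`), so that anchor lies on the upper margin and
    the lower run does not wrap around the list start.  Falls back to the
    full list when no 3->4 switch exists.
    """
    start = next(
        (k for k, sw in enumerate(switches)
         if sw.from_quadrant == 3 and sw.to_quadrant == 4),
        None,
    )
    if start is None:
        return list(switches)
    out: list[Switch] = []
    n = len(switches)
    for off in range(n):
        sw = switches[(start + off) % n]
        if sw.to_quadrant == 2:
            break
        out.append(sw)
    return out


def encode_contour(
    contour: Contour,
    step: float = DEFAULT_STEP,
    tol: float = DEFAULT_TOL,
    curv_tol: float = DEFAULT_CURV_TOL,
    min_primitive_steps: int = 1,
) -> ContourEncoding:
    """Run the full syntactic stage on a raw contour."""
    ccw = normalize_orientation(contour)
    res = resample_contour(ccw, step)
    prims = segment_primitives(res, tol, curv_tol, min_primitive_steps)
    sinquads, switches = build_sinquads(prims, res)
    switches = _anchor_switches(switches, res)
    key = canonicalize_key(encode_key(sinquads, switches))
    low = clinical_switches(switches, res)
    if low:
        clin = canonicalize_key(Key(tuple(sw.token for sw in low)))
    else:
        clin = key
    logger.debug("encode_contour: key=%s clinical=%s", key, clin)
    return ContourEncoding(res, prims, sinquads, switches, key, clin)


def _segment_direction(contour: Contour, index: int) -> np.ndarray:
    pts = contour.points
    return pts[(index + 1) % len(pts)] - pts[index]


def interior_angle(d_in: np.ndarray, d_out: np.ndarray) -> float:
    """Interior angle (degrees, in [0, 180]) at a vertex with incoming and
    outgoing direction vectors: 180 for a straight continuation, 90 for
    perpendicular segments, small for a sharp spur."""
    nin = np.linalg.norm(d_in)
    nout = np.linalg.norm(d_out)
    if nin == 0 or nout == 0:
        raise ValueError("zero-length direction vector")
    c = float(np.dot(-d_in, d_out) / (nin * nout))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _switch_angle(contour: Contour, sw: Switch) -> float:
    d_out = _segment_direction(contour, sw.index)
    d_in = _segment_direction(contour, sw.index - 1)
    return interior_angle(d_in, d_out)


def measure_alpha(
    switches: list[Switch], contour: Contour, clinical: bool = True
) -> float | None:
    """Alpha at the first 4->1 switch, in canonical clinical token order.

    The angle is measured between the minimal (one-step) segment ending the
    4-sinquad and the one opening the 1-sinquad.  ``None`` when the key has
    no 4->1 transition (the pipeline then routes to atypical handling).
    """
    pool = clinical_switches(switches, contour) if clinical else switches
    for sw in pool:
        if sw.from_quadrant == 4 and sw.to_quadrant == 1:
            return _switch_angle(contour, sw)
    return None


def measure_beta(
    switches: list[Switch], contour: Contour, clinical: bool = True
) -> float | None:
    """Beta, the analogous angle at the first 3->4 switch (reported only)."""
    pool = clinical_switches(switches, contour) if clinical else switches
    for sw in pool:
        if sw.from_quadrant == 3 and sw.to_quadrant == 4:
            return _switch_angle(contour, sw)
    return None


def classify_vertebra(
    contour: Contour,
    configs: dict[str, ClassConfig] | None = None,
    class_id: str = "K0",
    step: float = DEFAULT_STEP,
    tol: float = DEFAULT_TOL,
    curv_tol: float = DEFAULT_CURV_TOL,
) -> Diagnosis:
    """Hierarchical classification of one vertebra contour.

    The anatomical class ``class_id`` (K0..K5) is operator input: the
    classes differ anatomically and each carries its own fuzzy
    configuration.  Atypical keys map directly to serious pathological
    changes; typical keys are refined by the fuzzy stage on alpha.
    """
    if configs is None:
        configs = default_class_configs()
    if class_id not in configs:
        raise ValueError(f"unknown class_id {class_id!r}")
    enc = encode_contour(contour, step, tol, curv_tol)
    coarse = match_equivalence_class(enc.clinical_key)
    alpha = measure_alpha(enc.switches, enc.contour)
    beta = measure_beta(enc.switches, enc.contour)
    angles = SwitchAngles(alpha=alpha, beta=beta)
    if coarse == "atypical" or alpha is None:
        if coarse == "typical" and alpha is None:
            logger.warning("typical key without a 4->1 switch; routing to serious")
            coarse = "atypical"
        return Diagnosis(
            key=enc.key_str,
            clinical_key=enc.clinical_key_str,
            coarse="atypical",
            angles=angles,
            fuzzy=None,
            final=FINAL_SERIOUS,
            class_id=class_id,
        )
    from .fuzzy import classify_fuzzy  # local import keeps module deps one-way

    fuzzy = classify_fuzzy(alpha, configs[class_id])
    final = FINAL_SYN if fuzzy.decision == "syndesmophyte" else FINAL_HEALTHY
    return Diagnosis(
        key=enc.key_str,
        clinical_key=enc.clinical_key_str,
        coarse="typical",
        angles=angles,
        fuzzy=fuzzy,
        final=final,
        class_id=class_id,
    )
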