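"""Fuzzy refinement of typical vertebra contours by the switch angle alpha.

For each vertebra class ``K_0 .. K_5`` two trapezoidal membership functions
over the angle alpha (degrees, in [0, 180]) are defined: ``mu_syn`` for the
class with syndesmophyte (small, acute alpha) and ``mu_non_syn`` for the
healthy class (large, obtuse alpha).  Linguistic truth modifiers are derived
from areas under the membership graph,

    S_m_false = (b - a) * n / 4        for n in [0, 1]
    S_t       = (b - a) * n / 4        for n in [1, 2]
    S_m_true  = (b - a) * (n - 1) / n  for n in [2, +inf)

with ``b - a`` the support width of the function.  Normalizing the areas at
n = 1 and n = 2 by 100 gives the rule cut-offs (for the default class-K0
geometry: 0.29 and 0.58 for mu_syn, 0.23 and 0.45 for mu_non_syn), and the
dilation hedge — the square root of the upper cut-off — gives the "clearly
belongs" boundary (0.76 and 0.67).  The final decision assigns the vertebra
to the class with the greater membership value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from math import sqrt
from typing import Mapping

import yaml

logger = logging.getLogger("sinquad")

CLASS_IDS = ("K0", "K1", "K2", "K3", "K4", "K5")

LABEL_CLEARLY = "clearly_belongs"
LABEL_ALMOST = "almost_belongs"
LABEL_UNCLEAR = "unclear"
LABEL_NOT_MEMBER = "not_member"


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.225 -> 0.23), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TrapezoidMF:
    """Trapezoidal membership function over alpha in degrees.

    Zero outside ``[a, d]``, one on the plateau ``[b_left, b_right]``,
    linear on the shoulders.
    """

    a: float
    b_left: float
    b_right: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b_left <= self.b_right <= self.d):
            raise ValueError("trapezoid edges must satisfy a <= b_left <= b_right <= d")

    @property
    def support_width(self) -> float:
        """Width ``b - a`` of the support (the ``d - a`` span)."""
        return self.d - self.a

    def __call__(self, alpha: float) -> float:
        return membership(self, alpha)

    def area(self) -> float:
        """Closed-form area under the graph: plateau plus half shoulders."""
        return (self.b_right - self.b_left) + 0.5 * (
            (self.b_left - self.a) + (self.d - self.b_right)
        )


def membership(mf: TrapezoidMF, alpha: float) -> float:
    """Evaluate the trapezoid; ``alpha`` must lie in [0, 180] degrees."""
    if not 0.0 <= alpha <= 180.0:
        raise ValueError(f"alpha must be in [0, 180] degrees, got {alpha!r}")
    if alpha < mf.a or alpha > mf.d:
        return 0.0
    if mf.b_left <= alpha <= mf.b_right:
        return 1.0
    if alpha < mf.b_left:
        return (alpha - mf.a) / (mf.b_left - mf.a)
    return (mf.d - alpha) / (mf.d - mf.b_right)


def modifier_area(b_minus_a: float, n: float) -> float:
    """Area parameterizing the linguistic truth modifier ``n``.

    ``(b-a)*n/4`` on the false/intermediate branches (n in [0, 2]) and
    ``(b-a)*(n-1)/n`` on the true branch (n >= 2); the branches agree at
    the boundaries.
    """
    if b_minus_a <= 0:
        raise ValueError("support width must be positive")
    if n < 0:
        raise ValueError("modifier n must be non-negative")
    if n <= 2:
        return b_minus_a * n / 4.0
    return b_minus_a * (n - 1.0) / n


@dataclass(frozen=True)
class ModifierAreas:
    """The three branch areas evaluated at one modifier value ``n``."""

    n: float
    s_m_false: float  # (b-a) n/4, the label-"false" branch, n in [0, 1]
    s_t: float        # (b-a) n/4, the transitional branch, n in [1, 2]
    s_m_true: float   # (b-a)(n-1)/n, the label-"true" branch, n >= 2

    @classmethod
    def at(cls, b_minus_a: float, n: float) -> "ModifierAreas":
        if b_minus_a <= 0:
            raise ValueError("support width must be positive")
        if n < 0:
            raise ValueError("modifier n must be non-negative")
        linear = b_minus_a * n / 4.0
        true_branch = b_minus_a * (n - 1.0) / n if n > 0 else 0.0
        return cls(n=n, s_m_false=linear, s_t=linear, s_m_true=true_branch)


@dataclass(frozen=True)
class Thresholds:
    """Rule cut-offs derived from a membership function's support width."""

    not_member: float   # mu <= not_member: does not belong
    almost: float       # mu >= almost: belongs (almost, unless clearly)
    clearly: float      # mu >= clearly: clearly belongs (dilation hedge)

    @property
    def unclear_upper(self) -> float:
        """Upper edge of the unclear band (equals the ``almost`` cut-off)."""
        return self.almost

    def __post_init__(self) -> None:
        if not 0 <= self.not_member < self.almost < self.clearly <= 1:
            raise ValueError("thresholds must satisfy 0 <= not_member < almost < clearly <= 1")


def derive_thresholds(b_minus_a: float) -> Thresholds:
    """Thresholds from a support width, reproducing the printed rule bounds.

    ``not_member`` is the n=1 area over 100, ``almost`` the n=2 area over
    100, both rounded half-up to two decimals; ``clearly`` is the dilation
    (square root) of ``almost``, rounded the same way.  Width 115.6 yields
    (0.29, 0.58, 0.76) and width 90 yields (0.23, 0.45, 0.67).
    """
    if b_minus_a <= 0:
        raise ValueError("support width must be positive")
    not_member = round_half_up(modifier_area(b_minus_a, 1.0) / 100.0)
    almost = round_half_up(modifier_area(b_minus_a, 2.0) / 100.0)
    clearly = round_half_up(sqrt(almost))
    logger.debug(
        "derive_thresholds(width=%.3f): not_member=%.2f almost=%.2f clearly=%.2f",
        b_minus_a, not_member, almost, clearly,
    )
    return Thresholds(not_member=not_member, almost=almost, clearly=clearly)


def linguistic_label(mu: float, thresholds: Thresholds) -> str:
    """Map a membership value to the four-level linguistic scale."""
    if mu >= thresholds.clearly:
        return LABEL_CLEARLY
    if mu >= thresholds.almost:
        return LABEL_ALMOST
    if mu > thresholds.not_member:
        return LABEL_UNCLEAR
    return LABEL_NOT_MEMBER


#: Default class-K0 geometry: mu_syn has support [0, 115.6] with plateau up
#: to 90 degrees; mu_non_syn has support [90, 180] with plateau from 115.6.
#: The shoulders are complementary on the overlap [90, 115.6], so
#: mu_syn + mu_non_syn = 1 everywhere on [0, 180].
DEFAULT_MF_SYN = TrapezoidMF(a=0.0, b_left=0.0, b_right=90.0, d=115.6)
DEFAULT_MF_NON_SYN = TrapezoidMF(a=90.0, b_left=115.6, b_right=180.0, d=180.0)


@dataclass(frozen=True)
class ClassConfig:
    """Per-vertebra-class fuzzy configuration (K0 .. K5)."""

    class_id: str
    mf_syn: TrapezoidMF = DEFAULT_MF_SYN
    mf_non_syn: TrapezoidMF = DEFAULT_MF_NON_SYN
    thresholds_syn: Thresholds = field(default=None)  # type: ignore[assignment]
    thresholds_non_syn: Thresholds = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.class_id not in CLASS_IDS:
            raise ValueError(f"class_id must be one of {CLASS_IDS}")
        if self.thresholds_syn is None:
            object.__setattr__(
                self, "thresholds_syn", derive_thresholds(self.mf_syn.support_width)
            )
        if self.thresholds_non_syn is None:
            object.__setattr__(
                self,
                "thresholds_non_syn",
                derive_thresholds(self.mf_non_syn.support_width),
            )

    @property
    def support_width_syn(self) -> float:
        return self.mf_syn.support_width

    @property
    def support_width_non_syn(self) -> float:
        return self.mf_non_syn.support_width


def default_class_configs() -> dict[str, ClassConfig]:
    """One config per anatomical class; K1..K5 reuse the K0 geometry until
    calibrated from data."""
    return {cid: ClassConfig(class_id=cid) for cid in CLASS_IDS}


def load_class_configs(path) -> dict[str, ClassConfig]:
    """Load per-class trapezoid parameters from a YAML document.

    The document maps class ids to ``{syn: [a, b_left, b_right, d],
    non_syn: [a, b_left, b_right, d]}``; absent classes fall back to the
    defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    configs = default_class_configs()
    for cid, entry in doc.items():
        if cid not in CLASS_IDS:
            raise ValueError(f"unknown class id in config: {cid!r}")
        mf_syn = TrapezoidMF(*entry["syn"]) if "syn" in entry else DEFAULT_MF_SYN
        mf_non = (
            TrapezoidMF(*entry["non_syn"]) if "non_syn" in entry else DEFAULT_MF_NON_SYN
        )
        configs[cid] = ClassConfig(class_id=cid, mf_syn=mf_syn, mf_non_syn=mf_non)
    return configs


DECISION_SYN = "syndesmophyte"
DECISION_HEALTHY = "healthy"


@dataclass(frozen=True)
class FuzzyResult:
    """Both memberships, their linguistic labels, and the max-rule decision."""

    mu_syn: float
    mu_non_syn: float
    label_syn: str
    label_non_syn: str
    decision: str
    tie: bool = False

    def to_dict(self) -> dict:
        return {
            "mu_syn": self.mu_syn,
            "mu_non_syn": self.mu_non_syn,
            "mu_syn_display": f"{round_half_up(self.mu_syn):.2f}",
            "mu_non_syn_display": f"{round_half_up(self.mu_non_syn):.2f}",
            "label_syn": self.label_syn,
            "label_non_syn": self.label_non_syn,
            "decision": self.decision,
            "tie": self.tie,
        }


def classify_fuzzy(alpha: float, config: ClassConfig) -> FuzzyResult:
    """Evaluate both memberships at ``alpha`` and decide by the maximum.

    An exact tie is resolved conservatively to healthy, flagged and logged.
    """
    mu_s = membership(config.mf_syn, alpha)
    mu_ns = membership(config.mf_non_syn, alpha)
    tie = mu_s == mu_ns
    if tie:
        logger.warning(
            "classify_fuzzy: membership tie at alpha=%.3f (class %s); "
            "falling back to healthy", alpha, config.class_id,
        )
    decision = DECISION_SYN if mu_s > mu_ns else DECISION_HEALTHY
    return FuzzyResult(
        mu_syn=mu_s,
        mu_non_syn=mu_ns,
        label_syn=linguistic_label(mu_s, config.thresholds_syn),
        label_non_syn=linguistic_label(mu_ns, config.thresholds_non_syn),
        decision=decision,
        tie=tie,
    )
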