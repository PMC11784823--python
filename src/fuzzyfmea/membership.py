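"""Membership-function algebra and linguistic variables.

Triangular and trapezoidal membership functions (MFs) map a crisp score to
a degree of membership in [0, 1] for a linguistic term such as "low" or
"very high".  A :class:`LinguisticVariable` bundles an ordered family of
terms over a numeric universe — here the 1–10 rating scales for occurrence,
severity, detection, and the fuzzy risk priority number (fRPN).

Default variables follow the linguistic bands of the rating scales:
level 1 = {1}, level 2 = {2, 3}, level 3 = {4, 5, 6}, level 4 = {7, 8},
level 5 = {9, 10}.  Severity and detection use five triangular terms,
occurrence five trapezoidal terms, and the fRPN output ten triangular terms
peaked at the integer scores 1…10.  All breakpoints are configurable; the
defaults place full membership on each band's core and half-overlap
adjacent terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "MembershipParameterError",
    "OutOfRangeError",
    "TriangularMF",
    "TrapezoidalMF",
    "MembershipFunction",
    "LinguisticVariable",
    "occurrence_variable",
    "severity_variable",
    "detection_variable",
    "rpn_variable",
    "OCCURRENCE_LABELS",
    "SEVERITY_LABELS",
    "DETECTION_LABELS",
    "RPN_LABELS",
]


class MembershipParameterError(ValueError):
    """Raised when MF breakpoints violate their ordering invariant."""


class OutOfRangeError(ValueError):
    """Raised when a crisp input falls outside a variable's universe."""


@dataclass(frozen=True)
class TriangularMF:
    """Triangular MF with left foot ``a``, peak ``m``, right foot ``b``.

    Membership rises linearly on (a, m), equals 1 at m, falls linearly on
    (m, b), and is exactly 0 outside [a, b].  Degenerate shoulders (a == m
    or m == b) keep membership 1 at the shared breakpoint, so boundary
    terms of a universe stay well defined.
    """

    a: float
    m: float
    b: float

    def __post_init__(self) -> None:
        if not self.a <= self.m:
            raise MembershipParameterError(
                f"triangular MF requires a <= m, got a={self.a} > m={self.m}"
            )
        if not self.m <= self.b:
            raise MembershipParameterError(
                f"triangular MF requires m <= b, got m={self.m} > b={self.b}"
            )

    @property
    def support(self) -> tuple[float, float]:
        return (self.a, self.b)

    @property
    def prototype(self) -> float:
        """The crisp value with full membership (the peak)."""
        return self.m

    def __call__(self, x: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        xs = np.asarray(x, dtype=float)
        out = np.zeros(xs.shape)
        if self.a < self.m:
            rising = (xs > self.a) & (xs < self.m)
            out[rising] = (xs[rising] - self.a) / (self.m - self.a)
        if self.m < self.b:
            falling = (xs > self.m) & (xs < self.b)
            out[falling] = (self.b - xs[falling]) / (self.b - self.m)
        out[xs == self.m] = 1.0
        return out if out.ndim else float(out)

    def params(self) -> list[float]:
        return [self.a, self.m, self.b]


@dataclass(frozen=True)
class TrapezoidalMF:
    """Trapezoidal MF with feet ``a``/``d`` and plateau shoulders ``b``/``c``.

    Membership is 1 on [b, c], linear on the limbs, and exactly 0 outside
    [a, d].
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for lo, hi, names in (
            (self.a, self.b, "a <= b"),
            (self.b, self.c, "b <= c"),
            (self.c, self.d, "c <= d"),
        ):
            if not lo <= hi:
                raise MembershipParameterError(
                    f"trapezoidal MF requires {names}, got {lo} > {hi}"
                )

    @property
    def support(self) -> tuple[float, float]:
        return (self.a, self.d)

    @property
    def prototype(self) -> float:
        """Midpoint of the plateau (full-membership region)."""
        return 0.5 * (self.b + self.c)

    def __call__(self, x: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        xs = np.asarray(x, dtype=float)
        out = np.zeros(xs.shape)
        if self.a < self.b:
            rising = (xs > self.a) & (xs < self.b)
            out[rising] = (xs[rising] - self.a) / (self.b - self.a)
        if self.c < self.d:
            falling = (xs > self.c) & (xs < self.d)
            out[falling] = (self.d - xs[falling]) / (self.d - self.c)
        out[(xs >= self.b) & (xs <= self.c)] = 1.0
        return out if out.ndim else float(out)

    def params(self) -> list[float]:
        return [self.a, self.b, self.c, self.d]


MembershipFunction = Union[TriangularMF, TrapezoidalMF]


@dataclass(frozen=True)
class LinguisticVariable:
    """A named universe with an ordered family of fuzzy terms.

    Terms are ordered from lowest to highest risk level; their prototypes
    (peaks / plateau midpoints) must strictly increase, and every point of
    the universe must carry positive membership in at least one term.
    """

    name: str
    universe: tuple[float, float]
    terms: tuple[tuple[str, MembershipFunction], ...]

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise ValueError(f"universe must satisfy lo < hi, got [{lo}, {hi}]")
        if len(self.terms) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 terms")
        protos = [mf.prototype for _, mf in self.terms]
        if not all(p1 < p2 for p1, p2 in zip(protos, protos[1:])):
            raise ValueError(
                f"term prototypes of {self.name!r} must strictly increase "
                f"along the risk order, got {protos}"
            )
        # coverage: no gap in the union of supports on a dense probe grid
        probe = np.linspace(lo, hi, 1001)
        degrees = np.max([mf(probe) for _, mf in self.terms], axis=0)
        if np.any(degrees <= 0.0):
            gap = probe[np.argmax(degrees <= 0.0)]
            raise ValueError(
                f"terms of {self.name!r} do not cover the universe "
                f"(zero membership near x={gap:.3f})"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.terms)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def prototypes(self) -> np.ndarray:
        """Crisp prototype point of each term, in risk order."""
        return np.array([mf.prototype for _, mf in self.terms])

    def fuzzify(self, x: float) -> np.ndarray:
        """Membership degree of crisp ``x`` in each term (risk order).

        Raises :class:`OutOfRangeError` when x lies outside the universe;
        inputs are never silently clipped.
        """
        lo, hi = self.universe
        if not lo <= x <= hi:
            raise OutOfRangeError(
                f"{self.name}={x} outside universe [{lo}, {hi}]"
            )
        return np.array([float(mf(x)) for _, mf in self.terms])

    def grid(self, step: float) -> np.ndarray:
        """Uniform sampling of the universe with spacing ``step``."""
        lo, hi = self.universe
        if not 0 < step < hi - lo:
            raise ValueError(
                f"grid step must lie in (0, {hi - lo}), got {step}"
            )
        n = int(round((hi - lo) / step))
        return np.linspace(lo, hi, n + 1)


# ---------------------------------------------------------------------------
# Default linguistic variables for the 1-10 FMEA rating scales
# ---------------------------------------------------------------------------

OCCURRENCE_LABELS = ("almost none", "low", "medium", "high", "very high")
SEVERITY_LABELS = ("almost none", "low", "medium", "high", "very high")
# detection score 1 = certain detection (lowest risk), 10 = very low
# detectability (highest risk)
DETECTION_LABELS = ("certain", "high", "medium", "low", "very low")
RPN_LABELS = (
    "none",
    "very low",
    "low",
    "high low",
    "low medium",
    "medium",
    "high medium",
    "low high",
    "high",
    "very high",
)

_UNIVERSE = (1.0, 10.0)
# triangular peaks on the band midpoints of the 1-10 scale
_INPUT_PEAKS = (1.0, 2.5, 5.0, 7.5, 10.0)
# trapezoidal plateaus on the band cores
_OCCURRENCE_PLATEAUS = ((1, 1), (2, 3), (4, 6), (7, 8), (9, 10))


def _five_triangles(labels: Sequence[str], name: str) -> LinguisticVariable:
    peaks = _INPUT_PEAKS
    terms = []
    for i, label in enumerate(labels):
        a = peaks[i - 1] if i > 0 else peaks[0]
        b = peaks[i + 1] if i < len(peaks) - 1 else peaks[-1]
        terms.append((label, TriangularMF(a, peaks[i], b)))
    return LinguisticVariable(name, _UNIVERSE, tuple(terms))


def severity_variable() -> LinguisticVariable:
    """Default severity variable: five triangular terms on [1, 10]."""
    return _five_triangles(SEVERITY_LABELS, "severity")


def detection_variable() -> LinguisticVariable:
    """Default detection variable: five triangular terms, certain → very low."""
    return _five_triangles(DETECTION_LABELS, "detection")


def occurrence_variable() -> LinguisticVariable:
    """Default occurrence variable: five trapezoidal terms on [1, 10].

    Plateaus sit on the linguistic band cores [1,1], [2,3], [4,6], [7,8],
    [9,10]; each limb reaches the adjacent plateau edge.
    """
    plateaus = _OCCURRENCE_PLATEAUS
    terms = []
    for i, label in enumerate(OCCURRENCE_LABELS):
        b, c = (float(v) for v in plateaus[i])
        a = float(plateaus[i - 1][1]) if i > 0 else b
        d = float(plateaus[i + 1][0]) if i < len(plateaus) - 1 else c
        terms.append((label, TrapezoidalMF(a, b, c, d)))
    return LinguisticVariable("occurrence", _UNIVERSE, tuple(terms))


def rpn_variable() -> LinguisticVariable:
    """Default fRPN output variable: ten triangular terms peaked at 1…10."""
    terms = []
    for i, label in enumerate(RPN_LABELS):
        peak = float(i + 1)
        a = max(peak - 1.0, 1.0)
        b = min(peak + 1.0, 10.0)
        terms.append((label, TriangularMF(a, peak, b)))
    return LinguisticVariable("rpn", _UNIVERSE, tuple(terms))
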