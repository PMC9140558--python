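"""Fieller confidence sets for the gene-level skewness ratio.

The ratio gamma = b1 / bc (bc the averaged slope) admits a Wald pivot at
any hypothesized gamma0:

    (b1 - gamma0 * bc) / sqrt(V1 + gamma0^2 * Vc - 2 gamma0 * C1c)

Squaring and inverting the test gives a quadratic inequality
A g^2 + B g + C <= 0 with

    A = bc^2 - z^2 Vc,  B = 2 (z^2 C1c - b1 bc),  C = b1^2 - z^2 V1.

Depending on the signs of A and the discriminant the solution set is a
bounded interval, the complement of one (two pieces), the whole line, or
empty; the reported set is the intersection with [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .glm import RatioComponents

__all__ = ["IntervalEstimate", "point_estimate_gf", "fieller_ci"]

LOWER, UPPER = 0.0, 2.0
_NONINF_TOL = 1e-10  # endpoint slack when testing set == [0, 2]
_DELTA_TOL = 1e-12  # |discriminant| below this is treated as zero


@dataclass
class IntervalEstimate:
    """A point estimate plus a classified confidence/credible set in [0, 2].

    ``interval`` holds 0, 1 or 2 disjoint closed pieces.  Classification:
    ``regular`` (one proper piece), ``point`` (zero-width), ``empty``,
    ``noninformative`` (the whole [0, 2]) or ``discontinuous`` (two
    pieces).
    """

    point: float
    raw_point: float
    interval: list[tuple[float, float]]
    classification: str
    alpha: float
    method: str
    case: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def width(self) -> float:
        """Total length; the width of a two-piece set is the sum of pieces."""
        return float(sum(hi - lo for lo, hi in self.interval))

    def covers(self, gamma: float) -> bool:
        return any(lo <= gamma <= hi for lo, hi in self.interval)


def truncate(x: float) -> float:
    return float(min(max(x, LOWER), UPPER))


def point_estimate_gf(rc: RatioComponents) -> tuple[float, float]:
    """Raw ratio b1 / bc and its truncation to [0, 2].

    A zero denominator gives a signed infinity by the numerator sign;
    0/0 is NaN (degenerate, flagged by the caller).
    """
    if rc.betac == 0.0:
        raw = np.nan if rc.betac1 == 0.0 else np.inf * np.sign(rc.betac1)
    else:
        raw = rc.betac1 / rc.betac
    truncated = np.nan if np.isnan(raw) else truncate(raw)
    return float(raw), truncated


def _classify(pieces: list[tuple[float, float]]) -> str:
    """Post-truncation classification; precedence empty > noninformative >
    discontinuous > point > regular."""
    if not pieces:
        return "empty"
    if (
        len(pieces) == 1
        and abs(pieces[0][0] - LOWER) < _NONINF_TOL
        and abs(pieces[0][1] - UPPER) < _NONINF_TOL
    ):
        return "noninformative"
    if len(pieces) == 2:
        return "discontinuous"
    if pieces[0][1] - pieces[0][0] == 0.0:
        return "point"
    return "regular"


def _intersect(pieces: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out = []
    for lo, hi in pieces:
        lo, hi = max(lo, LOWER), min(hi, UPPER)
        if lo <= hi:
            out.append((lo, hi))
    return out


def solve_quadratic_set(A: float, B: float, C: float) -> tuple[list, dict]:
    """Solution set of A g^2 + B g + C <= 0 intersected with [0, 2].

    Returns (pieces, case record).  Covers the degenerate rows the
    four-case display omits: A = 0 solves the linear inequality, a
    near-zero discriminant collapses to the vertex point.
    """
    case: dict = {"A": A, "B": B, "C": C}
    if A == 0.0:
        case["branch"] = "linear"
        if B == 0.0:
            pieces = [(-np.inf, np.inf)] if C <= 0 else []
        else:
            root = -C / B
            pieces = [(-np.inf, root)] if B > 0 else [(root, np.inf)]
        return _intersect(pieces), case

    delta = B * B - 4.0 * A * C
    case["delta"] = delta
    if abs(delta) < _DELTA_TOL:
        delta = 0.0
    if delta == 0.0:
        vertex = -B / (2.0 * A)
        case["branch"] = "degenerate"
        # opens upward: only the vertex satisfies <=; downward: everywhere
        pieces = [(vertex, vertex)] if A > 0 else [(-np.inf, np.inf)]
    elif delta > 0:
        r = np.sqrt(delta)
        lo, hi = sorted(((-B - r) / (2.0 * A), (-B + r) / (2.0 * A)))
        if A > 0:
            case["branch"] = "bounded"
            pieces = [(lo, hi)]
        else:
            case["branch"] = "complement"
            pieces = [(-np.inf, lo), (hi, np.inf)]
    else:  # delta < 0: no real root
        case["branch"] = "no_root"
        pieces = [] if A > 0 else [(-np.inf, np.inf)]
    return _intersect(pieces), case


def fieller_ci(
    rc: RatioComponents, alpha: float = 0.05, method: str = "fieller"
) -> IntervalEstimate:
    """Fieller confidence set for gamma at level 1 - alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if rc.var_betac < 0 or rc.var_betac1 < 0:
        raise ValueError("variances must be nonnegative")
    z2 = stats.norm.ppf(1.0 - alpha / 2.0) ** 2
    A = rc.betac**2 - z2 * rc.var_betac
    B = 2.0 * (z2 * rc.cov_1c - rc.betac1 * rc.betac)
    C = rc.betac1**2 - z2 * rc.var_betac1
    flags = []
    if A == B == C == 0.0:
        raise ValueError("all components zero: confidence set undefined")
    pieces, case = solve_quadratic_set(A, B, C)
    raw, trunc = point_estimate_gf(rc)
    if np.isnan(raw):
        flags.append("degenerate_point")
    return IntervalEstimate(
        point=trunc,
        raw_point=raw,
        interval=pieces,
        classification=_classify(pieces),
        alpha=alpha,
        method=method,
        case=case,
        flags=flags,
    )
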