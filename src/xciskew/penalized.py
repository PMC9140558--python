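"""Penalized Fieller estimation of the skewness ratio.

The raw ratio explodes when the denominator estimate bc is near zero.
Maximizing the penalized log-likelihood

    pl(bc0) = -(bc - bc0)^2 / (2 Vc) + lam * log|bc0|

pushes the denominator away from zero:

    bc~ = bc / 2 + sign(bc) * sqrt(bc^2 / 4 + lam * Vc)

with shrinkage factor xi = bc~ / (2 bc~ - bc) and Var(bc~) = xi^2 Vc.
The numerator is bias-corrected by b1~ = b1 + g~ (bc~ - bc) with
g~ = b1 / bc~, and the corrected moments feed the same quadratic-set
machinery as the plain Fieller method.  With lam = z^2 / 4 the
pre-truncation set is always a bounded interval, so the penalized method
never yields a two-piece (discontinuous) set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fieller import IntervalEstimate, point_estimate_gf, solve_quadratic_set, truncate, _classify
from .glm import RatioComponents

__all__ = [
    "PenalizedComponents",
    "default_penalty",
    "penalize_denominator",
    "correct_numerator",
    "pf_estimate",
]


@dataclass
class PenalizedComponents:
    betac_t: float  # penalized denominator
    xi: float  # shrinkage factor
    lam: float
    var_betac_t: float
    gamma_t: float | None = None  # interim ratio b1 / penalized denominator
    betac1_t: float | None = None  # corrected numerator
    var_betac1_t: float | None = None
    cov_1c_t: float | None = None
    flags: list[str] | None = None


def default_penalty(alpha: float) -> float:
    """lam = z_{1-alpha/2}^2 / 4, the choice that guarantees a bounded set."""
    return float(stats.norm.ppf(1.0 - alpha / 2.0) ** 2 / 4.0)


def penalize_denominator(rc: RatioComponents, lam: float) -> PenalizedComponents:
    """Maximize the penalized log-likelihood of the denominator.

    sign(0) is taken as +1 so the fully degenerate point bc = 0 still
    yields the positive root +sqrt(lam * Vc); the event is flagged.
    """
    if lam <= 0:
        raise ValueError("penalty must be positive")
    flags: list[str] = []
    bc, vc = rc.betac, rc.var_betac
    if vc == 0.0:
        warnings.warn("zero denominator variance: penalization is a no-op", stacklevel=2)
        return PenalizedComponents(betac_t=bc, xi=1.0, lam=lam, var_betac_t=0.0, flags=["no_op"])
    s = 1.0 if bc >= 0 else -1.0
    if bc == 0.0:
        flags.append("sign_zero")
    betac_t = bc / 2.0 + s * np.sqrt(bc * bc / 4.0 + lam * vc)
    xi = betac_t / (2.0 * betac_t - bc)
    return PenalizedComponents(
        betac_t=float(betac_t),
        xi=float(xi),
        lam=lam,
        var_betac_t=float(xi * xi * vc),
        flags=flags,
    )


def correct_numerator(rc: RatioComponents, pc: PenalizedComponents) -> PenalizedComponents:
    """Bias-correct the numerator and propagate its moments.

    Var(b1~) = xi^-2 V1 - 4 (xi^-1 - 1) g~ C1c + 4 (1 - xi)^2 g~^2 Vc
    Cov(b1~, bc~) = C1c - 2 xi (1 - xi) g~ Vc

    In the zero-penalty limit xi -> 1 every correction term vanishes and
    the penalized moments reduce to the plain ones.  A negative computed
    variance (possible through the subtraction term) is floored at 0 and
    flagged.
    """
    if pc.xi == 0.0:
        raise RuntimeError("corrupted penalized state: xi = 0")
    flags = list(pc.flags or [])
    gamma_t = rc.betac1 / pc.betac_t
    betac1_t = rc.betac1 + gamma_t * (pc.betac_t - rc.betac)
    xi = pc.xi
    var1 = (
        rc.var_betac1 / xi**2
        - 4.0 * (1.0 / xi - 1.0) * gamma_t * rc.cov_1c
        + 4.0 * (1.0 - xi) ** 2 * gamma_t**2 * rc.var_betac
    )
    if var1 < 0.0:
        flags.append("var_floored")
        var1 = 0.0
    cov = rc.cov_1c - 2.0 * xi * (1.0 - xi) * gamma_t * rc.var_betac
    return PenalizedComponents(
        betac_t=pc.betac_t,
        xi=pc.xi,
        lam=pc.lam,
        var_betac_t=pc.var_betac_t,
        gamma_t=float(gamma_t),
        betac1_t=float(betac1_t),
        var_betac1_t=float(var1),
        cov_1c_t=float(cov),
        flags=flags,
    )


def pf_estimate(
    rc: RatioComponents, alpha: float = 0.05, lam: float | None = None
) -> IntervalEstimate:
    """Penalized point estimate and confidence set, truncated to [0, 2]."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if lam is None:
        lam = default_penalty(alpha)
    pc = correct_numerator(rc, penalize_denominator(rc, lam))
    if pc.var_betac_t == 0.0:
        # degenerate variances: the set collapses to the unpenalized point
        est = point_estimate_gf(rc)
        pt = est[1]
        return IntervalEstimate(
            point=pt,
            raw_point=est[0],
            interval=[(pt, pt)] if not np.isnan(pt) else [],
            classification="point" if not np.isnan(pt) else "empty",
            alpha=alpha,
            method="pf",
            flags=list(pc.flags or []),
        )
    z2 = stats.norm.ppf(1.0 - alpha / 2.0) ** 2
    A = pc.betac_t**2 - z2 * pc.var_betac_t
    B = 2.0 * (z2 * pc.cov_1c_t - pc.betac1_t * pc.betac_t)
    C = pc.betac1_t**2 - z2 * pc.var_betac1_t
    pieces, case = solve_quadratic_set(A, B, C)
    raw = pc.betac1_t / pc.betac_t
    return IntervalEstimate(
        point=truncate(raw),
        raw_point=float(raw),
        interval=pieces,
        classification=_classify(pieces),
        alpha=alpha,
        method="pf",
        case=case,
        flags=list(pc.flags or []),
    )
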