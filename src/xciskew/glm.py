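"""Working-model fits and the ratio components behind every estimator.

The two-slope working model regresses the trait on the burden pair:

    h(mu_i) = beta0 + b1 * x1_i + b2 * x2_i + b' z_i

with identity link (Gaussian errors) for quantitative traits and logit
link for case-control traits.  The skewness parameter of interest is the
ratio gamma = b1 / ((b1 + b2) / 2), so every downstream method consumes
the numerator coefficient, the averaged denominator coefficient, and
their (co)variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .burden import BurdenVariables

__all__ = [
    "FitResult",
    "RatioComponents",
    "fit_quantitative",
    "fit_qualitative",
    "derive_ratio_components",
]


class NonIdentifiableFitError(ValueError):
    """Design matrix rank-deficient (e.g. x1 identical to x2)."""


class UnstableFitError(RuntimeError):
    """Logistic fit diverged or the classes are separable."""


@dataclass
class FitResult:
    beta0: float
    betac1: float  # coefficient of x1
    betac2: float  # coefficient of x2
    b: np.ndarray  # covariate coefficients
    cov: np.ndarray  # 2x2 covariance of (betac1, betac2)
    full_cov: np.ndarray  # covariance of all coefficients, design order
    loglik: float
    trait_type: str
    sigma: float | None = None  # residual SD, quantitative only


@dataclass
class RatioComponents:
    """Numerator/denominator pair of the skewness ratio with its moments."""

    betac1: float
    betac: float
    var_betac1: float
    var_betac: float
    cov_1c: float


def _design(burden: BurdenVariables, Z: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(burden.x1), burden.x1, burden.x2]
    if Z is not None and np.size(Z):
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != burden.x1.shape[0]:
            Z = Z.T
        cols.extend(Z.T)
    D = np.column_stack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise NonIdentifiableFitError(
            "design matrix is rank deficient; the two burden variables "
            "may be identical (every carrier minor-homozygous)"
        )
    return D


def _pack(res, trait_type: str, sigma: float | None = None) -> FitResult:
    params = np.asarray(res.params)
    full_cov = np.asarray(res.cov_params())
    return FitResult(
        beta0=float(params[0]),
        betac1=float(params[1]),
        betac2=float(params[2]),
        b=params[3:].copy(),
        cov=full_cov[1:3, 1:3].copy(),
        full_cov=full_cov,
        loglik=float(res.llf),
        trait_type=trait_type,
        sigma=sigma,
    )


def fit_quantitative(
    y: np.ndarray, burden: BurdenVariables, Z: np.ndarray | None = None
) -> FitResult:
    """Gaussian/identity fit by OLS.

    The coefficient covariance uses the unbiased residual mean square on
    n - p degrees of freedom (standard Wald inference).
    """
    D = _design(burden, Z)
    y = np.asarray(y, dtype=float)
    if y.shape[0] <= D.shape[1]:
        raise ValueError("need more samples than model coefficients")
    res = sm.OLS(y, D).fit()
    sigma = float(np.sqrt(res.mse_resid))
    return _pack(res, "quantitative", sigma=sigma)


def fit_qualitative(
    y: np.ndarray, burden: BurdenVariables, Z: np.ndarray | None = None
) -> FitResult:
    """Logistic fit by Newton/IRLS; covariance is the inverse observed
    information at the MLE.

    Raises UnstableFitError on non-convergence or (quasi-)separation,
    detected through diverging coefficients.
    """
    D = _design(burden, Z)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise UnstableFitError("both classes must be present")
    try:
        res = sm.Logit(y, D).fit(disp=0, maxiter=100, tol=1e-8)
    except Exception as exc:  # singular Hessian etc.
        raise UnstableFitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise UnstableFitError("logistic fit did not converge")
    if np.any(np.abs(res.params) > 30):
        raise UnstableFitError("diverging coefficients suggest separation")
    return _pack(res, "qualitative")


def derive_ratio_components(fit: FitResult) -> RatioComponents:
    """Moments of the ratio numerator b1 and denominator (b1 + b2) / 2.

    Var of the mean coefficient is (V1 + V2 + 2 C12) / 4 and the
    numerator/denominator covariance is V1 / 2 + C12 / 2, the linear
    combination a = (1/2, 1/2) applied to the 2x2 fit covariance.
    """
    v1 = float(fit.cov[0, 0])
    v2 = float(fit.cov[1, 1])
    c12 = float(fit.cov[0, 1])
    return RatioComponents(
        betac1=fit.betac1,
        betac=0.5 * (fit.betac1 + fit.betac2),
        var_betac1=v1,
        var_betac=0.25 * (v1 + v2 + 2.0 * c12),
        cov_1c=0.5 * v1 + 0.5 * c12,
    )
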