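"""Synthetic gene/trait generator and the replicate study runner.

The generator emulates a single trait-associated gene of J SNPs typed in
n unrelated females:

* MAFs: common variants ~ U(0.01, 0.5), rare variants ~ U(0.005, 0.01),
  with ``eta`` the proportion of rare SNPs (positions random).
* Genotypes: each haplotype is a thresholded latent Gaussian vector with
  AR(1) correlation rho^|j-k| (linkage disequilibrium); the two
  haplotypes are independent, so marginals are Hardy-Weinberg.
* Skewed inactivation: heterozygote codes are replaced by the true
  gamma, so a heterozygote contributes gamma (not 1) to the genetic
  value.
* Effects: |beta_j| = e * |log10 MAF_j| / 2, with e = 1.5 for rare and
  1.1 for common SNPs; a fraction ``tau`` of SNPs (random positions) get
  a positive sign, the rest negative.
* Traits: quantitative y = beta0 + value . beta + delta * Q + N(0,
  sigma^2) with a standard-normal covariate Q; qualitative traits are
  Bernoulli-logit with subjects accumulated sequentially to an exact 1:1
  case-control ratio.

``run_study`` replays the full design: per replicate the truth gamma_s
is drawn from U(0, 2), data are simulated, MAFs and weights re-estimated
from the simulated sample, the two-slope model fitted, and all requested
estimators run.  ``compute_metrics`` reduces the replicate table to the
point- and interval-estimation summaries (MSE, extreme-value and
empty/noninformative/discontinuous proportions, coverage, width
statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import PriorSpec, SamplerConfig, bayes_estimate
from .burden import GeneDataset, beta_weights, build_burden, estimate_mafs
from .fieller import IntervalEstimate, fieller_ci, point_estimate_gf
from .glm import (
    NonIdentifiableFitError,
    UnstableFitError,
    derive_ratio_components,
    fit_qualitative,
    fit_quantitative,
)
from .penalized import pf_estimate

__all__ = [
    "SimConfig",
    "ReplicateResult",
    "simulate_mafs",
    "simulate_genotypes",
    "apply_xci_coding",
    "effect_sizes",
    "simulate_quantitative",
    "simulate_qualitative",
    "simulate_gene",
    "run_study",
    "compute_metrics",
    "metrics_frame",
]

ALL_METHODS = ("fieller", "pf", "gbn", "gbu")


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs; defaults are the evaluated conditions."""

    n: int = 500
    J: int = 100
    eta: float = 0.0  # proportion of rare SNPs
    tau: float = 0.6  # proportion of positive-effect SNPs
    rho: float = 0.5  # latent AR(1) correlation
    trait_type: str = "quantitative"
    beta0: float = 0.5
    delta: float = 0.5  # covariate effect
    e_rare: float = 1.5
    e_common: float = 1.1
    sigma_eps: float = 1.0
    reps: int = 500
    alpha: float = 0.05
    seed: int = 0
    gamma_truth: float | None = None  # None -> drawn U(0, 2) per replicate
    methods: tuple[str, ...] = ("fieller", "pf")
    bayes_config: SamplerConfig | None = None


@dataclass
class ReplicateResult:
    gamma_truth: float
    estimates: dict[str, IntervalEstimate] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def simulate_mafs(J: int, eta: float, rng: np.random.Generator):
    """Draw per-SNP MAFs; returns (mafs, rare_mask)."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    n_rare = int(np.floor(eta * J))
    rare = np.zeros(J, dtype=bool)
    rare[rng.choice(J, size=n_rare, replace=False)] = True
    mafs = rng.uniform(0.01, 0.5, size=J)
    mafs[rare] = rng.uniform(0.005, 0.01, size=n_rare)
    return mafs, rare


def simulate_genotypes(
    n: int, mafs: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Genotype codes from two independent thresholded AR(1) haplotypes.

    The latent vector follows V_j = rho V_{j-1} + sqrt(1 - rho^2) eps_j
    (stationary unit-variance AR(1)); the minor allele is called when
    V_j exceeds the (1 - MAF_j) normal quantile.
    """
    if not abs(rho) < 1.0:
        raise ValueError("|rho| must be < 1")
    mafs = np.asarray(mafs, dtype=float)
    J = mafs.size
    thresh = stats.norm.ppf(1.0 - mafs)
    code = np.zeros((n, J), dtype=np.int8)
    scale = np.sqrt(1.0 - rho * rho)
    for _ in range(2):  # two haplotypes per female
        eps = rng.standard_normal((n, J))
        V = np.empty((n, J))
        V[:, 0] = eps[:, 0]
        for j in range(1, J):
            V[:, j] = rho * V[:, j - 1] + scale * eps[:, j]
        code += V > thresh
    return code


def apply_xci_coding(codes: np.ndarray, gamma: float) -> np.ndarray:
    """Replace heterozygote codes by gamma; homozygotes keep 0/2."""
    if not 0.0 <= gamma <= 2.0:
        raise ValueError("gamma must lie in [0, 2]")
    values = np.asarray(codes, dtype=float).copy()
    values[np.asarray(codes) == 1] = gamma
    return values


def effect_sizes(
    mafs: np.ndarray,
    rare_flags: np.ndarray,
    tau: float,
    e_rare: float,
    e_common: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Signed per-SNP effects |beta_j| = e_j |log10 MAF_j| / 2."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0.0) | (mafs >= 1.0)):
        raise ValueError("MAFs must lie strictly in (0, 1)")
    J = mafs.size
    e = np.where(np.asarray(rare_flags, bool), e_rare, e_common)
    mag = e * np.abs(np.log10(mafs)) / 2.0
    signs = np.full(J, -1.0)
    n_pos = int(np.floor(tau * J))
    signs[rng.choice(J, size=n_pos, replace=False)] = 1.0
    return signs * mag


def simulate_quantitative(
    value_matrix, Q, betas, beta0, delta, sigma_eps, rng: np.random.Generator
) -> np.ndarray:
    value_matrix = np.asarray(value_matrix, dtype=float)
    y = beta0 + value_matrix @ betas + delta * np.asarray(Q, float)
    return y + sigma_eps * rng.standard_normal(value_matrix.shape[0])


def _qual_batch(n_draw, mafs, rho, gamma, betas, beta0, delta, rng):
    codes = simulate_genotypes(n_draw, mafs, rho, rng)
    Q = rng.standard_normal(n_draw)
    lin = beta0 + apply_xci_coding(codes, gamma) @ betas + delta * Q
    y = rng.random(n_draw) < 1.0 / (1.0 + np.exp(-lin))
    return codes, Q, y


def simulate_qualitative(
    n: int,
    mafs,
    rho,
    gamma,
    betas,
    beta0,
    delta,
    rng: np.random.Generator,
    max_attempts: int = 1_000_000,
):
    """Sequentially accumulate subjects to an exact 1:1 case-control split.

    Returns (codes, Q, y) with exactly n/2 cases and n/2 controls;
    surplus subjects of a full stratum are discarded.  A safety cap
    guards against degenerate prevalence.
    """
    if n % 2:
        raise ValueError("n must be even for a 1:1 case-control design")
    half = n // 2
    kept_codes, kept_Q, kept_y = [], [], []
    n_cases = n_controls = 0
    drawn = 0
    while n_cases < half or n_controls < half:
        if drawn >= max_attempts:
            raise RuntimeError("case-control accrual exceeded the attempt cap")
        batch = min(max(n, 256), max_attempts - drawn)
        codes, Q, y = _qual_batch(batch, mafs, rho, gamma, betas, beta0, delta, rng)
        drawn += batch
        for stratum, need in ((1, half - n_cases), (0, half - n_controls)):
            idx = np.flatnonzero(y == stratum)[: max(need, 0)]
            if idx.size:
                kept_codes.append(codes[idx])
                kept_Q.append(Q[idx])
                kept_y.append(y[idx])
                if stratum == 1:
                    n_cases += idx.size
                else:
                    n_controls += idx.size
    codes = np.concatenate(kept_codes)
    Q = np.concatenate(kept_Q)
    y = np.concatenate(kept_y).astype(float)
    return codes, Q, y


def simulate_gene(config: SimConfig, gamma: float, rng: np.random.Generator) -> GeneDataset:
    """One simulated dataset at the given true gamma."""
    mafs, rare = simulate_mafs(config.J, config.eta, rng)
    betas = effect_sizes(mafs, rare, config.tau, config.e_rare, config.e_common, rng)
    if config.trait_type == "quantitative":
        codes = simulate_genotypes(config.n, mafs, config.rho, rng)
        Q = rng.standard_normal(config.n)
        y = simulate_quantitative(
            apply_xci_coding(codes, gamma), Q, betas,
            config.beta0, config.delta, config.sigma_eps, rng,
        )
    else:
        codes, Q, y = simulate_qualitative(
            config.n, mafs, config.rho, gamma, betas, config.beta0, config.delta, rng
        )
    return GeneDataset(
        genotypes=codes, trait=y, trait_type=config.trait_type, covariates=Q[:, None]
    )


def analyze_gene(
    dataset: GeneDataset,
    methods=ALL_METHODS,
    alpha: float = 0.05,
    bayes_config: SamplerConfig | None = None,
) -> tuple[dict[str, IntervalEstimate], dict[str, str]]:
    """Run the requested estimators on one gene; failures are recorded,
    not raised."""
    import warnings as _w

    estimates: dict[str, IntervalEstimate] = {}
    failures: dict[str, str] = {}
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        mafs, codes = estimate_mafs(dataset.genotypes, recode=True)
    n = dataset.n_samples
    mafs_w = np.clip(mafs, 1.0 / (2 * n + 1), None)  # monomorphic guard
    ds = replace_genotypes(dataset, codes)
    weights = beta_weights(mafs_w)
    burden = build_burden(ds, weights)
    try:
        if ds.trait_type == "quantitative":
            fit = fit_quantitative(ds.trait, burden, ds.covariates)
        else:
            fit = fit_qualitative(ds.trait, burden, ds.covariates)
    except (NonIdentifiableFitError, UnstableFitError, ValueError) as exc:
        return estimates, {m: str(exc) for m in methods}
    rc = derive_ratio_components(fit)
    for method in methods:
        try:
            if method == "fieller":
                estimates[method] = fieller_ci(rc, alpha)
            elif method == "pf":
                estimates[method] = pf_estimate(rc, alpha)
            elif method in ("gbn", "gbu"):
                prior = PriorSpec(
                    gamma_prior="truncnorm" if method == "gbn" else "uniform"
                )
                _, gf_point = point_estimate_gf(rc)
                init = np.concatenate(
                    [
                        [fit.beta0, rc.betac, np.nan_to_num(gf_point, nan=1.0)],
                        fit.b,
                        [fit.sigma] if fit.sigma is not None else [],
                    ]
                )
                estimates[method] = bayes_estimate(
                    ds.trait, burden.x1, burden.x2, Z=ds.covariates,
                    prior=prior, trait_type=ds.trait_type,
                    config=bayes_config, alpha=alpha, init=init,
                )
            else:
                raise ValueError(f"unknown method {method!r}")
        except Exception as exc:  # per-method failure is recorded
            failures[method] = str(exc)
    return estimates, failures


def replace_genotypes(dataset: GeneDataset, codes: np.ndarray) -> GeneDataset:
    return GeneDataset(
        genotypes=codes,
        trait=dataset.trait,
        trait_type=dataset.trait_type,
        mafs=dataset.mafs,
        covariates=dataset.covariates,
        sample_ids=dataset.sample_ids,
        snp_ids=dataset.snp_ids,
    )


def run_study(config: SimConfig) -> list[ReplicateResult]:
    """Replicate loop: draw truth, simulate, estimate, record."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.reps)
    results = []
    for child in children:
        rng = np.random.default_rng(child)
        gamma = (
            rng.uniform(0.0, 2.0)
            if config.gamma_truth is None
            else float(config.gamma_truth)
        )
        dataset = simulate_gene(config, gamma, rng)
        bayes_cfg = config.bayes_config or SamplerConfig()
        bayes_cfg = replace(
            bayes_cfg, seed=int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
        )
        estimates, failures = analyze_gene(
            dataset, methods=config.methods, alpha=config.alpha, bayes_config=bayes_cfg
        )
        results.append(
            ReplicateResult(gamma_truth=gamma, estimates=estimates, failures=failures)
        )
    return results


def compute_metrics(results: list[ReplicateResult], alpha: float = 0.05) -> dict:
    """Reduce replicate results to the study's summary metrics.

    Conventions: an empty set never covers; the noninformative set [0, 2]
    always covers.  Width statistics exclude empty sets; a two-piece set
    contributes the sum of its piece lengths.  Extreme-value proportions
    count point estimates exactly 0 or exactly 2.  All proportions are
    fractions in [0, 1].
    """
    if not results:
        raise ValueError("no replicate results")
    methods = sorted({m for r in results for m in r.estimates})
    out: dict[str, dict] = {}
    for method in methods:
        pairs = [
            (r.gamma_truth, r.estimates[method]) for r in results if method in r.estimates
        ]
        truths = np.array([t for t, _ in pairs])
        ests = [e for _, e in pairs]
        points = np.array([e.point for e in ests])
        ok = ~np.isnan(points)
        widths = np.array([e.width for e in ests if e.classification != "empty"])
        cls = np.array([e.classification for e in ests])
        covered = np.array([e.covers(t) for t, e in pairs])
        R = len(ests)
        out[method] = {
            "reps": R,
            "failures": sum(1 for r in results if method in r.failures),
            "mse": float(np.mean((points[ok] - truths[ok]) ** 2)) if ok.any() else np.nan,
            "prop0": float(np.mean(points[ok] == 0.0)) if ok.any() else np.nan,
            "prop2": float(np.mean(points[ok] == 2.0)) if ok.any() else np.nan,
            "cp": float(np.mean(covered)),
            "wmean": float(np.mean(widths)) if widths.size else np.nan,
            "wmedian": float(np.median(widths)) if widths.size else np.nan,
            "wsd": float(np.std(widths, ddof=1)) if widths.size > 1 else np.nan,
            "wiqr": float(stats.iqr(widths)) if widths.size else np.nan,
            "ep": float(np.mean(cls == "empty")),
            "np": float(np.mean(cls == "noninformative")),
            "dp": float(np.mean(cls == "discontinuous")),
        }
    return out


def metrics_frame(metrics: dict) -> pd.DataFrame:
    """Tidy one-row-per-method table mirroring the study summaries."""
    return pd.DataFrame.from_dict(metrics, orient="index").rename_axis("method")
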