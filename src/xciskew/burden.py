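"""Gene-level burden decomposition of female X-chromosome genotypes.

A gene with J SNPs is collapsed into two weighted burden variables per
subject: ``x1`` counts (with MAF-based weights) the SNPs at which the
subject carries at least one minor allele, ``x2`` those at which she is
homozygous for the minor allele.  For any heterozygote genotypic value
``gamma`` in [0, 2] the weighted genotypic burden decomposes exactly as
``gamma * x1 + (2 - gamma) * x2``, which is what makes the gene-level
skewness parameter identifiable from a two-slope regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GeneDataset",
    "BurdenVariables",
    "estimate_mafs",
    "beta_weights",
    "build_burden",
    "weighted_gamma_identity",
]


@dataclass
class GeneDataset:
    """Female-only genotype/phenotype data for a single gene.

    genotypes holds minor-allele counts in {0, 1, 2}; ``trait_type`` is
    ``"quantitative"`` or ``"qualitative"`` (0/1 case-control).
    """

    genotypes: np.ndarray
    trait: np.ndarray
    trait_type: str
    mafs: np.ndarray | None = None
    covariates: np.ndarray | None = None
    sample_ids: list[str] | None = None
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.trait = np.asarray(self.trait, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D sample x SNP matrix")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype codes must be 0, 1 or 2")
        n, J = self.genotypes.shape
        if self.trait.shape != (n,):
            raise ValueError("trait length must match the number of samples")
        if self.trait_type not in ("quantitative", "qualitative"):
            raise ValueError("trait_type must be 'quantitative' or 'qualitative'")
        if self.trait_type == "qualitative" and not np.isin(self.trait, (0, 1)).all():
            raise ValueError("qualitative trait must be coded 0/1")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != n:
                raise ValueError("covariates must have one row per sample")
        m = 0 if self.covariates is None else self.covariates.shape[1]
        if n < m + 3:
            raise ValueError("need at least m + 3 samples to fit the model")
        if self.mafs is not None:
            self.mafs = np.asarray(self.mafs, dtype=float)
            if self.mafs.shape != (J,):
                raise ValueError("one MAF per SNP expected")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class BurdenVariables:
    """Weighted burden decomposition of one gene."""

    weights: np.ndarray
    x1: np.ndarray  # per-subject weighted count of SNPs with >=1 minor allele
    x2: np.ndarray  # per-subject weighted count of minor-homozygous SNPs
    carriers_any: np.ndarray  # per-SNP number of subjects with >=1 minor allele
    carriers_hom: np.ndarray  # per-SNP number of minor-homozygous subjects


def estimate_mafs(genotypes: np.ndarray, *, recode: bool = False):
    """Allele-frequency estimates from minor-allele count codes.

    ``maf_j = sum_i code_ij / (2n)``.  Monomorphic columns (all zero) are
    flagged with a warning; for weight evaluation the caller should clip
    them away from zero.  With ``recode=True``, columns whose estimated
    frequency exceeds 0.5 (minor/major labels inverted in the input) are
    flipped ``g -> 2 - g`` and the corrected matrix is returned alongside.
    """
    g = np.asarray(genotypes)
    n = g.shape[0]
    mafs = g.sum(axis=0) / (2.0 * n)
    mono = mafs == 0.0
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic SNP(s); clip MAF before weighting",
            stacklevel=2,
        )
    if not recode:
        return mafs
    flip = mafs > 0.5
    if flip.any():
        warnings.warn(
            f"{int(flip.sum())} SNP(s) with estimated MAF > 0.5 recoded g -> 2-g",
            stacklevel=2,
        )
        g = g.copy()
        g[:, flip] = 2 - g[:, flip]
        mafs = g.sum(axis=0) / (2.0 * n)
    return mafs, g


def beta_weights(mafs: np.ndarray, a: float = 0.5, b: float = 0.5) -> np.ndarray:
    """Beta(a, b) density evaluated at each MAF (the burden-test weight).

    The default a = b = 0.5 up-weights rare variants; the weight is strictly
    decreasing in MAF on (0, 0.5].  MAFs of exactly 0 or 1 give an infinite
    density and are rejected.
    """
    m = np.asarray(mafs, dtype=float)
    if np.any((m <= 0.0) | (m >= 1.0)):
        raise ValueError("degenerate weight: MAF must lie strictly in (0, 1)")
    return stats.beta.pdf(m, a, b)


def build_burden(dataset: GeneDataset, weights: np.ndarray) -> BurdenVariables:
    """Collapse a gene into the two burden variables x1 and x2."""
    w = np.asarray(weights, dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive and finite")
    g = dataset.genotypes
    any_minor = (g >= 1).astype(float)
    hom_minor = (g == 2).astype(float)
    return BurdenVariables(
        weights=w,
        x1=any_minor @ w,
        x2=hom_minor @ w,
        carriers_any=any_minor.sum(axis=0).astype(int),
        carriers_hom=hom_minor.sum(axis=0).astype(int),
    )


def weighted_gamma_identity(
    gammas_per_snp: np.ndarray,
    weights: np.ndarray,
    carriers_any: np.ndarray,
    carriers_hom: np.ndarray,
) -> float:
    """Gene-level gamma as the weighted mean of per-SNP skewness degrees.

    The effective weight of SNP j is ``w_j * (carriers_any_j -
    carriers_hom_j)``, i.e. proportional to the number of heterozygous
    carriers.  Undefined when every carrier is minor-homozygous at every
    SNP (zero denominator).
    """
    w = np.asarray(weights, dtype=float)
    eff = w * (np.asarray(carriers_any) - np.asarray(carriers_hom))
    denom = eff.sum()
    if denom == 0:
        raise ZeroDivisionError(
            "gene-level gamma undefined: no heterozygous carriers at any SNP"
        )
    return float(eff @ np.asarray(gammas_per_snp, dtype=float) / denom)
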