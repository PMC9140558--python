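"""Readers, quality control and phenotype preprocessing.

Genotypes arrive either as a VCF (biallelic X-chromosome sites, GT
field) or as a plain samples x SNPs TSV of minor-allele counts.  Missing
calls are carried as NaN through QC; subjects with any missing call in a
gene are dropped before estimation (the model has no missing-data
mechanism).  QC mirrors standard pre-analysis filters: genotype call
rate, MAF floor, individual call rate, and an exact Hardy-Weinberg test
on female diploid counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("xciskew")

__all__ = [
    "GeneMap",
    "read_genotypes",
    "write_genotype_tsv",
    "read_phenotypes",
    "qc_filter",
    "hwe_exact_p",
    "rank_inverse_normal",
]

DEFAULT_QC = {
    "geno_call_rate": 0.99,
    "maf_min": 1e-5,
    "ind_call_rate": 0.99,
    "hwe_p": 1e-6,
}


@dataclass
class GeneMap:
    """SNP -> gene assignment table with columns snp_id, gene_id
    (chrom/position optional)."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"snp_id", "gene_id"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"gene map must have columns {sorted(required)}")
        dup = self.table.duplicated(["gene_id", "snp_id"])
        if dup.any():
            raise ValueError("duplicate snp_id within a gene in the gene map")

    @classmethod
    def from_tsv(cls, path) -> "GeneMap":
        return cls(pd.read_csv(path, sep="\t"))

    def genes(self, min_snps: int = 2) -> dict[str, list[str]]:
        """gene_id -> snp list; genes below ``min_snps`` are flagged and
        skipped (single-SNP genes have dedicated single-locus methods)."""
        out = {}
        for gene, grp in self.table.groupby("gene_id"):
            snps = list(grp["snp_id"])
            if len(snps) < min_snps:
                logger.warning("gene %s has %d SNP(s); skipped", gene, len(snps))
                continue
            out[gene] = snps
        return out


def read_genotypes(path, fmt: str = "tsv", samples: list[str] | None = None) -> pd.DataFrame:
    """Genotype matrix (samples x SNPs) of alternate-allele counts.

    ``samples`` restricts to the listed individuals (e.g. unrelated
    females); reading fails if none remain.  Missing calls become NaN.
    Multi-allelic VCF sites are dropped with a log line.  Orientation to
    the minor allele happens later, at estimation time.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.apply(pd.to_numeric, errors="coerce")
    elif fmt == "vcf":
        df = _read_vcf(path)
    else:
        raise ValueError("format must be 'tsv' or 'vcf'")
    if samples is not None:
        keep = [s for s in df.index if s in set(samples)]
        df = df.loc[keep]
    if df.shape[0] == 0:
        raise ValueError("no samples left after filtering")
    bad = ~(df.isin((0, 1, 2)) | df.isna())
    if bad.any().any():
        raise ValueError("genotype codes outside {0, 1, 2, missing} found")
    return df


def _read_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names, cols = [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(variant.gt_types, dtype=float)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        codes = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        names.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        cols.append(codes)
    if n_multi:
        logger.info("dropped %d multi-allelic site(s)", n_multi)
    if not names:
        raise ValueError("no biallelic variants in VCF")
    return pd.DataFrame(np.column_stack(cols), index=list(vcf.samples), columns=names)


def write_genotype_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype/covariate table: sample_id, trait, then covariates."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError("phenotype file needs at least a trait column")
    return df


@lru_cache(maxsize=4096)
def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test p-value on diploid genotype counts.

    Conditions on the sample size and the minor-allele count and
    enumerates every heterozygote count of matching parity; under HWE
    P(het = h) is proportional to 2^h / (h! n_AA! n_aa!).  The p-value
    sums the probabilities of all outcomes no more likely than the
    observed one (the standard exact-test convention).
    """
    from scipy.special import gammaln

    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_min + 1)
        - gammaln(hom_maj + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    idx = np.flatnonzero(hets == n_het)
    if idx.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = probs[idx[0]]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def qc_filter(
    genotypes: pd.DataFrame, thresholds: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Standard pre-analysis filters on a samples x SNPs matrix with NaN
    missing calls.

    Removes, in order: SNPs with genotype call rate below threshold, SNPs
    with MAF below the floor, individuals with call rate below threshold,
    and SNPs failing the exact Hardy-Weinberg test.  Returns the filtered
    matrix and a per-criterion removal report.
    """
    th = {**DEFAULT_QC, **(thresholds or {})}
    df = genotypes.copy()
    report = {}

    call = df.notna().mean(axis=0)
    drop = call.index[call < th["geno_call_rate"]]
    report["geno_call_rate"] = list(drop)
    df = df.drop(columns=drop)

    with np.errstate(invalid="ignore"):
        freq = df.mean(axis=0, skipna=True) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
    drop = maf.index[(maf < th["maf_min"]) | maf.isna()]
    report["maf_min"] = list(drop)
    df = df.drop(columns=drop)

    ind_call = df.notna().mean(axis=1) if df.shape[1] else pd.Series(dtype=float)
    drop_ind = ind_call.index[ind_call < th["ind_call_rate"]]
    report["ind_call_rate"] = list(drop_ind)
    df = df.drop(index=drop_ind)

    hwe_fail = []
    for snp in df.columns:
        col = df[snp].dropna().astype(int)
        counts = col.value_counts()
        n_het = int(counts.get(1, 0))
        n2, n0 = int(counts.get(2, 0)), int(counts.get(0, 0))
        n_hom_minor, n_hom_major = (n2, n0) if n2 <= n0 else (n0, n2)
        if hwe_exact_p(n_het, n_hom_minor, n_hom_major) < th["hwe_p"]:
            hwe_fail.append(snp)
    report["hwe_p"] = hwe_fail
    df = df.drop(columns=hwe_fail)

    if df.shape[1] == 0:
        raise ValueError(f"all SNPs removed by QC: {report}")
    return df, report


def rank_inverse_normal(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets.

    Returns Phi^-1((rank - 3/8) / (n + 1/4)); ties get average ranks, so
    the output is invariant to any monotone transform of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to rank")
    if np.ptp(x) == 0.0:
        raise ValueError("constant trait cannot be rank-transformed")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size + 1.0 - 2.0 * offset))
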