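import numpy as np
import pytest

from xciskew.burden import GeneDataset, beta_weights, build_burden, estimate_mafs
from xciskew.simulate import replace_genotypes, simulate_genotypes, simulate_mafs


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_burden(n=200, J=10, seed=0, maf_low=0.05, maf_high=0.5):
    """Seeded burden variables from simulated genotypes (analysis-side
    weights, no trait)."""
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_low, maf_high, size=J)
    codes = simulate_genotypes(n, mafs, 0.5, rng)
    ds = GeneDataset(genotypes=codes, trait=np.zeros(n), trait_type="quantitative")
    est, codes2 = estimate_mafs(codes, recode=True)
    w = beta_weights(np.clip(est, 1.0 / (2 * n + 1), None))
    return build_burden(replace_genotypes(ds, codes2), w)


def working_model_data(n=500, gamma=1.0, betac=0.05, sigma=1.0, seed=0, J=20):
    """Data generated from the two-slope working model itself (well
    specified): y = b0 + betac*(gamma*x1 + (2-gamma)*x2) + delta*Q + eps."""
    rng = np.random.default_rng(seed)
    mafs, _ = simulate_mafs(J, 0.0, rng)
    codes = simulate_genotypes(n, mafs, 0.5, rng)
    ds = GeneDataset(genotypes=codes, trait=np.zeros(n), trait_type="quantitative")
    est, codes2 = estimate_mafs(codes, recode=True)
    w = beta_weights(np.clip(est, 1.0 / (2 * n + 1), None))
    burden = build_burden(replace_genotypes(ds, codes2), w)
    Q = rng.standard_normal(n)
    y = 0.5 + betac * (gamma * burden.x1 + (2.0 - gamma) * burden.x2) + 0.5 * Q
    if sigma > 0:
        y = y + sigma * rng.standard_normal(n)
    return y, burden, Q


def random_ratio_components(rng, weak=False):
    """Random but valid ratio components (positive-definite covariance)."""
    from xciskew.glm import RatioComponents

    b1 = rng.normal(0.0, 0.3)
    b2 = rng.normal(0.0, 0.3)
    betac = 0.5 * (b1 + b2)
    scale = 0.2 if weak else 0.05
    A = rng.normal(0.0, scale, size=(2, 2))
    cov = A @ A.T + 1e-6 * np.eye(2)
    v1 = cov[0, 0]
    vc = 0.25 * (cov[0, 0] + cov[1, 1] + 2.0 * cov[0, 1])
    c1c = 0.5 * cov[0, 0] + 0.5 * cov[0, 1]
    return RatioComponents(
        betac1=b1, betac=betac, var_betac1=v1, var_betac=vc, cov_1c=c1c
    )
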