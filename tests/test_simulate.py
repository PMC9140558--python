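"""Synthetic-data generator marginals and the study runner."""

import numpy as np
import pytest
from scipy import stats

from xciskew.simulate import (
    SimConfig,
    apply_xci_coding,
    compute_metrics,
    effect_sizes,
    run_study,
    simulate_genotypes,
    simulate_mafs,
    simulate_qualitative,
    simulate_quantitative,
)


class TestSimulateMafs:
    def test_eta_zero_all_common(self, rng):
        mafs, rare = simulate_mafs(100, 0.0, rng)
        assert not rare.any()
        assert np.all((mafs >= 0.01) & (mafs <= 0.5))

    def test_eta_one_all_rare(self, rng):
        mafs, rare = simulate_mafs(100, 1.0, rng)
        assert rare.all()
        assert np.all((mafs >= 0.005) & (mafs <= 0.01))

    def test_rare_maf_mean(self, rng):
        # U(0.005, 0.01) has mean 0.0075
        draws = [simulate_mafs(100, 0.4, rng) for _ in range(200)]
        rare_mafs = np.concatenate([m[r] for m, r in draws])
        assert len(rare_mafs) == 200 * 40
        se = (0.01 - 0.005) / np.sqrt(12 * len(rare_mafs))
        assert rare_mafs.mean() == pytest.approx(0.0075, abs=3 * se)


class TestSimulateGenotypes:
    def test_hardy_weinberg_marginals(self):
        # two independent haplotypes force HWE: chi-square GOF not rejected
        rng = np.random.default_rng(1)
        mafs = np.array([0.05, 0.2, 0.4])
        codes = simulate_genotypes(100_000, mafs, 0.5, rng)
        for j, m in enumerate(mafs):
            obs = np.bincount(codes[:, j], minlength=3)
            exp = 100_000 * np.array([(1 - m) ** 2, 2 * m * (1 - m), m**2])
            chi2 = ((obs - exp) ** 2 / exp).sum()
            assert stats.chi2.sf(chi2, df=2) > 0.001

    def test_carrier_frequency(self):
        rng = np.random.default_rng(2)
        m = 0.3
        codes = simulate_genotypes(100_000, np.array([m]), 0.5, rng)
        p_carrier = np.mean(codes[:, 0] >= 1)
        expect = 1 - (1 - m) ** 2
        assert p_carrier == pytest.approx(expect, abs=3 * np.sqrt(expect * (1 - expect) / 1e5))
        assert codes[:, 0].mean() == pytest.approx(2 * m, abs=0.01)

    def test_rho_zero_independence(self):
        rng = np.random.default_rng(3)
        codes = simulate_genotypes(50_000, np.full(2, 0.3), 0.0, rng)
        r = np.corrcoef(codes[:, 0], codes[:, 1])[0, 1]
        assert abs(r) < 3 / np.sqrt(50_000)

    def test_latent_correlation_matches_orthant_oracle(self):
        # allele-level correlation induced by latent rho: the joint carrier
        # probability is a bivariate-normal orthant probability
        rng = np.random.default_rng(4)
        m = 0.3
        n = 100_000
        codes = simulate_genotypes(n, np.full(2, m), 0.5, rng)
        t = stats.norm.ppf(1 - m)
        p11 = stats.multivariate_normal(
            mean=[0, 0], cov=[[1, 0.5], [0.5, 1]]
        ).cdf([-t, -t])  # P(V1 > t, V2 > t) by symmetry
        r_allele = (p11 - m * m) / (m * (1 - m))
        # genotype = sum of two iid haplotypes: same correlation
        r_emp = np.corrcoef(codes[:, 0], codes[:, 1])[0, 1]
        assert r_emp == pytest.approx(r_allele, abs=0.02)


class TestCoding:
    def test_gamma_one_identity(self, rng):
        codes = rng.integers(0, 3, size=(20, 5))
        np.testing.assert_array_equal(apply_xci_coding(codes, 1.0), codes)

    def test_gamma_zero_and_two(self):
        row = np.array([[0, 1, 2]])
        np.testing.assert_array_equal(apply_xci_coding(row, 0.0), [[0, 0, 2]])
        np.testing.assert_array_equal(apply_xci_coding(row, 2.0), [[0, 2, 2]])


class TestEffectSizes:
    def test_magnitudes(self, rng):
        mafs = np.array([0.1, 0.01])
        beta = effect_sizes(mafs, np.array([False, True]), 1.0, 1.5, 1.1, rng)
        assert abs(beta[0]) == pytest.approx(0.55)
        assert abs(beta[1]) == pytest.approx(1.5)

    def test_tau_one_all_positive(self, rng):
        mafs = np.full(50, 0.2)
        beta = effect_sizes(mafs, np.zeros(50, bool), 1.0, 1.5, 1.1, rng)
        assert np.all(beta > 0)

    def test_tau_sign_count(self, rng):
        beta = effect_sizes(np.full(100, 0.2), np.zeros(100, bool), 0.6, 1.5, 1.1, rng)
        assert (beta > 0).sum() == 60


class TestTraits:
    def test_deterministic_when_noiseless(self, rng):
        vals = rng.random((30, 4))
        betas = rng.normal(size=4)
        Q = rng.standard_normal(30)
        y = simulate_quantitative(vals, Q, betas, 0.5, 0.5, 0.0, rng)
        np.testing.assert_allclose(y, 0.5 + vals @ betas + 0.5 * Q)

    def test_variance_decomposition(self):
        rng = np.random.default_rng(9)
        mafs, rare = simulate_mafs(20, 0.0, rng)
        betas = effect_sizes(mafs, rare, 0.6, 1.5, 1.1, rng)
        codes = simulate_genotypes(20_000, mafs, 0.5, rng)
        vals = apply_xci_coding(codes, 1.2)
        Q = rng.standard_normal(20_000)
        y = simulate_quantitative(vals, Q, betas, 0.5, 0.5, 1.0, rng)
        explained = np.var(vals @ betas + 0.5 * Q)
        assert np.var(y) == pytest.approx(explained + 1.0, rel=0.05)

    def test_case_control_exact_balance(self):
        rng = np.random.default_rng(10)
        mafs, rare = simulate_mafs(10, 0.0, rng)
        betas = effect_sizes(mafs, rare, 0.6, 1.5, 1.1, rng) * 0.1
        codes, Q, y = simulate_qualitative(200, mafs, 0.5, 1.0, betas, 0.0, 0.5, rng)
        assert y.sum() == 100
        assert len(y) == 200 and codes.shape == (200, 10)

    def test_null_prevalence_half(self):
        rng = np.random.default_rng(11)
        mafs = np.full(5, 0.3)
        codes, Q, y = simulate_qualitative(
            400, mafs, 0.5, 1.0, np.zeros(5), 0.0, 0.0, rng
        )
        assert y.mean() == 0.5  # by construction

    def test_odd_n_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_qualitative(9, np.full(3, 0.3), 0.5, 1.0, np.zeros(3), 0.0, 0.0, rng)


class TestRunStudy:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n=200, J=20, reps=2, seed=33, methods=("fieller", "pf"))
        r1 = run_study(cfg)
        r2 = run_study(cfg)
        assert r1[0].gamma_truth == r2[0].gamma_truth
        for a, b in zip(r1, r2):
            for m in a.estimates:
                assert a.estimates[m].point == b.estimates[m].point
                assert a.estimates[m].interval == b.estimates[m].interval

    def test_replicates_complete(self):
        cfg = SimConfig(n=200, J=20, reps=5, seed=7, methods=("fieller", "pf"))
        results = run_study(cfg)
        assert len(results) == 5
        for r in results:
            assert 0.0 <= r.gamma_truth <= 2.0
            assert set(r.estimates) | set(r.failures) >= {"fieller", "pf"}


class TestComputeMetrics:
    def _mk(self, truth, point, pieces, classification):
        from xciskew.fieller import IntervalEstimate
        from xciskew.simulate import ReplicateResult

        est = IntervalEstimate(
            point=point, raw_point=point, interval=pieces,
            classification=classification, alpha=0.05, method="fieller",
        )
        return ReplicateResult(gamma_truth=truth, estimates={"fieller": est})

    def test_all_noninformative(self):
        res = [self._mk(t, 1.0, [(0.0, 2.0)], "noninformative") for t in (0.2, 1.9, 1.0)]
        m = compute_metrics(res)["fieller"]
        assert m["cp"] == 1.0 and m["np"] == 1.0 and m["wmean"] == 2.0

    def test_single_replicate_mse(self):
        m = compute_metrics([self._mk(1.0, 1.5, [(1.0, 2.0)], "regular")])["fieller"]
        assert m["mse"] == pytest.approx(0.25)

    def test_width_conventions_hand_count(self):
        # 2 empty, 3 noninformative, 5 regular of width 1:
        # EP 0.2, NP 0.3, width mean over the 8 nonempty = (3*2 + 5*1)/8
        res = (
            [self._mk(1.0, 0.0, [], "empty") for _ in range(2)]
            + [self._mk(1.0, 1.0, [(0.0, 2.0)], "noninformative") for _ in range(3)]
            + [self._mk(1.0, 1.0, [(0.5, 1.5)], "regular") for _ in range(5)]
        )
        m = compute_metrics(res)["fieller"]
        assert m["ep"] == pytest.approx(0.2)
        assert m["np"] == pytest.approx(0.3)
        assert m["wmean"] == pytest.approx(1.375)

    def test_empty_set_never_covers(self):
        m = compute_metrics([self._mk(1.0, 0.0, [], "empty")])["fieller"]
        assert m["cp"] == 0.0
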