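import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcnpatch import (
    CollateralConfig,
    contact_pmf,
    dcn_count_distribution,
    expected_contacted,
    joint_prob_x_dcns,
    prob_at_least,
    resample_means,
    simulate_wiring_counts,
)
from dcnpatch.convergence_stats import coefficient_of_variation as cv


def enumerated_pmf(y, m, p):
    """Brute-force oracle: sum probabilities over all 2^m contact patterns."""
    total = 0.0
    for pattern in range(2**m):
        k = bin(pattern).count("1")
        if k == y:
            total += p**k * (1 - p) ** (m - k)
    return total


class TestContactPmf:
    def test_matches_enumeration_m10(self):
        cfg = CollateralConfig(n=50, z=5, m=10)
        for y in range(11):
            assert contact_pmf(y, cfg) == pytest.approx(
                enumerated_pmf(y, 10, 0.1), abs=1e-12
            )

    def test_no_contact_probability(self):
        cfg = CollateralConfig(n=50, z=5, m=10)
        assert contact_pmf(0, cfg) == pytest.approx(0.9**10)
        assert contact_pmf(0, cfg) == pytest.approx(0.34868, abs=5e-6)

    def test_empty_presynaptic_population(self):
        assert contact_pmf(0, CollateralConfig(n=50, z=5, m=0)) == 1.0

    def test_y_above_m_rejected(self):
        with pytest.raises(ValueError):
            contact_pmf(11, CollateralConfig(n=50, z=5, m=10))

    @given(
        n=st.integers(2, 60),
        z=st.integers(1, 10),
        m=st.integers(0, 40),
    )
    @settings(max_examples=60, deadline=None)
    def test_pmf_normalizes(self, n, z, m):
        if z > n:
            return
        cfg = CollateralConfig(n=n, z=z, m=m)
        total = sum(contact_pmf(y, cfg) for y in range(m + 1))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestProbAtLeast:
    def test_y_zero_is_certain(self):
        assert prob_at_least(0, CollateralConfig(n=50, z=5, m=10)) == 1.0

    def test_expected_dcns_with_any_contact(self):
        # 50 * (1 - 0.9^10) = 32.566 -> 33 after rounding
        exact, rounded = expected_contacted(1, CollateralConfig(50, 5, 10))
        assert exact == pytest.approx(32.566, abs=5e-4)
        assert rounded == 33

    def test_convergent_excitation_from_33_neighbours(self):
        # P(>=2 of 33 at divergence 1:5) = 0.8558 -> 86%
        p = prob_at_least(2, CollateralConfig(50, 5, 33))
        assert round(100 * p) == 86

    def test_joint_distribution_normalizes(self):
        cfg = CollateralConfig(50, 5, 10)
        total = sum(joint_prob_x_dcns(x, 1, cfg) for x in range(51))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestWiringMonteCarlo:
    def test_counts_conserve_total_contacts(self):
        cfg = CollateralConfig(n=50, z=5, m=10)
        counts = simulate_wiring_counts(cfg, 100, seed=0)
        assert np.all(counts.sum(axis=1) == cfg.m * cfg.z)

    def test_analytic_pmf_matches_wiring_simulation(self):
        cfg = CollateralConfig(n=50, z=5, m=10)
        reps = 20_000
        counts = simulate_wiring_counts(cfg, reps, seed=1)
        for y in (0, 1, 2):
            frac = (counts == y).mean()  # over reps*n DCN slots
            expected = contact_pmf(y, cfg)
            se = np.sqrt(expected * (1 - expected) / reps)  # conservative
            assert abs(frac - expected) < 3 * se

    def test_mean_contacted_matches_analytic(self):
        cfg = CollateralConfig(n=50, z=5, m=10)
        counts = simulate_wiring_counts(cfg, 20_000, seed=2)
        contacted = (counts >= 1).sum(axis=1)
        exact, _ = expected_contacted(1, cfg)
        se = contacted.std(ddof=1) / np.sqrt(contacted.size)
        assert abs(contacted.mean() - exact) < 3 * se


class TestCountDistribution:
    def test_zero_rate_is_point_mass_at_zero(self):
        dist = dcn_count_distribution(rate_hz=0.0, seed=0)
        assert np.all(dist.raw == 0)
        assert np.all(dist.rolled == 0)

    def test_mean_matches_binomial_oracle(self):
        # refractory off: E[count] = 40 * rate * 0.001 exactly
        means = []
        for seed in range(20):
            dist = dcn_count_distribution(rate_hz=147.5, refractory_ms=0.0,
                                          seed=seed)
            means.append(dist.raw.mean())
        expected = 40 * 147.5 * 0.001
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - expected) < 3 * se

    def test_rolling_narrows_distribution(self):
        sds = {"raw": [], "rolled": []}
        for seed in range(10):
            dist = dcn_count_distribution(seed=seed)
            sds["raw"].append(dist.raw.std())
            sds["rolled"].append(dist.rolled.std())
        assert np.mean(sds["rolled"]) < np.mean(sds["raw"])


class TestResampling:
    def test_constant_source_gives_zero_cv(self):
        means = resample_means(np.full(50, 7.0), seed=0)
        assert cv(means) == 0.0

    def test_clt_cv_reduction_sqrt5(self):
        # near-normal source; SE of a 5-sample mean = SD/sqrt(5)
        rng = np.random.default_rng(0)
        source = rng.binomial(40, 0.15, size=2000).astype(float)
        means = resample_means(source, resample_count=20_000, sample_size=5,
                               seed=1)
        ratio = cv(source) / cv(means)
        assert ratio == pytest.approx(np.sqrt(5), rel=0.06)

    def test_sample_size_one_preserves_cv(self):
        rng = np.random.default_rng(2)
        source = rng.normal(10, 2, size=500)
        means = resample_means(source, resample_count=20_000, sample_size=1,
                               seed=3)
        assert cv(means) == pytest.approx(cv(source), rel=0.05)

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            resample_means([], seed=0)
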