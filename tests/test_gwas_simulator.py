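"""Synthetic haplotypes, effect draws and summary-statistic generation."""

import numpy as np
import pytest
from scipy import stats as sps

from colocpriors.gwas_simulator import (
    SimConfig,
    SimulatedPair,
    SimulationError,
    draw_effect,
    expected_z,
    simulate_haplotypes,
    simulate_pair,
    simulate_stats,
)
from colocpriors.fixtures import shape_density
from colocpriors.prior_sources import density_to_weights


class TestSimulateHaplotypes:
    def test_zero_decay_gives_near_independence(self):
        config = SimConfig(n_variants=40, ld_decay=0.0, n_haplotypes=10_000, seed=2)
        _, ld, _ = simulate_haplotypes(config)
        off = ld.r[np.triu_indices(40, 1)]
        assert np.abs(off).max() < 0.1

    def test_same_seed_reproduces_everything(self):
        config = SimConfig(n_variants=30, ld_decay=0.9, seed=7)
        h1, ld1, maf1 = simulate_haplotypes(config)
        h2, ld2, maf2 = simulate_haplotypes(config)
        np.testing.assert_array_equal(h1, h2)
        np.testing.assert_array_equal(ld1.r, ld2.r)
        np.testing.assert_array_equal(maf1, maf2)

    def test_high_decay_gives_high_adjacent_correlation(self):
        # latent AR(0.95) thresholded to alleles: adjacent binary r above 0.5
        # (tetrachoric attenuation keeps it below the latent 0.95)
        config = SimConfig(n_variants=100, ld_decay=0.95, ld_block_sizes=[50, 50],
                           maf_range=(0.1, 0.5), n_haplotypes=10_000, seed=1)
        _, ld, _ = simulate_haplotypes(config)
        adj = np.delete(np.diag(ld.r, 1), 49)  # drop the block boundary
        assert adj.mean() > 0.5

    def test_exchangeable_model_gives_plateau(self):
        config = SimConfig(n_variants=60, ld_decay=0.95, ld_model="exchangeable",
                           ld_block_sizes=[60], maf_range=(0.1, 0.5),
                           n_haplotypes=10_000, seed=3)
        _, ld, _ = simulate_haplotypes(config)
        off = ld.r[np.triu_indices(60, 1)]
        assert off.min() > 0.3  # every pair correlated, not just neighbours

    def test_maf_within_bounds(self):
        config = SimConfig(n_variants=50, seed=4)
        _, _, maf = simulate_haplotypes(config)
        assert np.all((maf > 0) & (maf <= 0.5))


class TestDrawEffect:
    def test_mean_matches_order_statistic(self):
        # E[max of 100 N(0,1)] = 2.50759...; effects are scaled by sd 0.05
        rng = np.random.default_rng(5)
        config = SimConfig()
        draws = np.array([draw_effect(config, rng) for _ in range(10_000)])
        expected_mean = 0.05 * 2.50759
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected_mean) < 2 * se + 1e-3
        assert np.all(draws > 0)

    def test_seeded_draw_reproducible(self):
        config = SimConfig(seed=11)
        assert draw_effect(config) == draw_effect(config)


class TestExpectedZ:
    def _ld(self, q=3):
        from colocpriors.region_data import LDMatrix

        r = np.eye(q)
        r[0, 1] = r[1, 0] = 1.0
        return LDMatrix([f"v{i}" for i in range(q)], r)

    def test_null_effect_gives_zero_means(self):
        mu, _ = expected_z(0, 0.0, self._ld(), np.array([0.3, 0.3, 0.3]), SimConfig())
        np.testing.assert_array_equal(mu, 0.0)

    def test_perfect_proxy_shares_the_causal_mean(self):
        mu, _ = expected_z(0, 0.2, self._ld(), np.array([0.3, 0.3, 0.3]), SimConfig())
        assert mu[1] == pytest.approx(mu[0])

    def test_causal_mean_closed_form(self):
        # gamma=0.2, f=0.3, phi=0.5, N=4000: mu_c = 0.2 * sqrt(2*0.21*0.25*4000)
        config = SimConfig(n_cases=2000, n_controls=2000)
        mu, se = expected_z(0, 0.2, self._ld(), np.array([0.3, 0.3, 0.3]), config)
        expected = 0.2 * np.sqrt(2 * 0.3 * 0.7 * 0.25 * 4000)
        assert mu[0] == pytest.approx(expected, rel=1e-12)
        assert se[0] == pytest.approx(1 / np.sqrt(2 * 0.3 * 0.7 * 0.25 * 4000), rel=1e-12)

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError, match="maf"):
            expected_z(0, 0.1, self._ld(), np.array([0.0, 0.3, 0.3]), SimConfig())


class TestSimulateStats:
    def test_accepted_draw_satisfies_min_p_rule(self):
        rng = np.random.default_rng(6)
        config = SimConfig(n_variants=50, ld_decay=0.9, seed=None)
        _, ld, maf = simulate_haplotypes(config, rng)
        for _ in range(5):
            gamma = draw_effect(config, rng)
            stats, attempts = simulate_stats(0, gamma, ld, maf, config, rng)
            assert stats.pvalues().min() < config.min_p
            assert 1 <= attempts <= config.max_attempts

    def test_strong_effect_accepted_first_attempt(self):
        rng = np.random.default_rng(7)
        config = SimConfig(n_variants=20, seed=None)
        _, ld, maf = simulate_haplotypes(config, rng)
        # mu_c = 10 makes the acceptance event essentially certain
        gamma = 10.0 / np.sqrt(2 * maf[0] * (1 - maf[0]) * 0.25 * config.n_total)
        attempts = [simulate_stats(0, gamma, ld, maf, config, rng)[1] for _ in range(20)]
        assert np.mean(attempts) < 1.5

    def test_unreachable_threshold_raises(self):
        rng = np.random.default_rng(8)
        config = SimConfig(n_variants=10, min_p=1e-300, max_attempts=5, seed=None)
        _, ld, maf = simulate_haplotypes(config, rng)
        with pytest.raises(SimulationError, match="5 attempts"):
            simulate_stats(0, 0.0, ld, maf, config, rng)

    def test_end_to_end_reproducible(self):
        config = SimConfig(n_variants=30, seed=9)
        _, ld, maf = simulate_haplotypes(config)
        a, _ = simulate_stats(3, 0.3, ld, maf, config, np.random.default_rng(1))
        b, _ = simulate_stats(3, 0.3, ld, maf, config, np.random.default_rng(1))
        np.testing.assert_array_equal(a.beta, b.beta)


def _pair_setup(seed=10, q=60):
    rng = np.random.default_rng(seed)
    # permissive acceptance: keeps the many-replicate tests fast
    config = SimConfig(n_variants=q, ld_decay=0.9, min_p=0.5, seed=None)
    _, ld, maf = simulate_haplotypes(config, rng)
    tss = 1_000_000
    positions = np.sort(rng.choice(
        np.arange(tss - 500_000, tss + 500_000), size=q, replace=False)).astype(np.int64)
    density = shape_density("laplace_at_tss")
    return rng, config, ld, maf, tss, positions, density


class TestSimulatePair:
    def test_h4_shares_the_causal_variant(self):
        rng, config, ld, maf, tss, positions, density = _pair_setup()
        for _ in range(10):
            pair = simulate_pair("H4", density, tss, "+", positions, ld, maf, config, rng)
            assert pair.causal1 == pair.causal2

    def test_h3_draws_a_distinct_causal_variant(self):
        rng, config, ld, maf, tss, positions, density = _pair_setup(seed=11)
        for _ in range(10):
            pair = simulate_pair("H3", density, tss, "+", positions, ld, maf, config, rng)
            assert pair.causal1 != pair.causal2

    def test_causal_sampling_follows_the_supplied_density(self):
        # goodness of fit of causal1 draws against the density-derived
        # sampling weights, chi-squared over 10 equal-probability bins
        rng, config, ld, maf, tss, positions, density = _pair_setup(seed=12)
        weights = density_to_weights(density, positions, tss, "+",
                                     variant_ids=ld.variant_ids)
        prob = weights.w / weights.w.sum()
        draws = np.array([
            simulate_pair("H4", density, tss, "+", positions, ld, maf, config, rng).causal1
            for _ in range(2000)
        ])
        edges = np.searchsorted(np.cumsum(prob), np.linspace(0.1, 0.9, 9))
        bins = np.concatenate([[0], edges, [len(prob)]])
        observed = np.histogram(draws, bins=bins)[0]
        expected = np.array([prob[bins[i]:bins[i + 1]].sum() for i in range(10)]) * len(draws)
        keep = expected > 0
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = sps.chi2.sf(chi2, df=keep.sum() - 1)
        assert p > 0.001

    def test_pair_invariants_enforced(self):
        rng, config, ld, maf, tss, positions, density = _pair_setup(seed=13)
        pair = simulate_pair("H4", density, tss, "+", positions, ld, maf, config, rng)
        with pytest.raises(ValueError, match="H4"):
            SimulatedPair(pair.stats1, pair.stats2, "H4", 1, 2, ld, (1, 1))

    def test_reproducible_given_seed(self):
        _, config, ld, maf, tss, positions, density = _pair_setup(seed=14)
        a = simulate_pair("H3", density, tss, "+", positions, ld, maf, config,
                          np.random.default_rng(99))
        b = simulate_pair("H3", density, tss, "+", positions, ld, maf, config,
                          np.random.default_rng(99))
        assert (a.causal1, a.causal2) == (b.causal1, b.causal2)
        np.testing.assert_array_equal(a.stats1.beta, b.stats1.beta)
        np.testing.assert_array_equal(a.stats2.beta, b.stats2.beta)
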