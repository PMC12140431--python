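"""Distance densities, bandwidth selection and the weight builders."""

import numpy as np
import pytest

from colocpriors.prior_sources import (
    ABC_MISSING_SCORE,
    AbcRecord,
    DENSITY_GRID_SIZE,
    DistanceDensity,
    EqtlRecord,
    GnocchiRecord,
    PolyFunRecord,
    abc_to_weights,
    density_to_weights,
    estimate_density,
    gnocchi_to_weights,
    polyfun_to_weights,
    read_density,
    sheather_jones_bandwidth,
    signed_distance,
    top_eqtl_per_gene,
    write_density,
)
from colocpriors.region_data import ValidationError


class TestSignedDistance:
    @pytest.mark.parametrize(
        "pos,tss,strand,expected",
        [(110, 100, "+", 10), (110, 100, "-", -10), (100, 100, "+", 0), (100, 100, "-", 0)],
    )
    def test_orientation(self, pos, tss, strand, expected):
        assert signed_distance(pos, tss, strand) == expected


class TestTopEqtlPerGene:
    def test_keeps_minimum_p_per_gene(self):
        recs = [
            EqtlRecord("g1", 150, 100, "+", 1e-9, "v1"),
            EqtlRecord("g1", 200, 100, "+", 1e-12, "v2"),
        ]
        out = top_eqtl_per_gene(recs)
        assert len(out) == 1 and out[0].variant_id == "v2"

    def test_gene_below_threshold_dropped(self):
        recs = [EqtlRecord("g1", 150, 100, "+", 1e-7, "v1")]
        assert top_eqtl_per_gene(recs) == []

    def test_tie_break_matches_exhaustive_scan(self):
        # ties at the minimal p resolve by TSS distance then variant id
        rng = np.random.default_rng(8)
        recs = []
        for g in range(5):
            p_min = 10.0 ** rng.uniform(-12, -9)
            for k in range(6):
                recs.append(
                    EqtlRecord(
                        f"g{g}",
                        int(1000 + rng.integers(-500, 500)),
                        1000,
                        "+",
                        p_min if k < 3 else p_min * 10,
                        f"g{g}v{k}",
                    )
                )
        out = {r.gene_id: r for r in top_eqtl_per_gene(recs)}
        for g in range(5):
            gene_recs = [r for r in recs if r.gene_id == f"g{g}"]
            best_p = min(r.p_value for r in gene_recs)
            tied = [r for r in gene_recs if r.p_value == best_p]
            best_d = min(abs(r.variant_pos - r.tss) for r in tied)
            tied = [r for r in tied if abs(r.variant_pos - r.tss) == best_d]
            expected = min(tied, key=lambda r: r.variant_id)
            assert out[f"g{g}"].variant_id == expected.variant_id


class TestSheatherJones:
    def test_matches_r_solve_the_equation_oracle(self):
        # frozen oracle: solving the plug-in equation with exact (unbinned)
        # pairwise functionals in R gives 5265.224 for this seeded sample
        rng = np.random.default_rng(2024)
        x = rng.laplace(0.0, 30000.0, size=2000)
        x = x[np.abs(x) <= 500000]
        assert sheather_jones_bandwidth(x) == pytest.approx(5265.224, rel=0.01)

    def test_matches_r_bw_sj_on_bimodal_sample(self):
        # frozen oracle: R's stats::bw.SJ returns 0.20701727 for this sample
        rng = np.random.default_rng(2024)
        rng.laplace(0.0, 30000.0, size=2000)  # advance the stream as when frozen
        y = np.concatenate([rng.normal(0, 1, 500), rng.normal(4, 0.5, 300)])
        assert sheather_jones_bandwidth(y) == pytest.approx(0.20701727, rel=0.01)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            sheather_jones_bandwidth(np.full(100, 3.0))


class TestEstimateDensity:
    def test_grid_has_512_pairs_spanning_data_range(self):
        rng = np.random.default_rng(1)
        d = rng.laplace(0, 30_000, 1000)
        dens = estimate_density(d)
        assert len(dens.grid) == DENSITY_GRID_SIZE
        assert len(dens.density) == DENSITY_GRID_SIZE
        inside = d[np.abs(d) <= 500_000]
        assert dens.grid[0] == pytest.approx(inside.min())
        assert dens.grid[-1] == pytest.approx(inside.max())

    def test_integral_close_to_one_for_peaked_density(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0, 50_000, 10_000)
        dens = estimate_density(d)
        assert 0.95 <= dens.integral() <= 1.05

    def test_identical_distances_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            estimate_density(np.full(100, 1000.0))

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValidationError, match="pool"):
            estimate_density(np.arange(30) * 1000.0)

    def test_window_filter_applies(self):
        rng = np.random.default_rng(3)
        d = np.concatenate([rng.laplace(0, 30_000, 1000), [2e6, -3e6]])
        dens = estimate_density(d)
        assert abs(dens.grid).max() <= 500_000

    def test_mode_recovery_within_one_grid_step(self):
        # parameter recovery: draws from a Laplace centred at zero
        rng = np.random.default_rng(4)
        d = np.clip(rng.laplace(0, 30_000, 10_000), -500_000, 500_000)
        dens = estimate_density(d)
        step = dens.grid[1] - dens.grid[0]
        assert abs(dens.mode()) <= step


class TestDensityType:
    def test_rejects_wrong_grid_size(self):
        with pytest.raises(ValidationError, match="512"):
            DistanceDensity(np.linspace(-1, 1, 100), np.ones(100) / 2, bandwidth=1.0)

    def test_rejects_non_normalised_density(self):
        grid = np.linspace(-1, 1, 512)
        with pytest.raises(ValidationError, match="integrates"):
            DistanceDensity(grid, np.full(512, 5.0), bandwidth=1.0)

    def test_round_trip(self, tmp_path):
        grid = np.linspace(-500_000, 500_000, 512)
        dens = DistanceDensity(grid, np.exp(-np.abs(grid) / 3e4) / 6e4, bandwidth=100.0,
                               source="synthetic")
        write_density(dens, tmp_path / "d.tsv", tmp_path / "d.json")
        back = read_density(tmp_path / "d.tsv", tmp_path / "d.json")
        np.testing.assert_allclose(back.grid, dens.grid)
        np.testing.assert_allclose(back.density, dens.density)
        assert back.bandwidth == dens.bandwidth
        assert back.source == "synthetic"


def _even_density(scale=50_000.0):
    grid = np.linspace(-500_000, 500_000, 512)
    dens = np.exp(-0.5 * (grid / scale) ** 2) / (scale * np.sqrt(2 * np.pi))
    return DistanceDensity(grid, dens, bandwidth=scale)


class TestDensityToWeights:
    def test_position_at_mode_gets_maximal_weight(self):
        dens = _even_density()
        tss = 1_000_000
        positions = [tss - 200_000, tss - 1_000, tss, tss + 150_000]
        w = density_to_weights(dens, positions, tss, "+")
        assert w.w.argmax() == 2

    def test_symmetric_positions_get_equal_weights(self):
        dens = _even_density()
        tss = 1_000_000
        w = density_to_weights(dens, [tss - 77_000, tss + 77_000], tss, "+")
        assert w.w[0] == pytest.approx(w.w[1], rel=1e-9)

    def test_strand_flip_mirrors_profile(self):
        grid = np.linspace(-500_000, 500_000, 512)
        skew = np.exp(-np.abs(grid - 100_000) / 3e4) / 6e4  # asymmetric density
        dens = DistanceDensity(grid, skew, bandwidth=1.0)
        tss = 1_000_000
        plus = density_to_weights(dens, [tss + 100_000, tss - 100_000], tss, "+")
        minus = density_to_weights(dens, [tss - 100_000, tss + 100_000], tss, "-")
        np.testing.assert_allclose(plus.w, minus.w, rtol=1e-12)

    def test_positions_beyond_grid_clamp_to_boundary(self):
        dens = _even_density()
        tss = 1_000_000
        w = density_to_weights(dens, [tss + 700_000], tss, "+")
        assert w.w[0] == pytest.approx(max(dens.density[-1], 1e-12))

    def test_floor_prevents_zero_weights(self):
        grid = np.linspace(-500_000, 500_000, 512)
        dens = np.zeros(512)
        dens[250:262] = 1.0 / (12 * (grid[1] - grid[0]))  # narrow box
        d = DistanceDensity(grid, dens / np.trapezoid(dens, grid), bandwidth=1.0)
        w = density_to_weights(d, [1_990_000], 1_500_000, "+")
        assert w.w[0] >= 1e-12


class TestAbcWeights:
    VARIANTS = [("v1", "1", 1500), ("v2", "1", 5000), ("v3", "1", 2000)]

    def test_median_over_biosamples(self):
        recs = [
            AbcRecord("1", 1000, 2000, "G", "b1", 0.02),
            AbcRecord("1", 1000, 2000, "G", "b2", 0.04),
        ]
        w = abc_to_weights(recs, "G", self.VARIANTS)
        assert w.w[0] == pytest.approx(0.03)

    def test_variant_outside_all_enhancers_gets_half_min_score(self):
        recs = [AbcRecord("1", 1000, 2000, "G", "b1", 0.5)]
        w = abc_to_weights(recs, "G", self.VARIANTS)
        assert w.w[1] == ABC_MISSING_SCORE

    def test_interval_end_is_exclusive(self):
        # 1-based position 2001 is 0-based 2000, the exclusive end
        recs = [AbcRecord("1", 1000, 2000, "G", "b1", 0.5)]
        w = abc_to_weights(recs, "G", [("v", "1", 2001)])
        assert w.w[0] == ABC_MISSING_SCORE
        w = abc_to_weights(recs, "G", [("v", "1", 2000)])
        assert w.w[0] == 0.5

    def test_overlapping_enhancers_take_max_median(self):
        recs = [
            AbcRecord("1", 1000, 3000, "G", "b1", 0.1),
            AbcRecord("1", 1400, 1600, "G", "b1", 0.4),
        ]
        w = abc_to_weights(recs, "G", [("v1", "1", 1500)])
        assert w.w[0] == pytest.approx(0.4)

    def test_other_genes_filtered_out(self):
        recs = [AbcRecord("1", 1000, 2000, "OTHER", "b1", 0.9)]
        w = abc_to_weights(recs, "G", self.VARIANTS)
        np.testing.assert_array_equal(w.w, ABC_MISSING_SCORE)


class TestGnocchiWeights:
    def test_shared_region_gives_uniform_weights(self):
        recs = [GnocchiRecord("1", 0, 10_000, 1.3)]
        w = gnocchi_to_weights(recs, [("a", "1", 100), ("b", "1", 200), ("c", "1", 300)])
        np.testing.assert_allclose(w.w, 1 / 3, rtol=1e-12)

    def test_softmax_closed_form(self):
        recs = [GnocchiRecord("1", 0, 1000, 1.0), GnocchiRecord("1", 1000, 2000, 0.0)]
        w = gnocchi_to_weights(recs, [("a", "1", 500), ("b", "1", 1500)])
        e = np.e
        np.testing.assert_allclose(w.w, [e / (e + 1), 1 / (e + 1)], rtol=1e-12)

    def test_nearest_region_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        recs = [
            GnocchiRecord("1", int(s), int(s) + 1000, float(rng.normal()))
            for s in rng.choice(np.arange(0, 100_000, 1000), size=20, replace=False)
        ]
        variants = [(f"v{i}", "1", int(p)) for i, p in
                    enumerate(rng.integers(1, 100_000, size=30))]

        def edge_dist(rec, pos0):
            if rec.start <= pos0 < rec.end:
                return 0
            return rec.start - pos0 if pos0 < rec.start else pos0 - (rec.end - 1)

        expected_scores = np.array([
            min(recs, key=lambda r: (edge_dist(r, pos - 1), r.start)).score
            for _, _, pos in variants
        ])
        expected = np.exp(expected_scores - expected_scores.max())
        expected /= expected.sum()
        w = gnocchi_to_weights(recs, variants)
        np.testing.assert_allclose(w.w, expected, rtol=1e-12)

    def test_variant_between_regions_takes_nearer(self):
        recs = [GnocchiRecord("1", 0, 1000, 2.0), GnocchiRecord("1", 5000, 6000, -1.0)]
        # 1-based 1501 -> 0-based 1500: distance 501 to left edge end-1=999,
        # 3500 to right start
        w = gnocchi_to_weights(recs, [("a", "1", 1501), ("b", "1", 5500)])
        assert w.w[0] > w.w[1]  # left (higher) score assigned to the first

    def test_no_records_on_chromosome_errors(self):
        recs = [GnocchiRecord("2", 0, 1000, 1.0)]
        with pytest.raises(ValidationError, match="chromosome"):
            gnocchi_to_weights(recs, [("a", "1", 100)])


class TestPolyfunWeights:
    def test_matched_snp_uses_table_variance(self):
        recs = [PolyFunRecord("1", 100, 3e-8, "a"), PolyFunRecord("1", 200, 1e-9, "b")]
        w = polyfun_to_weights(recs, [("a", "1", 100)])
        assert w.w[0] == pytest.approx(3e-8)

    def test_unmatched_snp_gets_table_minimum(self):
        recs = [PolyFunRecord("1", 100, 3e-8, "a"), PolyFunRecord("1", 200, 1e-9, "b")]
        w = polyfun_to_weights(recs, [("zzz", "9", 999)])
        assert w.w[0] == pytest.approx(1e-9)

    def test_position_fallback_when_id_unknown(self):
        recs = [PolyFunRecord("1", 100, 3e-8)]
        w = polyfun_to_weights(recs, [("anyname", "1", 100)])
        assert w.w[0] == pytest.approx(3e-8)

    def test_all_unmatched_is_uniform_hence_unweighted_coloc(self):
        from colocpriors.coloc_engine import coloc_from_lbf
        from colocpriors.region_data import LogBFVector, PriorWeights

        recs = [PolyFunRecord("1", 100, 2e-9, "x")]
        variants = [(f"v{i}", "2", 1000 + i) for i in range(10)]
        w = polyfun_to_weights(recs, variants)
        rng = np.random.default_rng(10)
        ids = [v[0] for v in variants]
        lbf1 = LogBFVector(ids, rng.normal(0, 2, 10))
        lbf2 = LogBFVector(ids, rng.normal(0, 2, 10))
        res_w = coloc_from_lbf(lbf1, lbf2, weights1=PriorWeights(w.variant_ids, w.w))
        res_u = coloc_from_lbf(lbf1, lbf2)
        np.testing.assert_allclose(res_w.pp, res_u.pp, atol=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            polyfun_to_weights([], [("a", "1", 100)])
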