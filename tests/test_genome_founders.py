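"""Genetic map construction, founder simulation, marker QC, and distances."""

import numpy as np
import pandas as pd
import pytest

from dhpredict import build_map, gene_diversity, modified_rogers_distance, simulate_founders
from dhpredict.genome_founders import EmptyPanelError, filter_markers


class TestBuildMap:
    def test_uniform_spacing_distributes_markers_evenly(self):
        gmap = build_map(7, 1.5, 700, spacing="uniform")
        counts = np.bincount(gmap.marker_chrom)
        assert list(counts) == [100] * 7
        pos = gmap.marker_pos[gmap.chrom_slice(0)]
        assert pos[0] == 0.0 and pos[-1] == pytest.approx(1.5)
        assert np.allclose(np.diff(pos), 1.5 / 99)

    def test_two_marker_chromosome_spans_endpoints(self):
        gmap = build_map(1, 1.0, 2, spacing="uniform")
        assert list(gmap.marker_pos) == [0.0, 1.0]

    def test_random_spacing_is_deterministic_given_seed(self):
        a = build_map(7, 1.5, 700, spacing="random", seed=5)
        b = build_map(7, 1.5, 700, spacing="random", seed=5)
        assert np.array_equal(a.marker_pos, b.marker_pos)
        c = build_map(7, 1.5, 700, spacing="random", seed=6)
        assert not np.array_equal(a.marker_pos, c.marker_pos)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_chrom=0, chrom_length_morgan=1.0, n_markers=10),
            dict(n_chrom=2, chrom_length_morgan=-1.0, n_markers=10),
            dict(n_chrom=7, chrom_length_morgan=1.5, n_markers=13),  # < 2 per chrom
            dict(n_chrom=1, chrom_length_morgan=1.0, n_markers=5, spacing="fancy"),
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_map(**kwargs)


class TestSimulateFounders:
    def test_full_divergence_separates_pools_at_every_marker(self, barley_map):
        p = simulate_founders(barley_map, pool_divergence=1.0, seed=1)
        mrd = modified_rogers_distance(p)
        elite = [i for i, q in enumerate(p.pools) if q == "elite"]
        donor = [i for i, q in enumerate(p.pools) if q == "donor"]
        assert np.allclose(mrd[np.ix_(elite, donor)], 1.0)

    def test_zero_divergence_leaves_no_marker_fixed_between_pools(self, barley_map):
        p = simulate_founders(barley_map, pool_divergence=0.0, min_maf=0.1, seed=2)
        hap = p.haplotypes
        elite, donor = hap[:5], hap[5:]
        fixed_opposite = (
            (np.ptp(elite, axis=0) == 0) & (np.ptp(donor, axis=0) == 0) & (elite[0] != donor[0])
        )
        assert not fixed_opposite.any()
        maf = np.minimum(hap.mean(0), 1 - hap.mean(0))
        assert (maf >= 0.1).all()

    def test_differentiated_marker_count_follows_rounding(self, barley_map):
        p = simulate_founders(barley_map, pool_divergence=0.3, seed=3)
        assert int(p.pool_differentiated.sum()) == 210

    def test_fixed_seed_is_bit_reproducible(self, barley_map):
        a = simulate_founders(barley_map, seed=7)
        b = simulate_founders(barley_map, seed=7)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.pool_differentiated, b.pool_differentiated)

    def test_panel_gene_diversity_respects_min_maf(self, barley_map):
        p = simulate_founders(barley_map, min_maf=0.1, seed=4)
        div = np.array([gene_diversity(col) for col in p.haplotypes.astype(float).T])
        assert (div >= 2 * 0.1 * 0.9 - 1e-12).all()

    def test_too_few_founders_rejected(self, barley_map):
        with pytest.raises(ValueError):
            simulate_founders(barley_map, n_elite=1, n_donor=0)


class TestFilterMarkers:
    def test_toy_example_keeps_only_clean_polymorphic_marker(self):
        # marker 0 clean and segregating, marker 1 half missing, marker 2 monomorphic
        g = np.array(
            [
                [0, np.nan, 2],
                [2, np.nan, 2],
                [0, 0, 2],
                [2, 2, 2],
            ],
            dtype=float,
        )
        filtered, report = filter_markers(g, max_missing_marker=0.10, min_diversity=0.10)
        assert report.n_markers_kept == 1
        assert list(report.marker_kept) == [True, False, False]
        assert filtered.shape == (4, 1)

    def test_clean_balanced_matrix_passes_untouched(self):
        g = np.tile([[0.0], [2.0]], (5, 4))
        filtered, report = filter_markers(g)
        assert report.n_markers_kept == 4 and report.n_lines_kept == 10
        assert np.allclose(report.marker_gene_diversity, 0.5)

    def test_randomized_fixture_matches_brute_force_oracle(self, rng):
        g = rng.choice([0.0, 2.0], size=(50, 20))
        g[rng.random(g.shape) < 0.06] = np.nan
        g[:, 3] = 0.0  # planted monomorphic
        g[:40, 7] = np.nan  # planted high missingness
        g[11, rng.choice(20, 8, replace=False)] = np.nan  # noisy line

        # independent brute-force re-application of the rules
        keep_m = []
        for j in range(20):
            col = g[:, j]
            obs = col[~np.isnan(col)]
            miss = np.isnan(col).mean()
            _, counts = np.unique(obs, return_counts=True)
            div = 1 - ((counts / counts.sum()) ** 2).sum() if obs.size else 0.0
            keep_m.append(miss <= 0.10 and div >= 0.10 and len(counts) <= 2)
        keep_l = [np.isnan(g[i, keep_m]).mean() <= 0.15 for i in range(50)]
        expected = g[np.ix_(keep_l, keep_m)]

        filtered, report = filter_markers(g)
        assert list(report.marker_kept) == keep_m
        assert list(report.line_kept) == keep_l
        assert np.array_equal(filtered, expected, equal_nan=True)

    def test_filtering_is_idempotent(self, rng):
        g = rng.choice([0.0, 2.0], size=(40, 30))
        g[rng.random(g.shape) < 0.12] = np.nan
        once, _ = filter_markers(g)
        twice, report = filter_markers(once)
        assert np.array_equal(once, twice, equal_nan=True)
        assert report.n_markers_kept == once.shape[1]
        assert report.n_lines_kept == once.shape[0]

    def test_dataframe_round_trips_labels(self):
        frame = pd.DataFrame(
            np.tile([[0.0], [2.0]], (2, 3)),
            index=list("abcd"),
            columns=["m1", "m2", "m3"],
        )
        filtered, _ = filter_markers(frame)
        assert list(filtered.index) == list("abcd")
        assert list(filtered.columns) == ["m1", "m2", "m3"]

    def test_all_markers_removed_raises(self):
        g = np.full((4, 3), 2.0)  # all monomorphic
        with pytest.raises(EmptyPanelError):
            filter_markers(g)


class TestModifiedRogersDistance:
    def test_identical_opposite_and_half_different_lines(self):
        lines = np.array(
            [
                [0, 0, 0, 0],
                [0, 0, 0, 0],
                [1, 1, 1, 1],
                [1, 1, 0, 0],
            ],
            dtype=float,
        )
        d = modified_rogers_distance(lines)
        assert d[0, 1] == 0.0
        assert d[0, 2] == pytest.approx(1.0)
        assert d[0, 3] == pytest.approx(np.sqrt(0.5))
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)

    def test_triangle_inequality_on_random_panels(self, rng):
        for _ in range(10):
            lines = rng.integers(0, 2, size=(8, 40)).astype(float)
            d = modified_rogers_distance(lines)
            for i in range(8):
                for j in range(8):
                    for k in range(8):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_missing_genotypes_rejected(self):
        lines = np.array([[0.0, np.nan], [1.0, 0.0]])
        with pytest.raises(ValueError, match="missing"):
            modified_rogers_distance(lines)
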