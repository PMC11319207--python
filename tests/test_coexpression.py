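"""Coexpression statistics: filters, tied-rank Spearman, deltaC, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_spearman
from crossacd import coexpression as cx, simulate as sim
from crossacd.types import CountMatrix, GenomicInterval


def _cm(counts, chrom="chr1"):
    counts = np.asarray(counts, dtype=float)
    n_cells, n_genes = counts.shape
    features = pd.DataFrame(
        {
            "chrom": [chrom] * n_genes,
            "start": np.arange(n_genes) * 1_000,
            "end": np.arange(n_genes) * 1_000 + 500,
        },
        index=pd.Index([f"g{i}" for i in range(n_genes)]),
    )
    return CountMatrix(
        cells=[f"c{i}" for i in range(n_cells)], features=features, counts=counts
    )


class TestExpressionFilter:
    def test_detected_gene_threshold_is_strict(self, rng):
        n_genes = 3_000
        counts = np.zeros((2, n_genes))
        counts[0, :2_600] = 1  # exactly 2,600 detected -> removed
        counts[1, :2_601] = 1  # 2,601 detected -> kept
        out, rep = cx.filter_expression_matrix(_cm(counts), min_mean_count=0.0)
        assert out.cells == ["c1"]
        assert rep.n_cells_out == 1

    def test_gene_mean_boundary(self):
        counts = np.array([[0.99, 1.0, 3.0]] * 4)
        out, _ = cx.filter_expression_matrix(
            _cm(counts), min_genes_per_cell=0, min_mean_count=1.0
        )
        assert out.feature_ids == ["g1", "g2"]

    def test_all_cells_removed_is_error(self):
        with pytest.raises(ValueError):
            cx.filter_expression_matrix(_cm(np.zeros((3, 5))))


class TestSpearmanTied:
    def test_perfect_monotone(self):
        assert cx.spearman_tied([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert cx.spearman_tied([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tie_handling_worked_example(self):
        # average ranks: x -> 1, 2.5, 2.5, 4 ; y -> 1, 3, 2, 4
        assert cx.spearman_tied([1, 2, 2, 4], [1, 3, 2, 4]) == pytest.approx(
            0.9487, abs=1e-4
        )

    def test_constant_vector_undefined(self):
        assert np.isnan(cx.spearman_tied([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cx.spearman_tied([1, 2, 3], [1, 2])

    def test_matches_oracle_exhaustive_length_4(self):
        vecs = [np.array(v, float) for v in itertools.product(range(3), repeat=4)]
        for x in vecs:
            for y in vecs:
                expected = brute_spearman(x, y)
                got = cx.spearman_tied(x, y)
                if expected is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("length", [5, 6])
    def test_matches_oracle_sampled_lengths_5_6(self, length, rng):
        vecs = [np.array(v, float) for v in itertools.product(range(3), repeat=length)]
        partners = rng.choice(len(vecs), size=(300, 2))
        for i, j in partners:
            expected = brute_spearman(vecs[i], vecs[j])
            got = cx.spearman_tied(vecs[i], vecs[j])
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=3, max_size=15),
        st.lists(st.integers(min_value=0, max_value=20), min_size=3, max_size=15),
    )
    def test_invariant_under_monotone_transform(self, xs, ys):
        n = min(len(xs), len(ys))
        x = np.array(xs[:n], float)
        y = np.array(ys[:n], float)
        base = cx.spearman_tied(x, y)
        transformed = cx.spearman_tied(np.exp(x / 5.0), y)
        if np.isnan(base):
            assert np.isnan(transformed)
        else:
            assert transformed == pytest.approx(base, abs=1e-12)

    def test_pairwise_matches_scalar(self, rng):
        counts = rng.poisson(5.0, size=(30, 6)).astype(float)
        counts[:, 3] = 2.0  # constant feature
        rho = cx.pairwise_spearman(counts)
        for i in range(6):
            for j in range(6):
                scalar = cx.spearman_tied(counts[:, i], counts[:, j])
                if np.isnan(scalar):
                    assert np.isnan(rho[i, j])
                else:
                    assert rho[i, j] == pytest.approx(scalar, abs=1e-12)


class TestAcdPairSpearman:
    def test_single_gene_pair(self, rng):
        counts = rng.poisson(10.0, size=(50, 2)).astype(float)
        s, sbar = cx.acd_pair_spearman(_cm(counts), ["g0"], ["g1"])
        assert s.shape == (1, 1)
        assert sbar == pytest.approx(cx.spearman_tied(counts[:, 0], counts[:, 1]))

    def test_constant_side_missing(self):
        counts = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        _, sbar = cx.acd_pair_spearman(_cm(counts), ["g0"], ["g1"])
        assert np.isnan(sbar)

    def test_empty_gene_set_rejected(self, rng):
        counts = rng.poisson(10.0, size=(10, 2)).astype(float)
        with pytest.raises(ValueError):
            cx.acd_pair_spearman(_cm(counts), [], ["g1"])


class TestDifferentialAndCoefficient:
    def test_differential_trivials(self):
        s = np.array([[0.1, np.nan], [0.2, 0.3]])
        np.testing.assert_array_equal(
            cx.differential_spearman(s, s)[np.isfinite(s)], 0.0
        )
        d = cx.differential_spearman(s, s + 0.1)
        assert d[0, 0] == pytest.approx(0.1)
        assert np.isnan(d[0, 1])
        with pytest.raises(ValueError):
            cx.differential_spearman(s, np.zeros((3, 3)))

    def test_sign_count_worked_example(self):
        delta = np.array([[0.1, -0.2], [0.3, 0.4]])
        assert cx.coexpression_coefficient(delta) == pytest.approx(0.5)

    def test_all_positive_and_degenerate(self):
        assert cx.coexpression_coefficient(np.full((2, 2), 0.3)) == 1.0
        assert np.isnan(cx.coexpression_coefficient(np.zeros((2, 2))))
        assert np.isnan(cx.coexpression_coefficient(np.full((2, 2), np.nan)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=1, max_size=9
        )
    )
    def test_condition_swap_antisymmetry(self, entries):
        delta = np.array(entries)
        a = cx.coexpression_coefficient(delta)
        b = cx.coexpression_coefficient(-delta)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert b == pytest.approx(-a)


class TestDistanceDecay:
    def test_moving_average_center(self):
        d = np.arange(5) * 1e6 + 0.5e6
        v = np.array([1.0, 2, 3, 4, 5])
        curve = cx.distance_decay(d, v, bin_width_bp=1e6)
        assert curve["mean_smooth"].iloc[2] == pytest.approx(3.0)

    def test_single_bin_unchanged(self):
        curve = cx.distance_decay(np.array([1e5, 2e5]), np.array([1.0, 3.0]), 1e6)
        assert len(curve) == 1
        assert curve["mean_smooth"].iloc[0] == pytest.approx(2.0)

    def test_coupled_fixture_decays(self, acds_one_chrom):
        """Distance decay of S-bar is non-increasing on average under an
        exponentially decaying coupling."""
        m, _ = sim.gen_expression_counts(
            acds_one_chrom,
            n_cells=250,
            coupling_cis=0.7,
            decay_length_bp=8e6,
            seed=21,
        )
        rho = cx.pairwise_spearman(m.counts)
        gene_map = cx.assign_genes_to_acds(m.features, acds_one_chrom)
        gidx = {g: k for k, g in enumerate(m.feature_ids)}
        dists, vals = [], []
        for i in range(len(acds_one_chrom)):
            for j in range(i + 1, len(acds_one_chrom)):
                bi = [gidx[g] for g in gene_map[acds_one_chrom[i].id]]
                bj = [gidx[g] for g in gene_map[acds_one_chrom[j].id]]
                vals.append(np.nanmean(rho[np.ix_(bi, bj)]))
                dists.append(
                    abs(acds_one_chrom[i].midpoint - acds_one_chrom[j].midpoint)
                )
        curve = cx.distance_decay(
            np.array(dists), np.array(vals), bin_width_bp=6e6
        )
        smoothed = curve["mean_smooth"].to_numpy()
        assert smoothed[0] > smoothed[-1]
        assert np.mean(np.diff(smoothed) <= 1e-9) >= 0.6


class TestChromosomeSummary:
    def _pairstat(self, acds, values):
        dist = cx.pair_distance_matrix(acds)
        from crossacd.types import PairStatMatrix

        return PairStatMatrix(
            row_ids=[a.id for a in acds],
            col_ids=[a.id for a in acds],
            values=values,
            distances=dist,
            stat_name="deltaC",
        )

    def test_constant_values(self, acds_multi):
        n = len(acds_multi)
        vals = np.full((n, n), 0.2)
        np.fill_diagonal(vals, np.nan)
        summary, counts = cx.chromosome_wise_summary(
            self._pairstat(acds_multi, vals), {a.id: a.chrom for a in acds_multi}
        )
        assert np.allclose(summary.to_numpy(), 0.2)
        assert counts.to_numpy().sum() > 0

    def test_missing_trans_cells(self, acds_multi):
        n = len(acds_multi)
        vals = np.full((n, n), np.nan)
        # only cis pairs on chr1 defined
        for i in range(6):
            for j in range(6):
                if i != j:
                    vals[i, j] = 0.5
        summary, _ = cx.chromosome_wise_summary(
            self._pairstat(acds_multi, vals), {a.id: a.chrom for a in acds_multi}
        )
        assert summary.loc["chr1", "chr1"] == pytest.approx(0.5)
        assert np.isnan(summary.loc["chr1", "chr2"])


class TestPipelineCalibration:
    def test_null_replicates_center_on_zero(self, acds_multi):
        """Two independent draws from the same ground truth give mean
        deltaC within 3 SE of zero (the control cross-validation design)."""
        m1, _ = sim.gen_expression_counts(
            acds_multi, n_cells=300, coupling_cis=0.0, seed=31
        )
        m2, _ = sim.gen_expression_counts(
            acds_multi, n_cells=300, coupling_cis=0.0, seed=32
        )
        res = cx.coexpression_analysis(
            m1, m2, acds_multi, min_genes_per_cell=0, min_mean_count=0.0
        )
        _, _, vals = res.delta_c.upper_triangle()
        vals = vals[np.isfinite(vals)]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 3 * se

    def test_recovery_orders_couplings(self, acds_multi):
        """Raising cis coupling raises S-bar and drives cis deltaC positive
        while trans pairs stay near the null."""
        m_ctrl, _ = sim.gen_expression_counts(
            acds_multi, n_cells=400, coupling_cis=0.1, decay_length_bp=6e6, seed=41
        )
        m_dep, _ = sim.gen_expression_counts(
            acds_multi, n_cells=400, coupling_cis=0.5, decay_length_bp=6e6, seed=42
        )
        res = cx.coexpression_analysis(
            m_ctrl, m_dep, acds_multi, min_genes_per_cell=0, min_mean_count=0.0
        )
        ii, jj, vals = res.delta_c.upper_triangle()
        dist = res.delta_c.distances[ii, jj]
        cis = vals[np.isfinite(dist) & np.isfinite(vals)]
        trans = vals[~np.isfinite(dist) & np.isfinite(vals)]
        sb_c = res.sbar_ctrl.upper_triangle()[2]
        sb_d = res.sbar_dep.upper_triangle()[2]
        cis_mask = np.isfinite(res.delta_c.distances[np.triu_indices(len(res.acds), 1)])
        assert np.nanmedian(sb_d[cis_mask]) > np.nanmedian(sb_c[cis_mask])
        assert np.median(cis) > 0.3
        trans_se = trans.std(ddof=1) / np.sqrt(len(trans))
        assert abs(trans.mean()) <= 3 * trans_se
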