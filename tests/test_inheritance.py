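import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from nticell import (
    CellSeries,
    KEDistribution,
    fidelity_by_regime,
    generation_fidelity,
    jsd,
    ke_distribution,
    pairwise_jsd_cluster,
)
from nticell.inheritance import _rank_biserial, shared_bin_edges


def _dist(probs, edges=None, cell_id=0):
    probs = np.asarray(probs, dtype=float)
    if edges is None:
        edges = np.arange(probs.size + 1, dtype=float)
    return KEDistribution(cell_id, edges, probs, n_samples=100)


def _series(values, cell_id=0):
    values = np.asarray(values, dtype=float)
    return CellSeries(cell_id, np.arange(values.size), values, transformed=True)


class TestKeDistribution:
    def test_constant_series_occupies_one_bin(self):
        d = ke_distribution(_series(np.full(100, 1.7)), n_bins=10)
        assert np.count_nonzero(d.probabilities) == 1
        assert d.probabilities.max() == 1.0

    def test_probabilities_sum_to_one(self, rng):
        d = ke_distribution(_series(rng.normal(size=500)), n_bins=30)
        assert d.probabilities.sum() == pytest.approx(1.0)

    def test_window_restricts_samples(self, rng):
        s = _series(rng.normal(size=200))
        d = ke_distribution(s, window=(50, 150), n_bins=10)
        assert d.n_samples == 100

    def test_small_window_flagged_with_warning(self, rng):
        with pytest.warns(UserWarning, match="samples"):
            d = ke_distribution(_series(rng.normal(size=20)), n_bins=5)
        assert d.flagged

    def test_untransformed_series_rejected(self):
        s = CellSeries(0, np.arange(60), np.ones(60))
        with pytest.raises(ValueError, match="log-transformed"):
            ke_distribution(s)

    def test_shared_edges_span_pooled_percentiles(self, rng):
        a, b = rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)
        edges = shared_bin_edges([a, b], n_bins=40)
        assert edges.size == 41
        assert edges[0] < 0 and edges[-1] > 5


class TestJsd:
    def test_identical_distributions_give_zero(self):
        p = _dist([0.2, 0.3, 0.5])
        assert jsd(p, _dist([0.2, 0.3, 0.5])) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self):
        assert jsd(_dist([1, 0]), _dist([0, 1])) == pytest.approx(1.0)

    def test_hand_computed_two_bin_value(self):
        # point mass vs (1/2, 1/2): 1/2*log2(4/3) + 1/4*log2(2/3) + 1/4
        expected = 0.5 * np.log2(4 / 3) + 0.25 * np.log2(2 / 3) + 0.25
        assert jsd(_dist([1, 0]), _dist([0.5, 0.5])) == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(0.3113, abs=5e-5)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(12))
            q = rng.dirichlet(np.ones(12))
            d1, d2 = _dist(p), _dist(q)
            assert jsd(d1, d2) == pytest.approx(jsd(d2, d1), abs=1e-12)
            assert 0.0 <= jsd(d1, d2) <= 1.0

    def test_mismatched_bins_rejected(self):
        p = _dist([0.5, 0.5])
        q = _dist([0.5, 0.5], edges=np.array([0.0, 2.0, 4.0]))
        with pytest.raises(ValueError, match="bin edges"):
            jsd(p, q)


class TestClustering:
    def test_matrix_symmetric_with_zero_diagonal(self, rng):
        dists = [_dist(rng.dirichlet(np.ones(8)), cell_id=i) for i in range(5)]
        mat, _ = pairwise_jsd_cluster(dists)
        assert np.allclose(mat, mat.T)
        assert np.all(np.diag(mat) == 0)

    def test_cut_at_point_three_separates_disjoint_cell(self):
        a = _dist([0.5, 0.5, 0.0, 0.0], cell_id=0)
        b = _dist([0.5, 0.5, 0.0, 0.0], cell_id=1)
        c = _dist([0.0, 0.0, 0.5, 0.5], cell_id=2)
        _, labels = pairwise_jsd_cluster([a, b, c], cut_height=0.3)
        assert labels[0] == labels[1] != labels[2]
        assert len(set(labels)) == 2

    def test_zero_cut_isolates_every_cell(self, rng):
        dists = [_dist(rng.dirichlet(np.ones(8)), cell_id=i) for i in range(4)]
        _, labels = pairwise_jsd_cluster(dists, cut_height=0.0)
        assert len(set(labels)) == 4


class TestFidelityByRegime:
    def _pairs(self, rng, shift=0.1):
        rows = []
        for cat, loc in [
            ("coupled", 0.15),
            ("information_closure", 0.15 + shift),
            ("independent", 0.2),
        ]:
            for _ in range(15):
                rows.append(dict(category=cat, jsd=abs(rng.normal(loc, 0.05))))
        return pd.DataFrame(rows)

    def test_rank_biserial_consistent_with_u(self, rng):
        g1 = rng.normal(0.0, 1.0, 23)
        g2 = rng.normal(0.8, 1.0, 31)
        u, _, r = _rank_biserial(g1, g2)
        assert u == pytest.approx((1 - r) * len(g1) * len(g2) / 2)
        assert -1 <= r <= 1
        # orientation: group with larger values second => r >= 0
        assert r >= 0

    def test_u_statistic_matches_scipy_orientation(self, rng):
        g_small = rng.normal(0, 1, 12)
        g_big = rng.normal(2, 1, 15)
        u, p, r = _rank_biserial(g_big, g_small)  # order must not matter
        assert u == mannwhitneyu(g_small, g_big, alternative="two-sided").statistic
        assert p == mannwhitneyu(g_small, g_big, alternative="two-sided").pvalue

    def test_identical_groups_are_insignificant(self, rng):
        vals = rng.random(20)
        df = pd.DataFrame(
            [dict(category=c, jsd=v) for c in ("coupled", "independent") for v in vals]
        )
        stats = fidelity_by_regime(df)
        assert stats.kruskal_h == pytest.approx(0.0, abs=1e-9)
        for pair in stats.pairwise.values():
            assert pair["p_corr"] == 1.0

    def test_bonferroni_triples_and_caps(self, rng):
        stats = fidelity_by_regime(self._pairs(rng))
        for pair in stats.pairwise.values():
            assert pair["p_corr"] == pytest.approx(min(1.0, 3 * pair["p_raw"]))

    def test_excluded_categories_are_dropped(self, rng):
        df = self._pairs(rng)
        df = pd.concat(
            [df, pd.DataFrame([dict(category="anomalous", jsd=0.9)] * 5)],
            ignore_index=True,
        )
        stats = fidelity_by_regime(df)
        assert "anomalous" not in stats.group_means

    def test_tiny_category_warned_and_excluded(self, rng):
        df = self._pairs(rng)
        df = df[~((df["category"] == "independent") & (df.index % 15 != 0))]
        with pytest.warns(UserWarning, match="excluded"):
            stats = fidelity_by_regime(df)
        assert "independent" not in stats.group_means


class TestGenerationFidelity:
    def test_single_pair_reports_no_sd(self):
        df = pd.DataFrame(
            [dict(series="s0", generation=1, jsd=0.25)]
        )
        out = generation_fidelity(df)
        t = out["transitions"]["gen0->1"]
        assert t["mean"] == pytest.approx(0.25)
        assert t["sd"] is None

    def test_proportional_construction_gives_unit_correlation(self):
        rows = []
        for i, ic in enumerate([0.1, 0.3, 0.5, 0.7]):
            for _ in range(3):
                rows.append(
                    dict(series=f"s{i}", generation=3, jsd=ic * 0.5,
                         ic_fraction_gen3=ic)
                )
        out = generation_fidelity(pd.DataFrame(rows))
        assert out["ic_fraction_correlation"]["pearson_r"] == pytest.approx(1.0)

    def test_pooled_means_invariant_to_series_relabeling(self, rng):
        df = pd.DataFrame(
            dict(
                series=rng.choice(["a", "b", "c"], 30),
                generation=rng.choice([1, 2, 3], 30),
                jsd=rng.random(30),
            )
        )
        shuffled = df.assign(series=rng.permutation(df["series"].to_numpy()))
        t1 = generation_fidelity(df)["transitions"]
        t2 = generation_fidelity(shuffled)["transitions"]
        for k in t1:
            assert t1[k]["mean"] == pytest.approx(t2[k]["mean"])
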