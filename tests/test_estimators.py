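import numpy as np
import pytest

from nticell import EstimatorConfig, RegimeSpec, cmi_knn, mi_knn, simulate_community, simulate_lineage
from nticell.estimators import info_triple_from_samples

from _oracles import gauss_cmi, gauss_mi, plugin_mi

TOL = 0.05  # bits


def _sample(cov, n, rng):
    return rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=n).T


class TestConfig:
    @pytest.mark.parametrize("kw", [dict(k=0), dict(lag=0), dict(jitter_scale=-1)])
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ValueError):
            EstimatorConfig(**kw)


class TestMiKnn:
    def test_independent_pairs_near_zero(self, est_config, rng):
        x, y = rng.normal(size=(2, 2000))
        assert abs(mi_knn(x, y, est_config)) < TOL

    def test_bivariate_gaussian_matches_closed_form(self, est_config, rng):
        rho = 0.6
        cov = np.array([[1, rho], [rho, 1]])
        x, y = _sample(cov, 5000, rng)
        expected = -0.5 * np.log2(1 - rho**2)  # ~0.322 bits
        assert mi_knn(x, y, est_config) == pytest.approx(expected, abs=TOL)

    def test_discrete_joint_matches_plugin_oracle(self, est_config, rng):
        joint = np.array(
            [[0.10, 0.05, 0.02, 0.03],
             [0.02, 0.15, 0.05, 0.03],
             [0.05, 0.02, 0.12, 0.06],
             [0.03, 0.05, 0.04, 0.18]]
        )
        flat = joint.ravel()
        draws = rng.choice(16, size=5000, p=flat)
        xi, yi = np.divmod(draws, 4)
        # jitter makes the discrete sample continuous for the KNN estimator
        cfg = EstimatorConfig(k=est_config.k, jitter_scale=0.05, seed=9)
        est = mi_knn(xi.astype(float), yi.astype(float), cfg)
        from _oracles import empirical_joint

        expected = plugin_mi(empirical_joint(xi, yi, 4))
        assert est == pytest.approx(expected, abs=TOL)

    def test_length_mismatch_and_short_input_rejected(self, est_config):
        with pytest.raises(ValueError, match="equal length"):
            mi_knn(np.zeros(10), np.zeros(11), est_config)
        with pytest.raises(ValueError, match="k\\+2"):
            mi_knn(np.zeros(5), np.zeros(5), est_config)

    def test_deterministic_given_seed(self, est_config, rng):
        x, y = rng.normal(size=(2, 500))
        assert mi_knn(x, y, est_config) == mi_knn(x, y, est_config)


class TestCmiKnn:
    def test_irrelevant_conditioner_recovers_mi(self, est_config, rng):
        rho = 0.5
        cov = np.array([[1, rho], [rho, 1]])
        x, y = _sample(cov, 5000, rng)
        z = rng.normal(size=5000)
        assert cmi_knn(x, y, z, est_config) == pytest.approx(
            mi_knn(x, y, est_config), abs=TOL
        )

    def test_markov_chain_conditioning_kills_dependence(self, est_config, rng):
        x = rng.normal(size=5000)
        z = 0.8 * x + 0.6 * rng.normal(size=5000)
        y = 0.7 * z + 0.5 * rng.normal(size=5000)
        assert abs(cmi_knn(x, y, z, est_config)) < TOL

    def test_gaussian_triple_matches_partial_correlation(self, est_config, rng):
        cov = np.array(
            [[1.0, 0.6, 0.4],
             [0.6, 1.0, 0.5],
             [0.4, 0.5, 1.0]]
        )
        x, y, z = _sample(cov, 5000, rng)
        expected = gauss_cmi(cov, [0], [1], [2])
        assert cmi_knn(x, y, z, est_config) == pytest.approx(expected, abs=TOL)


class TestInfoTriple:
    def test_independent_context_gives_small_ntic(self, est_config, rng):
        a = 0.8
        x = np.empty(3000)
        x[0] = rng.normal()
        eps = rng.normal(size=3000)
        for t in range(1, 3000):
            x[t] = a * x[t - 1] + eps[t]
        c = rng.normal(size=3000)
        triple = info_triple_from_samples(x, c, est_config)
        assert abs(triple.ntic) < 0.1

    def test_context_equal_to_series_removes_self_information(self, est_config, rng):
        # when C_t = X_t, conditioning on C removes all self-prediction
        a = 0.8
        x = np.empty(3000)
        x[0] = rng.normal()
        eps = rng.normal(size=3000)
        for t in range(1, 3000):
            x[t] = a * x[t - 1] + eps[t]
        triple = info_triple_from_samples(x, x.copy(), est_config)
        assert abs(triple.cmi_self_given_ctx) < 0.1
        assert triple.ntic == pytest.approx(triple.mi_self, abs=0.1)

    def test_jointly_gaussian_triple_matches_closed_forms(self, est_config, rng):
        # covariance of (x_t, x_{t+1}, c_t); all five quantities vs theory
        cov = np.array(
            [[1.0, 0.55, 0.35],
             [0.55, 1.0, 0.30],
             [0.35, 0.30, 1.0]]
        )
        xt, xt1, ct = _sample(cov, 5000, rng)
        assert mi_knn(xt1, xt) == pytest.approx(gauss_mi(cov, [1], [0]), abs=TOL)
        assert mi_knn(xt1, ct) == pytest.approx(gauss_mi(cov, [1], [2]), abs=TOL)
        assert cmi_knn(xt1, xt, ct) == pytest.approx(
            gauss_cmi(cov, [1], [0], [2]), abs=TOL
        )
        assert cmi_knn(xt1, ct, xt) == pytest.approx(
            gauss_cmi(cov, [1], [2], [0]), abs=TOL
        )
        ntic = gauss_mi(cov, [1], [0]) - gauss_cmi(cov, [1], [0], [2])
        est = mi_knn(xt1, xt) - cmi_knn(xt1, xt, ct)
        assert est == pytest.approx(ntic, abs=2 * TOL)

    def test_misaligned_frames_rejected(self, est_config):
        from nticell import CellSeries, ContextSeries, info_triple

        s = CellSeries(0, np.arange(100), np.random.default_rng(0).random(100),
                       transformed=True)
        c = ContextSeries(0, np.arange(1, 101), np.zeros(100), transformed=True)
        with pytest.raises(ValueError, match="aligned"):
            info_triple(s, c, est_config)

    def test_chain_rule_residual_small_on_gaussian_systems(self, est_config, rng):
        from _oracles import random_covariance

        for _ in range(5):
            cov = random_covariance(3, rng)
            x, y, z = _sample(cov, 3000, rng)
            lhs = mi_knn(y, x) - cmi_knn(y, x, z)
            rhs = mi_knn(y, z) - cmi_knn(y, z, x)
            assert abs(lhs - rhs) < 0.1

    def test_ntic_definition_identity(self, est_config, rng):
        x, c = rng.normal(size=(2, 600))
        t = info_triple_from_samples(x, c, est_config)
        assert t.ntic == pytest.approx(t.mi_self - t.cmi_self_given_ctx, abs=1e-12)


def test_ntic_stable_across_neighbour_counts():
    """Per-cell NTIC estimates correlate strongly between nearby k values."""
    lineage = simulate_lineage(3, 1800, seed=21)
    bundle = simulate_community(lineage, RegimeSpec.coupled(), seed=21)
    from nticell.kinematics import log_resample, mean_field, segment_phases

    transformed = {cid: log_resample(s, stride=1) for cid, s in bundle.series.items()}
    estimates = {k: [] for k in (5, 8, 10, 12)}
    for cid in bundle.lineage.cell_ids:
        if bundle.lineage.generation_of(cid) < 2:
            continue
        ctx = mean_field(transformed, cid)
        s = transformed[cid]
        seg = segment_phases(s, window_samples=100)
        lo, hi = seg.middle
        sub = s.slice_frames(lo, hi)
        m = (ctx.frames >= lo) & (ctx.frames < hi)
        for k in estimates:
            t = info_triple_from_samples(
                sub.values, ctx.values[m], EstimatorConfig(k=k)
            )
            estimates[k].append(t.ntic)
    ks = sorted(estimates)
    for i in range(len(ks)):
        for j in range(i + 1, len(ks)):
            r = np.corrcoef(estimates[ks[i]], estimates[ks[j]])[0, 1]
            assert r >= 0.9, f"k={ks[i]} vs k={ks[j]}: r={r:.3f}"
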