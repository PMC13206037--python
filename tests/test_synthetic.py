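import numpy as np
import pytest
from scipy.stats import kurtosis

from nticell import RegimeSpec, simulate_community, simulate_lineage
from nticell.kinematics import kinetic_energy
from nticell.synthetic import ar1, regime_kernel_step, simulate_tracks

from _oracles import gauss_cmi, gauss_mi, pulse_community_cov, drive_community_cov


class TestRegimeSpec:
    def test_independent_regime_forbids_coupling(self):
        with pytest.raises(ValueError, match="independent"):
            RegimeSpec(regime_label="independent", context_coefficient=0.5,
                       shared_innovation_sd=1.0)

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError, match="regime"):
            RegimeSpec(regime_label="entangled")
        with pytest.raises(ValueError, match="marginal_type"):
            RegimeSpec(regime_label="coupled", marginal_type="uniform")


class TestKernelStep:
    def test_independent_spec_ignores_context(self):
        spec = RegimeSpec.independent()
        a = regime_kernel_step(1.0, 5.0, 0.0, spec, 0.3)
        b = regime_kernel_step(1.0, -7.0, 0.0, spec, 0.3)
        assert a == b

    def test_noiseless_coupled_step_is_exact_linear_combination(self):
        spec = RegimeSpec.coupled(private_noise_sd=0.0, shared_innovation_sd=1.0)
        out = regime_kernel_step(2.0, 3.0, 0.0, spec, 12.34)
        assert out == pytest.approx(
            spec.self_coefficient * 2.0 + spec.context_coefficient * 3.0
        )

    def test_pure_function_is_deterministic(self):
        spec = RegimeSpec.coupled()
        assert regime_kernel_step(0.5, 0.2, 0.1, spec, 0.7) == regime_kernel_step(
            0.5, 0.2, 0.1, spec, 0.7
        )


class TestSimulateCommunity:
    def test_same_seed_is_bit_identical(self, small_coupled_bundle):
        lineage = simulate_lineage(3, 600, seed=11)
        again = simulate_community(lineage, RegimeSpec.coupled(), seed=11)
        for cid in lineage.cell_ids:
            assert np.array_equal(
                small_coupled_bundle.series[cid].values, again.series[cid].values
            )

    def test_different_seed_differs(self):
        lineage = simulate_lineage(2, 300, seed=1)
        b1 = simulate_community(lineage, RegimeSpec.coupled(), seed=1)
        b2 = simulate_community(lineage, RegimeSpec.coupled(), seed=2)
        assert not np.array_equal(b1.series[3].values, b2.series[3].values)

    def test_series_spans_lifespan_and_ke_nonnegative(self, small_coupled_bundle):
        for cid in small_coupled_bundle.lineage.cell_ids:
            b, e = small_coupled_bundle.lineage.lifespan(cid)
            s = small_coupled_bundle.series[cid]
            assert s.frames[0] == b and s.frames[-1] == e - 1
            assert np.min(s.values) >= 0

    def test_missing_generation_spec_rejected(self):
        lineage = simulate_lineage(2, 300, seed=1)
        with pytest.raises(KeyError, match="generation"):
            simulate_community(lineage, {0: RegimeSpec.coupled()}, seed=1)

    def test_siblings_share_pulse_stream(self):
        """Contemporaneous IC cells are mutually correlated; independent
        cells are not."""
        lineage = simulate_lineage(3, 1200, seed=5)
        ic = simulate_community(lineage, RegimeSpec.information_closed(), seed=5)
        ind = simulate_community(lineage, RegimeSpec.independent(), seed=5)

        def corr(bundle):
            a = np.log(bundle.series[7].values[200:1000])
            b = np.log(bundle.series[8].values[200:1000])
            return np.corrcoef(a, b)[0, 1]

        assert corr(ic) > 0.4
        assert abs(corr(ind)) < 0.2

    def test_serialization_roundtrip(self, small_coupled_bundle, tmp_path):
        from nticell.pipeline import load_bundle

        small_coupled_bundle.write(tmp_path)
        back = load_bundle(tmp_path)
        assert back.truth == small_coupled_bundle.truth
        for cid in small_coupled_bundle.lineage.cell_ids:
            assert np.allclose(
                back.series[cid].values, small_coupled_bundle.series[cid].values
            )


class TestMarginals:
    def test_heavy_tail_has_larger_excess_kurtosis(self):
        heavy, steep = [], []
        for seed in range(10):
            lineage = simulate_lineage(0, 3000, seed=seed)
            h = simulate_community(
                lineage, RegimeSpec.independent(marginal_type="heavy_tailed"),
                seed=seed,
            )
            s = simulate_community(
                lineage, RegimeSpec.independent(marginal_type="steep_decay"),
                seed=seed,
            )
            heavy.append(kurtosis(h.series[0].values))
            steep.append(kurtosis(s.series[0].values))
        assert all(h > s for h, s in zip(heavy, steep))


class TestTracks:
    def test_kinetic_energy_roundtrip(self, small_coupled_bundle):
        tracks = simulate_tracks(small_coupled_bundle, seed=4)
        cid = 3
        s = kinetic_energy(tracks[cid], dt=small_coupled_bundle.dt, cell_id=cid)
        assert np.allclose(s.values, small_coupled_bundle.series[cid].values)


class TestDesignCalibration:
    """The generator's latent structure matches its exact Gaussian theory.

    The sample moments of simulated communities must agree with the
    closed-form stationary covariances used to place each regime's
    information signature (computed independently via the discrete
    Lyapunov equation)."""

    def test_information_closed_latent_covariance_matches_theory(self):
        spec = RegimeSpec.information_closed(envelope_depth=1.0)
        lineage = simulate_lineage(3, 20000, seed=31)
        bundle = simulate_community(lineage, spec, seed=31)
        theory = pulse_community_cov(
            spec.self_coefficient, spec.pulse_now, spec.pulse_lag, n_siblings=7
        )
        # align all gen-3 cells on their common (jitter-free) frame window
        lo = max(bundle.lineage.lifespan(c)[0] for c in range(7, 15)) + 200
        hi = min(bundle.lineage.lifespan(c)[1] for c in range(7, 15))
        latent = {
            cid: np.log(bundle.series[cid].slice_frames(lo, hi).values)
            for cid in range(7, 15)
        }
        x = latent[7]
        ct_full = np.mean([latent[c] for c in range(8, 15)], axis=0)
        xt, xt1, ct = x[:-1], x[1:], ct_full[:-1]
        emp = np.cov(np.vstack([xt, xt1, ct]))
        assert np.allclose(emp, theory, rtol=0.12, atol=0.08)
        # and the designed signature: MI(X';C) clearly positive, NTIC ~ 0
        mi_ctx = gauss_mi(theory, [1], [2])
        ntic = gauss_mi(theory, [1], [0]) - gauss_cmi(theory, [1], [0], [2])
        assert mi_ctx > 0.02
        assert abs(ntic) < 0.01

    def test_coupled_design_has_large_positive_ntic(self):
        spec = RegimeSpec.coupled()
        theory = drive_community_cov(
            spec.self_coefficient,
            spec.context_coefficient,
            spec.drive_persistence,
            spec.shared_innovation_sd,
            spec.private_noise_sd,
        )
        ntic = gauss_mi(theory, [1], [0]) - gauss_cmi(theory, [1], [0], [2])
        assert ntic > 0.1
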