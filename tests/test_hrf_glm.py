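"""HRF, GLM, FDR, activation detection, PSC and two-gamma fitting."""

import numpy as np
import pytest

from efcpipe._validation import ValidationError
from efcpipe.design import StimulusDesign, StimulusEvent
from efcpipe.hrf_glm import (
    CycleAverage,
    HRFSpec,
    bh_fdr,
    build_design,
    canonical_hrf,
    compute_psc,
    cycle_average,
    detect_activation,
    fit_glm,
    fit_two_gamma,
    rest_baseline_mask,
    two_gamma_model,
)


class TestCanonicalHRF:
    def test_zero_at_origin(self):
        _, h = canonical_hrf()
        assert h[0] == 0.0

    def test_peak_between_4_and_7_seconds(self):
        t, h = canonical_hrf()
        assert 4.0 <= t[np.argmax(h)] <= 7.0
        assert np.max(h) == pytest.approx(1.0)

    def test_no_undershoot_means_nonnegative(self):
        _, h = canonical_hrf(HRFSpec(undershoot_ratio=0.0))
        assert np.all(h >= 0)


class TestBuildDesign:
    def test_no_events_gives_zero_task_column(self):
        d = StimulusDesign(tr=2.0, n_volumes=30, events=(StimulusEvent(5.0, 10.0, "fus"),))
        X = build_design(d, conditions=["heat"])
        np.testing.assert_allclose(X.column("heat"), 0.0)

    def test_peak_follows_onset_by_at_least_peak_delay(self):
        d = StimulusDesign(tr=2.0, n_volumes=40, events=(StimulusEvent(10.0, 16.0, "heat"),))
        X = build_design(d)
        col = X.column("heat")
        t_peak = X.times[np.argmax(col)]
        assert t_peak >= 10.0 + HRFSpec().peak_delay - 2.0  # TR quantization slack

    def test_convolution_matches_fine_grid_oracle(self):
        d = StimulusDesign(tr=2.0, n_volumes=40, events=(StimulusEvent(10.0, 16.0, "heat"),))
        hrf = HRFSpec(dt=0.05)
        X = build_design(d, hrf)
        # oracle: direct Riemann convolution integral at dt = 0.05
        spec_t, kernel = canonical_hrf(hrf)
        fine = np.arange(0, 80, 0.05)
        box = ((fine >= 10.0) & (fine < 26.0)).astype(float)
        conv = np.array([
            np.sum(box[: i + 1][::-1] * np.interp(fine[: i + 1], spec_t, kernel, right=0.0)) * 0.05
            for i in range(len(fine))
        ])
        oracle = np.interp(X.times, fine, conv)
        np.testing.assert_allclose(X.column("heat"), oracle, atol=5e-3)

    def test_disjoint_conditions_disjoint_support(self):
        d = StimulusDesign(
            tr=2.0, n_volumes=80,
            events=(StimulusEvent(10.0, 16.0, "heat"), StimulusEvent(100.0, 16.0, "heat_fus")),
        )
        X = build_design(d)
        h = X.column("heat")
        f = X.column("heat_fus")
        # heat support ends within the HRF duration after its block
        assert np.all(np.abs(h[X.times > 26.0 + 32.0]) < 1e-6)
        assert np.all(np.abs(f[X.times < 100.0]) < 1e-6)


class TestFitGLM:
    def test_exact_recovery_no_noise(self):
        d = StimulusDesign(tr=2.0, n_volumes=60, events=(StimulusEvent(10.0, 16.0, "heat"),))
        X = build_design(d)
        y = 2.0 * X.column("heat")
        res = fit_glm(y, X)
        assert res.beta_for("heat")[0] == pytest.approx(2.0, abs=1e-10)
        assert res.residual_variance[0] == pytest.approx(0.0, abs=1e-18)

    def test_pure_confound_gives_zero_task_beta(self):
        d = StimulusDesign(tr=2.0, n_volumes=60, events=(StimulusEvent(10.0, 16.0, "heat"),))
        conf = np.random.default_rng(0).normal(size=(60, 1))
        X = build_design(d, confounds=conf)
        res = fit_glm(3.0 * conf[:, 0], X)
        assert abs(res.beta_for("heat")[0]) < 1e-10

    def test_normal_equations_oracle(self):
        # hand-rolled (X'X)^-1 X'y on 10x3 systems, 1e-8 agreement
        rng = np.random.default_rng(7)
        from efcpipe.hrf_glm import DesignMatrix

        for _ in range(20):
            M = rng.normal(size=(10, 3))
            y = rng.normal(size=(10, 2))
            X = DesignMatrix(times=np.arange(10.0), matrix=M, names=["a", "b", "c"], condition_map={})
            res = fit_glm(y, X)
            beta_oracle = np.linalg.solve(M.T @ M, M.T @ y).T
            np.testing.assert_allclose(res.beta, beta_oracle, atol=1e-8)
            resid = y - M @ beta_oracle.T
            sigma2 = (resid**2).sum(axis=0) / (10 - 3)
            se_oracle = np.sqrt(np.outer(sigma2, np.diag(np.linalg.inv(M.T @ M))))
            np.testing.assert_allclose(res.se, se_oracle, atol=1e-8)

    def test_monte_carlo_unbiased(self):
        d = StimulusDesign(tr=2.0, n_volumes=60, events=(StimulusEvent(10.0, 16.0, "heat"),))
        X = build_design(d)
        rng = np.random.default_rng(11)
        col = X.column("heat")
        betas = []
        for _ in range(300):
            y = 1.5 * col + rng.normal(0, 1.0, size=60)
            betas.append(fit_glm(y, X).beta_for("heat")[0])
        mean = np.mean(betas)
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(mean - 1.5) < 2 * se + 1e-3

    def test_dof_guard(self):
        from efcpipe.hrf_glm import DesignMatrix

        M = np.linalg.qr(np.random.default_rng(0).normal(size=(3, 3)))[0]
        X = DesignMatrix(times=np.arange(3.0), matrix=M, names=list("abc"), condition_map={})
        with pytest.raises(ValidationError):
            fit_glm(np.ones(3), X)


class TestBHFDR:
    def test_single_p(self):
        adj, rej = bh_fdr(np.array([0.01]))
        assert adj[0] == pytest.approx(0.01)
        assert rej[0]

    def test_hand_computed_case(self):
        # BH by hand: 0.01 <= 1/4*0.05, 0.02 <= 2/4*0.05, 0.03 <= 3/4*0.05, 0.9 > 0.05
        adj, rej = bh_fdr(np.array([0.01, 0.02, 0.03, 0.9]), q=0.05)
        assert list(rej) == [True, True, True, False]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.9])

    def test_all_ones(self):
        _, rej = bh_fdr(np.ones(10))
        assert not rej.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr(np.array([0.5, 1.2]))

    def test_adjusted_monotone_in_sorted_p(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(size=25))
        adj, _ = bh_fdr(p)
        assert np.all(np.diff(adj) >= -1e-12)


class TestDetectActivation:
    def _maps(self, coords, shape=(5, 5, 5)):
        t = np.zeros(shape)
        p = np.ones(shape)
        for c in coords:
            t[c] = 10.0
            p[c] = 1e-6
        return t, p

    def test_isolated_voxel_excluded(self):
        t, p = self._maps([(2, 2, 2)])
        act = detect_activation(t, p, min_contig=2)
        assert act.n_clusters == 0

    def test_face_adjacent_pair_retained(self):
        t, p = self._maps([(2, 2, 2), (2, 2, 3)])
        act = detect_activation(t, p, min_contig=2)
        assert act.n_clusters == 1
        assert act.mask.sum() == 2

    def test_diagonal_pair_connectivity_dependence(self):
        t, p = self._maps([(2, 2, 2), (3, 3, 3)])
        assert detect_activation(t, p, connectivity=6).n_clusters == 0
        assert detect_activation(t, p, connectivity=26).n_clusters == 1

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            detect_activation(np.zeros((2, 2, 2)), np.ones((3, 3, 3)))

    def test_axis_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        t = rng.normal(2.0, 1.0, size=(4, 5, 6))
        p = rng.uniform(0, 0.2, size=(4, 5, 6))
        a = detect_activation(t, p)
        b = detect_activation(np.transpose(t, (2, 0, 1)), np.transpose(p, (2, 0, 1)))
        assert np.array_equal(np.transpose(a.mask, (2, 0, 1)), b.mask)


class TestPSC:
    def test_constant_series_zero(self):
        psc = compute_psc(np.full((20, 1), 100.0), np.ones(20, bool))
        np.testing.assert_allclose(psc, 0.0)

    def test_two_percent(self):
        y = np.full(10, 100.0)
        y[5] = 102.0
        base = np.ones(10, bool)
        base[5] = False
        psc = compute_psc(y, base)
        assert psc[5, 0] == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        y = 100 + rng.normal(size=30)
        base = np.zeros(30, bool)
        base[:10] = True
        np.testing.assert_allclose(compute_psc(y, base), compute_psc(2 * y, base), atol=1e-10)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            compute_psc(np.zeros(10), np.ones(10, bool))

    def test_rest_tail_mask(self):
        d = StimulusDesign(tr=2.0, n_volumes=50, events=(StimulusEvent(20.0, 16.0, "heat"),))
        mask = rest_baseline_mask(d, d.frame_times(), mode="rest_tail", tail_s=10.0)
        times = d.frame_times()
        assert not mask[(times >= 20.0) & (times < 36.0)].any()  # never inside the block
        assert mask.any()


class TestCycleAverage:
    def _design(self, n_cycles=3):
        events = tuple(
            StimulusEvent(10.0 + 46.0 * i, 16.0, "heat") for i in range(n_cycles)
        )
        n_vol = int((10.0 + 46.0 * n_cycles) / 2) + 1
        return StimulusDesign(tr=2.0, n_volumes=n_vol, events=events)

    def test_identical_cycles_zero_se(self):
        d = self._design(3)
        times = d.frame_times()
        base = np.sin(2 * np.pi * (np.arange(23)) / 23)
        psc = np.zeros(d.n_volumes)
        for ev in d.events:
            i0 = int(ev.onset / 2)
            psc[i0 : i0 + 23] = base
        ca = cycle_average(psc, times, d, "heat")
        assert ca.n_cycles == 3
        np.testing.assert_allclose(ca.se_psc, 0.0, atol=1e-12)
        np.testing.assert_allclose(ca.mean_psc, base, atol=1e-12)

    def test_se_matches_sampling_oracle(self):
        # pointwise SE of n iid N(0,1) cycles ~= 1/sqrt(n) on average
        d = self._design(7)
        times = d.frame_times()
        rng = np.random.default_rng(123)
        ses = []
        for _ in range(200):
            psc = rng.normal(size=d.n_volumes)
            ca = cycle_average(psc, times, d, "heat")
            ses.append(ca.se_psc.mean())
        assert np.mean(ses) == pytest.approx(1 / np.sqrt(7), rel=0.10)

    def test_no_cycles_rejected(self):
        d = self._design(2)
        with pytest.raises(ValidationError):
            cycle_average(np.zeros(d.n_volumes), d.frame_times(), d, "heat_fus")


class TestTwoGamma:
    def _cycle(self, y, dt=2.0):
        t = np.arange(len(y)) * dt
        return CycleAverage(window_times=t, mean_psc=y, se_psc=np.zeros_like(y),
                            n_cycles=7, condition="heat")

    def test_self_consistency_noiseless(self):
        t = np.arange(0, 46, 2.0)
        y = two_gamma_model(t, 1.2, 1.0, 6.0, 1.0, 0.3, 9.0, 6.0, 1.5)
        fit = fit_two_gamma(self._cycle(y))
        assert fit.amp1 == pytest.approx(1.2, rel=0.01)
        assert fit.amp2 == pytest.approx(0.3, rel=0.01)
        assert fit.lag1 == pytest.approx(1.0, abs=0.5)
        assert fit.lag2 == pytest.approx(9.0, abs=0.5)
        assert fit.lag1 < fit.lag2

    def test_zero_input_zero_amps(self):
        fit = fit_two_gamma(self._cycle(np.zeros(23)))
        assert abs(fit.amp1) < 1e-6 and abs(fit.amp2) < 1e-6

    def test_amplitude_linearity(self):
        t = np.arange(0, 46, 2.0)
        y = two_gamma_model(t, 1.0, 1.0, 6.0, 1.0, 0.2, 10.0, 6.0, 1.5)
        f1 = fit_two_gamma(self._cycle(y))
        f3 = fit_two_gamma(self._cycle(3 * y))
        assert f3.amp1 == pytest.approx(3 * f1.amp1, rel=0.02)
        assert f3.lag1 == pytest.approx(f1.lag1, abs=0.3)

    def test_window_too_short(self):
        with pytest.raises(ValidationError):
            fit_two_gamma(self._cycle(np.zeros(5)))
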