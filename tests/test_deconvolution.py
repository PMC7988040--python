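"""Deconvolution contracts: nuisance estimators, exact solver, event calling."""

import numpy as np
import pytest
from scipy.optimize import nnls

from microgt.deconvolution import (
    AR1Params,
    choose_penalty,
    debias_activity,
    deconvolve_session,
    estimate_ar_coeff,
    estimate_noise,
    extract_events,
    oasis_ar1,
    percentile_baseline,
)
from microgt.simulate import (
    CalciumKernel,
    ModuleStructure,
    SpikeTrainModel,
    simulate_spike_trains,
    spikes_to_fluorescence,
)

FR = 30.0


def nnls_oracle(y, gamma, lam):
    """Exact solution of the penalized problem via non-negative least squares.

    With c = A s (A the lower-triangular gamma-power matrix), the objective
    1/2||As - y||^2 + lam * 1's completes the square to a plain NNLS problem
    against y - lam * A^{-T} 1.
    """
    T = y.size
    A = np.tril(gamma ** np.subtract.outer(np.arange(T), np.arange(T)))
    mu = np.linalg.solve(A.T, np.ones(T))
    s, _ = nnls(A, y - lam * mu)
    c = A @ s
    return 0.5 * np.sum((c - y) ** 2) + lam * s.sum()


class TestEstimators:
    def test_noise_on_pure_gaussian(self):
        errs = []
        for seed in range(50):
            y = np.random.default_rng(seed).normal(0, 1.0, 10_000)
            errs.append(estimate_noise(y))
        assert 0.9 < np.mean(errs) < 1.1
        assert all(0.85 < e < 1.15 for e in errs)

    def test_noise_on_constant_trace_is_zero(self):
        assert estimate_noise(np.full(1000, 3.0)) == pytest.approx(0.0, abs=1e-12)

    def test_noise_on_noiseless_kernel_trace_is_small(self):
        spikes = np.zeros((1, 2000), dtype=int)
        spikes[0, ::200] = 1
        kern = CalciumKernel(decay=0.95, unit_amplitude=1.0, baseline=0.0, noise_sd=0.0)
        tr = spikes_to_fluorescence(spikes, kern, seed=0)[0]
        assert estimate_noise(tr) <= 0.05 * kern.unit_amplitude

    def test_noise_requires_64_samples(self):
        with pytest.raises(ValueError):
            estimate_noise(np.zeros(63))

    @pytest.mark.parametrize("seed", range(10))
    def test_ar_coeff_recovers_gamma(self, seed):
        spikes, _ = simulate_spike_trains(
            SpikeTrainModel(base_rate=2.0), ModuleStructure(), 1, 10_000, FR, seed=seed
        )
        kern = CalciumKernel(decay=0.95, unit_amplitude=1.0, baseline=0.0, noise_sd=0.02)
        tr = spikes_to_fluorescence(spikes, kern, seed=seed + 100)[0]
        assert estimate_ar_coeff(tr) == pytest.approx(0.95, abs=0.02)

    def test_ar_coeff_on_white_noise_is_small(self):
        for seed in range(5):
            y = np.random.default_rng(seed).normal(size=10_000)
            g = estimate_ar_coeff(y)
            assert 0.0 < g <= 0.1

    def test_ar_coeff_always_in_unit_interval(self, rng):
        for _ in range(20):
            y = rng.normal(size=200) + rng.normal() * np.linspace(0, 1, 200)
            assert 0.0 < estimate_ar_coeff(y, lags=3) < 1.0

    def test_ar_coeff_zero_variance_errors(self):
        with pytest.raises(ValueError):
            estimate_ar_coeff(np.ones(1000))


class TestOasis:
    def test_zero_trace_gives_zero_solution(self):
        res = oasis_ar1(np.zeros(100), AR1Params(gamma=0.9), 0.0)
        assert np.all(res.denoised == 0)
        assert np.all(res.activity == 0)

    def test_noiseless_single_event_exact_recovery(self):
        spikes = np.zeros((1, 20), dtype=int)
        spikes[0, 7] = 1
        kern = CalciumKernel(decay=0.9, unit_amplitude=0.6, baseline=0.0, noise_sd=0.0)
        y = spikes_to_fluorescence(spikes, kern, seed=0)[0]
        res = oasis_ar1(y, AR1Params(gamma=0.9), 0.0)
        s = res.activity
        assert np.flatnonzero(s > 1e-6).tolist() == [7]
        assert s[7] == pytest.approx(0.6, abs=1e-6)

    def test_noiseless_multi_event_zero_false_events(self):
        spikes = np.zeros((1, 200), dtype=int)
        spikes[0, [20, 60, 61, 140]] = [1, 2, 1, 3]
        kern = CalciumKernel(decay=0.95, unit_amplitude=0.4, baseline=0.0, noise_sd=0.0)
        y = spikes_to_fluorescence(spikes, kern, seed=0)[0]
        s = oasis_ar1(y, AR1Params(gamma=0.95), 0.0).activity
        detected = np.flatnonzero(s > 1e-8)
        assert detected.tolist() == [20, 60, 61, 140]
        assert np.allclose(s[detected], [0.4, 0.8, 0.4, 1.2], atol=1e-8)

    def test_feasibility_on_random_traces(self, rng):
        for _ in range(20):
            y = rng.normal(size=300)
            g = rng.uniform(0.5, 0.98)
            res = oasis_ar1(y, AR1Params(gamma=g), rng.uniform(0, 1))
            c = res.denoised
            assert np.max(g * c[:-1] - c[1:], initial=0.0) <= 1e-9

    def test_objective_matches_nnls_oracle(self, rng):
        worst = 0.0
        for _ in range(100):
            T = 15
            g = rng.uniform(0.3, 0.98)
            lam = rng.uniform(0.0, 2.0)
            y = rng.normal(0, 1, T)
            res = oasis_ar1(y, AR1Params(gamma=g), lam)
            worst = max(worst, abs(res.objective(y) - nnls_oracle(y, g, lam)))
        assert worst < 1e-6

    def test_sparsity_monotone_in_penalty(self, rng):
        y = rng.normal(0, 0.2, 400) + spikes_to_fluorescence(
            rng.poisson(0.05, (1, 400)),
            CalciumKernel(decay=0.9, unit_amplitude=1.0, baseline=0.0, noise_sd=0.0),
            seed=0,
        )[0]
        params = AR1Params(gamma=0.9)
        counts = [
            int(np.sum(oasis_ar1(y, params, lam).activity > 1e-9))
            for lam in [0.0, 0.1, 0.3, 1.0, 3.0, 10.0]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            oasis_ar1(np.array([0.0, np.nan]), AR1Params(gamma=0.9), 0.0)

    def test_noise_constrained_penalty_matches_residual(self, rng):
        spikes = rng.poisson(0.02, (1, 2000))
        kern = CalciumKernel(decay=0.95, unit_amplitude=0.5, baseline=0.0, noise_sd=0.05)
        y = spikes_to_fluorescence(spikes, kern, seed=1)[0]
        params = AR1Params(gamma=0.95, noise_sd=0.05)
        res, lam = choose_penalty(y, params)
        rss = np.sum((res.denoised - y) ** 2)
        assert rss == pytest.approx(0.05**2 * y.size, rel=0.05)
        assert lam > 0


class TestEventExtraction:
    def _result(self, s, sd=0.1):
        from microgt.deconvolution import DeconvolutionResult

        return DeconvolutionResult(
            denoised=s, activity=s, params=AR1Params(gamma=0.9, noise_sd=sd),
            sparsity_penalty=0.0,
        )

    def test_zero_activity_empty_train(self):
        ev = extract_events(self._result(np.zeros(100)), FR)
        assert ev.n_events == 0

    def test_close_candidates_merge_with_summed_amplitude(self):
        s = np.zeros(100)
        s[10] = 1.0
        s[11] = 0.7
        ev = extract_events(self._result(s), FR, min_separation_ms=5 / FR * 1000)
        assert ev.n_events == 1
        assert ev.times_ms[0] == pytest.approx(10 / FR * 1000)
        assert ev.amplitudes[0] == pytest.approx(1.7)

    def test_separated_candidates_stay_distinct(self):
        s = np.zeros(100)
        s[10] = 1.0
        s[40] = 0.8
        ev = extract_events(self._result(s), FR)
        assert ev.n_events == 2

    def test_detection_recall_precision_at_snr5(self):
        # Poisson ground truth, amplitude/noise = 5: both rates >= 0.9
        hits = tot = tp = det_n = 0
        for seed in range(20):
            spikes, _ = simulate_spike_trains(
                SpikeTrainModel(base_rate=0.1), ModuleStructure(), 8, 3600, FR, seed=seed
            )
            kern = CalciumKernel(decay=0.95, unit_amplitude=0.175, baseline=1.0, noise_sd=0.035)
            traces = spikes_to_fluorescence(spikes, kern, seed=1000 + seed)
            _, trains, _ = deconvolve_session(traces, FR)
            for i, train in enumerate(trains):
                det = np.round(train.times_ms / 1000 * FR).astype(int)
                true = np.flatnonzero(spikes[i])
                hits += sum(1 for t in true if det.size and np.min(np.abs(det - t)) <= 2)
                tot += true.size
                tp += sum(1 for d in det if true.size and np.min(np.abs(true - d)) <= 2)
                det_n += det.size
        assert hits / tot >= 0.9
        assert tp / det_n >= 0.9


def test_percentile_baseline_tracks_offset(rng):
    drift = np.linspace(0.0, 2.0, 6000)
    y = drift + rng.normal(0, 0.05, 6000)
    base = percentile_baseline(y, FR)
    # low-percentile baseline sits slightly below the drift but follows it
    assert np.all(base[1000:-1000] < drift[1000:-1000] + 0.05)
    assert np.corrcoef(base, drift)[0, 1] > 0.99


def test_debias_restores_shrunk_amplitudes(rng):
    spikes = np.zeros((1, 1200), dtype=int)
    spikes[0, 100::150] = 1
    kern = CalciumKernel(decay=0.95, unit_amplitude=0.2, baseline=0.0, noise_sd=0.04)
    y = spikes_to_fluorescence(spikes, kern, seed=3)[0]
    params = AR1Params(gamma=0.95, noise_sd=0.04)
    res, lam = choose_penalty(y, params)
    assert lam > 0
    s2 = debias_activity(res, y)
    true = np.flatnonzero(spikes[0])
    pen_amps = [res.activity[t - 1 : t + 2].max() for t in true]
    deb_amps = [s2[t - 1 : t + 2].max() for t in true]
    assert np.mean(deb_amps) > np.mean(pen_amps)
    assert np.mean(deb_amps) == pytest.approx(0.2, rel=0.15)
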