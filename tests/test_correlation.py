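"""Correlator estimator, FCS models, purification, and fit round trips."""

import numpy as np
import pytest

from alexfret.correlation import (
    CorrelationCurve,
    FCSModelParams,
    bootstrap_sigma,
    correlate,
    correlate_with_error,
    diffusion_curve,
    fit_divided,
    fit_global,
    fit_kinetic_exponential,
    kinetic_amplitudes,
    make_lag_edges,
    model_curve,
    pinhole_tau_factor,
    purify,
    radius_from_fit,
    rates_from_relaxation,
)
from alexfret.photons import BASE_DT, PhotonStream


def _poisson_times(rate, duration, rng):
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0, duration, n))


class TestCorrelator:
    def test_flat_for_poisson_stream(self, rng):
        t = _poisson_times(20e3, 10.0, rng)
        c = correlate_with_error(t, duration=10.0,
                                 edges=make_lag_edges(1e-6, 0.4))
        assert np.all(np.abs(c.values) < 4 * np.maximum(c.sigma, 1e-12))

    def test_uncorrelated_cross_channels(self, rng):
        a = _poisson_times(15e3, 10.0, rng)
        b = _poisson_times(10e3, 10.0, rng)
        c = correlate(a, b, duration=10.0, edges=make_lag_edges(1e-6, 0.4))
        assert np.abs(c.values).max() < 0.1

    def test_blinking_molecule_matches_kinetic_model(self, rng):
        # telegraph intensity: exact exponential correlation decay
        from alexfret.config import immobile_config
        from alexfret.kinetics import TwoStateModel
        from alexfret.photons import split_channels
        from alexfret.simulate import simulate_experiment

        cfg = immobile_config(g_barrier=9.0, duration=10.0, seed=5)
        stream = simulate_experiment(cfg)
        ch = split_channels(stream)
        curve = correlate_with_error(
            ch["A514"], edges=make_lag_edges(1e-6, 0.2)
        )
        model = TwoStateModel.from_barrier(9.0, 1.5)
        fit = fit_kinetic_exponential(curve, K=model.K)
        assert fit.params["tau_K"] == pytest.approx(model.tau_K, rel=0.15)
        amp = kinetic_amplitudes(model.occupancy1, 0.8, 0.1)["AA"]
        assert fit.params["amplitude"] == pytest.approx(amp, rel=0.15)

    def test_alex_modulation_oscillations(self):
        # donor-excited detection oscillates at the 1 us ALEX period
        from alexfret.config import ExperimentConfig, SpeciesConfig
        from alexfret.photons import split_channels
        from alexfret.simulate import simulate_experiment

        cfg = ExperimentConfig(
            duration=20.0, seed=6,
            species=[SpeciesConfig("x", 5, "both", (10e-9, 10e-9), (0.8, 0.1))],
        )
        stream = simulate_experiment(cfg)
        ch = split_channels(stream)
        fine = np.arange(1, 61) * 1e-7  # 100 ns bins up to 6 us
        c = correlate(ch["A514"], duration=cfg.duration, edges=fine)
        on_peak = c.values[9::10]  # lags at multiples of 1 us
        off_peak = c.values[4::10]  # half-period offsets
        assert on_peak.mean() > off_peak.mean() + 0.5

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.array([]), duration=1.0)


class TestBootstrap:
    def test_sigma_scales_with_duration(self, rng):
        edges = make_lag_edges(1e-5, 0.05)
        sig = {}
        for T in (5.0, 20.0):
            reps = []
            for _ in range(3):
                t = _poisson_times(20e3, T, rng)
                reps.append(bootstrap_sigma(t, duration=T, edges=edges))
            sig[T] = np.mean(reps, axis=0)
        # quadrupling the duration roughly halves the error
        ratio = np.median(sig[5.0] / sig[20.0])
        assert 1.4 < ratio < 2.9

    def test_truncates_long_lags(self, rng):
        t = _poisson_times(20e3, 2.0, rng)
        with pytest.warns(UserWarning, match="truncating"):
            sig = bootstrap_sigma(t, duration=2.0, edges=make_lag_edges(1e-5, 1.0))
        assert sig.size < make_lag_edges(1e-5, 1.0).size - 1


class TestPurify:
    def _stream(self, times_s, duration=1.0):
        ts = np.round(np.asarray(times_s) / BASE_DT).astype(np.int64)
        n = ts.size
        return PhotonStream(ts, np.zeros(n, np.uint8), np.zeros(n, np.uint8), duration)

    def _bursts(self, intervals):
        import pandas as pd

        return pd.DataFrame(
            {"start_s": [a for a, _ in intervals], "end_s": [b for _, b in intervals]}
        )

    def test_zero_window_keeps_burst_photons_only(self):
        s = self._stream([0.10, 0.20, 0.21, 0.22, 0.30])
        t = s.times  # window edges from the same clock as the photons
        out = purify(s, self._bursts([(t[1], t[3])]), 0.0)
        assert len(out) == 3

    def test_full_window_keeps_everything(self):
        s = self._stream([0.1, 0.5, 0.9])
        out = purify(s, self._bursts([(0.4, 0.6)]), 10.0)
        assert len(out) == 3

    def test_window_merging(self):
        # bursts 1 ms apart: +/- 1 ms windows overlap and merge into one
        s = self._stream([0.1945, 0.1970])
        bursts = self._bursts([(0.195, 0.196), (0.197, 0.198)])
        out = purify(s, bursts, 1e-3)
        assert len(out) == 2
        assert len(np.asarray(out.metadata["purify_windows"])) == 1
        # distant bursts stay separate
        far = purify(s, self._bursts([(0.195, 0.196), (0.204, 0.205)]), 1e-3)
        assert len(np.asarray(far.metadata["purify_windows"])) == 2

    def test_duration_preserved_for_normalization(self):
        s = self._stream([0.5], duration=3.0)
        out = purify(s, self._bursts([(0.4, 0.6)]), 1e-3)
        assert out.duration == 3.0


class TestModels:
    def test_kinetic_factor_vanishes_for_equal_fret(self):
        p = FCSModelParams(tau_D=1e-3, E1=0.5, E2=0.5, tau_K=1e-3, f1=0.6)
        with pytest.warns(UserWarning):
            c = model_curve(p, "AA", np.geomspace(1e-6, 1e-1, 20))
        pure = p.C0 * diffusion_curve(np.geomspace(1e-6, 1e-1, 20), 1e-3, p.aspect)
        assert np.allclose(c, pure)

    def test_extreme_fret_amplitudes(self):
        # f1 = f2 = 0.5, E1 = 1, E2 = 0: DxD and AxA double, DxA vanishes
        amps = kinetic_amplitudes(0.5, 1.0, 0.0)
        assert amps["DD"] == pytest.approx(1.0)
        assert amps["AA"] == pytest.approx(1.0)
        assert amps["DA"] == pytest.approx(1.0)
        p = FCSModelParams(tau_D=1e-3, f1=0.5, E1=1.0, E2=0.0, tau_K=1e-3)
        tau = np.array([1e-9])
        assert model_curve(p, "DD", tau)[0] == pytest.approx(2.0 * p.C0, rel=1e-3)
        assert model_curve(p, "DA", tau)[0] == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("f1,E1,E2", [(0.3, 0.9, 0.2), (0.8, 0.8, 0.1), (0.5, 0.6, 0.4)])
    def test_amplitude_identity(self, f1, E1, E2):
        # (A_DA)^2 = A_DD * A_AA at alpha = 0, beta = 1
        amps = kinetic_amplitudes(f1, E1, E2)
        assert amps["DA"] ** 2 == pytest.approx(amps["DD"] * amps["AA"], rel=1e-12)

    def test_long_lag_limit(self):
        p = FCSModelParams(tau_D=1e-3, tau_K=1e-4)
        c = model_curve(p, "AA", np.array([1e2]))
        assert c[0] < 1e-3
        # half amplitude at tau = tau_D for an infinitely elongated focus
        p2 = FCSModelParams(tau_D=1e-3, aspect=1e9, tau_K=None)
        assert model_curve(p2, "AA", np.array([1e-3]))[0] == pytest.approx(0.5, rel=1e-4)

    def test_conformational_signs(self):
        p = FCSModelParams(tau_D=1e-3, f1=0.8, E1=0.8, E2=0.1, tau_K=1e-3)
        tau = np.array([1e-6])
        base = p.C0 * diffusion_curve(tau, p.tau_D, p.aspect)
        assert model_curve(p, "AA", tau)[0] > base[0]
        assert model_curve(p, "DD", tau)[0] > base[0]
        assert model_curve(p, "DA", tau)[0] < base[0]


class TestFitRoundTrips:
    lags = make_lag_edges(2e-6, 5.0)
    grid = np.sqrt(lags[:-1] * lags[1:])

    def _curve(self, p, pair):
        v = model_curve(p, pair, self.grid)
        return CorrelationCurve(self.grid, v, np.full_like(v, 1e-3), pair, 60.0)

    def test_divided_case_two_exact_recovery(self):
        p = FCSModelParams(
            C0=5.0, tau_D=None, tau_D1=1.7e-3, tau_D2=2.5e-3,
            f1=0.818, E1=0.8, E2=0.1, tau_K=30e-3,
        )
        aa, da = self._curve(p, "AA"), self._curve(p, "DA")
        fit = fit_divided(
            aa, da, "II",
            {"E1": 0.8, "E2": 0.1, "K": p.f1 / (1 - p.f1),
             "tau_D1": 1.7e-3, "tau_D2": 2.5e-3},
        )
        assert fit.params["tau_K"] == pytest.approx(30e-3, rel=1e-4)
        assert fit.chisqr < 1e-10
        k12, k21 = rates_from_relaxation(fit.params["tau_K"], fit.params["K"])
        assert k12 == pytest.approx((1 - p.f1) / 30e-3, rel=1e-3)
        assert fit.k12 == pytest.approx(k12)

    def test_divided_case_one_recovers_relaxation(self):
        p = FCSModelParams(C0=5.0, tau_D=2e-3, f1=0.6, E1=0.75, E2=0.25, tau_K=2e-4)
        aa, da = self._curve(p, "AA"), self._curve(p, "DA")
        e_overlap = p.f1 * p.E1 + (1 - p.f1) * p.E2
        fit = fit_divided(aa, da, "I", {"E_overlap": e_overlap})
        assert fit.params["tau_K"] == pytest.approx(2e-4, rel=1e-3)
        assert fit.chisqr < 1e-8
        # the identifiable amplitude combination is recovered even though
        # K and dE individually are degenerate
        K, dE = fit.params["K"], fit.params["dE"]
        f1 = K / (1 + K)
        assert f1 * (1 - f1) * dE**2 == pytest.approx(
            p.f1 * (1 - p.f1) * (p.E1 - p.E2) ** 2, rel=1e-3
        )

    def test_divided_ratio_tends_to_one_case_one(self):
        p = FCSModelParams(C0=5.0, tau_D=2e-3, f1=0.6, E1=0.75, E2=0.25, tau_K=2e-4)
        aa, da = self._curve(p, "AA"), self._curve(p, "DA")
        ratio = aa.values / da.values
        assert ratio[-1] == pytest.approx(1.0, rel=1e-6)
        assert ratio[0] > 1.2

    def test_global_exact_recovery(self):
        p = FCSModelParams(
            C0=5.0, tau_D=None, tau_D1=1.7e-3, tau_D2=2.5e-3,
            f1=0.818, E1=0.8, E2=0.1, tau_K=30e-3,
        )
        curves = {pr: self._curve(p, pr) for pr in ("DD", "AA", "DA")}
        fit = fit_global(
            curves, "II",
            {"E1": 0.8, "E2": 0.1, "K": p.f1 / (1 - p.f1),
             "tau_D1": 1.7e-3, "tau_D2": 2.5e-3},
        )
        assert fit.params["tau_K"] == pytest.approx(30e-3, rel=1e-3)
        for pr in ("DD", "AA", "DA"):
            assert fit.params[f"C0_{pr}"] == pytest.approx(5.0, rel=1e-3)
        assert fit.chisqr < 1e-8

    def test_global_two_curve_variant(self):
        p = FCSModelParams(C0=3.0, tau_D=2e-3, f1=0.6, E1=0.75, E2=0.25, tau_K=2e-4)
        curves = {pr: self._curve(p, pr) for pr in ("AA", "DA")}
        e_overlap = p.f1 * p.E1 + (1 - p.f1) * p.E2
        fit = fit_global(curves, "I", {"E_overlap": e_overlap})
        assert fit.params["tau_K"] == pytest.approx(2e-4, rel=0.01)

    def test_kinetic_exponential_round_trip(self):
        tau = self.grid
        vals = 0.02 + 0.3 * np.exp(-tau / 5e-4)
        curve = CorrelationCurve(tau, vals, np.full_like(vals, 1e-4), "AA", 60.0)
        fit = fit_kinetic_exponential(curve)
        assert fit.params["tau_K"] == pytest.approx(5e-4, rel=1e-4)
        assert fit.params["offset"] == pytest.approx(0.02, abs=1e-4)


class TestRadiusConversion:
    def test_linear_in_diffusion_time(self):
        r1 = radius_from_fit(1e-3, 2.14e-7)
        r2 = radius_from_fit(2e-3, 2.14e-7)
        assert r2 == pytest.approx(2 * r1)

    def test_gaussian_profile_round_trip(self):
        from alexfret.brownian import diffusion_coefficient

        R = 10e-9
        omega = 2.1417e-7
        tau_d = omega**2 / diffusion_coefficient(R)  # 1/e^2 convention
        assert radius_from_fit(tau_d, omega) == pytest.approx(R, rel=1e-6)

    def test_pinhole_factor_shortens_tau(self):
        kappa = pinhole_tau_factor(50e-6 / 120 / 2.1417e-7, 8.0)
        assert 0.6 < kappa < 0.9
        # opening the pinhole recovers the Gaussian convention
        assert pinhole_tau_factor(10.0, 8.0) == pytest.approx(1.0, abs=0.02)

    def test_literal_convention(self):
        # literal Eq: D = omega^2/(4 tau) is 4x smaller, so R is 4x larger
        assert radius_from_fit(1e-3, 2e-7, convention="literal") == pytest.approx(
            4 * radius_from_fit(1e-3, 2e-7)
        )
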