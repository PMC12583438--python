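"""Burst search, E/S algebra, population fitting, and correction estimation."""

import numpy as np
import pandas as pd
import pytest

from alexfret.bursts import (
    burst_es,
    corrected_es,
    estimate_corrections,
    find_bursts,
    fit_fret_histogram,
    select_bursts,
)
from alexfret.photons import BASE_DT, PhotonStream


def _stream_from_times(times_s, em=None, ex=None, duration=None):
    ts = np.asarray(np.round(np.asarray(times_s) / BASE_DT), dtype=np.int64)
    n = ts.size
    em = np.zeros(n, np.uint8) if em is None else np.asarray(em, np.uint8)
    ex = np.zeros(n, np.uint8) if ex is None else np.asarray(ex, np.uint8)
    duration = duration or (times_s[-1] + 1e-3 if n else 1.0)
    return PhotonStream(ts, em, ex, duration)


class TestBurstSearch:
    def test_below_threshold_no_burst(self):
        s = _stream_from_times(np.arange(24) * 1e-6)
        assert len(find_bursts(s)) == 0

    def test_at_threshold_one_burst(self):
        s = _stream_from_times(np.arange(25) * 1e-6)
        df = find_bursts(s)
        assert len(df) == 1
        assert df.iloc[0]["n_photons"] == 25

    def test_long_gap_splits_and_drops_halves(self):
        # 50 photons with a 300 us gap in the middle: both halves < 25
        t = np.concatenate([np.arange(24) * 1e-6, 324e-6 + np.arange(26) * 1e-6])
        df = find_bursts(_stream_from_times(t))
        assert len(df) == 1  # only the 26-photon half survives
        t2 = np.concatenate([np.arange(24) * 1e-6, 324e-6 + np.arange(24) * 1e-6])
        assert len(find_bursts(_stream_from_times(t2))) == 0

    def test_exact_gap_boundary_is_strict(self):
        # a gap of exactly 200 us splits (comparison is strict)
        t = np.concatenate([np.arange(25) * 1e-6, 25e-6 + 200e-6 + np.arange(25) * 1e-6])
        df = find_bursts(_stream_from_times(t))
        assert len(df) == 2

    def test_channel_relabeling_invariance(self, rng):
        t = np.sort(rng.uniform(0, 0.1, 2000))
        em = rng.integers(0, 2, t.size)
        ex = rng.integers(0, 2, t.size)
        a = find_bursts(_stream_from_times(t, em, ex))
        b = find_bursts(_stream_from_times(t, 1 - em, ex))
        assert np.array_equal(a["i_start"], b["i_start"])
        assert np.array_equal(a["n_photons"], b["n_photons"])


class TestESAlgebra:
    def test_basic_values(self):
        e, s, valid = burst_es([80], [20], [100])
        assert e[0] == pytest.approx(0.8)
        assert s[0] == pytest.approx(0.5)
        assert valid[0]

    def test_edge_cases(self):
        e, _, _ = burst_es([0], [50], [10])
        assert e[0] == 0.0
        _, s, _ = burst_es([30], [30], [0])
        assert s[0] == 1.0  # donor-only signature

    def test_corrections_identity_at_defaults(self):
        df = pd.DataFrame(
            {"A514": [80], "D514": [20], "A632": [100], "E_raw": [0.8], "S_raw": [0.5],
             "valid": [True]}
        )
        out = corrected_es(df, 0.0, 1.0, 0.0)
        assert out["E_corr"].iloc[0] == pytest.approx(0.8)
        assert out["S_corr"].iloc[0] == pytest.approx(0.5)

    def test_leakage_correction_value(self):
        df = pd.DataFrame(
            {"A514": [28], "D514": [80], "A632": [100], "valid": [True]}
        )
        out = corrected_es(df, alpha=0.1, beta=1.0, delta_dir=0.0)
        assert out["E_corr"].iloc[0] == pytest.approx(20 / 100)

    def test_direct_excitation_subtraction(self):
        df = pd.DataFrame(
            {"A514": [30], "D514": [70], "A632": [100], "valid": [True]}
        )
        out = corrected_es(df, alpha=0.0, beta=1.0, delta_dir=0.05)
        assert out["E_corr"].iloc[0] == pytest.approx(25 / 95)

    def test_negative_corrected_counts_propagate(self):
        df = pd.DataFrame({"A514": [1], "D514": [50], "A632": [0], "valid": [True]})
        out = corrected_es(df, alpha=0.1, beta=1.0)
        assert out["E_corr"].iloc[0] < 0  # unclipped


class TestSelection:
    def _table(self, e, s):
        return pd.DataFrame(
            {"E_corr": e, "S_corr": s, "E_raw": e, "S_raw": s,
             "valid": np.ones(len(e), bool)}
        )

    def test_strictly_inside(self):
        df = self._table([0.5, 0.2, 0.8], [0.5, 0.2, 0.8])
        out = select_bursts(df, e_range=(0.2, 0.8), s_range=(0.2, 0.8))
        assert len(out) == 1

    def test_s_window_removes_single_labeled(self):
        df = self._table([0.1, 0.8, 0.05], [0.99, 0.5, 0.01])
        out = select_bursts(df, s_range=(0.2, 0.8))
        assert len(out) == 1 and out["S_corr"].iloc[0] == 0.5

    def test_empty_intersection_ok(self):
        df = self._table([0.5], [0.5])
        assert len(select_bursts(df, e_range=(0.9, 1.0), s_range=(0.0, 0.1))) == 0


class TestPopulationFit:
    def _bursts_from_normals(self, rng, means, sigmas, weights, n=2000):
        comp = rng.choice(len(means), size=n, p=weights)
        e = rng.normal(np.asarray(means)[comp], np.asarray(sigmas)[comp])
        return pd.DataFrame({"E_corr": e, "E_raw": e, "valid": np.ones(n, bool)})

    def test_well_separated_two_populations(self, rng):
        df = self._bursts_from_normals(rng, [0.8, 0.1], [0.05, 0.05], [0.7, 0.3])
        fit = fit_fret_histogram(df, n_components=3)
        fit = fit.sorted_by_mean()
        assert fit.means[0] == pytest.approx(0.1, abs=0.02)
        assert fit.means[-1] == pytest.approx(0.8, abs=0.02)
        assert not fit.overlap

    def test_single_population_prunes_components(self, rng):
        df = self._bursts_from_normals(rng, [0.5], [0.1], [1.0])
        fit = fit_fret_histogram(df, n_components=3)
        assert fit.n_components <= 2
        assert np.average(fit.means, weights=fit.weights) == pytest.approx(0.5, abs=0.03)

    def test_overlapping_populations_flagged(self, rng):
        # 0.5 +/- 0.15 and 0.6 +/- 0.15 merge in the histogram (case I)
        df = self._bursts_from_normals(rng, [0.5, 0.6], [0.15, 0.15], [0.5, 0.5], n=4000)
        fit = fit_fret_histogram(df, n_components=3)
        assert fit.overlap

    def test_too_few_bursts_raises(self, rng):
        df = self._bursts_from_normals(rng, [0.5], [0.1], [1.0], n=10)
        with pytest.raises(ValueError, match="bursts"):
            fit_fret_histogram(df)


class TestCorrectionEstimation:
    def _mixed_table(self, rng, alpha, n=300):
        # donor-only bursts: E = alpha/(1+alpha), S ~ 1
        n_do = n
        d514 = rng.poisson(80, n_do)
        a514 = rng.binomial(d514, alpha)
        do = pd.DataFrame({"A514": a514, "D514": d514, "A632": np.zeros(n_do)})
        # acceptor-only: no 514 signal except nothing here (delta = 0)
        ao = pd.DataFrame(
            {"A514": rng.poisson(0.5, n), "D514": np.zeros(n),
             "A632": rng.poisson(80, n)}
        )
        df = pd.concat([do, ao], ignore_index=True)
        e, s, valid = burst_es(df["A514"], df["D514"], df["A632"])
        df["E_raw"], df["S_raw"], df["valid"] = e, s, valid
        return df

    def test_recovers_leakage(self, rng):
        df = self._mixed_table(rng, alpha=0.1)
        alpha_hat, delta_hat = estimate_corrections(df)
        assert alpha_hat == pytest.approx(0.1, abs=0.02)
        assert delta_hat == pytest.approx(0.0, abs=0.02)

    def test_zero_leakage(self, rng):
        df = self._mixed_table(rng, alpha=0.0)
        alpha_hat, _ = estimate_corrections(df)
        assert alpha_hat == pytest.approx(0.0, abs=0.01)

    def test_correction_recenters_donor_only(self, rng):
        df = self._mixed_table(rng, alpha=0.1)
        alpha_hat, delta_hat = estimate_corrections(df)
        out = corrected_es(df, alpha_hat, 1.0, delta_hat)
        do = out[out["S_raw"] > 0.9]
        assert abs(do["E_corr"].mean()) < 0.02

    def test_missing_population_raises(self, rng):
        df = self._mixed_table(rng, alpha=0.1)
        df = df[df["S_raw"] > 0.5]  # drop acceptor-only
        with pytest.raises(ValueError, match="manually"):
            estimate_corrections(df)
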