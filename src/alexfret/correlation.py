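"""Photon correlation analysis: correlator, purified FCS, models, and fits.

The correlator counts photon pairs into log-spaced lag bins directly from the
time tags,

    C(tau) = <I_A(t) I_B(t+tau)> / (<I_A><I_B>) - 1,

estimated per bin [tau_k, tau_k+1) as the pair count normalized by the number
of lattice lag offsets in the bin and the effective overlap time (T - tau).
Zero-lag self pairs never enter because the lag grid starts above zero.
Statistical errors come from splitting the measurement into equal segments
and scaling the segment-to-segment standard deviation down by sqrt(n);
fits are weighted by 1/sigma_C.

Model family for a two-state FRET system (donor-excitation channels):

    C_pair(tau) = C0 * C_diff,pair(tau) * C_kin,pair(tau)

with the single-species diffusion factor

    C_diff(tau) = (1 + tau/tau_D)^-1 (1 + tau/(a^2 tau_D))^-1/2,

a FRET-brightness-weighted two-component mixture when the states diffuse
differently (weights (1-E_i)^2, E_i^2 and E_i(1-E_i) for DxD, AxA and DxA),
and kinetic factors 1 +/- A_pair * exp(-tau/tau_K) whose amplitudes carry the
leakage alpha and relative brightness beta.  Conformational exchange raises
the two autocorrelations and lowers the cross-correlation; at alpha=0,
beta=1 the amplitudes obey A_DA^2 = A_DD * A_AA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .brownian import DEFAULT_TEMPERATURE, DEFAULT_VISCOSITY
from .photons import BASE_DT, PhotonStream
from scipy import constants

__all__ = [
    "CorrelationCurve",
    "FCSModelParams",
    "FitResult",
    "make_lag_edges",
    "correlate",
    "bootstrap_sigma",
    "correlate_with_error",
    "purify",
    "diffusion_curve",
    "kinetic_amplitudes",
    "model_curve",
    "fit_kinetic_exponential",
    "fit_diffusion",
    "fit_divided",
    "fit_global",
    "radius_from_fit",
    "rates_from_relaxation",
]


# --------------------------------------------------------------------------
# correlator


@dataclass
class CorrelationCurve:
    """Correlation values on a log-spaced lag grid for one channel pair."""

    lags: np.ndarray  # s, strictly increasing (geometric bin centers)
    values: np.ndarray
    sigma: np.ndarray | None
    pair: str = ""
    duration: float = 0.0
    n_a: int = 0
    n_b: int = 0
    edges: np.ndarray | None = None  # bin edges, s

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.sigma is not None and np.any(np.asarray(self.sigma) < 0):
            raise ValueError("sigma must be non-negative")

    def restrict(self, min_lag: float = 0.0, max_lag: float = np.inf) -> "CorrelationCurve":
        m = (self.lags >= min_lag) & (self.lags <= max_lag)
        return CorrelationCurve(
            self.lags[m],
            self.values[m],
            None if self.sigma is None else self.sigma[m],
            self.pair,
            self.duration,
            self.n_a,
            self.n_b,
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"lag_s": self.lags, "C": self.values}
        if self.sigma is not None:
            d["sigma_C"] = self.sigma
        return pd.DataFrame(d)


def make_lag_edges(
    min_lag: float = 1e-6,
    max_lag: float = 10.0,
    points_per_decade: int = 12,
    base_dt: float = BASE_DT,
) -> np.ndarray:
    """Log-spaced lag-bin edges snapped to the 100 ns lattice (in seconds)."""
    n = int(np.ceil(np.log10(max_lag / min_lag) * points_per_decade)) + 1
    edges = np.geomspace(min_lag, max_lag, n)
    steps = np.unique(np.round(edges / base_dt).astype(np.int64))
    steps = steps[steps >= 1]
    return steps * base_dt


def _as_steps(stream, base_dt: float | None):
    if isinstance(stream, PhotonStream):
        return stream.timestamps, stream.base_dt, stream.duration
    t = np.asarray(stream, dtype=float)
    dt = BASE_DT if base_dt is None else base_dt
    return np.round(t / dt).astype(np.int64), dt, None


def correlate(
    stream_a,
    stream_b=None,
    duration: float | None = None,
    edges: np.ndarray | None = None,
    base_dt: float | None = None,
    pair: str = "",
) -> CorrelationCurve:
    """Photon-pair correlation of two time-tag sequences on a log-lag grid.

    ``stream_a``/``stream_b`` are :class:`PhotonStream` objects or arrays of
    arrival times in seconds; ``stream_b=None`` gives the autocorrelation.
    ``duration`` (s) is required when passing bare arrays.  The normalization
    uses the mean rates over the full duration, so a gated (purified) stream
    keeps its original time axis with non-selected intensity counted as zero.
    """
    ts_a, dt, dur_a = _as_steps(stream_a, base_dt)
    if stream_b is None:
        ts_b, dur_b = ts_a, dur_a
    else:
        ts_b, dt_b, dur_b = _as_steps(stream_b, base_dt)
        if isinstance(stream_b, PhotonStream) and abs(dt_b - dt) > 1e-15:
            raise ValueError("streams have different base time steps")
    if duration is None:
        duration = dur_a if dur_a is not None else dur_b
    if duration is None:
        raise ValueError("duration required when correlating bare time arrays")
    if ts_a.size == 0 or ts_b.size == 0:
        raise ValueError("cannot correlate an empty photon stream")
    if edges is None:
        edges = make_lag_edges(max_lag=min(10.0, duration / 2), base_dt=dt)
    edge_steps = np.round(np.asarray(edges) / dt).astype(np.int64)

    # cumulative forward-pair counts at every edge
    cum = np.empty(edge_steps.size, dtype=np.float64)
    for i, e in enumerate(edge_steps):
        cum[i] = np.searchsorted(ts_b, ts_a + e, side="left").sum()
    pairs = np.diff(cum)

    n_steps = int(round(duration / dt))
    width = np.diff(edge_steps).astype(float)  # lattice offsets per bin
    mid = 0.5 * (edge_steps[:-1] + edge_steps[1:])
    overlap = np.maximum(n_steps - mid, 1.0)  # steps with both t and t+tau inside
    mean_a = ts_a.size / n_steps
    mean_b = ts_b.size / n_steps
    values = pairs / (width * overlap * mean_a * mean_b) - 1.0
    lags = np.sqrt(edge_steps[:-1].astype(float) * edge_steps[1:]) * dt
    return CorrelationCurve(
        lags, values, None, pair, duration, ts_a.size, ts_b.size,
        edges=edge_steps * dt,
    )


def bootstrap_sigma(
    stream_a,
    stream_b=None,
    duration: float | None = None,
    edges: np.ndarray | None = None,
    n_segments: int = 10,
    base_dt: float | None = None,
) -> np.ndarray:
    """Per-lag standard deviation of the correlation estimator.

    The measurement is split into ``n_segments`` equal segments; the standard
    deviation across segment-wise curves, divided by sqrt(n_segments), scales
    the scatter to the full-length estimator.  Lags longer than half a
    segment are truncated (with a warning) before segmenting.
    """
    ts_a, dt, dur_a = _as_steps(stream_a, base_dt)
    ts_b = ts_a if stream_b is None else _as_steps(stream_b, base_dt)[0]
    if duration is None:
        duration = dur_a
    if duration is None:
        raise ValueError("duration required")
    if edges is None:
        edges = make_lag_edges(max_lag=duration / (2 * n_segments), base_dt=dt)
    edges = np.asarray(edges)
    seg_len = duration / n_segments
    if edges[-1] > seg_len / 2:
        warnings.warn(
            "maximum lag exceeds half a bootstrap segment; truncating lag range",
            stacklevel=2,
        )
        edges = edges[edges <= seg_len / 2]
    seg_steps = int(round(seg_len / dt))
    curves = []
    for s in range(n_segments):
        lo, hi = s * seg_steps, (s + 1) * seg_steps
        sel_a = ts_a[(ts_a >= lo) & (ts_a < hi)] - lo
        sel_b = ts_b[(ts_b >= lo) & (ts_b < hi)] - lo
        if sel_a.size == 0 or sel_b.size == 0:
            continue
        c = correlate(
            sel_a * dt, None if stream_b is None else sel_b * dt,
            duration=seg_len, edges=edges, base_dt=dt,
        )
        curves.append(c.values)
    if len(curves) < 2:
        raise ValueError("too few non-empty segments for a bootstrap error")
    return np.std(np.array(curves), axis=0, ddof=1) / np.sqrt(len(curves))


def correlate_with_error(
    stream_a,
    stream_b=None,
    duration: float | None = None,
    edges: np.ndarray | None = None,
    n_segments: int = 10,
    base_dt: float | None = None,
    pair: str = "",
) -> CorrelationCurve:
    """Correlation curve with bootstrap errors on a shared lag grid."""
    curve = correlate(stream_a, stream_b, duration, edges, base_dt, pair)
    sigma = bootstrap_sigma(
        stream_a, stream_b, duration or curve.duration, curve.edges, n_segments, base_dt
    )
    n_sig = sigma.size
    curve.lags = curve.lags[:n_sig]
    curve.values = curve.values[:n_sig]
    curve.edges = curve.edges[: n_sig + 1]
    curve.sigma = sigma
    return curve


# --------------------------------------------------------------------------
# purified FCS


def purify(
    stream: PhotonStream,
    bursts: pd.DataFrame,
    t_purify: float,
) -> PhotonStream:
    """Keep photons within ``t_purify`` of any selected burst.

    Windows [start - t_purify, end + t_purify] are merged when overlapping.
    The returned stream keeps the original duration, so downstream
    correlation normalizes by the full-duration mean with non-selected
    intensity treated as zero.
    """
    if len(bursts) == 0:
        return stream.select(np.zeros(len(stream), dtype=bool))
    starts = np.sort(bursts["start_s"].to_numpy()) - t_purify
    ends = np.sort(bursts["end_s"].to_numpy()) + t_purify
    merged_s, merged_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    ms = np.clip(np.array(merged_s), 0.0, stream.duration)
    me = np.clip(np.array(merged_e), 0.0, stream.duration)
    t = stream.times
    idx = np.searchsorted(ms, t, side="right") - 1
    keep = (idx >= 0) & (t <= me[np.clip(idx, 0, None)])
    out = stream.select(keep)
    out.metadata = dict(
        out.metadata,
        purify_windows=np.column_stack([ms, me]).tolist(),
        t_purify=t_purify,
    )
    return out


def _interval_self_overlap(ms: np.ndarray, me: np.ndarray, tau: float) -> float:
    """|U ∩ (U - tau)| for a union U of sorted disjoint intervals."""
    s2, e2 = ms + tau, me + tau
    i = j = 0
    tot = 0.0
    n = ms.size
    while i < n and j < n:
        lo = ms[i] if ms[i] > s2[j] else s2[j]
        hi = me[i] if me[i] < e2[j] else e2[j]
        if hi > lo:
            tot += hi - lo
        if me[i] < e2[j]:
            i += 1
        else:
            j += 1
    return tot


def gate_factor(
    windows: np.ndarray, lags: np.ndarray, duration: float
) -> np.ndarray:
    """Autocorrelation factor of the purify gate at each lag.

    For gate indicator w(t) (union of merged windows), returns
    <w(t) w(t+tau)> / <w>^2 = A(tau) * T / W^2 with A the self-overlap and
    W the total gated time.  Dividing the gated correlation (plus one) by
    this factor removes the spurious decay the gating itself imprints at
    lags comparable to the window length.
    """
    windows = np.asarray(windows, dtype=float)
    ms, me = windows[:, 0], windows[:, 1]
    W = float(np.sum(me - ms))
    if W <= 0:
        raise ValueError("empty gate")
    A = np.array([_interval_self_overlap(ms, me, la) for la in np.asarray(lags)])
    return A * duration / W**2


def correlate_purified(
    stream_a: PhotonStream,
    stream_b: PhotonStream | None = None,
    edges: np.ndarray | None = None,
    n_segments: int = 10,
    pair: str = "",
) -> CorrelationCurve:
    """Gate-corrected correlation of purified streams (with bootstrap errors).

    ``stream_a``/``stream_b`` must come from :func:`purify` (their metadata
    carries the gate windows).  The raw full-duration-normalized correlation
    is divided by the gate autocorrelation factor so the molecular shape
    survives at lags comparable to the window length.
    """
    if "purify_windows" not in stream_a.metadata:
        raise ValueError("stream was not produced by purify()")
    curve = correlate_with_error(stream_a, stream_b, edges=edges,
                                 n_segments=n_segments, pair=pair)
    gf = gate_factor(
        np.asarray(stream_a.metadata["purify_windows"]), curve.lags, curve.duration
    )
    curve.values = (curve.values + 1.0) / gf - 1.0
    if curve.sigma is not None:
        curve.sigma = curve.sigma / gf
    return curve


# --------------------------------------------------------------------------
# models


@dataclass
class FCSModelParams:
    """Parameters of the two-state FRET-FCS correlation model."""

    C0: float = 1.0
    tau_D: float | None = 1e-3  # shared diffusion time (case I), s
    tau_D1: float | None = None  # per-state diffusion times (case II), s
    tau_D2: float | None = None
    aspect: float = 8.0
    f1: float = 0.5
    E1: float = 0.8
    E2: float = 0.1
    alpha: float = 0.0
    beta: float = 1.0
    tau_K: float | None = None  # no kinetic term when None
    case: str = "II"


def diffusion_curve(tau: np.ndarray, tau_d: float, aspect: float) -> np.ndarray:
    """Single-species 3D diffusion factor of the correlation function."""
    x = np.asarray(tau, dtype=float) / tau_d
    return 1.0 / ((1.0 + x) * np.sqrt(1.0 + x / aspect**2))


def kinetic_amplitudes(
    f1: float, E1: float, E2: float, alpha: float = 0.0, beta: float = 1.0
) -> dict[str, float]:
    """Conformational-exchange amplitudes for D×D, A×A and D×A.

    The cross-correlation amplitude enters the model with a minus sign.
    """
    f2 = 1.0 - f1
    ebar = f1 * E1 + f2 * E2
    de2 = (E1 - E2) ** 2
    a_dd = f1 * f2 * de2 / (1.0 - ebar) ** 2
    a_aa = (
        f1 * f2 * de2 * (beta - alpha) ** 2
        / (beta * ebar + alpha * (1.0 - ebar)) ** 2
    )
    a_da = (
        f1 * f2 * de2 * (beta - alpha)
        / (beta * (1.0 - ebar) * ebar + alpha * (1.0 - ebar) ** 2)
    )
    return {"DD": a_dd, "AA": a_aa, "DA": a_da}


_PAIR_WEIGHTS = {
    "DD": lambda E: (1.0 - E) ** 2,
    "AA": lambda E: E**2,
    "DA": lambda E: E * (1.0 - E),
}


def _diffusion_factor(p: FCSModelParams, pair: str, tau: np.ndarray) -> np.ndarray:
    two_species = p.tau_D1 is not None and p.tau_D2 is not None
    if two_species and not np.isclose(p.tau_D1, p.tau_D2):
        w = _PAIR_WEIGHTS[pair]
        w1 = p.f1 * w(p.E1)
        w2 = (1.0 - p.f1) * w(p.E2)
        c1 = diffusion_curve(tau, p.tau_D1, p.aspect)
        c2 = diffusion_curve(tau, p.tau_D2, p.aspect)
        return (w1 * c1 + w2 * c2) / (w1 + w2)
    tau_d = p.tau_D if p.tau_D is not None else p.tau_D1
    return diffusion_curve(tau, tau_d, p.aspect)


def _kinetic_factor(p: FCSModelParams, pair: str, tau: np.ndarray) -> np.ndarray:
    if p.tau_K is None:
        return np.ones_like(np.asarray(tau, dtype=float))
    if np.isclose(p.E1, p.E2):
        return np.ones_like(np.asarray(tau, dtype=float))
    amps = kinetic_amplitudes(p.f1, p.E1, p.E2, p.alpha, p.beta)
    decay = np.exp(-np.asarray(tau, dtype=float) / p.tau_K)
    sign = -1.0 if pair == "DA" else 1.0
    return 1.0 + sign * amps[pair] * decay


def model_curve(p: FCSModelParams, pair: str, tau: np.ndarray) -> np.ndarray:
    """Full correlation model C0 * C_diff,pair * C_kin,pair on lag grid tau."""
    if pair not in ("DD", "AA", "DA"):
        raise ValueError("pair must be one of 'DD', 'AA', 'DA'")
    if (
        p.tau_K is not None
        and np.isclose(p.E1, p.E2)
    ):
        warnings.warn(
            "E1 = E2 makes the kinetic term vanish; tau_K is unidentifiable",
            stacklevel=2,
        )
    return p.C0 * _diffusion_factor(p, pair, tau) * _kinetic_factor(p, pair, tau)


# --------------------------------------------------------------------------
# fit results


@dataclass
class FitResult:
    """Fitted parameters with uncertainties and diagnostics."""

    params: dict[str, float]
    stderr: dict[str, float | None]
    chisqr: float
    redchi: float
    success: bool
    case: str | None = None
    message: str = ""
    n_data: int = 0
    n_varys: int = 0
    residuals: np.ndarray | None = None

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    @property
    def K(self) -> float | None:
        return self.params.get("K")

    @property
    def f1(self) -> float | None:
        K = self.K
        return None if K is None else K / (1.0 + K)

    @property
    def k12(self) -> float | None:
        """Forward rate 1->2: (1-f1)/tau_K."""
        if self.K is None or "tau_K" not in self.params:
            return None
        return (1.0 - self.f1) / self.params["tau_K"]

    @property
    def k21(self) -> float | None:
        if self.K is None or "tau_K" not in self.params:
            return None
        return self.f1 / self.params["tau_K"]


def rates_from_relaxation(tau_K: float, K: float) -> tuple[float, float]:
    """(k12, k21) from the relaxation time and equilibrium constant."""
    f1 = K / (1.0 + K)
    return (1.0 - f1) / tau_K, f1 / tau_K


def _result_from_lmfit(out, case=None, residuals=None) -> FitResult:
    params = {k: float(v.value) for k, v in out.params.items()}
    stderr = {
        k: (None if v.stderr is None else float(v.stderr))
        for k, v in out.params.items()
    }
    return FitResult(
        params,
        stderr,
        float(out.chisqr),
        float(out.redchi),
        bool(out.success),
        case,
        out.message,
        int(out.ndata),
        int(out.nvarys),
        residuals,
    )


def _weights(curve: CorrelationCurve) -> np.ndarray:
    if curve.sigma is None:
        return np.ones_like(curve.values)
    sig = np.where(curve.sigma > 0, curve.sigma, np.inf)
    return 1.0 / sig


# --------------------------------------------------------------------------
# fitting


def fit_kinetic_exponential(
    curve: CorrelationCurve,
    K: float | None = None,
    baseline: bool = True,
    min_lag: float = 0.0,
    max_lag: float = np.inf,
) -> FitResult:
    """Fit C(tau) = offset + A exp(-tau/tau_K) (immobilized molecules).

    With no diffusion the only surviving timescale is the conformational
    relaxation.  If the equilibrium constant ``K`` is supplied (e.g. known
    FRET states, or from burst analysis), it is recorded so the result can
    split tau_K into k12 = f2/tau_K and k21 = f1/tau_K.
    """
    c = curve.restrict(min_lag, max_lag)
    p = lmfit.Parameters()
    amp0 = max(float(c.values[0]), 1e-3)
    # crude timescale guess: lag where the curve first drops below amp/e
    below = np.nonzero(c.values < amp0 / np.e)[0]
    tau0 = c.lags[below[0]] if below.size else c.lags[len(c.lags) // 2]
    p.add("amplitude", value=amp0, min=0)
    p.add("tau_K", value=float(tau0), min=c.lags[0] / 100, max=c.lags[-1] * 100)
    p.add("offset", value=0.0, vary=baseline)
    w = _weights(c)

    def resid(pars):
        m = pars["offset"] + pars["amplitude"] * np.exp(-c.lags / pars["tau_K"])
        return (m - c.values) * w

    out = lmfit.minimize(resid, p)
    res = _result_from_lmfit(out, residuals=resid(out.params) / w)
    if K is not None:
        res.params["K"] = float(K)
        res.stderr.setdefault("K", None)
    return res


def fit_diffusion(
    curve: CorrelationCurve,
    aspect: float = 8.0,
    with_kinetics: bool = False,
    min_lag: float = 2e-6,
    max_lag: float = np.inf,
    tau_d_guess: float = 1e-3,
) -> FitResult:
    """Fit a single-species diffusion model, optionally times a kinetic term.

    Model: C(tau) = C0 * C_diff(tau; tau_D, a) * (1 + A exp(-tau/tau_K)).
    Lags below ``min_lag`` are excluded (ALEX-modulation artifacts).
    """
    c = curve.restrict(min_lag, max_lag)
    p = lmfit.Parameters()
    p.add("C0", value=max(float(np.max(c.values)), 1e-3), min=0)
    p.add("tau_D", value=tau_d_guess, min=1e-7, max=10.0)
    p.add("amplitude", value=0.1 if with_kinetics else 0.0, min=0, max=100,
          vary=with_kinetics)
    p.add("tau_K", value=tau_d_guess * 10 if with_kinetics else 1.0,
          min=1e-7, max=100.0, vary=with_kinetics)
    w = _weights(c)

    def model(pars):
        kin = 1.0 + pars["amplitude"] * np.exp(-c.lags / pars["tau_K"])
        return pars["C0"] * diffusion_curve(c.lags, pars["tau_D"], aspect) * kin

    out = lmfit.minimize(lambda pars: (model(pars) - c.values) * w, p)
    return _result_from_lmfit(out)


def _divided_data(curve_aa, curve_da, min_lag, max_lag):
    if curve_aa.lags.size != curve_da.lags.size or not np.allclose(
        curve_aa.lags, curve_da.lags
    ):
        raise ValueError("divided fit needs curves on a common lag grid")
    aa = curve_aa.restrict(min_lag, max_lag)
    da = curve_da.restrict(min_lag, max_lag)
    good = da.values > 0
    if not np.all(good):
        warnings.warn(
            f"masking {np.count_nonzero(~good)} lags where the cross-correlation "
            "is non-positive",
            stacklevel=3,
        )
    ratio = np.where(good, aa.values / np.where(good, da.values, 1.0), np.nan)
    if aa.sigma is not None and da.sigma is not None:
        sig = np.abs(ratio) * np.sqrt(
            (aa.sigma / np.where(aa.values != 0, aa.values, np.inf)) ** 2
            + (da.sigma / np.where(good, da.values, np.inf)) ** 2
        )
        w = np.where((sig > 0) & good, 1.0 / np.where(sig > 0, sig, 1.0), 0.0)
    else:
        w = good.astype(float)
    return aa.lags[good], ratio[good], w[good]


def fit_divided(
    curve_aa: CorrelationCurve,
    curve_da: CorrelationCurve,
    case: str,
    constraints: dict,
    aspect: float = 8.0,
    alpha: float = 0.0,
    beta: float = 1.0,
    min_lag: float = 0.0,
    max_lag: float = np.inf,
    free_scale: bool = False,
) -> FitResult:
    """Fit the point-wise ratio C_AxA / C_DxA for the kinetic relaxation time.

    Dividing the FRET autocorrelation by the FRET x non-FRET
    cross-correlation cancels the shared diffusion factor (exactly so in
    case I, where both states share tau_D); the remaining decay from the
    ratio's plateau toward 1 is the conformational relaxation.

    case "I" (merged FRET populations): constraints supply ``E_overlap``; the
    fit frees K, dE = E1 - E2 and tau_K.  Only the combination
    f1*f2*dE^2 is identifiable from the ratio, so K and dE individually
    carry large uncertainties — tau_K is the robust output.

    case "II" (resolved populations): constraints supply E1, E2, K, tau_D1
    and tau_D2 from burst analysis; only tau_K (and optionally an overall
    scale) is free, and the diffusion ratio uses the FRET-weighted
    two-species mixture.
    """
    lags, ratio, w = _divided_data(curve_aa, curve_da, min_lag, max_lag)
    p = lmfit.Parameters()
    p.add("tau_K", value=constraints.get("tau_K_guess", 1e-3), min=1e-7, max=100)
    p.add("scale", value=1.0, vary=free_scale, min=0.1, max=10)
    if case == "I":
        e_overlap = constraints["E_overlap"]
        p.add("K", value=constraints.get("K_guess", 2.0), min=1e-3, max=1e3)
        p.add("dE", value=constraints.get("dE_guess", 0.5), min=0.0, max=1.0)

        def ratio_model(pars):
            K = pars["K"]
            f1 = K / (1 + K)
            e1 = e_overlap + (1 - f1) * pars["dE"]
            e2 = e_overlap - f1 * pars["dE"]
            amps = kinetic_amplitudes(f1, e1, e2, alpha, beta)
            decay = np.exp(-lags / pars["tau_K"])
            return pars["scale"] * (1 + amps["AA"] * decay) / (1 - amps["DA"] * decay)

    elif case == "II":
        E1, E2, K = constraints["E1"], constraints["E2"], constraints["K"]
        tau_d1 = constraints["tau_D1"]
        tau_d2 = constraints["tau_D2"]
        f1 = K / (1 + K)
        amps = kinetic_amplitudes(f1, E1, E2, alpha, beta)
        mp = FCSModelParams(
            tau_D1=tau_d1, tau_D2=tau_d2, aspect=aspect, f1=f1, E1=E1, E2=E2
        )
        diff_ratio = _diffusion_factor(mp, "AA", lags) / _diffusion_factor(
            mp, "DA", lags
        )

        def ratio_model(pars):
            decay = np.exp(-lags / pars["tau_K"])
            return (
                pars["scale"]
                * diff_ratio
                * (1 + amps["AA"] * decay)
                / (1 - amps["DA"] * decay)
            )

    else:
        raise ValueError("case must be 'I' or 'II'")

    out = lmfit.minimize(lambda pars: (ratio_model(pars) - ratio) * w, p)
    res = _result_from_lmfit(out, case=case)
    if case == "II":
        res.params["K"] = float(K)
        res.stderr.setdefault("K", None)
    return res


def fit_global(
    curves: dict[str, CorrelationCurve],
    case: str,
    constraints: dict,
    aspect: float = 8.0,
    alpha: float = 0.0,
    beta: float = 1.0,
    min_lag: float = 2e-6,
    max_lag: float = np.inf,
) -> FitResult:
    """Simultaneous weighted fit of the DxD, AxA and DxA correlations.

    Each curve keeps its own amplitude C0 and (case I) its own diffusion time
    tau_D; the kinetic parameters are shared.  Passing only a subset of pairs
    (e.g. omitting DxD) fits the remaining curves.  Case semantics follow
    :func:`fit_divided`.
    """
    pairs = [pr for pr in ("DD", "AA", "DA") if pr in curves]
    if not pairs:
        raise ValueError("no curves supplied")
    data = {pr: curves[pr].restrict(min_lag, max_lag) for pr in pairs}
    p = lmfit.Parameters()
    p.add("tau_K", value=constraints.get("tau_K_guess", 1e-3), min=1e-7, max=100)
    for pr in pairs:
        p.add(f"C0_{pr}", value=max(float(np.max(data[pr].values)), 1e-3), min=0)
    if case == "I":
        e_overlap = constraints["E_overlap"]
        p.add("K", value=constraints.get("K_guess", 2.0), min=1e-3, max=1e3)
        p.add("dE", value=constraints.get("dE_guess", 0.5), min=0.0, max=1.0)
        for pr in pairs:
            p.add(f"tau_D_{pr}", value=constraints.get("tau_D_guess", 1e-3),
                  min=1e-7, max=10.0)
    elif case == "II":
        E1, E2, K = constraints["E1"], constraints["E2"], constraints["K"]
        f1 = K / (1 + K)
        mp = FCSModelParams(
            tau_D1=constraints["tau_D1"], tau_D2=constraints["tau_D2"],
            aspect=aspect, f1=f1, E1=E1, E2=E2,
        )
    else:
        raise ValueError("case must be 'I' or 'II'")

    def resid(pars):
        parts = []
        if case == "I":
            K_i = pars["K"]
            f1_i = K_i / (1 + K_i)
            e1_i = e_overlap + (1 - f1_i) * pars["dE"]
            e2_i = e_overlap - f1_i * pars["dE"]
            amps = kinetic_amplitudes(f1_i, e1_i, e2_i, alpha, beta)
        else:
            amps = kinetic_amplitudes(f1, E1, E2, alpha, beta)
        for pr in pairs:
            c = data[pr]
            decay = np.exp(-c.lags / pars["tau_K"])
            sign = -1.0 if pr == "DA" else 1.0
            kin = 1.0 + sign * amps[pr] * decay
            if case == "I":
                diff = diffusion_curve(c.lags, pars[f"tau_D_{pr}"], aspect)
            else:
                diff = _diffusion_factor(mp, pr, c.lags)
            m = pars[f"C0_{pr}"] * diff * kin
            parts.append((m - c.values) * _weights(c))
        return np.concatenate(parts)

    out = lmfit.minimize(resid, p)
    res = _result_from_lmfit(out, case=case)
    if case == "II":
        res.params["K"] = float(K)
        res.stderr.setdefault("K", None)
    return res


from functools import lru_cache


@lru_cache(maxsize=32)
def pinhole_tau_factor(
    rp_over_omega: float,
    aspect: float = 8.0,
    n_grid: int = 512,
    theta_range: tuple[float, float] = (0.01, 50.0),
) -> float:
    """Ratio tau_fit / (omega^2/D) for a pinhole-truncated Gaussian profile.

    The detection profile exp(-r^2/2 omega^2) cut at lateral radius
    rp = rp_over_omega * omega decays faster than the untruncated Gaussian,
    so fitting the standard diffusion model to data from the truncated
    profile yields a shorter diffusion time.  The exact lateral correlation
    decay is computed from the profile's power spectrum
    (C_lat(tau) ∝ ∫ |g(k)|^2 exp(-D k^2 tau) d^2k) and the standard model is
    fitted over the dimensionless lag range ``theta_range`` (in units of
    omega^2/D); the returned factor is ~0.78 at the default geometry and
    tends to 1 as the pinhole opens.
    """
    from scipy.optimize import curve_fit

    L = 16.0
    x = (np.arange(n_grid) - n_grid // 2) * (L / n_grid)
    r2 = x[:, None] ** 2 + x[None, :] ** 2
    g = np.exp(-r2 / 2.0) * (r2 < rp_over_omega**2)
    G2 = np.abs(np.fft.fft2(g)) ** 2
    k = 2.0 * np.pi * np.fft.fftfreq(n_grid, L / n_grid)
    K2 = k[:, None] ** 2 + k[None, :] ** 2
    theta = np.geomspace(*theta_range, 48)  # tau in units of omega^2/D
    c_lat = np.array([(G2 * np.exp(-K2 * th)).sum() for th in theta]) / G2.sum()
    c = c_lat / np.sqrt(1.0 + theta / aspect**2)

    def model(th, c0, th_d):
        return c0 / ((1.0 + th / th_d) * np.sqrt(1.0 + th / (aspect**2 * th_d)))

    popt, _ = curve_fit(model, theta, c, p0=(1.0, 1.0))
    return float(popt[1])


def radius_from_fit(
    tau_d: float,
    omega_xy: float,
    temperature: float = DEFAULT_TEMPERATURE,
    viscosity: float = DEFAULT_VISCOSITY,
    convention: str = "e2",
    pinhole_radius: float | None = None,
    aspect: float = 8.0,
) -> float:
    """Hydrodynamic radius from a fitted diffusion time.

    tau_D = w^2/(4 D) with w the lateral detection radius, then
    R = kB T / (6 pi eta D).  The default convention uses the 1/e^2 radius
    w = 2*omega_xy of the simulated profile exp(-r^2 / 2 omega_xy^2), which
    makes simulate -> correlate -> fit -> radius round trips recover the
    input radius; ``convention="literal"`` uses w = omega_xy instead.

    When ``pinhole_radius`` is given, the conversion additionally corrects
    for the pinhole truncation of the detection profile (see
    :func:`pinhole_tau_factor`), which shortens fitted diffusion times by
    ~20 % at the default geometry.
    """
    if tau_d <= 0 or omega_xy <= 0:
        raise ValueError("tau_d and omega_xy must be positive")
    if convention == "e2":
        # tau_fit = kappa * omega^2 / D
        kappa = 1.0
        if pinhole_radius is not None:
            kappa = pinhole_tau_factor(
                round(pinhole_radius / omega_xy, 4), round(aspect, 4)
            )
        D = kappa * omega_xy**2 / tau_d
    elif convention == "literal":
        D = omega_xy**2 / (4.0 * tau_d)
    else:
        raise ValueError("convention must be 'e2' or 'literal'")
    return constants.k * temperature / (6.0 * np.pi * viscosity * D)
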