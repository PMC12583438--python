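"""Burst detection, E/S computation, corrections, and population fitting.

A burst is a run of at least ``min_photons`` consecutive photons (all four
detection channels pooled) whose inter-photon gaps are all strictly below
``max_gap`` (default 200 us).  Per burst the raw FRET efficiency and
stoichiometry are

    E = A514 / (A514 + D514)
    S = (A514 + D514) / (A514 + D514 + A632)

where e.g. A514 counts acceptor-emitted photons under donor excitation.
Corrections for spectral leakage alpha, relative brightness beta and direct
acceptor excitation delta follow the standard ALEX algebra:

    A514' = A514 - alpha*D514 - delta*A632
    E'    = A514' / (A514' + beta*D514)
    S'    = (A514' + D514) / (A514' + D514 + A632)

Double-labeled molecules cluster near intermediate S; donor-only molecules
sit at S ~ 1 and acceptor-only at S ~ 0, which is also how the correction
factors are estimated from the data itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .photons import PhotonStream

__all__ = [
    "find_bursts",
    "corrected_es",
    "select_bursts",
    "fit_fret_histogram",
    "estimate_corrections",
    "PopulationFit",
    "burst_es",
]

BURST_COLUMNS = [
    "i_start",
    "i_end",
    "start_s",
    "end_s",
    "n_photons",
    "D514",
    "A514",
    "D632",
    "A632",
    "E_raw",
    "S_raw",
    "E_corr",
    "S_corr",
    "valid",
]


def find_bursts(
    stream: PhotonStream,
    min_photons: int = 25,
    max_gap: float = 200e-6,
) -> pd.DataFrame:
    """Detect bursts on the pooled photon stream.

    Returns a DataFrame (one row per burst) with photon index ranges
    [i_start, i_end), per-channel counts, duration, and raw E/S.  A gap of
    exactly ``max_gap`` splits bursts (strict comparison).  Bursts whose E or
    S denominator is zero are marked ``valid=False`` and are excluded from
    histograms and selections downstream.
    """
    t = stream.times
    n = t.size
    if n == 0:
        return pd.DataFrame(columns=BURST_COLUMNS)
    gaps = np.diff(t)
    breaks = np.nonzero(gaps >= max_gap)[0] + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [n]))
    sizes = ends - starts
    keep = sizes >= min_photons
    starts, ends = starts[keep], ends[keep]

    em, ex = stream.emission, stream.excitation
    csum = {
        "D514": np.concatenate(([0], np.cumsum((em == 0) & (ex == 0)))),
        "A514": np.concatenate(([0], np.cumsum((em == 1) & (ex == 0)))),
        "D632": np.concatenate(([0], np.cumsum((em == 0) & (ex == 1)))),
        "A632": np.concatenate(([0], np.cumsum((em == 1) & (ex == 1)))),
    }
    data = {
        "i_start": starts,
        "i_end": ends,
        "start_s": t[starts] if starts.size else np.array([]),
        "end_s": t[ends - 1] if ends.size else np.array([]),
        "n_photons": ends - starts,
    }
    for ch, cs in csum.items():
        data[ch] = cs[ends] - cs[starts]
    df = pd.DataFrame(data)
    e, s, valid = burst_es(df["A514"].to_numpy(), df["D514"].to_numpy(), df["A632"].to_numpy())
    df["E_raw"], df["S_raw"], df["valid"] = e, s, valid
    df["E_corr"], df["S_corr"] = df["E_raw"], df["S_raw"]
    return df


def burst_es(
    a514: np.ndarray, d514: np.ndarray, a632: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw (E, S, valid) from per-burst channel counts."""
    a514 = np.asarray(a514, dtype=float)
    d514 = np.asarray(d514, dtype=float)
    a632 = np.asarray(a632, dtype=float)
    den_e = a514 + d514
    den_s = den_e + a632
    valid = (den_e > 0) & (den_s > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(den_e > 0, a514 / np.where(den_e > 0, den_e, 1.0), np.nan)
        s = np.where(den_s > 0, den_e / np.where(den_s > 0, den_s, 1.0), np.nan)
    return e, s, valid


def corrected_es(
    bursts: pd.DataFrame,
    alpha: float = 0.0,
    beta: float = 1.0,
    delta_dir: float = 0.0,
) -> pd.DataFrame:
    """Add leakage/brightness/direct-excitation corrected E and S columns.

    Negative corrected acceptor counts are possible under shot noise and are
    propagated unclipped.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    df = bursts.copy()
    a_corr = df["A514"] - alpha * df["D514"] - delta_dir * df["A632"]
    den_e = a_corr + beta * df["D514"]
    den_s = a_corr + df["D514"] + df["A632"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["E_corr"] = np.where(den_e != 0, a_corr / den_e, np.nan)
        df["S_corr"] = np.where(den_s != 0, (a_corr + df["D514"]) / den_s, np.nan)
    return df


def select_bursts(
    bursts: pd.DataFrame,
    e_range: tuple[float, float] = (0.0, 1.0),
    s_range: tuple[float, float] = (0.0, 1.0),
    use_corrected: bool = True,
) -> pd.DataFrame:
    """Bursts whose (E, S) fall strictly inside both open intervals."""
    e_col = "E_corr" if use_corrected else "E_raw"
    s_col = "S_corr" if use_corrected else "S_raw"
    e, s = bursts[e_col], bursts[s_col]
    mask = (
        bursts["valid"]
        & (e > e_range[0])
        & (e < e_range[1])
        & (s > s_range[0])
        & (s < s_range[1])
    )
    return bursts[mask]


@dataclass
class PopulationFit:
    """Normal-mixture fit of a burst FRET histogram."""

    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray  # sum to 1
    overlap: bool  # case I (merged populations) if True
    converged: bool
    chisqr: float

    @property
    def n_components(self) -> int:
        return len(self.means)

    def sorted_by_mean(self) -> "PopulationFit":
        order = np.argsort(self.means)
        return PopulationFit(
            self.means[order],
            self.sigmas[order],
            self.weights[order],
            self.overlap,
            self.converged,
            self.chisqr,
        )


def _mixture(x, *params):
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        w, mu, sig = params[i : i + 3]
        y = y + w * np.exp(-0.5 * ((x - mu) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
    return y


def fit_fret_histogram(
    bursts: pd.DataFrame,
    n_components: int = 3,
    bin_width: float = 0.02,
    use_corrected: bool = True,
    min_bursts: int = 50,
) -> PopulationFit:
    """Least-squares fit of a normal mixture to the binned E histogram.

    Components are initialized from quantiles of the E values; components
    whose fitted weight drops below 0.05 are pruned and the reduced mixture
    refitted.  The ``overlap`` flag marks merged populations (case I):
    E_high - sigma_high < E_low + sigma_low for the extreme components.
    """
    e_col = "E_corr" if use_corrected else "E_raw"
    e = bursts.loc[bursts["valid"], e_col].to_numpy(dtype=float)
    e = e[np.isfinite(e)]
    if e.size < min_bursts:
        raise ValueError(
            f"need at least {min_bursts} valid bursts to fit populations, got {e.size}"
        )
    lo = min(-0.1, np.floor(e.min() / bin_width) * bin_width)
    hi = max(1.1, np.ceil(e.max() / bin_width) * bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(e, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (e.size * bin_width)

    def run_fit(k: int):
        qs = np.quantile(e, (np.arange(k) + 0.5) / k)
        p0 = []
        for mu in qs:
            p0.extend([1.0 / k, mu, max(0.05, e.std() / k)])
        bounds_lo = [0.0, lo, 1e-3] * k
        bounds_hi = [1.0, hi, 1.0] * k
        popt, _ = curve_fit(
            _mixture, centers, density, p0=p0, bounds=(bounds_lo, bounds_hi),
            maxfev=20000,
        )
        return popt

    def degenerate(popt):
        """Components that duplicate each other or carry negligible weight."""
        w = np.array(popt[0::3])
        mu = np.array(popt[1::3])
        sig = np.abs(np.array(popt[2::3]))
        if np.any(w / w.sum() < 0.05):
            return True
        order = np.argsort(mu)
        mu, sig = mu[order], sig[order]
        return bool(np.any(np.diff(mu) < np.minimum(sig[:-1], sig[1:])))

    def ssr(popt):
        return float(np.sum((density - _mixture(centers, *popt)) ** 2))

    # parsimonious component count: add a component only when it both
    # improves the residual substantially and stays non-degenerate
    converged = True
    popt = None
    best_ssr = np.inf
    for k_try in range(1, n_components + 1):
        try:
            cand = run_fit(k_try)
        except RuntimeError:
            converged = popt is not None
            continue
        if popt is None or (ssr(cand) < 0.7 * best_ssr and not degenerate(cand)):
            popt, k, best_ssr = cand, k_try, ssr(cand)
            converged = True
    if popt is None:
        raise RuntimeError("FRET histogram fit failed for every component count")
    w = np.array(popt[0::3])
    mu = np.array(popt[1::3])
    sig = np.abs(np.array(popt[2::3]))
    w = w / w.sum()
    resid = density - _mixture(centers, *popt)
    order = np.argsort(mu)
    mu, sig, w = mu[order], sig[order], w[order]
    if len(mu) >= 2:
        overlap = (mu[-1] - sig[-1]) < (mu[0] + sig[0])
    else:
        overlap = True  # a single merged population
    return PopulationFit(mu, sig, w, bool(overlap), converged, float(np.sum(resid**2)))


def estimate_corrections(
    bursts: pd.DataFrame,
    s_donor_only: float = 0.9,
    s_acceptor_only: float = 0.1,
    min_bursts: int = 20,
) -> tuple[float, float]:
    """Estimate (alpha, delta) from the single-labeled burst populations.

    The donor-only population (S > 0.9) has raw E = alpha/(1+alpha), so
    alpha = E_DO/(1-E_DO); the acceptor-only population (S < 0.1) has raw
    S = delta/(1+delta), so delta = S_AO/(1-S_AO).  Single-point estimators;
    raise with guidance when a calibration population is missing.
    """
    valid = bursts[bursts["valid"]]
    donor_only = valid[valid["S_raw"] > s_donor_only]
    acceptor_only = valid[valid["S_raw"] < s_acceptor_only]
    if len(donor_only) < min_bursts or len(acceptor_only) < min_bursts:
        raise ValueError(
            "missing donor-only or acceptor-only calibration population "
            f"(found {len(donor_only)} / {len(acceptor_only)}, need {min_bursts}); "
            "supply alpha and delta manually"
        )
    e_do = float(donor_only["E_raw"].mean())
    s_ao = float(acceptor_only["S_raw"].mean())
    alpha = e_do / (1.0 - e_do)
    delta = s_ao / (1.0 - s_ao)
    return alpha, delta
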