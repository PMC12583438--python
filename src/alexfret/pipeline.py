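"""End-to-end orchestration: simulate -> bursts -> purify -> correlate -> fit.

Mirrors the combined burst / purified-FCS workflow: photons are simulated (or
loaded), bursts detected and corrected, the double-labeled population is
selected in (E, S), the photon stream is gated around those bursts, and the
gated correlation functions are fitted for kinetic and diffusion parameters.
The fit constraints follow the burst-histogram overlap criterion: merged FRET
populations (case I) share a diffusion time and only constrain
f1*E1 + f2*E2; resolved populations (case II) fix E1, E2 and K from the
burst analysis, leaving the relaxation time free.

Every stage is deterministic given the configuration seed; outputs carry the
configuration hash.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import bursts as bursts_mod
from . import correlation as corr_mod
from .config import ExperimentConfig, load_config, save_config
from .photons import PhotonStream, read_stream, split_channels, write_stream
from .simulate import simulate_experiment

__all__ = [
    "run_pipeline",
    "analyze_stream",
    "burst_stage",
    "correlation_stage",
    "pooled_donor_excitation",
    "subpopulation_radius",
    "immobile_relaxation",
    "ExperimentConfig",
    "load_config",
    "save_config",
]

log = logging.getLogger("alexfret")


def _timed(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("stage %-10s %.2f s", name, time.perf_counter() - self.t0)

    return _T()


def burst_stage(stream: PhotonStream, cfg: ExperimentConfig) -> pd.DataFrame:
    """Burst detection plus E/S correction using the configured factors."""
    df = bursts_mod.find_bursts(stream, cfg.burst_min_photons, cfg.burst_max_gap)
    opt = cfg.optics
    try:
        alpha_hat, delta_hat = bursts_mod.estimate_corrections(df)
    except ValueError:
        alpha_hat, delta_hat = opt.alpha, opt.delta_dir
    df = bursts_mod.corrected_es(df, alpha_hat, opt.beta, delta_hat)
    df.attrs["alpha_hat"] = alpha_hat
    df.attrs["delta_hat"] = delta_hat
    return df


def correlation_stage(
    stream: PhotonStream,
    cfg: ExperimentConfig,
    selected: pd.DataFrame,
    n_segments: int = 10,
    max_lag: float = 1.0,
) -> dict[str, corr_mod.CorrelationCurve]:
    """Purified correlation curves (DxD, AxA, DxA) from donor excitation."""
    gated = corr_mod.purify(stream, selected, cfg.t_purify)
    ch = split_channels(gated)
    edges = corr_mod.make_lag_edges(max_lag=min(max_lag, cfg.duration / (2 * n_segments)))
    curves = {}
    for pair, (a, b) in {
        "DD": ("D514", "D514"),
        "AA": ("A514", "A514"),
        "DA": ("D514", "A514"),
    }.items():
        sa, sb = ch[a], ch[b]
        if len(sa) == 0 or len(sb) == 0:
            continue
        curves[pair] = corr_mod.correlate_purified(
            sa, None if a == b else sb, edges=edges, n_segments=n_segments, pair=pair
        )
    return curves


def analyze_stream(stream: PhotonStream, cfg: ExperimentConfig) -> dict:
    """Burst + purified-FCS analysis of a photon stream; returns the report."""
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    if cfg.immobile:
        ch = split_channels(stream)
        curve = corr_mod.correlate_with_error(
            ch["A514"], edges=corr_mod.make_lag_edges(max_lag=cfg.duration / 40),
            pair="AA",
        )
        K = float(np.exp(cfg.delta_G))
        fit = corr_mod.fit_kinetic_exponential(curve, K=K)
        report["mode"] = "immobile"
        report["fit"] = _fit_to_dict(fit)
        report["curves"] = {"AA": curve}
        return report

    with _timed("bursts"):
        df = burst_stage(stream, cfg)
    selected = bursts_mod.select_bursts(df, s_range=cfg.s_range)
    report["mode"] = "mobile"
    report["n_bursts"] = int(len(df))
    report["n_selected"] = int(len(selected))
    report["alpha_hat"] = df.attrs.get("alpha_hat")

    pop = None
    if len(selected) >= 50:
        pop = bursts_mod.fit_fret_histogram(selected)
        report["populations"] = {
            "means": pop.means.tolist(),
            "sigmas": pop.sigmas.tolist(),
            "weights": pop.weights.tolist(),
            "overlap": pop.overlap,
        }
    report["case"] = "I" if (pop is None or pop.overlap) else "II"

    with _timed("correlate"):
        curves = correlation_stage(stream, cfg, selected)
    report["curves"] = curves

    if "AA" in curves and "DA" in curves:
        constraints: dict
        if report["case"] == "I":
            e_overlap = float(pop.means[np.argmax(pop.weights)]) if pop else 0.5
            constraints = {"E_overlap": e_overlap}
        else:
            spop = pop.sorted_by_mean()
            hi, lo = spop.means[-1], spop.means[0]
            w = spop.weights
            K_hat = float(w[-1] / max(w[0], 1e-6))
            # per-state diffusion times from each population's own purified
            # correlation (case II: resolved populations, separable sizes)
            constraints = {"E1": float(hi), "E2": float(lo), "K": K_hat}
            for key, mu, sig in (
                ("tau_D1", spop.means[-1], spop.sigmas[-1]),
                ("tau_D2", spop.means[0], spop.sigmas[0]),
            ):
                try:
                    sub = subpopulation_radius(
                        stream, cfg, (float(mu - sig), float(mu + sig)),
                        bursts=df,
                    )
                    constraints[key] = sub["tau_D"]
                except ValueError:
                    constraints[key] = None
            if constraints["tau_D1"] is None or constraints["tau_D2"] is None:
                shared = corr_mod.fit_diffusion(
                    curves["AA"], cfg.optics.aspect, with_kinetics=True,
                    min_lag=2e-5,
                ).params["tau_D"]
                constraints["tau_D1"] = constraints.get("tau_D1") or shared
                constraints["tau_D2"] = constraints.get("tau_D2") or shared
            constraints["tau_K_guess"] = max(
                2 * constraints["tau_D1"], 1e-3
            )
        fit = corr_mod.fit_divided(
            curves["AA"], curves["DA"], report["case"], constraints,
            aspect=cfg.optics.aspect, alpha=report["alpha_hat"] or 0.0,
        )
        report["fit"] = _fit_to_dict(fit)
    report["bursts"] = df
    report["selected"] = selected
    return report


def _fit_to_dict(fit: corr_mod.FitResult) -> dict:
    return {
        "params": fit.params,
        "stderr": fit.stderr,
        "chisqr": fit.chisqr,
        "redchi": fit.redchi,
        "success": fit.success,
        "case": fit.case,
        "k12": fit.k12,
        "k21": fit.k21,
        "K": fit.K,
    }


def pooled_donor_excitation(stream: PhotonStream) -> PhotonStream:
    """All donor-excitation photons (D514 + A514) as one stream.

    The pooled donor-excited brightness of a double-labeled molecule is
    nearly FRET-independent (only leakage couples it weakly), so its
    autocorrelation isolates diffusion from conformational kinetics.
    """
    ch = split_channels(stream)
    ts = np.union1d(ch["D514"].timestamps, ch["A514"].timestamps)
    out = PhotonStream(
        ts,
        np.zeros(ts.size, np.uint8),
        np.zeros(ts.size, np.uint8),
        stream.duration,
        stream.base_dt,
        dict(stream.metadata),
    )
    return out


def subpopulation_radius(
    stream: PhotonStream,
    cfg: ExperimentConfig,
    e_range: tuple[float, float],
    bursts: pd.DataFrame | None = None,
    max_lag_fit: float = 0.01,
    n_segments: int = 10,
) -> dict:
    """Purified-FCS diffusion analysis of one (E, S)-selected population.

    Selects bursts inside ``e_range`` and the configured S window, gates the
    stream with ``cfg.t_purify``, correlates the pooled donor-excitation
    photons (gate-corrected), fits the diffusion model, and converts the
    fitted diffusion time to a hydrodynamic radius with the pinhole-aware
    detection-profile calibration.
    """
    if bursts is None:
        bursts = burst_stage(stream, cfg)
    selected = bursts_mod.select_bursts(bursts, e_range=e_range, s_range=cfg.s_range)
    if len(selected) < 20:
        raise ValueError(f"only {len(selected)} bursts in E window {e_range}")
    gated = corr_mod.purify(stream, selected, cfg.t_purify)
    pooled = pooled_donor_excitation(gated)
    edges = corr_mod.make_lag_edges(
        max_lag=min(0.2, cfg.duration / (2 * n_segments))
    )
    curve = corr_mod.correlate_purified(pooled, edges=edges, n_segments=n_segments)
    fit = corr_mod.fit_diffusion(
        curve, cfg.optics.aspect, min_lag=2e-5, max_lag=max_lag_fit
    )
    tau_d = fit.params["tau_D"]
    tau_err = fit.stderr["tau_D"]
    radius = corr_mod.radius_from_fit(
        tau_d,
        cfg.optics.omega_xy,
        cfg.temperature,
        cfg.viscosity,
        pinhole_radius=cfg.optics.pinhole_radius_sample,
        aspect=cfg.optics.aspect,
    )
    rel = (tau_err / tau_d) if tau_err else None
    return {
        "n_bursts": int(len(selected)),
        "tau_D": tau_d,
        "tau_D_err": tau_err,
        "radius": radius,
        "radius_err": None if rel is None else radius * rel,
        "fit": fit,
        "curve": curve,
    }


def immobile_relaxation(
    stream: PhotonStream, cfg: ExperimentConfig, max_lag: float = 0.5
) -> corr_mod.FitResult:
    """Kinetic-exponential fit of an immobilized molecule's FRET channel."""
    ch = split_channels(stream)
    curve = corr_mod.correlate_with_error(
        ch["A514"], edges=corr_mod.make_lag_edges(max_lag=max_lag), pair="AA"
    )
    return corr_mod.fit_kinetic_exponential(curve, K=float(np.exp(cfg.delta_G)))


def run_pipeline(cfg: ExperimentConfig, outdir: str | Path) -> dict:
    """Simulate and analyze one experiment; write all outputs to ``outdir``.

    Writes the photon stream, burst table, E-S histogram counts, correlation
    curves, fit report and a manifest; returns the in-memory report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run: seed=%d hash=%s", cfg.seed, cfg.config_hash())
    with _timed("simulate"):
        stream = simulate_experiment(cfg)
    write_stream(stream, outdir / "photons.h5")
    log.info("simulated %d photons over %.1f s", len(stream), cfg.duration)

    report = analyze_stream(stream, cfg)

    if "bursts" in report:
        _write_burst_table(report["bursts"], outdir / "bursts.tsv")
        _write_es_histogram(report["selected"], outdir / "es_histogram.tsv")
    for pair, curve in report.get("curves", {}).items():
        curve.to_frame().to_csv(outdir / f"correlation_{pair}.tsv", sep="\t", index=False)

    json_report = {
        k: v for k, v in report.items() if k not in ("curves", "bursts", "selected")
    }
    (outdir / "fit_report.json").write_text(json.dumps(json_report, indent=2))
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    save_config(cfg, outdir / "config.toml")
    return report


def _write_burst_table(df: pd.DataFrame, path: Path) -> None:
    cols = [
        "start_s", "end_s", "n_photons", "D514", "A514", "A632",
        "E_raw", "S_raw", "E_corr", "S_corr",
    ]
    df[cols].to_csv(path, sep="\t", index=False)


def _write_es_histogram(df: pd.DataFrame, path: Path, bins: int = 50) -> None:
    h, e_edges, s_edges = np.histogram2d(
        df["E_corr"].clip(-0.2, 1.2), df["S_corr"].clip(-0.2, 1.2),
        bins=bins, range=[[-0.2, 1.2], [-0.2, 1.2]],
    )
    out = pd.DataFrame(h.astype(int))
    out.to_csv(path, sep="\t", index=False, header=False)
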