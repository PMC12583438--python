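"""Experiment configuration: species, kinetics, optics, timing, analysis.

Defaults mirror a typical ALEX spFRET-FCS measurement on nucleosomes: five
double-labeled molecules at 50 pM (50e-9 mol/m^3) in a periodic box, FRET
states E1 = 0.8 / E2 = 0.1 with radii R1 = 10 nm / R2 = 15 nm, delta_G = 1.5
kBT, peak detected intensities of 150 kHz (514 nm) and 100 kHz (632 nm), and
a 1 us ALEX period.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .brownian import DEFAULT_TEMPERATURE, DEFAULT_VISCOSITY
from .kinetics import DEFAULT_KS
from .optics import ALEXPattern, OpticsConfig

__all__ = [
    "SpeciesConfig",
    "ExperimentConfig",
    "mixed_population_config",
    "immobile_config",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class SpeciesConfig:
    """One molecular species in the sample."""

    name: str
    count: int
    label_config: str = "both"  # both | donor_only | acceptor_only
    radii: tuple[float, float] = (10e-9, 15e-9)  # per conformational state, m
    fret: tuple[float, float] = (0.8, 0.1)
    dynamic: bool = True  # static species stay in state 1


def _default_species() -> list[SpeciesConfig]:
    return [SpeciesConfig("nucleosome", count=5)]


@dataclass
class ExperimentConfig:
    """Full configuration of a simulated ALEX spFRET-FCS experiment."""

    duration: float = 30.0  # s
    seed: int = 0
    # two-state kinetics (kBT units)
    delta_G: float = 1.5
    g_barrier: float = 12.0
    ks: float = DEFAULT_KS
    dt_state: float | None = None  # None: 100 ns, or 10 us for G_barrier > 3
    # sample and diffusion
    concentration: float = 50e-9  # mol/m^3 (= 50 pM)
    temperature: float = DEFAULT_TEMPERATURE
    viscosity: float = DEFAULT_VISCOSITY
    dt_diffusion: float = 1e-5  # position update step, s
    species: list[SpeciesConfig] = field(default_factory=_default_species)
    immobile: bool = False  # single molecule pinned at the beam center
    continuous_donor: bool = False  # disable ALEX: donor laser always on
    # optics / excitation
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    alex: ALEXPattern = field(default_factory=ALEXPattern)
    # analysis defaults carried along with the data
    burst_min_photons: int = 25
    burst_max_gap: float = 200e-6
    t_purify: float = 1e-3
    s_range: tuple[float, float] = (0.2, 0.8)

    @property
    def delta_G_dagger(self) -> float:
        return self.g_barrier - self.delta_G

    @property
    def n_molecules(self) -> int:
        return sum(s.count for s in self.species)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "species" in d:
            d["species"] = [
                SpeciesConfig(
                    **{
                        **s,
                        "radii": tuple(s["radii"]),
                        "fret": tuple(s["fret"]),
                    }
                )
                for s in d["species"]
            ]
        if "optics" in d and isinstance(d["optics"], dict):
            o = dict(d["optics"])
            for k in ("beam_center_donor", "beam_center_acceptor"):
                if k in o:
                    o[k] = tuple(o[k])
            d["optics"] = OpticsConfig(**o)
        if "alex" in d and isinstance(d["alex"], dict):
            d["alex"] = ALEXPattern(**d["alex"])
        if "s_range" in d:
            d["s_range"] = tuple(d["s_range"])
        return cls(**d)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, embedded in outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def mixed_population_config(
    duration: float = 120.0,
    seed: int = 0,
    alpha: float = 0.1,
    radius: float = 10e-9,
    g_barrier: float = 12.0,
) -> ExperimentConfig:
    """Contaminated-sample scenario: bleached populations plus a small impurity.

    Ten labeled molecules of which 20 % are donor-only and 20 % acceptor-only
    (bleached acceptor/donor respectively), plus a much smaller (R = 1 nm)
    donor-like contaminant at the same concentration as the donor-only
    species; spectral leakage alpha = 0.1.
    """
    species = [
        SpeciesConfig("double", 6, "both", (radius, radius), (0.8, 0.1), True),
        SpeciesConfig("donor_only", 2, "donor_only", (radius, radius), (0.0, 0.0), False),
        SpeciesConfig("acceptor_only", 2, "acceptor_only", (radius, radius), (0.0, 0.0), False),
        SpeciesConfig("contaminant", 2, "donor_only", (1e-9, 1e-9), (0.0, 0.0), False),
    ]
    cfg = ExperimentConfig(
        duration=duration,
        seed=seed,
        g_barrier=g_barrier,
        species=species,
        optics=OpticsConfig(alpha=alpha),
    )
    return cfg


def immobile_config(
    g_barrier: float,
    duration: float = 60.0,
    seed: int = 0,
    I0: float = 100e3,
    fret: tuple[float, float] = (0.8, 0.1),
) -> ExperimentConfig:
    """Immobilized molecule at the beam center under continuous donor excitation."""
    return ExperimentConfig(
        duration=duration,
        seed=seed,
        g_barrier=g_barrier,
        immobile=True,
        continuous_donor=True,
        species=[SpeciesConfig("immobile", 1, "both", (10e-9, 10e-9), fret, True)],
        optics=OpticsConfig(I0_donor=I0, I_bg=0.0),
    )


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    """Write a flat TOML-style key/value config file."""
    lines = _toml_lines(cfg.to_dict())
    Path(path).write_text("\n".join(lines) + "\n")


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {v!r}")


def _toml_lines(d: dict, prefix: str = "") -> list[str]:
    lines: list[str] = []
    tables: list[str] = []
    for k, v in d.items():
        if v is None:
            continue
        if isinstance(v, dict):
            tables.append(f"[{prefix}{k}]")
            tables.extend(_toml_lines(v))
        elif isinstance(v, list) and v and isinstance(v[0], dict):
            for item in v:
                tables.append(f"[[{prefix}{k}]]")
                tables.extend(_toml_lines(item))
        else:
            lines.append(f"{k} = {_toml_value(v)}")
    return lines + tables


def load_config(path: str | Path) -> ExperimentConfig:
    import tomllib

    with open(path, "rb") as f:
        d = tomllib.load(f)
    return ExperimentConfig.from_dict(d)
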