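"""Time-tagged photon streams: emission, channel splitting, and file I/O.

Photons are represented by an integer timestamp in units of the base time
step (100 ns), an emission color (donor or acceptor detector) and the
excitation wavelength active when the photon was detected (514 or 632 nm).
Emission follows the shot-noise model: within each base step a photon is
recorded in a channel with probability min(I*dt, 1), at most one photon per
channel per step (valid because I*dt << 1 in all realistic configurations).

The interchange container is an HDF5 file (datasets ``timestamps``,
``emission``, ``excitation``; the full configuration, base step and seed in
attributes).  A plain-text TSV dialect with '#'-prefixed metadata headers is
provided so experimental exports can be adapted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BASE_DT",
    "PhotonStream",
    "emit_photons",
    "write_stream",
    "read_stream",
    "split_channels",
]

#: base time step for photon emission, s
BASE_DT = 100e-9

EMISSION_CODES = {"D": 0, "A": 1}
EXCITATION_CODES = {514: 0, 632: 1}
EMISSION_NAMES = {v: k for k, v in EMISSION_CODES.items()}
EXCITATION_NAMES = {v: k for k, v in EXCITATION_CODES.items()}


@dataclass
class PhotonStream:
    """Sorted time-tagged photons plus the metadata needed to re-analyze them.

    ``timestamps`` are integer multiples of ``base_dt``; ``emission`` and
    ``excitation`` are small integer codes (see EMISSION_CODES and
    EXCITATION_CODES).  ``duration`` is the wall-clock length of the
    measurement in seconds, at least ``(last timestamp + 1) * base_dt``.
    """

    timestamps: np.ndarray
    emission: np.ndarray
    excitation: np.ndarray
    duration: float
    base_dt: float = BASE_DT
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.emission = np.asarray(self.emission, dtype=np.uint8)
        self.excitation = np.asarray(self.excitation, dtype=np.uint8)
        if not (self.timestamps.size == self.emission.size == self.excitation.size):
            raise ValueError("timestamps, emission and excitation must align")
        if self.timestamps.size and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if self.timestamps.size and self.duration < self.timestamps[-1] * self.base_dt:
            raise ValueError("duration shorter than the last photon")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def times(self) -> np.ndarray:
        """Arrival times in seconds."""
        return self.timestamps * self.base_dt

    def channel_name(self, i: int) -> str:
        return f"{EMISSION_NAMES[int(self.emission[i])]}{EXCITATION_NAMES[int(self.excitation[i])]}"

    def select(self, mask: np.ndarray) -> "PhotonStream":
        return PhotonStream(
            self.timestamps[mask],
            self.emission[mask],
            self.excitation[mask],
            self.duration,
            self.base_dt,
            dict(self.metadata),
        )


_bernoulli_warned = False


def emit_photons(
    rates: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    t0_steps: int = 0,
) -> np.ndarray:
    """Bernoulli photon generation for one channel over consecutive steps.

    ``rates`` (Hz) gives the expected intensity in each base step; a photon is
    recorded with probability min(rate*dt, 1).  Returns the sorted integer
    timestamps (offset by ``t0_steps``).  Warns once when rate*dt exceeds 0.1,
    where the one-photon-per-step Bernoulli approximation of the Poisson
    process degrades.
    """
    global _bernoulli_warned
    if dt <= 0:
        raise ValueError("dt must be positive")
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    p = rates * dt
    if not _bernoulli_warned and np.any(p > 0.1):
        warnings.warn(
            "rate*dt exceeds 0.1: the one-photon-per-step approximation of the "
            "Poisson emission process is degrading",
            stacklevel=2,
        )
        _bernoulli_warned = True
    hits = np.nonzero(rng.random(p.shape) < p)[0]
    return hits + t0_steps


def split_channels(stream: PhotonStream) -> dict[str, PhotonStream]:
    """Partition a stream into the four (emission, excitation) channels."""
    out = {}
    for name in ("D514", "A514", "D632", "A632"):
        em = EMISSION_CODES[name[0]]
        ex = EXCITATION_CODES[int(name[1:])]
        mask = (stream.emission == em) & (stream.excitation == ex)
        out[name] = stream.select(mask)
    return out


def write_stream(stream: PhotonStream, path: str | Path) -> None:
    """Write a stream to ``path``; format chosen by suffix (.h5/.hdf5 or .tsv)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_h5(stream, path)
    elif path.suffix in (".tsv", ".txt"):
        _write_tsv(stream, path)
    else:
        raise ValueError(f"unknown photon-stream format {path.suffix!r}")


def read_stream(path: str | Path) -> PhotonStream:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_h5(path)
    if path.suffix in (".tsv", ".txt"):
        return _read_tsv(path)
    raise ValueError(f"unknown photon-stream format {path.suffix!r}")


def _write_h5(stream: PhotonStream, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        grp = f.create_group("photon_data")
        grp.create_dataset("timestamps", data=stream.timestamps, dtype=np.int64)
        grp.create_dataset("emission", data=stream.emission, dtype=np.uint8)
        grp.create_dataset("excitation", data=stream.excitation, dtype=np.uint8)
        f.attrs["base_dt"] = stream.base_dt
        f.attrs["duration"] = stream.duration
        f.attrs["metadata_json"] = json.dumps(stream.metadata)


def _read_h5(path: Path) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as f:
        grp = f["photon_data"]
        return PhotonStream(
            grp["timestamps"][()],
            grp["emission"][()],
            grp["excitation"][()],
            float(f.attrs["duration"]),
            float(f.attrs["base_dt"]),
            json.loads(f.attrs["metadata_json"]),
        )


def _write_tsv(stream: PhotonStream, path: Path) -> None:
    with open(path, "w") as f:
        f.write(f"# base_dt\t{stream.base_dt!r}\n")
        f.write(f"# duration\t{stream.duration!r}\n")
        f.write(f"# metadata\t{json.dumps(stream.metadata)}\n")
        f.write("timestamp_steps\temission\texcitation\n")
        for t, em, ex in zip(stream.timestamps, stream.emission, stream.excitation):
            f.write(f"{t}\t{EMISSION_NAMES[int(em)]}\t{EXCITATION_NAMES[int(ex)]}\n")


def _read_tsv(path: Path) -> PhotonStream:
    base_dt, duration, metadata = BASE_DT, None, {}
    rows: list[tuple[int, int, int]] = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line[1:].strip().split("\t", 1)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed header line") from exc
                if key == "base_dt":
                    base_dt = float(value)
                elif key == "duration":
                    duration = float(value)
                elif key == "metadata":
                    metadata = json.loads(value)
                continue
            if line.startswith("timestamp_steps"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                t = int(parts[0])
                em = EMISSION_CODES[parts[1]]
                ex = EXCITATION_CODES[int(parts[2])]
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record {line!r}") from exc
            rows.append((t, em, ex))
    arr = np.array(rows, dtype=np.int64).reshape(-1, 3)
    if duration is None:
        duration = float((arr[:, 0].max() + 1) * base_dt) if len(rows) else 0.0
    return PhotonStream(arr[:, 0], arr[:, 1], arr[:, 2], duration, base_dt, metadata)
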