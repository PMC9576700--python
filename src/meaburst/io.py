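"""File formats, run configuration and the seed policy.

Formats (all plain text except voltage):

* spike rasters — two-column tab-separated text (source id, spike time in
  seconds) with ``#``-prefixed header lines carrying duration, kind and
  the full source-id list (so silent sources survive a round trip);
* voltage — HDF5 with one ``voltage`` dataset (electrode x sample) and
  attributes ``fs`` (Hz) and ``units`` (microvolts);
* spectra and scan tables — comma-separated text with a ``#`` header
  comment block recording the analysis settings;
* run configuration — YAML, round-tripping ``RunConfig`` losslessly.

Seed policy: one master seed per run; per-stage seeds derive from a
stable hash of (master seed, stage name, replicate index) and stay below
2**31.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .network import NetworkConfig, NeuronParameters, SpikeRaster
from .spectral import DbSpectrum, WelchSettings
from .spikes import VoltageRecording

__all__ = [
    "RunConfig",
    "derive_seed",
    "save_raster",
    "load_raster",
    "save_voltage",
    "load_voltage",
    "save_spectrum",
    "save_table",
    "write_manifest",
]


def derive_seed(master: int, stage: str, replicate: int = 0) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}:{replicate}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one reproducible run."""

    experiment: str
    network: NetworkConfig = field(default_factory=NetworkConfig)
    genotypes: tuple = ("WT",)
    n_surrogates: int = 3
    n_electrodes: int = 64
    band: tuple = (0.0, 1.0)
    welch_nperseg: int | None = None
    output_dir: str = "results"
    master_seed: int = 0

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["network"] = asdict(self.network)
        doc["genotypes"] = list(self.genotypes)
        doc["band"] = list(self.band)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["network"] = NetworkConfig(**doc["network"])
        doc["genotypes"] = tuple(doc["genotypes"])
        doc["band"] = tuple(doc["band"])
        return cls(**doc)


def save_raster(raster: SpikeRaster, path) -> None:
    path = Path(path)
    lines = [
        "# meaburst spike raster v1",
        f"# duration_s\t{raster.duration!r}",
        f"# kind\t{raster.kind}",
        "# sources\t" + ",".join(str(s) for s in raster.source_ids),
        "# source_id\tspike_time_s",
    ]
    for sid, times in zip(raster.source_ids, raster.spike_times):
        lines.extend(f"{sid}\t{t:.6f}" for t in times)
    path.write_text("\n".join(lines) + "\n")


def load_raster(path) -> SpikeRaster:
    path = Path(path)
    duration = None
    kind = "simulated-neuron"
    sources: list[str] | None = None
    events: dict[str, list[float]] = {}
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "duration_s":
                duration = float(parts[1])
            elif parts[0] == "kind":
                kind = parts[1]
            elif parts[0] == "sources":
                sources = parts[1].split(",") if parts[1] else []
            continue
        if not line.strip():
            continue
        sid, t = line.split("\t")
        events.setdefault(sid, []).append(float(t))
    if duration is None or sources is None:
        raise InvalidInputError(f"{path} is not a meaburst raster file")

    def _coerce(sid: str):
        return int(sid) if sid.lstrip("-").isdigit() else sid

    ids = [_coerce(s) for s in sources]
    trains = tuple(
        np.asarray(sorted(events.get(str(s), [])), dtype=np.float64) for s in sources
    )
    return SpikeRaster(
        source_ids=tuple(ids), spike_times=trains, duration=duration, kind=kind
    )


def save_voltage(recording: VoltageRecording, path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("voltage", data=recording.data, compression="gzip")
        ds.attrs["fs"] = recording.fs
        ds.attrs["units"] = "uV"
        ds.attrs["electrode_ids"] = [str(e) for e in recording.electrode_ids]


def load_voltage(path) -> VoltageRecording:
    with h5py.File(path, "r") as f:
        ds = f["voltage"]
        ids = tuple(
            int(e) if e.lstrip("-").isdigit() else e
            for e in (s.decode() if isinstance(s, bytes) else s for s in ds.attrs["electrode_ids"])
        )
        return VoltageRecording(
            data=ds[...], fs=float(ds.attrs["fs"]), electrode_ids=ids
        )


def _settings_header(settings: WelchSettings, extra: dict | None = None) -> str:
    head = {
        "welch_nperseg": settings.nperseg,
        "welch_overlap": settings.overlap,
        "welch_window": settings.window,
        "fs_hz": settings.fs,
    }
    if extra:
        head.update(extra)
    return "".join(f"# {k}: {v}\n" for k, v in head.items())


def save_spectrum(spectrum: DbSpectrum, path) -> None:
    df = pd.DataFrame({"frequency_hz": spectrum.freqs, "power_db": spectrum.power_db})
    header = _settings_header(
        spectrum.settings,
        {
            "source_id": spectrum.source_id,
            "n_surrogates": spectrum.n_surrogates,
            "n_sources": spectrum.n_sources,
            "n_skipped": spectrum.n_skipped,
        },
    )
    with open(path, "w") as f:
        f.write(header)
        df.to_csv(f, index=False)


def save_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as f:
        for k, v in (meta or {}).items():
            f.write(f"# {k}: {v}\n")
        df.to_csv(f, index=False)


def write_manifest(path, config: RunConfig, seeds: dict, version: str) -> None:
    """Provenance record: config hash, per-stage seeds, package version."""
    doc = asdict(config)
    doc["network"] = asdict(config.network)
    blob = json.dumps(doc, sort_keys=True, default=str)
    manifest = {
        "config": doc,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": seeds,
        "package_version": version,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
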