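"""File formats: spectrogram/IQ containers, envelope CSV, run configuration.

Two interchange layouts are supported for the spectrogram:

* CSV — rows are velocity bins, the first column holds the velocity axis
  (cm/s) and the header row the time axis (s); acquisition metadata travels
  in leading ``#key=value`` comment lines.  Values are written with 17
  significant digits so the round trip is bit-exact for doubles.
* binary container — a ``.npy`` matrix next to a ``.json`` sidecar holding
  the axes and acquisition metadata (same basename); bit-exact by
  construction.

IQ signals use the analogous two-column (real, imag) CSV or ``.npy`` complex
array + JSON sidecar.  Envelope traces are CSV with a provenance header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pipeline import EnvelopeTrace, PipelineConfig
from .spectrogram import AcquisitionParams, IQSignal, Spectrogram

__all__ = [
    "save_spectrogram_csv", "load_spectrogram_csv",
    "save_spectrogram_bin", "load_spectrogram_bin",
    "save_iq_csv", "load_iq_csv", "save_iq_bin", "load_iq_bin",
    "save_envelope", "load_envelope", "load_input",
    "config_to_yaml", "config_from_yaml", "config_hash",
]

_FMT = "%.17g"


def _acq_dict(acq: AcquisitionParams) -> dict:
    return dataclasses.asdict(acq)


def _acq_from_dict(d: dict) -> AcquisitionParams:
    return AcquisitionParams(**{k: float(v) for k, v in d.items()})


def _check_uniform(ax: np.ndarray, name: str) -> None:
    d = np.diff(ax)
    if ax.size > 1 and (np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6, atol=1e-12)):
        raise ValueError(f"non-uniform or non-increasing {name} axis in input file")


# ---------------------------------------------------------------- spectrogram

def save_spectrogram_csv(sp: Spectrogram, path) -> None:
    path = Path(path)
    with path.open("w") as f:
        for k, v in _acq_dict(sp.acquisition).items():
            f.write(f"#{k}={v!r}\n")
        f.write("velocity_cm_s," + ",".join(_FMT % t for t in sp.times) + "\n")
        for r in range(sp.velocities.size):
            f.write(_FMT % sp.velocities[r] + ","
                    + ",".join(_FMT % x for x in sp.intensity[r]) + "\n")


def load_spectrogram_csv(path) -> Spectrogram:
    path = Path(path)
    meta: dict = {}
    with path.open() as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k] = float(v)
            pos = f.tell()
            line = f.readline()
        header = line.rstrip("\n").split(",")
        if not header or header[0] != "velocity_cm_s":
            raise ValueError("spectrogram CSV missing the velocity column header")
        times = np.array([float(x) for x in header[1:]])
        body = np.loadtxt(f, delimiter=",", ndmin=2)
    velocities = body[:, 0]
    intensity = body[:, 1:]
    _check_uniform(times, "time")
    _check_uniform(velocities, "velocity")
    acq = _acq_from_dict(meta) if meta else AcquisitionParams()
    return Spectrogram(intensity, times, velocities, acq)


def save_spectrogram_bin(sp: Spectrogram, path) -> None:
    """Binary matrix container: <path>.npy matrix + <path>.json axes sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), sp.intensity)
    sidecar = {"times": sp.times.tolist(), "velocities": sp.velocities.tolist(),
               "acquisition": _acq_dict(sp.acquisition), "kind": "spectrogram"}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_spectrogram_bin(path) -> Spectrogram:
    path = Path(path)
    intensity = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    times = np.asarray(meta["times"], dtype=float)
    velocities = np.asarray(meta["velocities"], dtype=float)
    _check_uniform(times, "time")
    _check_uniform(velocities, "velocity")
    return Spectrogram(intensity, times, velocities,
                       _acq_from_dict(meta["acquisition"]))


# ------------------------------------------------------------------------ IQ

def save_iq_csv(iq: IQSignal, path) -> None:
    path = Path(path)
    with path.open("w") as f:
        f.write(f"#sampling_rate={iq.sampling_rate!r}\n")
        for k, v in _acq_dict(iq.acquisition).items():
            f.write(f"#{k}={v!r}\n")
        f.write("real,imag\n")
        for z in iq.samples:
            f.write(_FMT % z.real + "," + _FMT % z.imag + "\n")


def load_iq_csv(path) -> IQSignal:
    path = Path(path)
    meta: dict = {}
    with path.open() as f:
        line = f.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k] = float(v)
            line = f.readline()
        if line.strip() != "real,imag":
            raise ValueError("IQ CSV must have a 'real,imag' header")
        body = np.loadtxt(f, delimiter=",", ndmin=2)
    if "sampling_rate" not in meta:
        raise ValueError("IQ CSV missing sampling_rate metadata")
    fs = meta.pop("sampling_rate")
    acq = _acq_from_dict(meta) if meta else AcquisitionParams()
    if abs(fs - acq.echo_sampling_rate) > 1e-6 * acq.echo_sampling_rate:
        raise ValueError("sampling_rate metadata mismatches echo_sampling_rate")
    return IQSignal(body[:, 0] + 1j * body[:, 1], fs, acq)


def save_iq_bin(iq: IQSignal, path) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), iq.samples)
    sidecar = {"sampling_rate": iq.sampling_rate,
               "acquisition": _acq_dict(iq.acquisition), "kind": "iq"}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_iq_bin(path) -> IQSignal:
    path = Path(path)
    samples = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    fs = float(meta["sampling_rate"])
    acq = _acq_from_dict(meta["acquisition"])
    if abs(fs - acq.echo_sampling_rate) > 1e-6 * acq.echo_sampling_rate:
        raise ValueError("sampling_rate metadata mismatches echo_sampling_rate")
    return IQSignal(samples, fs, acq)


def load_input(path, fmt: str):
    """Load a typed input object by declared format.

    Formats: ``csv`` / ``bin`` for spectrograms, ``iq-csv`` / ``iq`` for IQ
    containers.
    """
    loaders = {"csv": load_spectrogram_csv, "bin": load_spectrogram_bin,
               "iq-csv": load_iq_csv, "iq": load_iq_bin}
    if fmt not in loaders:
        raise ValueError(f"unknown format {fmt!r}; supported: {sorted(loaders)}")
    path = Path(path)
    probe = path if fmt.endswith("csv") else path.with_suffix(".npy")
    if not probe.exists():
        raise FileNotFoundError(f"input file not found: {probe}")
    return loaders[fmt](path)


# ------------------------------------------------------------------ envelope

ENVELOPE_COLUMNS = ["time_s", "velocity_cm_s", "sqi_pct", "artifact_flag",
                    "segment_id", "gamma_selected"]


def save_envelope(trace: EnvelopeTrace, path, provenance: dict | None = None) -> None:
    """Envelope trace as CSV with a ``#``-prefixed provenance header."""
    if trace.sqi.size and (trace.sqi.min() < 0 or trace.sqi.max() > 100):
        raise ValueError("sqi out of [0, 100] at write time")
    df = pd.DataFrame({
        "time_s": trace.times,
        "velocity_cm_s": trace.velocities,
        "sqi_pct": trace.sqi,
        "artifact_flag": trace.artifact.astype(int),
        "segment_id": trace.segment_id,
        "gamma_selected": trace.gamma_selected,
    })
    path = Path(path)
    with path.open("w") as f:
        f.write(f"#tool=tcdenv {__version__}\n")
        for k, v in (provenance or {}).items():
            f.write(f"#{k}={v}\n")
        df.to_csv(f, index=False, float_format="%.12g")


def load_envelope(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("time_s", "velocity_cm_s") if c not in df.columns]
    if missing:
        raise ValueError(f"envelope CSV missing columns: {missing}")
    return df


# -------------------------------------------------------------------- config

def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_listify(v) for v in obj]
    return obj


def config_to_yaml(cfg: PipelineConfig, path=None) -> str:
    text = yaml.safe_dump(_listify(dataclasses.asdict(cfg)), sort_keys=True,
                          default_flow_style=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(source) -> PipelineConfig:
    text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) else str(source)
    data = yaml.safe_load(text)
    from .beat_quality import QualityConfig
    from .spectrogram import StftConfig
    from .tracer import TracerConfig

    def build(cls, d):
        d = dict(d)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    return PipelineConfig(
        segment_length=data["segment_length"], min_tail=data["min_tail"],
        stft=build(StftConfig, data["stft"]),
        tracer=build(TracerConfig, data["tracer"]),
        quality=build(QualityConfig, data["quality"]),
        grid_multipliers=tuple(data["grid_multipliers"]),
        wall_cutoff=data["wall_cutoff"], post_cutoff=data["post_cutoff"],
        post_order=data["post_order"], post_median=data["post_median"])


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(config_to_yaml(cfg).encode()).hexdigest()[:16]
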