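"""Readers and writers: WAV / CSV signals, event tables, array artifacts,
feature tables.

Array artifacts are written as ``.npy``/``.npz`` with a JSON sidecar
(`<stem>.json`) carrying the scales, frequencies, pair list or window
centres, so the numeric payload stays language-portable and the metadata
diff-able.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .signal import Signal

__all__ = ["read_signal", "write_signal", "read_events", "FeatureTable",
           "save_array", "load_array"]

_REQUIRED_EVENTS = ("click0", "click1", "trial_end")

_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}


def read_signal(path: str | Path, fs_override: float | None = None,
                channel: int | None = None) -> Signal:
    """Read a Signal from WAV or single-column CSV.

    WAV sampling rate is honoured unless ``fs_override`` is given. CSV has
    no embedded rate, so ``fs_override`` is required there. Multi-channel
    WAV input needs an explicit ``channel``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(path)
        if data.ndim == 2:
            if channel is None:
                raise ValueError(
                    f"{path.name} has {data.shape[1]} channels; select one "
                    "with channel=<index>"
                )
            data = data[:, channel]
        scale = _PCM_SCALE.get(data.dtype)
        x = data.astype(np.float64) / scale if scale else data.astype(np.float64)
        return Signal(samples=x, fs=float(fs_override or fs))
    # plain numeric CSV, one value per line
    if fs_override is None:
        raise ValueError("CSV input carries no sampling rate; pass fs (e.g. --fs)")
    x = np.loadtxt(path, delimiter=",", ndmin=1)
    if x.ndim > 1:
        raise ValueError("expected a single-column CSV; got multiple columns")
    return Signal(samples=x, fs=float(fs_override))


def write_signal(signal: Signal, path: str | Path) -> None:
    """Write to WAV (16-bit PCM, peak-normalised if needed) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        x = signal.samples
        peak = np.max(np.abs(x)) or 1.0
        pcm = np.round(x / max(peak, 1.0) * (2**15 - 1)).astype(np.int16)
        wavfile.write(path, int(round(signal.fs)), pcm)
    else:
        np.savetxt(path, signal.samples, delimiter=",")


def read_events(path: str | Path, require: tuple[str, ...] = _REQUIRED_EVENTS) -> dict[str, float]:
    """Read named time marks from a CSV with columns (name, time_s)."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if "name" not in cols or "time_s" not in cols:
        raise ValueError("events file needs columns: name, time_s")
    df.columns = cols
    names = df["name"].astype(str).str.strip().tolist()
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate event names: {dupes}")
    events = dict(zip(names, df["time_s"].astype(float)))
    missing = [n for n in require if n not in events]
    if missing:
        raise ValueError(f"missing required event marks: {missing}")
    ordered = [events[n] for n in require if n in events]
    if any(b <= a for a, b in zip(ordered, ordered[1:])):
        raise ValueError(f"event times must increase in the order {require}")
    return events


def save_array(path: str | Path, header: dict, **arrays: np.ndarray) -> None:
    """Write arrays (.npz) plus a JSON sidecar with the given header."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = dict(header)
    sidecar["arrays"] = sorted(arrays)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=_jsonify))


def load_array(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        arrays = {k: z[k] for k in z.files}
    return header, arrays


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


@dataclass
class FeatureTable:
    """Named scalar features keyed by (signal, window/global, channel, band).

    A thin wrapper over a DataFrame that carries run metadata (config
    hash, seed, package version) through CSV round trips via '#'-prefixed
    header comments.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        key_cols = [c for c in ("signal", "state", "window", "channel", "band")
                    if c in self.data.columns]
        if key_cols and self.data.duplicated(subset=key_cols).any():
            raise ValueError("duplicate feature-table keys")

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        meta = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                k, _, v = line[1:].strip().partition(":")
                meta[k.strip()] = v.strip()
        data = pd.read_csv(path, skiprows=skip)
        return cls(data=data, metadata=meta)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=_jsonify).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
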