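"""Uniformly sampled real-valued time series with optional event marks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Signal"]


@dataclass
class Signal:
    """A single-channel, uniformly sampled, real-valued signal.

    Parameters
    ----------
    samples : array_like
        Real sample values (arbitrary units). Must be finite, length >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds (default 0).
    events : dict, optional
        Named time marks in seconds (e.g. ``click0``, ``click1``,
        ``trial_end``). Every mark must lie inside the sampled span.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    events: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size < 2:
            raise ValueError("signal needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.fs = float(self.fs)
        self.t0 = float(self.t0)
        tmax = self.t0 + (self.samples.size - 1) / self.fs
        for name, t in self.events.items():
            if not (self.t0 <= t <= tmax + 0.5 / self.fs):
                raise ValueError(
                    f"event {name!r} at t={t} s lies outside the sampled span "
                    f"[{self.t0}, {tmax}] s"
                )

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        """Nominal duration n/fs in seconds (one sample period per sample)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.samples.size - 1)
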