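"""Sliding-window (instantaneous) wavelet bispectrum and bicoherence.

A window of length T slides along the signal with hop dT1 (half overlap
when dT1 = 0.5 T, the EEG-analysis setting). Each window centre t0 gets the
whole-interval WBS/WBC of that window, yielding a time-ordered sequence of
bifrequency fields — the time-bifrequency object. The complex per-window
value decomposes into the instantaneous biamplitude A(a1, a2, t) >= 0 and
biphase phi(a1, a2, t) in (-pi, pi]; for the bicoherence the amplitude is
additionally bounded by 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cwt import CWTField
from .signal import Signal
from .wbs import BifreqGrid, wavelet_bispectrum

__all__ = ["WindowPlan", "InstField", "make_window_plan", "instantaneous_wbs", "instantaneous_wbc"]


@dataclass(frozen=True)
class WindowPlan:
    """Centred analysis windows [t0 - T/2, t0 + T/2] at hop dT1."""

    T: float
    dT1: float
    centres: np.ndarray  # seconds, strictly increasing
    T_total: float

    @property
    def n_windows(self) -> int:
        return self.centres.size

    def interval(self, k: int) -> tuple[float, float]:
        c = self.centres[k]
        return (c - self.T / 2.0, c + self.T / 2.0)


def make_window_plan(signal: Signal, T: float, dT1: float) -> WindowPlan:
    """Maximal set of fully contained windows of length T with hop dT1."""
    if not (0 < dT1 <= T):
        raise ValueError(f"need 0 < dT1 <= T, got dT1={dT1}, T={T}")
    duration = signal.duration
    if T > duration + 1e-12:
        raise ValueError(
            f"window T={T} s exceeds the signal duration {duration:.6g} s"
        )
    n_win = int(np.floor((duration - T) / dT1 + 1e-9)) + 1
    centres = signal.t0 + T / 2.0 + dT1 * np.arange(n_win)
    return WindowPlan(T=float(T), dT1=float(dT1), centres=centres, T_total=duration)


@dataclass
class InstField:
    """Per-window complex WBS (kind='wbs') or complex WBC (kind='wbc').

    ``values`` has shape (n_pairs, n_windows). ``amp * exp(1j * phase)``
    reconstructs the complex values exactly; zero-amplitude entries carry
    phase 0 by convention.
    """

    values: np.ndarray
    grid: BifreqGrid
    plan: WindowPlan
    kind: str  # 'wbs' | 'wbc'

    @property
    def amp(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        ph = np.angle(self.values)
        ph[self.values == 0] = 0.0
        return ph

    def pair_track(self, f1: float, f2: float) -> tuple[np.ndarray, np.ndarray]:
        """(window centres, amplitude) at the retained pair nearest (f1, f2)."""
        p = self.grid.nearest_pair(f1, f2)
        return self.plan.centres, self.amp[p]

    def window_max(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-window maximum amplitude over all pairs and its pair index."""
        return self.amp.max(axis=0), self.amp.argmax(axis=0)


def _per_window(cwt, bifreq, plan, normalise: bool):
    n_pairs = bifreq.n_pairs
    values = np.empty((n_pairs, plan.n_windows), dtype=np.complex128)
    for k in range(plan.n_windows):
        wbs = wavelet_bispectrum(cwt, bifreq, plan.interval(k))
        if normalise:
            denom = np.sqrt(wbs.norm_pair * wbs.norm_sum)
            safe = np.where(denom > 0, denom, 1.0)
            cval = np.where(denom > 0, wbs.values / safe, 0.0 + 0.0j)
            mod = np.abs(cval)
            if np.any(mod > 1.0 + 1e-9):
                raise FloatingPointError(
                    "instantaneous bicoherence exceeded 1 beyond tolerance"
                )
            over = mod > 1.0
            cval[over] /= mod[over]
            values[:, k] = cval
        else:
            values[:, k] = wbs.values
    return values


def instantaneous_wbs(cwt: CWTField, bifreq: BifreqGrid, plan: WindowPlan) -> InstField:
    """Per-window wavelet bispectrum: the IWBS time-bifrequency object."""
    return InstField(values=_per_window(cwt, bifreq, plan, False), grid=bifreq, plan=plan, kind="wbs")


def instantaneous_wbc(cwt: CWTField, bifreq: BifreqGrid, plan: WindowPlan) -> InstField:
    """Per-window wavelet bicoherence; amplitudes lie in [0, 1]."""
    return InstField(values=_per_window(cwt, bifreq, plan, True), grid=bifreq, plan=plan, kind="wbc")
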