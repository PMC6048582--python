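"""Seeded synthetic signals with known quadratic-phase-coupling structure.

Every estimator in the package is validated against these generators:

* ``gen_qpc`` — a sinusoid triplet at f1, f2, f1+f2 in additive white
  Gaussian noise. With a phase-locked triplet (phi3 = phi1 + phi2) the
  sum component is quadratically phase coupled; with an independent phi3
  (re-randomised blockwise) there is spectral power at the sum frequency
  but no coupling.
* ``gen_intermittent`` — the same triplet with coupling switched on only
  inside given time intervals, the test bed for time-resolved detection.
* ``gen_wheeze_like`` — a harmonic stack (default fundamental 160 Hz at
  fs = 5512 Hz) with optional slow linear frequency drift, emulating the
  musical character of a wheeze; coupling strength interpolates between
  harmonics with fully locked phases and blockwise-randomised ones.
* ``gen_pain_trial`` — a relax->pain trial whose within-band coupled
  component keeps full amplitude through the relax period and drops at a
  designed time after pain onset, so a tracked coupling amplitude crosses
  a relax-calibrated threshold at a known endurance fraction.

All generators are bit-deterministic given a seed. Noise is white
Gaussian with sigma relative to unit component amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .signal import Signal

__all__ = ["QPCSpec", "EpisodeSpec", "gen_qpc", "gen_intermittent", "gen_wheeze_like", "gen_pain_trial"]

# Default block length for phase re-randomisation in uncoupled regimes.
# The decohered bicoherence behaves as |mean of B unit phasors| over a
# window holding B blocks (Rayleigh p95 = sqrt(ln 20 / B)), so guaranteeing
# decoherence inside a 1 s analysis window needs B >= ~20 blocks.
PHASE_BLOCK_S = 0.05
#: crossfade applied to blockwise phase jumps (seconds)
CROSSFADE_S = 0.010


@dataclass(frozen=True)
class QPCSpec:
    """A (possibly) quadratically phase-coupled sinusoid triplet."""

    f1: float = 160.0
    f2: float = 320.0
    amp1: float = 1.0
    amp2: float = 1.0
    coupling: float = 1.0  # amplitude of the component at f1 + f2
    phase_mode: str = "locked"  # locked | independent | mixed
    noise_sigma: float = 0.0
    duration: float = 2.0
    fs: float = 5512.0
    seed: int = 0
    phase_block_s: float = PHASE_BLOCK_S

    def __post_init__(self) -> None:
        if self.f1 + self.f2 > self.fs / 2:
            raise ValueError("f1 + f2 exceeds the Nyquist frequency")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.duration * self.fs < 64:
            raise ValueError("need at least 64 samples")
        if self.phase_mode not in ("locked", "independent", "mixed"):
            raise ValueError(f"unknown phase_mode {self.phase_mode!r}")


@dataclass(frozen=True)
class EpisodeSpec:
    """Intermittent coupling: locked inside the intervals, decohered outside."""

    base: QPCSpec = field(default_factory=QPCSpec)
    coupling_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_end = 0.0
        for on, off in self.coupling_intervals:
            if not (0.0 <= on < off <= self.base.duration):
                raise ValueError(f"interval [{on}, {off}] outside the signal")
            if on < prev_end:
                raise ValueError("coupling intervals must be disjoint and sorted")
            prev_end = off


def _block_phases(n: int, fs: float, rng: np.random.Generator,
                  block_s: float = PHASE_BLOCK_S) -> np.ndarray:
    """Piecewise-constant random phase, one independent draw per block."""
    block = max(1, int(round(block_s * fs)))
    n_blocks = int(np.ceil(n / block))
    draws = rng.uniform(-np.pi, np.pi, n_blocks)
    return np.repeat(draws, block)[:n]


def _smooth_phasor(phase: np.ndarray, fs: float) -> np.ndarray:
    """Unit-magnitude-ish phasor with 10 ms crossfade at phase jumps."""
    z = np.exp(1j * phase)
    k = max(1, int(round(CROSSFADE_S * fs)))
    if k > 1:
        zr = ndimage.uniform_filter1d(z.real, size=k, mode="nearest")
        zi = ndimage.uniform_filter1d(z.imag, size=k, mode="nearest")
        z = zr + 1j * zi
    return z


def _third_component(spec: QPCSpec, t: np.ndarray, phi1: float, phi2: float,
                     rng: np.random.Generator) -> np.ndarray:
    f3 = spec.f1 + spec.f2
    locked = np.cos(2 * np.pi * f3 * t + phi1 + phi2)
    if spec.phase_mode == "locked":
        return spec.coupling * locked
    z = _smooth_phasor(_block_phases(t.size, spec.fs, rng, spec.phase_block_s), spec.fs)
    indep = np.real(np.exp(2j * np.pi * f3 * t) * z)
    if spec.phase_mode == "independent":
        return spec.coupling * indep
    # mixed: unit-amplitude component whose phasor is a coupling-weighted mix
    return spec.coupling * locked + (1.0 - spec.coupling) * indep


def gen_qpc(spec: QPCSpec) -> Signal:
    """Sinusoid triplet per ``spec``; deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs)) + 1
    t = np.arange(n) / spec.fs
    phi1, phi2 = rng.uniform(-np.pi, np.pi, 2)
    x = spec.amp1 * np.cos(2 * np.pi * spec.f1 * t + phi1)
    x += spec.amp2 * np.cos(2 * np.pi * spec.f2 * t + phi2)
    x += _third_component(spec, t, phi1, phi2, rng)
    if spec.noise_sigma > 0:
        x += spec.noise_sigma * rng.standard_normal(n)
    return Signal(samples=x, fs=spec.fs)


def gen_intermittent(espec: EpisodeSpec) -> Signal:
    """Triplet with phase locking only inside ``coupling_intervals``."""
    spec = espec.base
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs)) + 1
    t = np.arange(n) / spec.fs
    phi1, phi2 = rng.uniform(-np.pi, np.pi, 2)
    x = spec.amp1 * np.cos(2 * np.pi * spec.f1 * t + phi1)
    x += spec.amp2 * np.cos(2 * np.pi * spec.f2 * t + phi2)
    f3 = spec.f1 + spec.f2
    phase = _block_phases(n, spec.fs, rng, spec.phase_block_s)
    for on, off in espec.coupling_intervals:
        # half-open [on, off); an interval reaching the signal end keeps
        # its last sample so full coverage reproduces the locked triplet
        hi = off + 0.5 / spec.fs if off >= spec.duration else off
        inside = (t >= on) & (t < hi)
        phase[inside] = phi1 + phi2
    z = _smooth_phasor(phase, spec.fs)
    x += spec.coupling * np.real(np.exp(2j * np.pi * f3 * t) * z)
    if spec.noise_sigma > 0:
        x += spec.noise_sigma * rng.standard_normal(n)
    return Signal(samples=x, fs=spec.fs)


def gen_wheeze_like(
    f0: float = 160.0,
    n_harmonics: int = 3,
    drift: float = 0.0,
    coupling: float = 1.0,
    duration: float = 2.0,
    fs: float = 5512.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Signal:
    """Harmonic wheeze-like stack with linear frequency drift.

    The fundamental sweeps f0 + drift * t; harmonic k follows at k times
    the fundamental's instantaneous phase when fully coupled. ``coupling``
    mixes, per harmonic, the phase-locked component against one with
    blockwise-randomised extra phase. Durations at or below 150 ms are
    rejected: shorter episodes do not qualify as wheezes.
    """
    if duration <= 0.150:
        raise ValueError("a wheeze lasts longer than 150 ms; increase duration")
    if n_harmonics < 1:
        raise ValueError("need at least the fundamental")
    if n_harmonics * (f0 + abs(drift) * duration) > fs / 2:
        raise ValueError("highest harmonic exceeds the Nyquist frequency")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    phi0 = rng.uniform(-np.pi, np.pi)
    base_phase = 2 * np.pi * (f0 * t + 0.5 * drift * t**2) + phi0
    x = np.cos(base_phase)
    for k in range(2, n_harmonics + 1):
        amp = 0.8 ** (k - 1)
        locked = np.cos(k * base_phase)
        if coupling >= 1.0:
            x += amp * locked
            continue
        eta = _smooth_phasor(_block_phases(n, fs, rng), fs)
        indep = np.real(np.exp(1j * k * base_phase) * eta)
        x += amp * (coupling * locked + (1.0 - coupling) * indep)
    if noise_sigma > 0:
        x += noise_sigma * rng.standard_normal(n)
    return Signal(samples=x, fs=fs)


def gen_pain_trial(
    relax_s: float = 20.0,
    pain_s: float = 40.0,
    endurance_fraction: float = 0.5,
    band: tuple[float, float, float] = (14.0, 16.0, 30.0),
    fs: float = 128.0,
    noise_sigma: float = 0.05,
    residual_coupling: float = 0.05,
    seed: int = 0,
) -> Signal:
    """Relax -> pain EEG-like trial with a designed endurance fraction.

    The trial carries a phase-locked triplet (f1, f2, f1+f2) = ``band``
    (defaults inside the beta band). The coupled sum component keeps unit
    amplitude until t* = t_click1 + endurance_fraction * pain_s, then
    drops to ``residual_coupling`` over a 1 s crossfade, so a tracked
    coupling amplitude crosses a relax-calibrated threshold at t*.
    Events: click0 = 0, click1 = relax_s, trial_end = relax_s + pain_s.
    """
    if not 0.0 < endurance_fraction <= 1.0:
        raise ValueError("endurance_fraction must lie in (0, 1]")
    f1, f2, f3 = band
    if abs((f1 + f2) - f3) > 1e-9:
        raise ValueError("band must be a sum triplet (f1, f2, f1 + f2)")
    duration = relax_s + pain_s
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    phi1, phi2 = rng.uniform(-np.pi, np.pi, 2)
    x = np.cos(2 * np.pi * f1 * t + phi1) + np.cos(2 * np.pi * f2 * t + phi2)
    t_star = relax_s + endurance_fraction * pain_s
    if endurance_fraction >= 1.0:
        lam = np.ones(n)
    else:
        # unit amplitude, 1 s linear crossfade down to the residual at t*
        lam = np.interp(t, [t_star, t_star + 1.0], [1.0, residual_coupling],
                        left=1.0, right=residual_coupling)
    x += lam * np.cos(2 * np.pi * f3 * t + phi1 + phi2)
    if noise_sigma > 0:
        x += noise_sigma * rng.standard_normal(n)
    return Signal(
        samples=x,
        fs=fs,
        events={"click0": 0.0, "click1": relax_s, "trial_end": duration},
    )
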