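"""Fourier-based third-order spectra: bispectrum and bicoherence.

Direct (segment-averaged) estimators. For segment Fourier coefficients
X(w) the bispectrum is

    B(w1, w2) = E[ X(w1) X(w2) X*(w1 + w2) ],

nonzero when the three components are phase related (quadratic phase
coupling). The bicoherence normalises it to [0, 1]:

    b(w1, w2) = |B(w1, w2)| / sqrt( E|X(w1) X(w2)|^2 * E|X(w1+w2)|^2 ),

which is bounded by 1 via Cauchy-Schwarz over segments and reaches 1 only
under perfect phase locking. These serve as the stationary-case baseline
for the wavelet estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.signal import get_window

from .signal import Signal

__all__ = ["BispecField", "BicohField", "estimate_bispectrum", "estimate_bicoherence"]


@dataclass
class BispecField:
    """Bispectrum on the principal region Delta: k2 <= k1, k1 + k2 <= Nyquist bin.

    ``values[i, j]`` holds B(freq_axis[i], freq_axis[j]); entries outside
    Delta are NaN and ``mask`` is False there. ``norm_pair`` and ``norm_sum``
    are the segment-averaged magnitude terms used by the bicoherence.
    """

    values: np.ndarray  # complex (nf, nf), NaN outside Delta
    freq_axis: np.ndarray  # Hz
    n_segments: int
    power_spectrum: np.ndarray  # (nf,), >= 0
    mask: np.ndarray  # bool (nf, nf)
    norm_pair: np.ndarray  # E|X1 X2|^2 on Delta
    norm_sum: np.ndarray  # E|X(w1+w2)|^2 arranged on Delta


@dataclass
class BicohField:
    values: np.ndarray  # real in [0, 1] on Delta, NaN outside
    freq_axis: np.ndarray
    n_segments: int
    mask: np.ndarray
    zero_denominator: np.ndarray  # bool flags


def _segments(x: np.ndarray, seg_len: int, overlap: float) -> np.ndarray:
    hop = max(1, int(round(seg_len * (1.0 - overlap))))
    starts = range(0, x.size - seg_len + 1, hop)
    return np.stack([x[s : s + seg_len] for s in starts])


def estimate_bispectrum(
    signal: Signal,
    nfft: int,
    seg_len: int,
    overlap: float = 0.5,
    window: str = "hann",
) -> BispecField:
    """Direct segment-averaged bispectrum estimate on the principal region."""
    x = signal.samples
    if seg_len > x.size:
        raise ValueError("seg_len exceeds signal length")
    if nfft < seg_len:
        raise ValueError("nfft must be >= seg_len")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    segs = _segments(x, seg_len, overlap)
    if segs.shape[0] < 4:
        raise ValueError(
            f"only {segs.shape[0]} segments; need >= 4 for a usable estimate"
        )
    taper = get_window(window, seg_len, fftbins=True)
    segs = (segs - segs.mean(axis=1, keepdims=True)) * taper
    X = np.fft.rfft(segs, n=nfft, axis=1)  # (n_seg, nf)
    nf = X.shape[1]
    k = np.arange(nf)
    k1 = k[:, None]
    k2 = k[None, :]
    ksum = k1 + k2
    mask = (k2 <= k1) & (ksum <= nfft // 2)
    i1, i2 = np.nonzero(mask)
    isum = i1 + i2

    X1X2 = X[:, i1] * X[:, i2]
    X3 = X[:, isum]
    b_flat = np.mean(X1X2 * np.conj(X3), axis=0)
    npair_flat = np.mean(np.abs(X1X2) ** 2, axis=0)
    nsum_flat = np.mean(np.abs(X3) ** 2, axis=0)

    values = np.full((nf, nf), np.nan + 0j, dtype=np.complex128)
    norm_pair = np.full((nf, nf), np.nan)
    norm_sum = np.full((nf, nf), np.nan)
    values[i1, i2] = b_flat
    norm_pair[i1, i2] = npair_flat
    norm_sum[i1, i2] = nsum_flat
    # the product commutes, so the mirrored entries are filled explicitly;
    # `mask` still marks the non-redundant triangle
    values[i2, i1] = b_flat
    norm_pair[i2, i1] = npair_flat
    norm_sum[i2, i1] = nsum_flat

    ps = np.mean(np.abs(X) ** 2, axis=0) / (np.sum(taper**2) * signal.fs)
    freq_axis = np.fft.rfftfreq(nfft, d=1.0 / signal.fs)
    return BispecField(
        values=values,
        freq_axis=freq_axis,
        n_segments=segs.shape[0],
        power_spectrum=ps,
        mask=mask,
        norm_pair=norm_pair,
        norm_sum=norm_sum,
    )


def estimate_bicoherence(
    signal: Signal,
    nfft: int,
    seg_len: int,
    overlap: float = 0.5,
    window: str = "hann",
) -> BicohField:
    """Normalised bispectrum magnitude in [0, 1] on the principal region."""
    bs = estimate_bispectrum(signal, nfft, seg_len, overlap, window)
    denom2 = bs.norm_pair * bs.norm_sum
    zero = np.zeros_like(bs.mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.abs(bs.values) / np.sqrt(denom2)
    bad = bs.mask & ~(denom2 > 0)
    if np.all(np.abs(np.nan_to_num(bs.values[bs.mask])) == 0):
        warnings.warn("all-zero bispectrum; bicoherence set to 0", UserWarning)
    vals[bad] = 0.0
    zero |= bad
    finite = np.isfinite(vals)
    if np.any(vals[finite] > 1.0 + 1e-9):
        raise FloatingPointError("bicoherence exceeded 1 beyond numerical tolerance")
    vals[finite] = np.clip(vals[finite], 0.0, 1.0)
    return BicohField(
        values=vals,
        freq_axis=bs.freq_axis,
        n_segments=bs.n_segments,
        mask=bs.mask,
        zero_denominator=zero,
    )
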