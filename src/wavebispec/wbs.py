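"""Wavelet bispectrum, bicoherence and summed bicoherence.

The wavelet bispectrum over a finite interval [tau0, tau1] is

    WBS(a1, a2) = int_{tau0}^{tau1} W(a1, t) W(a2, t) W*(a, t) dt,

where the analysing scales obey the sum rule 1/a = 1/a1 + 1/a2, i.e. in
pseudo-frequency terms f = f1 + f2 within the frequency resolution of the
grid. It measures quadratic phase coupling (QPC) between the components at
f1, f2 and their sum. The wavelet bicoherence normalises it,

    WBC(a1, a2)^2 = |WBS|^2 / ( int |W(a1,t) W(a2,t)|^2 dt * int |W(a,t)|^2 dt ),

which lies in [0, 1] by the Cauchy-Schwarz inequality: 0 means absence and
1 strong presence of QPC over the interval. The summed wavelet bicoherence
accumulates squared WBC per sum frequency.

On a discrete scale grid the sum rule is satisfied only approximately; the
bifrequency pair table records, for every retained pair, the nearest sum
scale and the relative mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cwt import CWTField, ScaleGrid

__all__ = [
    "BifreqGrid",
    "WBSField",
    "WBCField",
    "build_bifreq_grid",
    "wavelet_bispectrum",
    "wavelet_bicoherence",
    "summed_wbc",
]

_PAIR_CHUNK = 128  # pairs per vectorised block, bounds peak memory


@dataclass(frozen=True)
class BifreqGrid:
    """Retained (f1, f2, f1+f2) scale-index triplets on the principal region.

    Pairs are canonical with ``f1 <= f2``; the bispectral product is
    symmetric under swap so nothing is lost. ``i_sum`` indexes the grid
    scale whose frequency is nearest f1 + f2 and ``match_error`` is the
    relative deviation |(f1 + f2) - f_sum| / (f1 + f2).
    """

    scale_grid: ScaleGrid
    i1: np.ndarray
    i2: np.ndarray
    i_sum: np.ndarray
    match_error: np.ndarray
    tolerance: float

    @property
    def n_pairs(self) -> int:
        return self.i1.size

    @property
    def f1(self) -> np.ndarray:
        return self.scale_grid.freqs[self.i1]

    @property
    def f2(self) -> np.ndarray:
        return self.scale_grid.freqs[self.i2]

    @property
    def f_sum(self) -> np.ndarray:
        """Matched (grid) sum frequency of each pair."""
        return self.scale_grid.freqs[self.i_sum]

    def nearest_pair(self, f1: float, f2: float) -> int:
        """Index of the retained pair closest to (f1, f2) in log-frequency."""
        lo, hi = min(f1, f2), max(f1, f2)
        d = np.log(self.f1 / lo) ** 2 + np.log(self.f2 / hi) ** 2
        return int(np.argmin(d))


def build_bifreq_grid(grid: ScaleGrid, tolerance: float = 0.05) -> BifreqGrid:
    """Enumerate principal-region pairs whose sum matches a grid scale.

    A pair (f1, f2), f1 <= f2, is retained when the grid frequency nearest
    f1 + f2 deviates from it by at most ``tolerance`` (relative), the
    paper-style reading of coupling "within the frequency resolution".
    """
    freqs = grid.freqs
    n = freqs.size
    i1l, i2l, isl, errl = [], [], [], []
    for j1 in range(n):
        for j2 in range(j1, n):
            fsum = freqs[j1] + freqs[j2]
            if fsum > freqs[-1] * (1.0 + tolerance):
                break  # inner loop ascending: later sums only larger
            js = int(np.argmin(np.abs(freqs - fsum)))
            err = abs(fsum - freqs[js]) / fsum
            if err <= tolerance:
                i1l.append(j1)
                i2l.append(j2)
                isl.append(js)
                errl.append(err)
    if not i1l:
        raise ValueError(
            "no bifrequency pair satisfies the sum rule within tolerance; "
            "use a denser scale grid or a larger tolerance"
        )
    return BifreqGrid(
        scale_grid=grid,
        i1=np.asarray(i1l),
        i2=np.asarray(i2l),
        i_sum=np.asarray(isl),
        match_error=np.asarray(errl),
        tolerance=float(tolerance),
    )


@dataclass
class WBSField:
    """Complex WBS per retained pair over one analysis interval.

    ``norm_pair`` = int |W1 W2|^2 dt and ``norm_sum`` = int |W3|^2 dt are
    the two normalisation integrals needed by the bicoherence.
    """

    values: np.ndarray  # complex (n_pairs,)
    grid: BifreqGrid
    interval: tuple[float, float]
    norm_pair: np.ndarray
    norm_sum: np.ndarray

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def biphase(self) -> np.ndarray:
        ph = np.angle(self.values)
        ph[self.values == 0] = 0.0
        return ph


@dataclass
class WBCField:
    values: np.ndarray  # real in [0, 1] per pair
    grid: BifreqGrid
    interval: tuple[float, float]
    zero_denominator: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.zero_denominator is None:
            self.zero_denominator = np.zeros(self.values.shape, dtype=bool)


def _interval_slice(cwt: CWTField, interval: tuple[float, float]) -> slice:
    t0c, t1c = interval
    lo = int(np.ceil((t0c - cwt.t0) * cwt.fs - 1e-9))
    hi = int(np.floor((t1c - cwt.t0) * cwt.fs + 1e-9))
    lo = max(lo, 0)
    hi = min(hi, cwt.n_samples - 1)
    if hi - lo < 1:
        raise ValueError(f"interval {interval} spans fewer than 2 samples")
    return slice(lo, hi + 1)


def wavelet_bispectrum(
    cwt: CWTField,
    bifreq: BifreqGrid,
    interval: tuple[float, float] | None = None,
    exclude_coi: bool = False,
) -> WBSField:
    """Trapezoidal time integral of W(a1) W(a2) W*(a_sum) over the interval.

    With ``exclude_coi`` the samples inside the cone of influence of any of
    the three scales contribute zero weight.
    """
    if bifreq.scale_grid is not cwt.grid and not np.array_equal(
        bifreq.scale_grid.freqs, cwt.grid.freqs
    ):
        raise ValueError("bifrequency grid was built from a different scale grid")
    if interval is None:
        interval = (cwt.t0, cwt.t0 + (cwt.n_samples - 1) / cwt.fs)
    sl = _interval_slice(cwt, interval)
    W = cwt.coeffs[:, sl]
    dt = 1.0 / cwt.fs
    n_pairs = bifreq.n_pairs
    values = np.empty(n_pairs, dtype=np.complex128)
    norm_pair = np.empty(n_pairs)
    norm_sum = np.empty(n_pairs)
    coi = cwt.cone_of_influence[:, sl] if exclude_coi else None
    for s in range(0, n_pairs, _PAIR_CHUNK):
        e = min(s + _PAIR_CHUNK, n_pairs)
        w12 = W[bifreq.i1[s:e]] * W[bifreq.i2[s:e]]
        w3 = W[bifreq.i_sum[s:e]]
        prod = w12 * np.conj(w3)
        p12 = np.abs(w12) ** 2
        p3 = np.abs(w3) ** 2
        if coi is not None:
            valid = ~(coi[bifreq.i1[s:e]] | coi[bifreq.i2[s:e]] | coi[bifreq.i_sum[s:e]])
            prod = prod * valid
            p12 = p12 * valid
            p3 = p3 * valid
        values[s:e] = np.trapezoid(prod, dx=dt, axis=1)
        norm_pair[s:e] = np.trapezoid(p12, dx=dt, axis=1)
        norm_sum[s:e] = np.trapezoid(p3, dx=dt, axis=1)
    return WBSField(
        values=values,
        grid=bifreq,
        interval=(float(interval[0]), float(interval[1])),
        norm_pair=norm_pair,
        norm_sum=norm_sum,
    )


def wavelet_bicoherence(wbsfield: WBSField) -> WBCField:
    """Normalise a WBS field to the [0, 1] bicoherence."""
    if np.any(wbsfield.norm_pair < 0) or np.any(wbsfield.norm_sum < 0):
        raise AssertionError("negative normalisation integral (internal error)")
    denom2 = wbsfield.norm_pair * wbsfield.norm_sum
    zero = ~(denom2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.abs(wbsfield.values) / np.sqrt(denom2)
    vals[zero] = 0.0
    if np.any(vals > 1.0 + 1e-9):
        raise FloatingPointError(
            "wavelet bicoherence exceeded 1 beyond numerical tolerance"
        )
    np.clip(vals, 0.0, 1.0, out=vals)
    return WBCField(
        values=vals,
        grid=wbsfield.grid,
        interval=wbsfield.interval,
        zero_denominator=zero,
    )


def summed_wbc(wbcfield: WBCField) -> tuple[np.ndarray, np.ndarray]:
    """Sum of squared WBC per matched sum frequency.

    Returns ``(sum_freqs, swbc)`` where ``sum_freqs`` are the distinct grid
    frequencies that occur as matched sums, ascending.
    """
    if wbcfield.values.size == 0:
        raise ValueError("empty bicoherence field")
    isum = wbcfield.grid.i_sum
    uniq = np.unique(isum)
    swbc = np.zeros(uniq.size)
    for k, js in enumerate(uniq):
        swbc[k] = np.sum(wbcfield.values[isum == js] ** 2)
    return wbcfield.grid.scale_grid.freqs[uniq], swbc
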