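"""EEG tonic-pain feature system on the bifrequency domain.

Features are band averages of bifrequency fields over the canonical EEG
rhythms (delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-49 Hz)
inside the principal region, optionally referenced to the relax state as
F = (P - R) / R and folded into hemispheric asymmetries (differential
left - right or rational left / right) over symmetric channel pairs.

The pain-endurance metric summarises a trial: with click1 marking pain
onset and trial end marking the tolerance limit, T_P = t_end - t_click1,
and T_tol is the time from click1 until the tracked coupling amplitude
first drops below a relax-calibrated threshold thr_P and stays there;
PE = T_tol / T_P in [0, 1]. Severe pain shows up as a *decrease* of the
tracked amplitude, so thresholds sit below the relax-period mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instantaneous import InstField
from .lattice import PairLattice, as_lattice
from .wbs import WBCField, WBSField
from scipy import ndimage

__all__ = [
    "BandScheme",
    "EEG_BANDS",
    "PEResult",
    "band_average",
    "band_track",
    "count_wbsamp_local_maxima",
    "apply_referencing",
    "hemispheric_asymmetry",
    "rmp_state_sequence",
    "relax_thresholds",
    "pain_endurance",
]

#: Canonical EEG band limits in Hz within the 1-49 Hz analysis passband.
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 49.0),
}

BandScheme = dict[str, tuple[float, float]]


def band_average(
    field: "WBSField | WBCField | PairLattice",
    bands: BandScheme | None = None,
    cross_band: bool = False,
) -> dict[str, float]:
    """Mean field value per band over pairs with both frequencies in band.

    The default intersects each band's square (band x band) with the
    principal region; an empty intersection yields NaN for that band.
    ``cross_band`` is reserved for rectangle (band1 x band2) averaging and
    is not enabled by default.
    """
    if cross_band:
        raise NotImplementedError("cross-band rectangles are off by default")
    bands = bands or EEG_BANDS
    if isinstance(field, PairLattice):
        lat = field
        f1 = np.repeat(lat.f1_axis, lat.f2_axis.size).reshape(lat.values.shape)
        f2 = np.tile(lat.f2_axis, (lat.f1_axis.size, 1))
        out = {}
        for name, (lo, hi) in bands.items():
            sel = lat.mask & (f1 >= lo) & (f1 <= hi) & (f2 >= lo) & (f2 <= hi)
            out[name] = float(lat.values[sel].mean()) if np.any(sel) else float("nan")
        return out
    grid = field.grid
    data = field.amplitude if isinstance(field, WBSField) else field.values
    f1, f2 = grid.f1, grid.f2
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (f1 >= lo) & (f1 <= hi) & (f2 >= lo) & (f2 <= hi)
        out[name] = float(data[sel].mean()) if np.any(sel) else float("nan")
    return out


def band_track(inst: InstField, band: str | tuple[float, float] = "beta") -> tuple[np.ndarray, np.ndarray]:
    """Per-window band-averaged amplitude track (window centres, values)."""
    lo, hi = EEG_BANDS[band] if isinstance(band, str) else band
    f1, f2 = inst.grid.f1, inst.grid.f2
    sel = (f1 >= lo) & (f1 <= hi) & (f2 >= lo) & (f2 <= hi)
    if not np.any(sel):
        raise ValueError(f"no retained bifrequency pair inside band {band}")
    return inst.plan.centres, inst.amp[sel].mean(axis=0)


def count_wbsamp_local_maxima(field: "WBSField | PairLattice") -> int:
    """Local-maxima count of the WBS amplitude thresholded to its top quartile.

    Values below the 75th percentile of the field are zeroed; the strict
    8-neighbour local maxima among the surviving cells are counted. The
    count expresses the multiplicity of the main QPC pairs.
    """
    lat = as_lattice(field)
    if not np.any(lat.mask):
        return 0
    vals = lat.values.copy()
    valid = lat.mask
    q75 = np.percentile(vals[valid], 75)
    vals = np.where(valid & (vals >= q75), vals, 0.0)
    surviving = valid & (vals > 0)
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    work = np.where(valid, vals, -np.inf)
    neigh = ndimage.maximum_filter(work, footprint=footprint, mode="constant", cval=-np.inf)
    return int(np.sum(surviving & (work > neigh)))


def apply_referencing(pain_value: float, relax_value: float, mode: str = "NoR") -> float:
    """NoR: pain value unchanged. RS: F = (P - R) / R."""
    if mode == "NoR":
        return float(pain_value)
    if mode == "RS":
        if relax_value == 0:
            return float("nan")
        return float((pain_value - relax_value) / relax_value)
    raise ValueError(f"unknown referencing mode {mode!r}")


def hemispheric_asymmetry(left: float, right: float, mode: str = "DAs") -> float:
    """DAs: left - right. RAs: left / right (NaN when right is 0)."""
    if mode == "DAs":
        return float(left - right)
    if mode == "RAs":
        if right == 0:
            return float("nan")
        return float(left / right)
    raise ValueError(f"unknown asymmetry mode {mode!r}")


def rmp_state_sequence(track: np.ndarray, thr_R: float, thr_P: float) -> list[str]:
    """Label each window R (relax), M (mild) or P (severe pain).

    Severe pain corresponds to *low* tracked amplitude: values above thr_R
    map to R, below thr_P to P, between to M. Pure thresholding, no
    hysteresis.
    """
    if not thr_P < thr_R:
        raise ValueError(f"need thr_P < thr_R, got thr_P={thr_P}, thr_R={thr_R}")
    track = np.asarray(track, dtype=np.float64)
    return ["R" if v > thr_R else ("P" if v < thr_P else "M") for v in track]


def relax_thresholds(
    relax_values: np.ndarray, n_sigma_R: float = 1.0, n_sigma_P: float = 10.0
) -> tuple[float, float]:
    """(thr_R, thr_P) = relax mean minus n_sigma_R / n_sigma_P relax sd.

    The relax sd is estimated from few, half-overlapping windows and the
    stationary track is non-Gaussian: excursions to 5 estimated-sd occur
    routinely, while a genuine coupling collapse drops the track by two
    orders of magnitude more. The severe-pain offset therefore defaults
    to 10 sd -- above any stationary excursion, far above the drop.
    """
    relax_values = np.asarray(relax_values, dtype=np.float64)
    if relax_values.size < 2:
        raise ValueError("need at least 2 relax-period windows to calibrate thresholds")
    mu, sd = relax_values.mean(), relax_values.std(ddof=1)
    return float(mu - n_sigma_R * sd), float(mu - n_sigma_P * sd)


@dataclass
class PEResult:
    """Pain-endurance summary of one trial."""

    T_tol: float
    T_P: float
    PE: float
    thr_P: float
    crossing_time: float | None


def pain_endurance(
    times: np.ndarray,
    values: np.ndarray,
    t_click1: float,
    t_end: float,
    thr_P: float | None = None,
    k_persist: int = 3,
    n_sigma_P: float = 10.0,
) -> PEResult:
    """Pain tolerance time from a per-window amplitude track.

    ``thr_P`` defaults to mean - ``n_sigma_P`` * std of the relax-period
    part of the track (window centres before ``t_click1``). T_tol is the
    time from click1 to the first window centre at which the track enters
    and stays below thr_P for at least ``k_persist`` consecutive windows;
    if it never does, T_tol = T_P. At the usual hop of half a window,
    adjacent windows share half their samples, so a single noise event
    spans two windows; the default persistence of three therefore demands
    two windows with disjoint samples below threshold.
    """
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if not t_click1 < t_end:
        raise ValueError("need t_click1 < t_end")
    T_P = float(t_end - t_click1)
    pain = times >= t_click1
    if not np.any(pain):
        raise ValueError("track lies entirely within the relax period")
    if thr_P is None:
        relax = values[times < t_click1]
        _, thr_P = relax_thresholds(relax, n_sigma_P=n_sigma_P)
    below = values < thr_P
    crossing = None
    idx = np.nonzero(pain)[0]
    run = 0
    for i in idx:
        run = run + 1 if below[i] else 0
        if run >= k_persist:
            crossing = float(times[i - k_persist + 1])
            break
    if crossing is None:
        T_tol = T_P
    else:
        T_tol = float(np.clip(crossing - t_click1, 0.0, T_P))
    return PEResult(
        T_tol=T_tol,
        T_P=T_P,
        PE=T_tol / T_P,
        thr_P=float(thr_P),
        crossing_time=crossing,
    )
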