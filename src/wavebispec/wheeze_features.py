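"""Wheeze nonlinearity features from wavelet bispectral fields.

A wheeze is a continuous adventitious lung sound (> 150 ms, distinct
spectral peaks above 100 Hz) whose musical, harmonic character can carry
quadratic phase coupling between its harmonics. The feature system here
captures that coupling in two views:

* global peaks (GPs) on the whole-signal WBS/WBC field — bifrequency
  position, height, and the contour-distance statistics mean(D), std(D)
  of the level contour around each peak;
* local peaks (LPs) on the sliding-window IWBS/IWBC — the per-window
  maximum and its position, whose level occupancy defines the
  nonlinearity index: windows are graded I..V when the window maximum
  lies in [0-0.2), [0.2-0.4), [0.4-0.6), [0.6-0.8), [0.8-1], and NLI_j is
  the fraction of the signal duration spent at level j.

The assembled feature vector carries 13 named scalars: NLI_I..NLI_V,
GP_height, f_c1, f_c2, meanD_GP, stdD_GP, and the LP-trajectory summary
LP_max, LP_f1, LP_f2.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .instantaneous import InstField
from .lattice import PairLattice, as_lattice
from .wbs import WBCField, WBSField

__all__ = [
    "Peak",
    "NLIProfile",
    "NLI_LEVEL_EDGES",
    "detect_peaks",
    "peak_contour",
    "nonlinearity_index",
    "wheeze_feature_vector",
]

NLI_LEVEL_EDGES = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
NLI_LEVEL_NAMES = ["I", "II", "III", "IV", "V"]


@dataclass
class Peak:
    """A bifrequency peak with optional level-contour statistics."""

    f_c1: float
    f_c2: float
    height: float
    index: tuple[int, int]
    contour: np.ndarray | None = None  # (m, 2) boundary points in Hz
    mean_D: float | None = None
    std_D: float | None = None
    truncated: bool = False


@dataclass
class NLIProfile:
    """Level occupancy of the per-window maximum coupling value."""

    ratios: dict[str, float]
    level_series: pd.DataFrame  # columns: t, value, level, f1, f2
    edges: np.ndarray = dc_field(default_factory=lambda: NLI_LEVEL_EDGES.copy())


def level_of(value: float) -> int:
    """Five-level grade of a coupling value in [0, 1]; bins half-open, last closed."""
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"coupling value {value} outside [0, 1]")
    lev = int(np.searchsorted(NLI_LEVEL_EDGES[1:-1], value, side="right"))
    return lev  # 0..4


def detect_peaks(
    field: "WBSField | WBCField | PairLattice",
    min_height: float = 0.1,
    min_separation: float = 0.0,
) -> list[Peak]:
    """Strict 8-neighbour local maxima on the pair lattice.

    Maxima below ``min_height`` times the global maximum are dropped; the
    survivors are greedily pruned in descending height so that no two
    retained peaks are closer than ``min_separation`` Hz (Euclidean in the
    bifrequency plane). Sorted by height, descending.
    """
    lat = as_lattice(field)
    vals = lat.masked(fill=-np.inf)
    if not np.any(lat.mask):
        return []
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_max = ndimage.maximum_filter(
        vals, footprint=footprint, mode="constant", cval=-np.inf
    )
    strict = lat.mask & (vals > neigh_max)
    gmax = vals[lat.mask].max()
    if not np.isfinite(gmax) or gmax <= 0:
        return []
    strict &= vals >= min_height * gmax
    idx = np.argwhere(strict)
    peaks = [
        Peak(
            f_c1=float(lat.f1_axis[i]),
            f_c2=float(lat.f2_axis[j]),
            height=float(vals[i, j]),
            index=(int(i), int(j)),
        )
        for i, j in idx
    ]
    peaks.sort(key=lambda p: -p.height)
    if min_separation > 0:
        kept: list[Peak] = []
        for p in peaks:
            if all(
                np.hypot(p.f_c1 - q.f_c1, p.f_c2 - q.f_c2) >= min_separation
                for q in kept
            ):
                kept.append(p)
        peaks = kept
    return peaks


def _index_to_hz(coords: np.ndarray, f1_axis: np.ndarray, f2_axis: np.ndarray) -> np.ndarray:
    """Map fractional (row, col) lattice coordinates to Hz by interpolation."""
    n1 = np.arange(f1_axis.size)
    n2 = np.arange(f2_axis.size)
    out = np.empty_like(coords)
    out[:, 0] = np.interp(coords[:, 0], n1, f1_axis)
    out[:, 1] = np.interp(coords[:, 1], n2, f2_axis)
    return out


def peak_contour(
    field: "WBSField | WBCField | PairLattice",
    peak: Peak,
    level: float = 0.5,
) -> Peak:
    """Level-set contour (marching squares) around a peak, with distances in Hz.

    Returns an enriched copy of ``peak`` with the contour at
    ``level * height``, and the mean and standard deviation of the
    Euclidean distances of the contour points from the peak position.
    An open contour (leaving the valid region) is truncated and flagged.
    """
    lat = as_lattice(field)
    vals = np.where(lat.mask, lat.values, 0.0)
    thr = level * peak.height
    contours = measure.find_contours(vals, thr)
    pi, pj = peak.index
    chosen = None
    truncated = False
    best_d = np.inf
    from matplotlib.path import Path

    for c in contours:
        closed = np.allclose(c[0], c[-1])
        if closed and Path(c).contains_point((pi, pj)):
            chosen = c
            truncated = False
            break
        # fall back: nearest contour (possibly open along the mask boundary)
        d = np.min(np.hypot(c[:, 0] - pi, c[:, 1] - pj))
        if d < best_d:
            best_d = d
            chosen = c
            truncated = not closed
    if chosen is None:
        raise ValueError("no contour found at the requested level")
    pts_hz = _index_to_hz(chosen, lat.f1_axis, lat.f2_axis)
    dists = np.hypot(pts_hz[:, 0] - peak.f_c1, pts_hz[:, 1] - peak.f_c2)
    return Peak(
        f_c1=peak.f_c1,
        f_c2=peak.f_c2,
        height=peak.height,
        index=peak.index,
        contour=pts_hz,
        mean_D=float(dists.mean()),
        std_D=float(dists.std()),
        truncated=truncated,
    )


def nonlinearity_index(inst: InstField) -> NLIProfile:
    """Grade each window's maximum coupling value and form the NLI ratios.

    The per-window statistic is the maximum instantaneous bicoherence
    amplitude over the principal region together with its argmax pair.
    """
    if inst.plan.n_windows < 1:
        raise ValueError("need at least one window")
    maxima, argmax = inst.window_max()
    levels = np.array([level_of(min(v, 1.0)) for v in maxima])
    counts = np.bincount(levels, minlength=5)
    ratios = {name: counts[k] / len(levels) for k, name in enumerate(NLI_LEVEL_NAMES)}
    series = pd.DataFrame(
        {
            "t": inst.plan.centres,
            "value": maxima,
            "level": [NLI_LEVEL_NAMES[l] for l in levels],
            "f1": inst.grid.f1[argmax],
            "f2": inst.grid.f2[argmax],
        }
    )
    return NLIProfile(ratios=ratios, level_series=series)


def wheeze_feature_vector(
    wbs: WBSField,
    wbc: WBCField,
    inst: InstField,
    min_height: float = 0.1,
    min_separation: float = 0.0,
    contour_level: float = 0.5,
    gp_source: str = "wbs",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the 13-scalar wheeze feature vector plus the LP trajectory.

    Global-peak features default to the WBS amplitude, whose maxima sit at
    the energetic coupling pairs; ``gp_source='wbc'`` switches to the
    normalised bicoherence (which saturates into a plateau for clean
    deterministic signals, making its argmax less localised). Both fields
    must come from the same signal. Returns ``(features, lp_trajectory)``.
    """
    prof = nonlinearity_index(inst)
    feats: dict[str, float] = {f"NLI_{k}": v for k, v in prof.ratios.items()}
    src = wbc if gp_source == "wbc" else wbs
    peaks = detect_peaks(src, min_height=min_height, min_separation=min_separation)
    if peaks:
        top = peak_contour(src, peaks[0], level=contour_level)
        feats.update(
            GP_height=top.height,
            f_c1=top.f_c1,
            f_c2=top.f_c2,
            meanD_GP=top.mean_D,
            stdD_GP=top.std_D,
        )
        feats["GP_missing"] = 0.0
    else:
        feats.update(
            GP_height=np.nan, f_c1=np.nan, f_c2=np.nan, meanD_GP=np.nan, stdD_GP=np.nan
        )
        feats["GP_missing"] = 1.0
    traj = prof.level_series
    k = int(np.argmax(traj["value"].to_numpy()))
    feats.update(
        LP_max=float(traj["value"].iloc[k]),
        LP_f1=float(traj["f1"].iloc[k]),
        LP_f2=float(traj["f2"].iloc[k]),
    )
    order = [
        "NLI_I", "NLI_II", "NLI_III", "NLI_IV", "NLI_V",
        "GP_height", "f_c1", "f_c2", "meanD_GP", "stdD_GP",
        "LP_max", "LP_f1", "LP_f2", "GP_missing",
    ]
    return pd.DataFrame([{k: feats[k] for k in order}]), traj
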