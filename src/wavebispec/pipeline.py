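"""End-to-end pipelines: CWT -> (I)WBS/(I)WBC -> feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .cwt import MorletParams, compute_cwt, make_scale_grid
from .instantaneous import instantaneous_wbc, instantaneous_wbs, make_window_plan
from .io import FeatureTable, config_hash
from .pain_features import (
    EEG_BANDS,
    apply_referencing,
    band_average,
    band_track,
    count_wbsamp_local_maxima,
    pain_endurance,
    relax_thresholds,
)
from .signal import Signal
from .wbs import build_bifreq_grid, wavelet_bicoherence, wavelet_bispectrum
from .wheeze_features import wheeze_feature_vector

__all__ = ["analyse", "wheeze_pipeline", "pain_pipeline"]


def analyse(signal: Signal, config: RunConfig):
    """Common front end: CWT, pair table, whole-interval and windowed fields."""
    params = MorletParams(f_b=config.f_b, f_c=config.f_c)
    grid = make_scale_grid(config.f_min, config.f_max, config.n_scales, signal.fs, params)
    cwt = compute_cwt(signal, grid, params)
    bifreq = build_bifreq_grid(grid, tolerance=config.tolerance)
    wbs = wavelet_bispectrum(cwt, bifreq, exclude_coi=config.exclude_coi)
    wbc = wavelet_bicoherence(wbs)
    plan = make_window_plan(signal, config.T, config.dT1)
    return cwt, bifreq, wbs, wbc, plan


def wheeze_pipeline(signal: Signal, config: RunConfig, signal_id: str = "signal") -> tuple[FeatureTable, pd.DataFrame]:
    """Whole wheeze feature system for one isolated wheeze episode."""
    cwt, bifreq, wbs, wbc, plan = analyse(signal, config)
    iwbc = instantaneous_wbc(cwt, bifreq, plan)
    feats, traj = wheeze_feature_vector(
        wbs, wbc, iwbc,
        min_height=config.min_height,
        min_separation=config.min_separation,
        contour_level=config.contour_level,
        gp_source=config.gp_source,
    )
    feats.insert(0, "signal", signal_id)
    meta = {"config_hash": config_hash(config.to_dict()), "seed": config.seed,
            "stage": "wheeze_features"}
    return FeatureTable(data=feats, metadata=meta), traj


def pain_pipeline(signal: Signal, config: RunConfig, signal_id: str = "trial",
                  relax_reference: Signal | None = None) -> tuple[FeatureTable, dict]:
    """Pain feature system for one event-marked trial (single channel).

    Band-averaged WBS amplitude / WBC per state (relax vs pain), the
    WBS-amplitude local-maxima count, optional referencing, and the
    pain-endurance result from the tracked band amplitude.
    """
    for name in ("click1", "trial_end"):
        if name not in signal.events:
            raise ValueError(f"pain pipeline needs event mark {name!r}")
    t_click1 = signal.events["click1"]
    t_end = signal.events["trial_end"]
    cwt, bifreq, wbs, wbc, plan = analyse(signal, config)
    rows = []
    for state, interval in (
        ("relax", (signal.t0, t_click1)),
        ("pain", (t_click1, t_end)),
    ):
        wbs_s = wavelet_bispectrum(cwt, bifreq, interval)
        wbc_s = wavelet_bicoherence(wbs_s)
        amp_avg = band_average(wbs_s)
        wbc_avg = band_average(wbc_s)
        lm = count_wbsamp_local_maxima(wbs_s)
        for band in EEG_BANDS:
            rows.append({
                "signal": signal_id, "state": state, "band": band,
                "WBSAmp": amp_avg[band], "WBC": wbc_avg[band], "WBSAmpLM": lm,
            })
    df = pd.DataFrame(rows)
    if config.referencing == "RS":
        refd = []
        for band in EEG_BANDS:
            sub = df[df["band"] == band].set_index("state")
            row = {"signal": signal_id, "state": "referenced", "band": band}
            for feat in ("WBSAmp", "WBC"):
                p_val = sub.loc["pain", feat]
                r_val = sub.loc["relax", feat]
                row[feat] = (
                    float("nan")
                    if not np.isfinite(p_val) or not np.isfinite(r_val)
                    else apply_referencing(p_val, r_val, "RS")
                )
            refd.append(row)
        df = pd.concat([df, pd.DataFrame(refd)], ignore_index=True)

    iwbs = instantaneous_wbs(cwt, bifreq, plan)
    centres, track = band_track(iwbs, config.band)
    relax_vals = track[centres < t_click1]
    thr_R, thr_P = relax_thresholds(relax_vals, config.n_sigma_R, config.n_sigma_P)
    pe = pain_endurance(centres, track, t_click1, t_end,
                        thr_P=thr_P, k_persist=config.k_persist)
    pe_doc = {"T_tol": pe.T_tol, "T_P": pe.T_P, "PE": pe.PE,
              "thr_P": pe.thr_P, "thr_R": thr_R,
              "crossing_time": pe.crossing_time}
    meta = {"config_hash": config_hash(config.to_dict()), "seed": config.seed,
            "stage": "pain_features"}
    return FeatureTable(data=df, metadata=meta), pe_doc
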