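"""Peak detection vs exhaustive scan, contour-distance statistics against
analytic Gaussian geometry, NLI level mapping, and the assembled feature
vector."""

import numpy as np
import pandas as pd
import pytest

from wavebispec import (
    PairLattice,
    RunConfig,
    detect_peaks,
    nonlinearity_index,
    peak_contour,
)
from wavebispec.instantaneous import InstField, WindowPlan
from wavebispec.pipeline import wheeze_pipeline
from wavebispec.synth import gen_wheeze_like
from wavebispec.wbs import BifreqGrid
from wavebispec.cwt import ScaleGrid


def gaussian_bump(ax1, ax2, c1, c2, s1, s2, height=1.0):
    g1 = np.exp(-((ax1 - c1) ** 2) / (2 * s1**2))
    g2 = np.exp(-((ax2 - c2) ** 2) / (2 * s2**2))
    return height * np.outer(g1, g2)


def exhaustive_peak_scan(values, mask):
    """Oracle: explicit loop over cells and their 8 neighbours."""
    out = []
    n1, n2 = values.shape
    for i in range(n1):
        for j in range(n2):
            if not mask[i, j]:
                continue
            v = values[i, j]
            is_max = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < n1 and 0 <= b < n2 and mask[a, b] and values[a, b] >= v:
                        is_max = False
            if is_max:
                out.append((i, j))
    return set(out)


class TestDetectPeaks:
    def test_two_separated_bumps(self):
        ax = np.arange(50.0, 650.0, 10.0)
        vals = gaussian_bump(ax, ax, 160, 160, 30, 30) + gaussian_bump(
            ax, ax, 160, 320, 30, 30, height=0.8
        )
        peaks = detect_peaks(PairLattice.full(vals, ax, ax), min_height=0.3)
        pos = {(p.f_c1, p.f_c2) for p in peaks}
        assert pos == {(160.0, 160.0), (160.0, 320.0)}
        assert peaks[0].height >= peaks[1].height

    def test_constant_field_has_no_strict_maximum(self):
        ax = np.arange(10.0, 100.0, 10.0)
        lat = PairLattice.full(np.full((ax.size, ax.size), 0.7), ax, ax)
        assert detect_peaks(lat) == []

    def test_matches_exhaustive_scan_on_random_fields(self, rng):
        ax = np.arange(32.0)
        for _ in range(20):
            vals = rng.random((32, 32))
            mask = rng.random((32, 32)) > 0.1
            lat = PairLattice(values=vals, f1_axis=ax, f2_axis=ax, mask=mask)
            got = {p.index for p in detect_peaks(lat, min_height=0.0)}
            assert got == exhaustive_peak_scan(vals, mask)

    def test_min_separation_prunes_greedily(self):
        ax = np.arange(0.0, 100.0, 10.0)
        vals = gaussian_bump(ax, ax, 30, 30, 8, 8) + gaussian_bump(
            ax, ax, 50, 30, 8, 8, height=0.9
        )
        all_peaks = detect_peaks(PairLattice.full(vals, ax, ax), min_height=0.1)
        pruned = detect_peaks(
            PairLattice.full(vals, ax, ax), min_height=0.1, min_separation=30.0
        )
        assert len(all_peaks) == 2 and len(pruned) == 1
        assert pruned[0].height == all_peaks[0].height


class TestPeakContour:
    def test_isotropic_bump_near_circular(self):
        ax = np.arange(0.0, 400.0, 4.0)
        vals = gaussian_bump(ax, ax, 200, 200, 40, 40)
        lat = PairLattice.full(vals, ax, ax)
        peak = detect_peaks(lat)[0]
        enr = peak_contour(lat, peak, level=0.5)
        assert enr.std_D / enr.mean_D <= 0.05
        # analytic half-height radius of a Gaussian: sigma*sqrt(2 ln 2)
        assert enr.mean_D == pytest.approx(40 * np.sqrt(2 * np.log(2)), rel=0.05)

    def test_anisotropic_bump_between_semi_axes(self):
        ax = np.arange(0.0, 400.0, 4.0)
        s1, s2 = 60.0, 30.0
        vals = gaussian_bump(ax, ax, 200, 200, s1, s2)
        lat = PairLattice.full(vals, ax, ax)
        enr = peak_contour(lat, detect_peaks(lat)[0], level=0.5)
        half = np.sqrt(2 * np.log(2))
        assert s2 * half < enr.mean_D < s1 * half
        assert enr.std_D > 0

    def test_single_cell_peak_contour(self):
        ax = np.arange(0.0, 50.0, 10.0)
        vals = np.zeros((5, 5))
        vals[2, 2] = 1.0
        lat = PairLattice.full(vals, ax, ax)
        enr = peak_contour(lat, detect_peaks(lat)[0], level=0.5)
        # marching squares crosses half way to the 4 zero neighbours
        assert enr.mean_D == pytest.approx(5.0)
        assert enr.std_D == pytest.approx(0.0, abs=1e-9)

    def test_contour_leaving_field_is_flagged(self):
        ax = np.arange(0.0, 100.0, 10.0)
        vals = gaussian_bump(ax, ax, 0, 50, 30, 30)  # centred on the edge
        lat = PairLattice.full(vals, ax, ax)
        peak = detect_peaks(lat)[0]
        enr = peak_contour(lat, peak, level=0.5)
        assert enr.truncated


def make_inst(maxima, f1=160.0, f2=160.0):
    """Minimal InstField whose per-window maxima are as given."""
    grid_sc = ScaleGrid.from_frequencies([f1, 2 * f1])
    bf = BifreqGrid(
        scale_grid=grid_sc,
        i1=np.array([0]),
        i2=np.array([0]),
        i_sum=np.array([1]),
        match_error=np.array([0.0]),
        tolerance=0.05,
    )
    centres = 0.5 + 0.5 * np.arange(len(maxima))
    plan = WindowPlan(T=1.0, dT1=0.5, centres=centres, T_total=len(maxima) * 0.5 + 0.5)
    vals = np.asarray(maxima, dtype=complex)[None, :]
    return InstField(values=vals, grid=bf, plan=plan, kind="wbc")


class TestNonlinearityIndex:
    def test_level_mapping_and_edges(self):
        prof = nonlinearity_index(make_inst([0.55]))
        assert prof.level_series["level"].iloc[0] == "III"
        # bin edges: half-open below, last closed
        for v, lev in [(0.0, "I"), (0.2, "II"), (0.4, "III"), (0.6, "IV"),
                       (0.8, "V"), (1.0, "V")]:
            assert nonlinearity_index(make_inst([v])).level_series["level"].iloc[0] == lev

    def test_uniform_spread(self):
        prof = nonlinearity_index(make_inst([0.1, 0.1, 0.3, 0.3, 0.5, 0.5,
                                             0.7, 0.7, 0.9, 0.9]))
        assert prof.ratios == {"I": 0.2, "II": 0.2, "III": 0.2, "IV": 0.2, "V": 0.2}
        assert sum(prof.ratios.values()) == pytest.approx(1.0, abs=1e-12)

    def test_ratios_sum_to_one_random(self, rng):
        for _ in range(20):
            prof = nonlinearity_index(make_inst(rng.uniform(0, 1, 17)))
            assert sum(prof.ratios.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(0 <= r <= 1 for r in prof.ratios.values())

    def test_ramped_coupling_spans_levels(self):
        ramp = np.linspace(0.05, 0.98, 20)
        prof = nonlinearity_index(make_inst(ramp))
        assert prof.ratios["I"] > 0 and prof.ratios["V"] > 0
        order = {"I": 0, "II": 1, "III": 2, "IV": 3, "V": 4}
        labels = [order[l] for l in prof.level_series["level"]]
        assert labels == sorted(labels)


@pytest.fixture(scope="module")
def harmonic_result():
    sig = gen_wheeze_like(duration=1.5, seed=4)
    cfg = RunConfig(T=0.5, dT1=0.25, n_scales=36)
    return wheeze_pipeline(sig, cfg)


class TestWheezeFeatureVector:
    def test_top_auto_coupling_gp_position(self, harmonic_result):
        table, _ = harmonic_result
        row = table.data.iloc[0]
        # noiseless 160/320/480 stack: dominant auto-coupling GP at (160, 160)
        auto = abs(row["f_c1"] - row["f_c2"]) < 1e-9
        near160 = abs(row["f_c1"] - 160.0) / 160.0 <= 0.06  # one log-grid step
        assert auto and near160
        assert row["GP_missing"] == 0.0

    def test_thirteen_named_features(self, harmonic_result):
        table, traj = harmonic_result
        expected = ["NLI_I", "NLI_II", "NLI_III", "NLI_IV", "NLI_V",
                    "GP_height", "f_c1", "f_c2", "meanD_GP", "stdD_GP",
                    "LP_max", "LP_f1", "LP_f2"]
        assert all(c in table.data.columns for c in expected)
        assert {"t", "value", "level", "f1", "f2"} <= set(traj.columns)

    def test_csv_round_trip(self, harmonic_result, tmp_path):
        table, _ = harmonic_result
        path = tmp_path / "features.csv"
        table.to_csv(path)
        from wavebispec import FeatureTable

        back = FeatureTable.from_csv(path)
        num = table.data.select_dtypes("number")
        pd.testing.assert_frame_equal(back.data[num.columns], num)
        assert back.metadata["config_hash"] == table.metadata["config_hash"]

    def test_monotone_in_coupling_strength(self):
        """Top-pair WBC never decreases as the coupled-component amplitude
        rises 0 -> 1 (fixed seed)."""
        from wavebispec import (
            build_bifreq_grid, compute_cwt, make_scale_grid,
            wavelet_bicoherence, wavelet_bispectrum,
        )
        from wavebispec.synth import QPCSpec, gen_qpc

        grid = None
        prev = -1.0
        for lam in np.linspace(0.0, 1.0, 9):
            sig = gen_qpc(QPCSpec(coupling=lam, phase_mode="locked",
                                  noise_sigma=0.1, seed=77))
            if grid is None:
                grid = make_scale_grid(100.0, 600.0, 24, sig.fs)
                bf = build_bifreq_grid(grid)
                p = bf.nearest_pair(160.0, 320.0)
            wbc = wavelet_bicoherence(wavelet_bispectrum(compute_cwt(sig, grid), bf))
            assert wbc.values[p] >= prev - 1e-9
            prev = wbc.values[p]
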