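# Methods

`wavebispec` implements third-order spectral analysis in the continuous-
wavelet domain: the wavelet bispectrum (WBS) and bicoherence (WBC), their
sliding-window "instantaneous" variants (IWBS/IWBC), a Fourier bispectrum
baseline, and two downstream feature systems (wheeze nonlinearity features
and EEG tonic-pain features). This note records the model, the numerical
choices, and what the synthetic test bed does and does not show.

## Estimators

**CWT.** The L2-normalised transform
`W(a, b) = a^{-1/2} ∫ x(t) ψ*((t−b)/a) dt` with the complex Morlet wavelet
`ψ(t) = (π f_b)^{-1/2} e^{2πi f_c t} e^{−t²/f_b}`. Scales are stored in
seconds with pseudo-frequency `f = f_c / a`; the default `f_c = 1`
realises the plain inverse-scale reading `f = 1/a`, and `f_b = 2` sets a
relative frequency resolution of about 22% — broad enough that the
discrete sum rule (below) is satisfiable on a log grid. The admissibility
correction for small centre frequencies is omitted (standard complex
Morlet); a warning is raised for `f_c < 0.8`. Discretisation is a Riemann
sum evaluated by FFT convolution per scale, with the Gaussian envelope
truncated at 6·√f_b scale units (envelope < 2.4e−16). Edges are
zero-padded and a cone of influence of one e-folding time `√f_b · a` per
edge is flagged, not deleted; bispectral integrals include flagged samples
unless told otherwise. The normalisation is the L2 convention `1/√a`
(the alternative `1/a` reading is a config-level change of `f_c` away,
since only products and ratios of coefficients enter the estimators).

**Fourier bispectrum / bicoherence** (baseline): direct segment-averaged
estimator, Hann taper, 50% overlap, per-segment mean removal;
`B(ω1,ω2) = E[X(ω1)X(ω2)X*(ω1+ω2)]` on the principal region
`Δ: ω2 ≤ ω1, ω1+ω2 ≤ Nyquist`, with
`b² = |B|² / (E|X1X2|² · E|X3|²)` so that `b ∈ [0,1]` by Cauchy–Schwarz
over segments. Sum bins map exactly (arithmetic bin grid). At least four
segments are required.

**Wavelet bispectrum.** On a scale grid, pairs `(f1, f2)` with `f1 ≤ f2`
(canonical order, lower frequency first — the bispectral product is
symmetric under swap) are retained when the grid frequency nearest
`f1 + f2` deviates by at most a relative tolerance (default 5%,
i.e. coupling "within the frequency resolution"). Per pair,
`WBS = ∫ W(a1,τ) W(a2,τ) W*(a,τ) dτ` by trapezoidal rule over the analysis
interval, with the two normalisation integrals `∫|W1W2|² dτ` and
`∫|W3|² dτ` accumulated alongside; `WBC = |WBS| / √(norm1 · norm2)` is
bounded by 1 exactly (weighted Cauchy–Schwarz), so any overshoot beyond
1 + 1e−9 is an error, smaller overshoot is clipped. Zero denominators give
0 with a flag. The summed WBC accumulates squared WBC per matched sum
frequency. The sum-scale factor is conjugated, per the Fourier analogy.

**Instantaneous variants.** Rectangular windows `[t0 − T/2, t0 + T/2]`
with hop ΔT1 (half-overlap at ΔT1 = 0.5 T, the EEG setting); each window
holds a whole-interval WBS/WBC. Amplitude/phase are modulus/argument of
the complex per-window value; zero-amplitude values carry phase 0 by
convention.

**A property worth remembering:** bicoherence measures *time constancy of
the biphase*, not a particular phase relation. Any deterministic,
stationary signal with fixed component phases saturates WBC near 1 at
every pair whose three scales carry energy — e.g. the pair (160, 160) of
a two-tone 160/320 Hz signal, whatever the phase of the 320 Hz tone.
Uncoupled *controls* therefore must decohere (randomised phase blocks) or
carry no deterministic energy at the sum scale. This is also why
whole-signal WBC fields of clean harmonic stacks form saturated plateaus:
global-peak *positions* are taken from the WBS amplitude by default,
which is energy-weighted and localised; the WBC-based alternative remains
available per config.

## Feature systems

**Wheeze features.** Global peaks: strict 8-neighbour local maxima on the
bifrequency lattice (≥ 10% of the field maximum by default, optional
greedy minimum-separation pruning). The contour of a peak is the marching-
squares level set at 50% of peak height (the defining level is nowhere
standardised; it is configurable), mapped to Hz; `mean(D)`/`std(D)` are
the mean and standard deviation of contour-point distances from the peak.
Local peaks: per-window maximum IWBC amplitude and its argmax pair. The
nonlinearity index grades each window into levels I–V on the bins
[0–0.2), [0.2–0.4), [0.4–0.6), [0.6–0.8), [0.8–1] (half-open, last
closed, so every value maps to exactly one level); `NLI_j` is the fraction
of windows at level j — windows are the time quantum, so duration ratios
are window-count ratios. The emitted vector has 13 scalars: `NLI_I..V`,
`GP_height`, `f_c1`, `f_c2`, `meanD_GP`, `stdD_GP`, and the LP-trajectory
summary `LP_max`, `LP_f1`, `LP_f2` (plus a missing-GP flag).

**Pain features.** Band averages over the canonical EEG rhythms (delta
1–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–49 Hz) use within-band
squares (`f1` and `f2` in the same band) intersected with Δ; note that
bands whose doubled lower edge exceeds the analysis ceiling (gamma under
a 49 Hz passband) have an empty intersection and are reported missing.
Referencing: `F = (P − R)/R`; asymmetries: `left − right` (DAs) and
`left / right` (RAs) over the seven symmetric pairs of the shipped
14-channel 10/20 montage (configuration data, not code). The WBS-amplitude
local-maxima count thresholds the field at its 75th percentile first.

**Pain endurance.** `T_P = t_end − t_click1`; the tracked quantity
(default: band-averaged IWBS amplitude in beta, per channel) is
calibrated on the relax period: `thr_P = mean − n_σP · sd`,
`thr_R = mean − n_σR · sd` (defaults 10 and 1). `T_tol` is the time from
click1 to the first window centre where the track enters and stays below
`thr_P` for ≥ k consecutive windows (default k = 3); `PE = T_tol / T_P`.
Two defaults deserve justification:

* **k = 3, not 2.** At hop ΔT1 = 0.5 T adjacent windows share half their
  samples, so a single noise excursion below threshold spans two
  consecutive windows; a persistence of two suppresses nothing. Three
  requires two sample-disjoint windows. `T_tol` is the start of the
  qualifying run, so the larger k adds no late bias.
* **n_σP = 10, not 2.** The relax sd is estimated from ~13 half-
  overlapping windows (≈ 7 effective dof) and the stationary track is
  not Gaussian: excursions to 5 estimated-sd occur routinely, while a
  genuine coupling collapse drops the track by two orders of magnitude
  (hundreds of sd). Ten sd sits an order of magnitude clear of both
  regimes. Both constants are configurable; the R/M/P state labelling
  keeps the conventional mean − 1 sd / mean − 2 sd pair available by
  passing explicit thresholds.

## Synthetic test bed

`gen_qpc` builds `cos(2πf1t+φ1) + cos(2πf2t+φ2) + λ·cos(2π(f1+f2)t+φ3)`
plus white Gaussian noise (σ relative to unit amplitude; real breath
sounds and EEG have coloured, non-stationary noise — the generators make
ground truth checkable, not physiology). Phase modes: `locked`
(φ3 = φ1+φ2), `independent` (φ3 redrawn per block), `mixed` (λ-weighted
phasor mix). `gen_intermittent` locks the phase only inside given
intervals. `gen_wheeze_like` stacks harmonics of a (possibly drifting)
160 Hz fundamental at fs = 5512 Hz, amplitudes 0.8^(k−1), and rejects
durations ≤ 150 ms (below the defining wheeze duration). `gen_pain_trial`
holds a locked beta-band triplet (14 + 16 → 30 Hz at fs = 128) at unit
coupling through the relax period and drops it to a 5% residual over a
1 s crossfade at `t_click1 + q · pain_s`, so the designed endurance
fraction q is recoverable to within one window hop.

**Decoherence block length.** Uncoupled regimes redraw φ3 blockwise with
10 ms crossfades. The decohered WBC over a window containing B blocks is
the modulus of a mean of B unit phasors: Rayleigh statistics give
p95 ≈ √(ln 20 / B) and P(WBC > 0.5) = e^(−B/4). Guaranteeing decoherence
inside a 1 s analysis window (p95 < 0.4, false-crossing rate < 1%)
therefore needs B ≥ ~20; the default block is 0.05 s. Tests that
deliberately use 0.25 s blocks over 2 s (B = 8) carry the matching
calibrated bound (p95 ≈ 0.61).

## Problem sizes and tolerances

Monte-Carlo checks run at the stated design points: 50 seeds for the
locked-vs-decohered detection levels (2 s at fs 5512, 40-scale grid
100–600 Hz), 25 seeds for onset localisation (6 s, 24 scales), 10 seeds
per endurance fraction q ∈ {0.2, 0.5, 0.8} (60 s trials at fs 128,
30 scales 4–45 Hz), 200 seeds for bicoherence bounds (0.35 s noise
snippets, 8 scales). Oracle-equivalence checks (vectorised estimator vs
explicit loop) demand 1e−10 relative agreement and achieve ~1e−15; the
bound on the loop sizes (4096 samples × 16 scales) keeps the pure-Python
oracles fast. The Gaussian-contour check compares the half-height contour
radius against the analytic `σ·√(2 ln 2)` within 5% (measured ~0.01%).

## Known limitations

* No statistical significance surface for WBC; surrogate thresholds
  appear only inside tests. Bicoherence saturation on deterministic
  stationary signals (above) means WBC alone cannot distinguish "locked
  by coupling" from "locked because nothing varies" without controls.
* Window-to-window values at 50% overlap are correlated; treat
  window-count statistics accordingly.
* Single-channel pipelines; multi-channel EEG is handled by running the
  pipeline per channel and combining features with the
  referencing/asymmetry transforms.
* EDF/BDF readers, wheeze segmentation from continuous recordings,
  classifier benchmarking, and inverse transforms are out of scope.
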