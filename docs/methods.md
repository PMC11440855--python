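# Methods

## Scope

`myoflow` quantifies myocardial blood flow (MBF) from dynamic cardiac SPECT
time–activity curves and reproduces the downstream clinical analysis:
semiquantitative 17-segment scoring, MINOCA/MICAD cohort comparison, and the
nonparametric statistical battery. Tomographic reconstruction, attenuation-map
handling, motion correction and gated functional analysis are out of scope —
the package starts from framed region curves and relative-uptake polar maps.

## Kinetic model

Dynamic acquisitions are re-binned into 20 frames (12 × 10 s, then 8 × 30 s;
camera start 10 s before injection). The acquisition itself is longer
(~610 s); the default schedule covers the first 360 s and both the frame
layout and the pre-injection offset are configurable.

The measured myocardial concentration follows the one-tissue compartment
model with a vascular/spillover fraction:

    C_meas(t) = (1 − fv) · K1 ∫₀ᵗ Ca(u) e^(−k2 (t−u)) du + fv · Ca(t)

with K1 (ml/min/g), k2 (1/min), fv ∈ [0, 0.8]. Frame times are in seconds;
the single per-minute → per-second conversion (1/60) is applied inside the
forward model only.

Two input representations are supported. A sampled arterial curve is treated
as frame-wise constant, for which the compartment ODE has an exact per-frame
solution (used by the fitter — fast and bias-free against curves produced the
same way). A continuous input model is integrated on a 5 ms grid with a
trapezoidal convolution; this path is validated against an independent RK4
discretization at 10 ms to a relative error below 1e−4.

**Arterial input function.** No parametric form is standard for a valve-plane
ROI curve, so the simulator uses a gamma-variate first pass, normalised so
its peak equals `amplitude` at `bolus_arrival + alpha·beta` seconds, plus a
recirculation tail `r·A·(1 − e^(−λt))` saturating at fraction r of the peak.
Defaults (amplitude 100 kBq/ml rest-scale, arrival 5 s, α = 3, β = 4 s,
r = 0.15, λ = 0.02/s) give a first-pass peak ~17 s after injection and a
near-flat late blood pool, typical of a compact intravenous bolus. Frame
averages are analytic (regularised incomplete gamma), checked against
10 000-point trapezoid quadrature.

**Fitting.** Weighted least squares over (K1, k2, fv) with bounds
K1 ∈ [0, 6], k2 ∈ [0, 5], fv ∈ [0, 0.8]; default weights proportional to
frame duration (longer frames collect proportionally more counts), uniform
weights available. Three fixed starting points span hypo- to hyper-perfusion;
ties resolve to the lowest residual, then the lowest K1, so fits are
deterministic. Non-convergence and all-zero inputs return flagged results
rather than raising. fv can be frozen (e.g. at 0) for software variants
without a spillover term.

## Flow conversion

First-pass extraction follows Renkin–Crone, E(F) = 1 − α e^(−β/F), with
K1 = F · E(F). dK1/dF = 1 − α e^(−β/F)(1 + β/F) ≥ 1 − α > 0, so K1(F) is
strictly increasing and inversion is a bracketed bisection on
[1e−6, 20] ml/min/g to 1e−8 absolute tolerance (round-trip error < 1e−6 over
the physiologic range). Two calibrated presets are shipped for
⁹⁹ᵐTc-sestamibi CZT quantification: AC (α = 0.879, β = 0.337) and NAC
(α = 0.814, β = 0.065). Myocardial flow reserve is MFR = stress/rest; flow
difference FD = stress − rest and may be negative.

## Segmental scoring

Relative uptake (percent of maximal myocardial uptake) over the 17 AHA
segments is banded into 5-point scores with descending cut-points, default
(70, 50, 30, 10)% — the conventional clinical banding; the publication this
emulates does not print its thresholds, so they are configurable. Segment →
territory assignment defaults to the standard AHA mapping (LAD: 1, 2, 7, 8,
13, 14, 17; RCA: 3, 4, 9, 10, 15; LCx: 5, 6, 11, 12, 16), apex to LAD, also
configurable. SSS/SRS are sums over stress/rest scores (range 0–68),
SDS = SSS − SRS, and a study is "abnormal" iff SSS > 3 (strict).

## Cohort analysis

MICAD requires stenosis ≥ 50% (inclusive) in at least one of LAD, LCx, RCA,
LM; otherwise MINOCA. A vessel territory is "injured" iff CMR shows both
late gadolinium enhancement and edema. All group comparisons use the
two-sided Mann–Whitney U test (exact enumeration when combined n ≤ 20 with
no ties, else normal approximation with midrank-tie and continuity
corrections — the behaviour of common statistical packages at these sample
sizes); correlations are Spearman with midrank ties and a t-approximation
p-value; categorical tables use the two-sided Fisher exact test (sum of
hypergeometric probabilities ≤ the observed table's). Summaries are median
(Q25; Q75) with type-7 linear interpolation. No multiple-testing correction
is applied, matching the emulated analysis.

## Synthetic cohorts — what the generator states, and what a green test means

The generator's defaults are the published study conditions: 10 MINOCA and
21 MICAD patients; per-group, per-state global flows drawn from log-normal
marginals calibrated so the median matches the printed group median exactly
and the IQR *width* matches via σ = asinh((Q75−Q25)/(2·median))/z₀.₇₅ (when
Q25 = 0 the fit falls back to the Q75/median ratio; a zero median is a
degenerate all-zero marginal, e.g. MVO in MINOCA). AC and NAC flows are two
marginal transforms of one latent — perfectly rank-correlated measurement
variants of the same physiology.

Territory flows share the patient's global latent with exchangeable
correlation 0.3 (no within-patient correlation is published; 0.3 is a
moderate, configurable default). Territories flagged injured — Bernoulli
with group rates 5/30 (MINOCA) and 34/63 (MICAD) — have stress flow
multiplied by the injured/non-injured median ratio 0.98/1.33 ≈ 0.74; rest
flow is left unscaled (the published rest difference is non-significant).

Serial troponin I (24 h, day 4, day 7; log-normal per group and time point,
decaying medians) and CMR burden (infarct size, MVO, edema, % of LV) are
tied to the patient's stress-flow latent through a Gaussian copula with
correlation 2 sin(πρ/6) for target Spearman ρ (troponin default −0.4; CMR
defaults −0.77/−0.53/−0.70). Because the measured global stress MBF is an
exact monotone transform of the same latent, the target rank correlation is
preserved without attenuation.

Polar maps are derived from territory flows as percent-of-maximum ratios
with 6% per-segment Gaussian jitter. Relative-uptake imaging cannot encode a
globally reduced flow, so generated summed scores separate the groups more
weakly than the published scores do — a real limitation of relative SPECT
that the simulation shares, and the reason score medians are not a
calibration target.

Dynamic studies: K1 from true MBF through the chosen Renkin–Crone preset;
k2 ~ U(0.1, 0.5)/min, fv ~ U(0.05, 0.2); stress input amplitude 3× rest
(9 vs 3 MBq/kg injected dose). Frame noise is a scaled-Gaussian surrogate
for Poisson counting: the relative standard deviation of each frame is
1/√(expected counts), where `count_scale` (default 5 × 10⁴) is the expected
count of a 10-s frame at the curve's peak. Tissue curves are driven by the
noiseless frame-averaged input so the generator and the fitter share one
forward model; projection-domain effects, motion and reconstruction bias are
*not* simulated. A green recovery test therefore establishes statistical
identifiability of the pipeline under counting noise, not robustness to
reconstruction artifacts.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical cohorts,
curves and fits.

## Numerical choices

- Bisection tolerance 1e−8 (flow), optimizer xtol/ftol 1e−12, so fit results
  are reproducible to machine-level across runs.
- Exponent k2·t ≤ 30 over the default schedule bounds keeps the
  convolution-by-exponential-weights path overflow-free.
- Degenerate analysis inputs (a group with < 2 patients, constant vectors,
  no injured territories) skip the affected comparison with a recorded
  warning; count summaries are always emitted.

## Known limitations

- The input function is a stand-in; real valve-plane ROI curves carry
  spill-in from myocardium that is not modelled.
- The 360 s default truncates the published 610 s acquisition (the paper
  trail does not say how late frames were handled); longer schedules are a
  constructor argument away.
- Whether the reference clinical software fits a spillover term is unknown;
  fv is fitted by default and can be fixed to 0.
- Group-level p-values of the original patient tables are not reproducible
  (no raw data); only calibration targets and count arithmetic are.
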