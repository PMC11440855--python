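# myoflow

Quantitative dynamic-SPECT myocardial blood-flow analysis for acute
myocardial infarction cohorts.

Patients with acute MI and *non-obstructive* coronary arteries (MINOCA,
stenosis < 50% everywhere) can show near-normal perfusion on conventional
relative SPECT images even when flow is impaired. Dynamic CZT SPECT measures
absolute myocardial blood flow (MBF, ml/min/g) at rest and under adenosine
stress, from which myocardial flow reserve (MFR = stress/rest) and flow
difference (FD = stress − rest) follow. `myoflow` implements that
quantification chain as a reusable, tested library and CLI for researchers
who want to simulate, fit and statistically analyse such studies without
access to scanner data:

- **Kinetics** — frame schedules (default 12 × 10 s + 8 × 30 s), a
  gamma-variate arterial input simulator, the one-tissue compartment model
  `C(t) = (1−fv)·K1·∫ Ca(u) e^(−k2(t−u)) du + fv·Ca(t)`, and a
  deterministic bounded multi-start least-squares fitter for (K1, k2, fv).
- **Flow conversion** — the Renkin–Crone extraction model
  `E(F) = 1 − α e^(−β/F)`, `K1 = F·E(F)`, with calibrated AC/NAC presets for
  ⁹⁹ᵐTc-sestamibi and guaranteed-monotone bisection inversion K1 → MBF.
- **Scoring** — 17-segment AHA polar-map banding into 5-point scores,
  SSS/SRS/SDS, SSS > 3 abnormality, territory aggregation (LAD/LCx/RCA).
- **Cohort analysis** — MINOCA/MICAD classification (≥ 50% stenosis,
  inclusive), CMR injury calls (LGE + edema), vessel/territory count
  summaries, and the nonparametric battery (Mann–Whitney U, Spearman,
  Fisher exact, median/IQR).
- **Synthetic cohorts** — seeded generators calibrated to published
  group-level medians/IQRs, with Gaussian-copula rank correlations between
  flow, serial troponin I and CMR burden, and scaled-Poisson dynamic-curve
  noise, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
import myoflow as mf

# simulate a stress acquisition at a known uptake rate and fit it back
sched = mf.default_frame_schedule()                      # 20 frames, 360 s
inp   = mf.simulate_input_function(mf.InputFunctionModel(amplitude=120.0), sched)
true  = mf.OneTissueParams(K1=0.424, k2=0.25, fv=0.12)   # K1 of ~2 ml/min/g flow
tac   = mf.add_frame_noise(mf.forward_tac(inp, true, sched),
                           count_scale=5e4, rng=np.random.default_rng(0))

fit = mf.fit_1tcm(tac, inp)
mbf = mf.flow_from_k1(fit.params.K1, mf.NAC)
print(f"fitted K1 = {fit.params.K1:.3f} ml/min/g (true 0.424)")
print(f"stress MBF (NAC) = {mbf:.2f} ml/min/g")
print(f"MFR = {mf.compute_flow_metrics(0.68, mbf).mfr:.2f}")
```

prints

```
fitted K1 = 0.422 ml/min/g (true 0.424)
stress MBF (NAC) = 1.99 ml/min/g
MFR = 2.93
```

— the fitted uptake rate matches the simulated truth to 0.5%, and inverting
the NAC Renkin–Crone preset recovers a hyperaemic flow of ~2 ml/min/g, a
normal stress MBF (obstructive-CAD territories typically sit below
1 ml/min/g).

Cohort level:

```python
patients, truths = mf.generate_cohort(seed=1)            # 10 MINOCA + 21 MICAD
report = mf.run_study_analysis(patients, variant="NAC")
```

yields group comparisons such as `stress MBF: MINOCA 2.01 vs MICAD 0.88
ml/min/g, p = 1e-05` and `stress MBF ~ troponin(24 h): rho = -0.48,
p = 0.0068` — lower hyperaemic flow in obstructive disease, and higher
necrosis-marker levels where flow is worse, with 93 territories tallied
(3 per patient) in the counts section.

The same steps are available from a shell:

```bash
myoflow simulate --seed 7 --out run/          # cohort.csv, truth.json, tacs/
myoflow fit --tac run/tacs/P001_stress.csv --out fits.json
myoflow analyze --cohort run/cohort.csv --out report.json
myoflow report --report report.json
```

## Acceptance script

`scripts/acceptance.py` re-runs the full simulate → fit → invert pipeline
from scratch: it generates 200 seeded cohorts at the default calibration,
fits the one-tissue model to every patient's global stress curve at the
default noise level, converts fitted K1 to MBF through the NAC preset and
reports the per-group median fitted stress MBF:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is roughly 1.5 minutes on one CPU.

## Layout

```
src/myoflow/     frames, kinetics, flowmodel, scoring, stats, cohort,
                 synthesis, io, cli
tests/           pytest suite (property tests via hypothesis, enumeration
                 oracles for the exact statistics, acceptance criteria)
docs/methods.md  model assumptions, calibration details, limitations
```
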