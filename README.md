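# lassa

Heart-rate extraction from remote photoplethysmography (rPPG) traces by
**l**ow-rank and **a**utocorrelation screened **s**ingular **s**pectrum
**a**nalysis.

A camera pointed at a face records a tiny periodic color change driven by
the blood-volume pulse, buried under illumination drift, motion artifacts
and sensor noise. `lassa` takes the spatially averaged green-channel trace
of the facial skin region (or raw frames plus a skin mask) and returns a
denoised pulse signal and a per-window heart-rate series with agreement
metrics against a reference PPG.

## Method

Per 30 s analysis window (stepped by 1 s) on a trace x(n) sampled at
*fps* Hz:

1. Preprocess: smoothness-prior detrend (trend = (I + λ²D₂ᵀD₂)⁻¹x),
   z-score normalization, 5-point moving average, then EEMD (noise std
   0.05, 100 ensembles) keeping the intrinsic mode whose spectrum peaks
   highest in the heart-rate band 0.7–3 Hz.
2. Embed as the L × K Hankel trajectory matrix **X** (L = 3 s of samples,
   K = N − L + 1) and decompose by SVD: **X** = Σᵢ λᵢuᵢvᵢᵀ.
3. Globally prune: split **X** = **A** + **E** by the exact augmented
   Lagrange multiplier algorithm for min ‖A‖★ + η‖E‖₁ s.t. X = A + E; keep
   the first s = rank(**A**) components.
4. Locally screen: each component series zᵢ (anti-diagonal averaging) gets
   a periodicity score ρᵢ = max interior peak of its normalized
   autocorrelation P(k); components with ρᵢ > 0.85 survive.
5. Reconstruct x_rc = Σ wᵢzᵢ with weights wᵢ ∝ λᵢ, and read HR as 60 × the
   in-band FFT magnitude peak.

Evaluation reports MAE, RMSE, Pearson r and Bland–Altman mean difference
with ±1.96 σ limits of agreement. See `docs/methods.md` for assumptions,
parameter defaults and limitations.

## Worked example

```python
import numpy as np
from lassa import (PulseSimConfig, simulate_pulse_trace, run_lassa,
                   LassaConfig, evaluate, HRSeries)

cfg = PulseSimConfig(duration_s=90.0, fps=30.0,
                     hr_bpm=[(0.0, 66.0), (90.0, 78.0)],   # rising schedule
                     artifact_rate=6.0, noise_sigma=0.3, seed=42)
sim = simulate_pulse_trace(cfg)
res = run_lassa(sim.trace, LassaConfig(), seed=42)
print("windows:", len(res.hr))
print("first five HR estimates (bpm):", np.round(res.hr.hr_bpm[:5], 2))

truth = HRSeries(res.hr.times,
                 np.interp(res.hr.times, sim.trace.times, sim.hr_bpm),
                 [""] * len(res.hr))
rep = evaluate(res.hr, truth)
print("MAE %.3f bpm  RMSE %.3f bpm  r %.3f" % (rep.mae_bpm, rep.rmse_bpm, rep.pearson_r))
print("Bland-Altman mean %.3f bpm, LoA [%.3f, %.3f]" % rep.bland_altman)
```

prints

```
windows: 61
first five HR estimates (bpm): [67.9  68.12 68.33 68.33 68.55]
MAE 0.127 bpm  RMSE 0.159 bpm  r 0.998
Bland-Altman mean 0.002 bpm, LoA [-0.312, 0.316]
```

The 61 windows are the 30 s analyses stepped at 1 s through the 90 s trace;
each estimate tracks the rising schedule to ~0.1 bpm (the padded-FFT grid is
~0.22 bpm), the correlation with the true schedule is 0.998, and the
Bland–Altman limits say 95% of window estimates fall within ±0.3 bpm of
truth on this trace.

The same pipeline is available from the shell:

```sh
lassa simulate --preset noisy --duration 120 --seed 11 --out trace.csv
lassa run --trace trace.csv --out results/ --seed 11
lassa eval results/hr.csv reference_hr.csv
```

`lassa run` writes `hr.csv` (time, hr_bpm, flags), `report.json`, and
per-window component score CSVs under `components/`.

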