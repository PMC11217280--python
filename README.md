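# lumifrontal

Analysis of light-intensity encoding in extracellularly recorded neurons of
the medial prefrontal cortex (mPFC) and the perihabenular thalamus (PHb).

Although the mPFC receives no direct retinal input, a subset of its neurons
changes firing rate with ambient light, via intrinsically photosensitive
retinal ganglion cells (ipRGCs) and the PHb. This package implements the
full analysis chain used to characterise that photosensitivity from spike
trains recorded during light-step and light-ramp stimulation, together with
a synthetic spike-train generator so that every stage runs — and is tested —
without access to recording hardware or animals.

The chain:

1. **PSTHs and analysis windows** — spikes binned at 100 ms over
   [−4, +16] s around each 10 s light pulse; baseline FR₀ (3 s pre-onset),
   early FR₁ (first 1 s) and steady-state FR₂ (last 6 s) window rates.
2. **Light-responsiveness** — paired two-sided permutation t-tests of
   FR₀ vs FR₁ (transient) and FR₀ vs FR₂ (persistent), pooling the three
   highest intensities (≤ 60 rep-level pairs) after removal of up to three
   scaled-MAD outlier responses per intensity.
3. **Intensity encoding** — the steady-state intensity-response curve is
   fitted with the Naka–Rushton sigmoid of log intensity *E*
   (log photons cm⁻² s⁻¹):

   R(E) = R_max · 10^(nE) / (10^(nE) + 10^(nK))

   A unit is *intensity-encoding* when the RMSE of its fit is strictly
   below the 5th percentile of a null distribution built from 100 refits of
   the responses shuffled along the intensity axis. Threshold intensity
   (FR criterion 0.1 Hz) and dynamic range follow in closed form.
4. **Functional typing** — PCA on baseline-subtracted mean PSTHs at the
   highest intensity (0.2 s bins, ≥ 85 % variance retained) followed by
   Gaussian-mixture clustering with AIC model selection, yielding the four
   canonical types E_on-off, S_on-off, E_on, S_on.
5. **Cell class** — fast-spiking vs regular-spiking classification from
   four waveform metrics (min–max normalised, PCA ≥ 95 %, Ward clustering).
6. **Dynamics** — ON-peak and late-response latencies, decay time, percent
   modulation M = 100·(FR − FR₀)/FR₀, and ramp-tracking analysis
   (phase-wise sigmoid fits, transition lag, hysteresis test).
7. **Anatomy** — total-least-squares probe-track fit, nearest-site unit
   localisation, and Monte-Carlo affiliation probabilities under the
   anisotropic mapping uncertainty (SDs 32/85/39 µm), plus incidence
   statistics per session and pooled per subregion/layer.
8. **Statistics** — permutation t-tests (paired and independent),
   permutation ANOVA, tmax multiple-comparison correction, χ² with
   φ/Cramér's V, Cohen's d.
9. **Photometry** — Govardovskii-nomogram pigment templates, quantum
   catches, photoisomerization rates.

## Worked example

```python
import numpy as np
from lumifrontal import (IntensityResponseModel, build_psth, window_rates,
                         make_step_protocol, simulate_unit, DEFAULT_ARCHETYPES)

protocol = make_step_protocol([9.4, 10.4, 11.4, 12.4, 13.4, 14.4, 15.4], n_reps=20)
train = simulate_unit(DEFAULT_ARCHETYPES["E_on"], protocol, seed=42)
rates = {e: window_rates(p) for e, p in build_psth(train, protocol).items()}

result = IntensityResponseModel.from_window_rates(rates).fit()
print(result.summary())
print("intensity-encoding:", result.encoding_test(seed=0).encoding_flag)
```

prints

```
Naka-Rushton intensity-response fit
===============================================
n points                                      7
direction                         enhanced (+1)
converged                                  True
RMSE (spikes/s)                          0.1434
-----------------------------------------------
param               estimate           std err
Rmax                  7.9771            0.2251
n                     1.0992            0.1193
K                    13.6741            0.0533
-----------------------------------------------
threshold @0.1 Hz                        11.949
dynamic range                  [12.806, 14.542]
intensity-encoding: True
```

The fitted maximum response (≈ 8.0 spikes/s), slope and semi-saturation
(≈ 13.7 log photons cm⁻² s⁻¹) recover the generating archetype's
parameters (R_max = 8, n = 1.2, K = 13.6); the RMSE is far below the
shuffle null, so the unit is flagged intensity-encoding; the threshold is
the intensity at which the fitted curve reaches 0.1 spikes/s.

The whole pipeline (simulate → PSTH → responsiveness → encoding → typing →
cell class → dynamics → mapping → report) runs as

```sh
lumifrontal run --out run_out --seed 1
```

or from Python through `lumifrontal.pipeline.run_pipeline`.

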