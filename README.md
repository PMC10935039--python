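# ocuclean

Ocular-artifact removal for single-channel sleep EEG.

Blinks and eye movements leak large, slow electrooculographic (EOG)
potentials into scalp EEG. Multi-channel recordings can be cleaned with
blind source separation directly, but portable sleep monitors often record
a single channel, where source separation is under-determined. `ocuclean`
implements a single-channel pipeline that manufactures the missing
channels by signal decomposition:

1. **Detection** — the recording is cut into 10 s windows and an RBF-SVM,
   fed with time-domain (skewness, kurtosis, Hjorth parameters), spectral
   (Welch band powers) and nonlinear (entropies, fractal dimension,
   Lempel–Ziv, Hurst) features ranked by mRMR, flags the contaminated
   windows. Clean windows are never touched.
2. **VMD** — each flagged window x(t) is decomposed into k band-limited
   modes u_k(t) with center frequencies ω_k by minimizing the summed
   analytic-signal bandwidths subject to Σ_k u_k ≈ x (frequency-domain
   ADMM). The hyperparameters (k, α) can be tuned per window by a genetic
   algorithm whose fitness is the minimum approximate entropy over modes;
   the defaults are (k, α) = (4, 120) with k ∈ [2, 10], α ∈ [100, 5000].
3. **SOBI** — the k modes are stacked as a k-channel observation X = AS
   and separated by second-order blind identification: whitening followed
   by joint approximate diagonalization (Jacobi rotations) of time-lagged
   covariance matrices E[W(t+ρ)Wᵀ(t)], ρ = 1…20 samples.
4. **ApEn rejection** — each source is scored with approximate entropy
   (m = 2, r = 0.15·SD, Chebyshev distance, self-matches included).
   Ocular components are smooth and regular, so sources with ApEn < 0.4
   are zeroed; the rest are projected back through Â and the cleaned
   modes are summed (inverse VMD) into the cleaned window.

A synthetic-data module generates surrogate clean EEG (band-structured
noise, alpha-dominant), surrogate EOG (Poisson blink trains over a slow
drift) and semi-simulated mixtures `X_mix = X_pure + θ·X_EOG` with
`SNR = RMS(X_pure)/RMS(θ·X_EOG)` controlled exactly, so every stage can be
validated against ground truth. Denoising quality is measured by CC,
RRMSE, MSE and PSNR against the pure signal, by band-wise power change
ΔP = P_in − P_out when no ground truth exists, and by standard multi-class
staging scores (precision/recall/F1, ACC, MF1, WF1) for downstream
sleep-staging evaluation.

## Worked example

```python
import numpy as np
from ocuclean import (PipelineConfig, Segment, denoise_segment,
                      gen_eog, gen_pure_eeg, mix, sim_metrics)

fs = 200.0
pure = gen_pure_eeg(10, fs, seed=1)          # surrogate clean EEG, unit SD
eog = gen_eog(10, fs, seed=2)                # blinks + slow drift
mixture, spec = mix(pure, eog, snr=1.0)      # theta chosen so RMS SNR = 1.0

cleaned, record = denoise_segment(Segment(mixture, fs=fs), PipelineConfig())

before = sim_metrics(pure, mixture)
after = sim_metrics(pure, cleaned.samples)
print(f"theta = {spec.theta:.4f}")
print(f"mode center frequencies (Hz): {np.round(record['omegas_hz'], 1)}")
print(f"source ApEn values: {np.round(record['apen_values'], 3)}")
print(f"rejected components: {record['rejected']}")
print(f"CC    before/after: {before.cc:.3f} / {after.cc:.3f}")
print(f"RRMSE before/after: {before.rrmse:.3f} / {after.rrmse:.3f}")
```

Output:

```
theta = 0.9799
mode center frequencies (Hz): [ 0.9 10.  17.8 25.9]
source ApEn values: [0.226 0.623 0.56  0.594]
rejected components: [0]
CC    before/after: 0.706 / 0.907
RRMSE before/after: 1.000 / 0.426
```

The EOG energy lands in the lowest-frequency source (ApEn 0.23, below the
0.4 threshold), which is rejected; the three EEG-like sources (ApEn > 0.5)
are kept. Cleaning raises the correlation with the hidden pure EEG from
0.71 to 0.91 and cuts the relative error from 1.00 to 0.43.

## Command line

```bash
ocuclean simulate --out corpus/ --n-per-class 100 --seed 0
ocuclean train --corpus corpus/ --out model.joblib
ocuclean denoise rec.edf --model model.joblib --out clean.csv --report report.json
ocuclean evaluate --snrs 0.5,1.0,2.0 --n 50 --out sweep.csv
ocuclean apen x.csv --fs 200          # stage-level inspection
ocuclean vmd  x.csv --fs 200 --k 4 --alpha 120 --out modes.csv
ocuclean sobi modes.csv --fs 200 --out sources.csv
```

EDF and delimited text are accepted as input (text needs `--fs`); cleaned
output is written as CSV plus a JSON report recording, per window, the
classifier label, the (k, α) used, per-source ApEn values and the rejected
components.

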