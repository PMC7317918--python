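# cardiocoh

Wavelet time–frequency analysis of cardiorespiratory dynamics under hypoxia:
instantaneous heart and respiration rates from ECG and respiratory-effort
recordings, wavelet phase coherence with IAAFT-surrogate significance, and a
modulation-band coherence statistic that quantifies periodic breathing (PB),
compared across exposure conditions and genotype groups.

## Who this is for

Physiologists and biomedical-signal analysts working with simultaneous
ECG / respiration / laser-Doppler flowmetry (LDF) recordings who want a
scripted, reproducible version of the classic oscillatory-dynamics workflow:
continuous wavelet transforms on a logarithmic frequency grid, ridge-based
instantaneous rates, phase-coherence spectra with surrogate thresholds, and
nonparametric group comparisons. A synthetic cohort generator with the same
statistical structure (PB-modulated respiration, RSA- and PB-modulated heart
rate, multi-band LDF, genotype-dependent PB depth) makes every stage testable
without access to clinical data.

## The method

For a uniformly sampled signal g(u), the analytic continuous wavelet
transform on a log-spaced grid f_k (32 voices/octave over 0.005–2 Hz) gives
complex coefficients W(f_k, t_n) with amplitude and phase. The default
mother wavelet is lognormal — a frequency-domain Gaussian in log f with
resolution parameter f0 = 1 — with the complex Morlet as an alternative.
Edge-contaminated coefficients inside the cone of influence (COI, the
e-folding time of the wavelet envelope at each frequency) are excluded from
every time average.

* **Instantaneous rates.** The heart rate is the ridge of |W| through the
  0.5–2 Hz band of the ECG transform (respiration rate: 0.145–0.6 Hz),
  solved globally by dynamic programming with a quadratic log-frequency jump
  penalty, refined by quadratic interpolation. An independent R–R-interval
  estimator (inverse time between detected R peaks) cross-checks the ridge.
* **Phase coherence.** For two signals with wavelet phases Φ1, Φ2,
  ΔΦ_{k,n} = Φ2 − Φ1 and

  C_Φ(f_k) = sqrt( ⟨cos ΔΦ⟩² + ⟨sin ΔΦ⟩² ),

  the length of the time-averaged unit phasor: 1 for a constant phase
  relation, → 0 for drifting phases.
* **Surrogate significance.** Because few low-frequency cycles inflate
  coherence, each spectrum is compared with the 95th percentile of 100 IAAFT
  surrogates (exact value distribution, approximate amplitude spectrum,
  phase relations destroyed); reported coherence has that threshold
  subtracted.
* **Periodic breathing.** PB appears as amplitude-modulated respiration near
  0.058 Hz; the mean adjusted coherence between the instantaneous heart rate
  and respiration over the 0.03–0.15 Hz *modulation band* is the per-subject
  PB statistic.
* **Group comparisons.** Kruskal–Wallis across conditions (normoxia,
  acute/sustained normobaric and hypobaric hypoxia) or genotype groups
  (e.g. NOTCH4 GG/GA/AA, CAT CC/CT/TT), with pairwise Wilcoxon rank-sum
  follow-up only when the omnibus test is significant at α = 0.05, and no
  multiplicity correction (the number of tests run is reported).

## Worked example

```python
import numpy as np
from cardiocoh import (SyntheticConfig, WaveletParams, band_mean, cwt,
                       generate_heart, generate_respiration,
                       phase_coherence, coherence_threshold, apply_threshold)

cfg = SyntheticConfig(duration_s=600, fs=4, seed=7)   # hypoxic profile
resp = generate_respiration(cfg)
ihr, ecg = generate_heart(cfg)

params = WaveletParams(fmin=0.02, fmax=0.6)
coh = phase_coherence(cwt(ihr, params), cwt(resp, params))
thr = coherence_threshold(ihr, resp, params, n=100, seed=11)
adj = apply_threshold(coh, thr)

k = coh.nearest_freq_index(cfg.f_mod)
print(f"raw coherence at {coh.freqs[k]:.3f} Hz: {coh.raw_coh[k]:.3f}")
print(f"band mean (0.03-0.15 Hz), threshold-subtracted: "
      f"{band_mean(adj, 0.03, 0.15):.3f}")
print(f"phase difference at f_mod: {coh.phase_diff[k]:+.3f} rad")
```

prints

```
raw coherence at 0.058 Hz: 0.999
band mean (0.03-0.15 Hz), threshold-subtracted: 0.068
phase difference at f_mod: +0.506 rad
```

The raw coherence near 1 at the PB frequency says the heart rate and the
respiration envelope are phase-locked there; the positive band mean after
threshold subtraction marks that locking as significant relative to the
IAAFT null; and the +0.5 rad phase difference recovers the lag imposed by
the generator (positive = respiration leads, the package's pinned
convention).

The same chain runs from a shell over a whole cohort:

```bash
cardiocoh simulate -c cfg.yaml -o cohort/
cardiocoh analyze  -c cfg.yaml -i cohort/ -o results/
cardiocoh report   -i results/
```

producing per-subject rate summaries, normalised group-mean power spectra,
coherence and phase-difference spectra, modulation-band tables, condition
and genotype test tables, and a JSON manifest that reproduces the run
bit-exactly from its seed.

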