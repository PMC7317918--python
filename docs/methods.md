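# Methods

This note records the models, parameters and numerical decisions behind
`cardiocoh`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## Continuous wavelet transform

The transform is an analytic constant-relative-bandwidth filter bank
evaluated by FFT. For each grid frequency f_k the frequency-domain window
is, with resolution parameter f0 (default 1):

* lognormal (default): `exp(-(2π f0 ln(f/f_k))² / 2)` for f > 0, zero
  otherwise — a Gaussian in log-frequency, the natural window on a
  logarithmic grid;
* Morlet: `exp(-(2π f0)² (f/f_k - 1)² / 2)` for f > 0 — a Gaussian in
  linear frequency.

Both dialects are implemented because the analysis protocol being
reproduced names the Morlet in its general description but ran its
computations with a lognormal default; lognormal is therefore the package
default.

**Normalisation.** Coefficients carry the 1/s scale normalisation of the
transform integral, making each filter a unit-gain bandpass: a unit
sine yields |W| = 1 on its ridge at any frequency. The alternative
1/sqrt(s) (L2) convention multiplies power by f0/f_k; that scale gain tilts
broad spectral features and was measured to displace the location of
smoothed peaks by more than one grid step, so the unit-gain convention is
used. Consequences worth knowing: white noise has time-averaged wavelet
power proportional to f_k (the filter bandwidth grows with frequency), not
flat; wavelet phases — and hence all coherence quantities — are identical
under either convention.

**Grid.** 32 voices per octave over [fmin, fmax] (pipeline default
0.005–2 Hz): a 2.19% spacing, fine enough that "within one grid step"
statements about peak positions are meaningful.

**Edges.** Records are zero-padded to a power of two at least
n + 2·τ(fmin)·fs samples long, where τ(f) is the e-folding time of the
wavelet's temporal envelope (computed numerically once per wavelet/f0 and
scaled as 1/f). The cone of influence marks |t − nearest edge| < τ(f_k);
COI coefficients are excluded from every time average rather than patched.
Note the COI boundary is where edge contamination has decayed to 1/e, not
to zero — comparisons demanding near-exact values (e.g. time-shift
covariance) hold at ~2 COI widths from the edge.

**Pre-processing** (on by default, matching the reproduced protocol):
subtract a cubic least-squares trend, then zero Fourier components outside
[fmin, fmax]. Records shorter than 3 cycles of fmin are rejected.

## Ridge extraction

The instantaneous rate in a band is the grid path k_t maximising
`Σ_t log|W(k_t,t)| − λ (Δ log2 f)²`, solved exactly by dynamic programming;
λ defaults to 10 per octave² per time step. The stiff default is
deliberate: on pulse-train-like signals (ECG) the second harmonic can carry
comparable amplitude for stretches, and at looser penalties (e.g. 2) the
path profitably jumps a whole octave onto it. At λ = 10 harmonic capture
disappears while a 0.6→1.4 Hz chirp over 10 min is still tracked within one
grid step. Ridge frequencies are refined by quadratic interpolation of
log-amplitude over the three neighbouring rows — exact for the lognormal
window, whose log-amplitude profile is a parabola in log f.

A physical limit to keep in mind: frequency modulation faster than the
filter bandwidth is attenuated before any ridge logic sees it. At f0 = 1,
respiratory sinus arrhythmia (RSA) at ~0.3 Hz on a ~1 Hz carrier survives
only at the ~10% level in the extracted rate; slow periodic-breathing
modulation (~0.058 Hz) passes essentially unattenuated. Rate summaries are
mean, *population* SD (divide by n), and CV = SD/mean, over non-COI times.

The auxiliary R–R estimator detects R peaks as local maxima above
median + 4·MAD separated by ≥ 0.3 s and holds 1/ΔT constant over each beat
interval; it agrees with the ridge rate to < 0.02 Hz on synthetic ECG and
serves as a cross-method check, not a replacement.

## Phase coherence and surrogate thresholds

Coherence uses phases of the full transforms (not extracted ridges) at
jointly valid times (both non-COI, both nonzero amplitude):
`C(f_k) = |⟨exp(i(Φ2−Φ1))⟩|`, with the circular mean phase difference
reported alongside. Convention, pinned in output metadata: signal 1 is the
IHR, signal 2 the respiration, so a positive phase difference means
respiration leads. Adjusted coherence is raw minus threshold and is *not*
clipped at zero — clipping would bias band averages upward.

IAAFT surrogates iterate (i) imposing the target amplitude spectrum on the
current phases and (ii) rank-remapping to the original value distribution,
stopping when the relative spectral mismatch changes by < 1e-6 or at 100
iterations; the returned series is the rank-remapped one, so its sorted
values equal the original's bit-exactly. Surrogates are generated for the
second signal only — one-sided surrogacy destroys the phase relation while
preserving both marginal structures. Thresholds are per-frequency 95th
percentiles (linear-interpolation quantiles) over 100 surrogates, each
child-seeded from a master seed.

For *band-level* significance the package uses the 95th percentile of the
surrogate band means (`CoherenceThreshold.band_threshold`) rather than the
band mean of per-frequency thresholds: coherence is strongly correlated
across neighbouring frequencies, and the band-mean null quantile is the
statistic whose exceedance rate is calibrated at 5% by construction.

## Group statistics

Kruskal–Wallis (tie-corrected, chi-square p with k−1 df) across conditions
or genotype groups; pairwise two-sided Wilcoxon rank-sum only when the
omnibus p < 0.05 (exact enumeration for combined n ≤ 12 without ties,
otherwise normal approximation with continuity and tie correction). Both
wrap scipy.stats; the test suite validates them against from-scratch
exhaustive permutation enumeration. No multiple-testing correction is
applied, mirroring the analysis being reproduced; every results table
carries the number of tests performed. Missing recordings are handled by
complete-case analysis per comparison.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

* **Respiration**: carrier near 0.30 Hz with envelope
  `E(t) = (1−m_pb) + m_pb · max(0, cos θ_pb − c)/(1−c)`, where c is set so
  the modulated term vanishes for `apnoea_duty` (default 0.3) of each PB
  cycle, plus an explicit baseline component `b_base cos θ_pb` — a pure AM
  carrier has no spectral line at the modulation frequency, only sidebands,
  whereas real PB respiration spectra show a genuine low-frequency peak
  (slow thoracic-volume drift across hyperpnoea/apnoea).
* **Heart**: instantaneous rate
  `f_heart + a_rsa sin(resp phase) + a_pb_hr cos(θ_pb − phi_lag) + drift`,
  clipped to 0.5–2 Hz; beats integrate the rate to unit phase increments.
  The ECG is a train of unit Gaussian pulses (SD 20 ms) each followed by a
  broad low repolarisation bump (0.3 amplitude, SD 80 ms, +0.32 s). The
  bump is not clinical morphology: a bare narrow-pulse comb has harmonics
  as strong as its fundamental, which makes band-limited ridge extraction
  ill-posed in a way real ECG is not.
* **LDF**: sum of narrowband phase-diffusing oscillators centred in the
  cardiac, respiratory, myogenic (0.052–0.145 Hz), neurogenic
  (0.021–0.052 Hz) and endothelial (0.005–0.021 Hz) bands, plus a PB-locked
  component with configurable (near-zero) lag.
* **Shared PB phase** θ_pb: all channels read one instantaneous PB phase
  whose frequency performs a mean-reverting (Ornstein–Uhlenbeck,
  correlation time 30 s) drift around 0.058 Hz. Mean reversion, not a free
  random walk: a reflected walk has a uniform occupation density, which
  smears the time-averaged spectral peak anywhere within its bounds, while
  the OU form keeps peaks at the configured frequencies. The drift also
  makes the PB components decohere from any fixed-frequency reference over
  a few correlation times — precisely the regime in which IAAFT surrogate
  testing can separate genuine cross-signal locking (the channels share the
  phase trajectory) from mere shared periodicity (which phase-randomised
  surrogates cannot destroy).

Default parameters (chosen once, as plausible resting-physiology values
consistent with the package's own recovery checks): f_resp = 0.30 Hz,
f_mod = 0.058 Hz, f_heart = 1.0 Hz, m_pb = 0.6, a_rsa = 0.05 Hz (~3 bpm
RSA deviation; with the f0 = 1 wavelet, deviations much above 0.06 Hz are
mostly filtered out of the extracted rate and are unrecoverable by any
linear estimator), a_pb_hr = 0.05 Hz, b_base = 0.3, phi_lag = 0.5 rad,
noise SD 0.1 per channel, frequency-drift stationary SD 0.01 Hz, 1800 s at
40 Hz.

**Cohort layer.** Genotypes are drawn once per subject (NOTCH4 and CAT at
the empirical cohort proportions; SOD2/BDNF/GPX1 as null markers). PB depth
(m_pb, a_pb_hr, b_base together) scales per condition — 0 in NN, 0.15 in
NHa, 1.0 in NH/HHa/HH — then multiplies by genotype effects: NOTCH4
carriers ×1.5 in all hypoxic conditions, CAT carriers ×0.67 in hypobaric
conditions only (defaults; both configurable). Attendance patterns emulate
dropouts (22/22/18/16/13). Everything is reproducible from a single seed
via spawned child streams.

**What passing tests show — and don't.** The generator produces stationary,
additively noisy, nearly sinusoidal oscillators with known ground truth; it
has no movement artefacts, ectopic beats, non-stationarity in baseline
physiology, or coupling mechanisms beyond imposed phase locking. Recovery
of its parameters therefore validates the *analysis chain* (transforms,
ridges, coherence, surrogates, statistics), not the physiological claims
one might draw from real recordings.

## Problem sizes in the validation studies

Replicate studies scale the recording down while keeping the generator's
scientific parameters at their defaults: coherence/surrogate replicates use
600 s records analysed at 2–4 Hz with band-limited transforms (the
modulation band needs nothing faster), 100 IAAFT surrogates per threshold,
and ≥100 seeded replicates; spectral-peak and genotype cohort studies use
the full 1800 s records (cheap without surrogate loops). The genotype
power/size study uses raw band coherence as the per-subject statistic: the
surrogate threshold is common-mode across subjects with identical recording
geometry and cancels in rank-based tests, and it is exercised separately in
the coherence replicates.

## Known limitations

* The ridge scheme is a deterministic stand-in for more elaborate published
  ridge methods; it assumes a single dominant mode per band.
* Fast frequency modulation (relative to the wavelet bandwidth) is
  attenuated in extracted rates by the transform itself, not by the ridge.
* The surrogate null assumes stationarity; strongly non-stationary records
  would need time-resolved surrogacy.
* Artefact detection (robust z-score with 0.25 s dilation) is a
  convenience, off by default; the emulated protocol relied on visual
  inspection with linear interpolation, and sidecar masks are the primary
  path.
* HDF5 intermediates store full complex coefficient matrices; 30-min
  records at 40 Hz over the full grid are ~300 MB per signal.
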