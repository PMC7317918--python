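"""IAAFT surrogates and surrogate significance thresholds for phase coherence.

Even unrelated signals show non-zero phase coherence, increasingly so at low
frequencies where the record holds few cycles.  To separate genuine coupling
from this bias, the coherence is compared with its null distribution under
"same spectra and amplitude distributions, no phase relation", built from
iterative amplitude-adjusted Fourier transform (IAAFT) surrogates: each
surrogate preserves the original value distribution exactly (it is a
permutation of the samples) and the amplitude spectrum approximately.
Coherence is deemed significant where it exceeds the 95th percentile of
100 surrogate coherences, and reported values have that threshold subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .coherence import CoherenceSpectrum, phase_coherence
from .signals import UniformSignal
from .wavelet import WaveletParams, cwt

__all__ = [
    "SurrogateSet",
    "CoherenceThreshold",
    "iaaft",
    "make_surrogates",
    "coherence_threshold",
    "apply_threshold",
]


@dataclass(frozen=True)
class SurrogateSet:
    """A batch of IAAFT surrogates of one signal."""

    surrogates: list[np.ndarray]
    n: int
    seed: int
    iterations_used: list[int]
    spectral_error: list[float]  # final relative amplitude-spectrum mismatch


def iaaft(
    signal: UniformSignal | np.ndarray,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, int, float]:
    """One IAAFT surrogate.

    Alternates (i) imposing the target Fourier amplitude spectrum while
    keeping current phases and (ii) rank-remapping to the original value
    distribution, until the relative amplitude-spectrum mismatch changes by
    less than ``tol`` or ``max_iter`` is reached.  The returned series is the
    rank-remapped one: its sorted values equal the original's bit-exactly.

    Returns ``(surrogate, iterations_used, spectral_error)``.
    """
    x = signal.samples if isinstance(signal, UniformSignal) else np.asarray(signal, float)
    if x.size < 64:
        raise ValueError("signal too short for IAAFT (need >= 64 samples)")
    if np.ptp(x) == 0:
        raise ValueError("constant signal has no phase content to randomise")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target_amp = np.abs(np.fft.rfft(x))
    target_norm = np.linalg.norm(target_amp)
    sorted_x = np.sort(x)
    s = rng.permutation(x)
    prev_err = np.inf
    it = 0
    err = np.inf
    for it in range(1, max_iter + 1):
        spec = np.fft.rfft(s)
        phases = np.angle(spec)
        s2 = np.fft.irfft(target_amp * np.exp(1j * phases), n=x.size)
        order = np.argsort(s2)
        s = np.empty_like(s2)
        s[order] = sorted_x  # rank remap: smallest s2 gets smallest original value
        err = float(np.linalg.norm(np.abs(np.fft.rfft(s)) - target_amp) / target_norm)
        if abs(prev_err - err) < tol:
            break
        prev_err = err
    return s, it, err


def make_surrogates(
    signal: UniformSignal, n: int = 100, seed: int = 0, max_iter: int = 100, tol: float = 1e-6
) -> SurrogateSet:
    """Generate ``n`` independent IAAFT surrogates from a master seed.

    Child seeds are spawned deterministically from the master seed, so the
    whole set is reproducible and surrogates are mutually independent.
    """
    if n < 1:
        raise ValueError("need n >= 1 surrogates")
    x = signal.samples
    if x.size < 64:
        raise ValueError("signal too short for IAAFT (need >= 64 samples)")
    if np.ptp(x) == 0:
        raise ValueError("constant signal has no phase content to randomise")
    children = np.random.SeedSequence(seed).spawn(n)
    # batched iteration: all surrogates advance together, rows frozen once
    # their relative spectral mismatch stops changing by more than tol
    target_amp = np.abs(np.fft.rfft(x))
    target_norm = np.linalg.norm(target_amp)
    sorted_x = np.sort(x)
    S = np.stack([np.random.default_rng(c).permutation(x) for c in children])
    prev_err = np.full(n, np.inf)
    iters = np.zeros(n, dtype=int)
    errs = np.full(n, np.inf)
    active = np.ones(n, dtype=bool)
    for it in range(1, max_iter + 1):
        rows = np.flatnonzero(active)
        spec = np.fft.rfft(S[rows], axis=1)
        s2 = np.fft.irfft(target_amp * np.exp(1j * np.angle(spec)), n=x.size, axis=1)
        order = np.argsort(s2, axis=1)
        remapped = np.empty_like(s2)
        np.put_along_axis(remapped, order, np.broadcast_to(sorted_x, s2.shape), axis=1)
        S[rows] = remapped
        err = np.linalg.norm(np.abs(np.fft.rfft(S[rows], axis=1)) - target_amp, axis=1) / target_norm
        iters[rows] = it
        converged = np.abs(prev_err[rows] - err) < tol
        errs[rows] = err
        prev_err[rows] = err
        active[rows[converged]] = False
        if not active.any():
            break
    return SurrogateSet(
        surrogates=list(S), n=n, seed=seed,
        iterations_used=iters.tolist(), spectral_error=errs.tolist(),
    )


@dataclass(frozen=True)
class CoherenceThreshold:
    """Per-frequency surrogate significance threshold.

    Also retains the full surrogate coherence matrix so band-level null
    quantiles can be formed from the same surrogates.
    """

    freqs: np.ndarray
    threshold: np.ndarray  # per-frequency percentile across surrogates
    surrogate_coh: np.ndarray  # shape (n_surrogates, n_freq)
    n: int
    percentile: float
    seed: int

    def band_threshold(self, f_lo: float, f_hi: float) -> float:
        """Percentile of surrogate *band-mean* coherences over [f_lo, f_hi].

        The calibrated null quantile for a band-averaged statistic: per-
        frequency thresholds averaged over the band would ignore the strong
        correlation of coherence across neighbouring frequencies.
        """
        sel = (self.freqs >= f_lo - 1e-12) & (self.freqs <= f_hi + 1e-12)
        if not sel.any():
            raise ValueError(f"no grid frequencies in band [{f_lo}, {f_hi}] Hz")
        band_vals = np.nanmean(self.surrogate_coh[:, sel], axis=1)
        return float(np.percentile(band_vals, self.percentile))


def coherence_threshold(
    sig1: UniformSignal,
    sig2: UniformSignal,
    tfr_params: WaveletParams | None = None,
    n: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> CoherenceThreshold:
    """Surrogate significance threshold for the coherence of (sig1, sig2).

    Surrogates are generated for the second signal only, the first left
    intact: this destroys any phase relation while preserving each signal's
    spectrum and value distribution.  For each surrogate the raw phase
    coherence against the original ``sig1`` transform is computed; the
    threshold at each frequency is the ``percentile`` quantile (linear
    interpolation between order statistics) across surrogates.
    """
    import warnings

    if n < 20 and percentile >= 95:
        warnings.warn(
            f"{percentile}th percentile poorly resolved with only {n} surrogates",
            stacklevel=2,
        )
    params = tfr_params or WaveletParams()
    tfr1 = cwt(sig1, params)
    sset = make_surrogates(sig2, n=n, seed=seed)
    sur_coh = np.empty((n, params.freqs.size))
    for i, s in enumerate(sset.surrogates):
        tfr_s = cwt(sig2.with_samples(s), params)
        sur_coh[i] = phase_coherence(tfr1, tfr_s).raw_coh
    threshold = np.nanpercentile(sur_coh, percentile, axis=0)
    return CoherenceThreshold(
        freqs=params.freqs,
        threshold=threshold,
        surrogate_coh=sur_coh,
        n=n,
        percentile=percentile,
        seed=seed,
    )


def apply_threshold(coh: CoherenceSpectrum, threshold: CoherenceThreshold | np.ndarray) -> CoherenceSpectrum:
    """Attach a surrogate threshold: adjusted coherence = raw - threshold."""
    thr = threshold.threshold if isinstance(threshold, CoherenceThreshold) else np.asarray(threshold, float)
    if isinstance(threshold, CoherenceThreshold) and not np.allclose(threshold.freqs, coh.freqs):
        raise ValueError("threshold frequency grid does not match coherence grid")
    if thr.shape != coh.raw_coh.shape:
        raise ValueError("threshold length does not match coherence grid")
    return replace(coh, threshold=thr)
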