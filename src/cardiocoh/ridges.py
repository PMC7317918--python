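"""Ridge extraction of instantaneous frequency from a time-frequency representation.

The instantaneous heart rate (IHR) is traced in the 0.5–2 Hz band of the
ECG's wavelet transform; the instantaneous respiration rate in 0.145–0.6 Hz.
The ridge is the amplitude-maximal path through the band, regularised by a
quadratic log-frequency jump penalty and solved globally by dynamic
programming.  An auxiliary R-R-interval estimator provides an independent
heart-rate readout for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import UniformSignal
from .wavelet import TimeFrequencyRepresentation

__all__ = [
    "Ridge",
    "RateSummary",
    "extract_ridge",
    "rate_series",
    "rate_summary",
    "rr_heart_rate",
]

IHR_BAND = (0.5, 2.0)
RESP_BAND = (0.145, 0.6)


@dataclass(frozen=True)
class Ridge:
    """Instantaneous frequency/phase/amplitude of one oscillatory mode."""

    times: np.ndarray  # s
    inst_freq: np.ndarray  # Hz, confined to `band`
    inst_phase: np.ndarray  # rad, wrapped to (-pi, pi]
    inst_amp: np.ndarray  # signal units (window-gain corrected)
    band: tuple[float, float]
    valid_mask: np.ndarray  # True at non-COI times
    fs: float

    def __post_init__(self) -> None:
        lo, hi = self.band
        f = self.inst_freq
        if f.min() < lo - 1e-9 or f.max() > hi + 1e-9:
            raise ValueError("ridge frequency escaped its band")

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("time\tfreq\tphase\tamp\n")
            for t, f, p, a in zip(self.times, self.inst_freq, self.inst_phase, self.inst_amp):
                fh.write(f"{t:.6f}\t{f:.8g}\t{p:.8g}\t{a:.8g}\n")


@dataclass(frozen=True)
class RateSummary:
    """Mean, population SD and coefficient of variation of a rate series."""

    mean: float
    sd: float
    cv: float  # NaN when mean <= 0


def _band_rows(tfr: TimeFrequencyRepresentation, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    rows = np.flatnonzero((tfr.freqs >= lo - 1e-12) & (tfr.freqs <= hi + 1e-12))
    if rows.size == 0:
        raise ValueError(f"band {band} contains no grid frequencies")
    return rows


def extract_ridge(
    tfr: TimeFrequencyRepresentation,
    band: tuple[float, float],
    penalty: float = 10.0,
) -> Ridge:
    """Trace the dominant oscillatory mode through a frequency band.

    Maximises ``sum_t log|W(k_t, t)| - penalty * (Delta log2 f)^2`` over all
    grid paths by dynamic programming (``penalty`` in units of 1/octave^2 per
    time step), then refines each ridge frequency by quadratic interpolation
    of log-amplitude across the three neighbouring grid rows.  For the
    lognormal wavelet the window is Gaussian in log f, so the log-amplitude
    parabola is exact and the refinement is unbiased.

    The default penalty is stiff enough that the path cannot profitably jump
    a whole octave onto the second harmonic of a pulse-train-like signal
    (ECG): harmonic capture, not tracking lag, is the failure mode that
    matters in the heart-rate band.
    """
    rows = _band_rows(tfr, band)
    W = tfr.coeffs[rows]
    amp = np.abs(W)
    if not amp.any():
        raise ValueError("all coefficients in the band are zero")
    logf2 = np.log2(tfr.freqs[rows])
    K, T = amp.shape
    tiny = amp.max() * 1e-12
    A = np.log(amp + tiny)

    pen = penalty * (logf2[:, None] - logf2[None, :]) ** 2  # pen[j, k]
    score = A[:, 0].copy()
    ptr = np.empty((T, K), dtype=np.int32)
    for t in range(1, T):
        cand = score[:, None] - pen  # (from j, to k)
        best_j = np.argmax(cand, axis=0)
        ptr[t] = best_j
        score = cand[best_j, np.arange(K)] + A[:, t]
    path = np.empty(T, dtype=np.int32)
    path[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        path[t - 1] = ptr[t, path[t]]

    idx = np.arange(T)
    k = path
    # quadratic refinement in log2 f (clipped to half a grid step, then to the band)
    km = np.clip(k - 1, 0, K - 1)
    kp = np.clip(k + 1, 0, K - 1)
    a_m, a_0, a_p = A[km, idx], A[k, idx], A[kp, idx]
    denom = a_m - 2 * a_0 + a_p
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (a_m - a_p) / denom
    delta = np.where((denom < 0) & np.isfinite(delta), np.clip(delta, -0.5, 0.5), 0.0)
    delta[(k == 0) | (k == K - 1)] = 0.0
    step = logf2[1] - logf2[0] if K > 1 else 0.0
    inst_freq = np.clip(2.0 ** (logf2[k] + delta * step), band[0], band[1])

    inst_phase = np.angle(W[k, idx])
    # unit-gain transform: |W| on the ridge is already in signal units
    inst_amp = amp[k, idx]
    # a time is valid when every band row is outside the COI (the slowest
    # row's cone is the widest, so this equals the lowest row's validity)
    valid = tfr.valid_mask[rows].all(axis=0)
    fs = 1.0 / float(np.mean(np.diff(tfr.times)))
    return Ridge(
        times=tfr.times.copy(),
        inst_freq=inst_freq,
        inst_phase=inst_phase,
        inst_amp=inst_amp,
        band=band,
        valid_mask=valid,
        fs=fs,
    )


def rate_series(
    ridge: Ridge, fs_out: float = 40.0, label: str = "ihr", trim: bool = True
) -> UniformSignal:
    """Resample the ridge's instantaneous frequency onto a uniform grid.

    With ``trim=True`` COI-invalid edges are cut first and the interior of
    the valid span is linearly interpolated at ``fs_out``; with
    ``trim=False`` the full record length is kept (edge values are then
    COI-contaminated, which a downstream transform's own COI re-excludes).
    """
    valid = np.flatnonzero(ridge.valid_mask)
    if valid.size < 2:
        raise ValueError("ridge has fewer than 2 valid times")
    if trim:
        t = ridge.times[valid[0] : valid[-1] + 1]
        f = ridge.inst_freq[valid[0] : valid[-1] + 1]
    else:
        t = ridge.times
        f = ridge.inst_freq
    n_out = max(int(np.floor((t[-1] - t[0]) * fs_out)) + 1, 2)
    t_new = t[0] + np.arange(n_out) / fs_out
    return UniformSignal(samples=np.interp(t_new, t, f), fs=fs_out, label=label, t0=t[0])


def rate_summary(series: UniformSignal) -> RateSummary:
    """Mean, population SD (divide by n) and CV = sd/mean of a rate series."""
    x = series.samples
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    cv = sd / mean if mean > 0 else float("nan")
    return RateSummary(mean=mean, sd=sd, cv=cv)


def rr_heart_rate(ecg: UniformSignal, min_rr_s: float = 0.3) -> UniformSignal:
    """Heart rate as the inverse of consecutive R-R peak intervals.

    R peaks are local maxima above an adaptive threshold (median + 4 MAD of
    the ECG), separated by at least ``min_rr_s``.  The rate is held constant
    over each beat interval, giving a piecewise-constant series on the ECG's
    own sampling grid.
    """
    if min_rr_s <= 0:
        raise ValueError("min_rr_s must be positive")
    x = ecg.samples
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    height = med + 4.0 * 1.4826 * mad if mad > 0 else med
    peaks, _ = sps.find_peaks(x, height=height, distance=max(int(min_rr_s * ecg.fs), 1))
    if peaks.size < 2:
        raise ValueError("fewer than 2 R peaks detected")
    rr = np.diff(peaks) / ecg.fs
    rates = 1.0 / rr
    out = np.empty(peaks[-1] - peaks[0])
    for i in range(peaks.size - 1):
        out[peaks[i] - peaks[0] : peaks[i + 1] - peaks[0]] = rates[i]
    return UniformSignal(
        samples=out, fs=ecg.fs, label="ihr_rr", t0=ecg.t0 + peaks[0] / ecg.fs
    )
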