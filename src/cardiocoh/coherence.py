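"""Wavelet phase coherence and circular phase difference between two signals.

At each frequency f_k the phase difference DPhi_{k,n} = Phi2 - Phi1 is formed
from the wavelet coefficients of the two signals at jointly valid (non-COI,
nonzero-amplitude) times, and the coherence is the length of the mean unit
phasor:

    C(f_k) = sqrt(<cos DPhi>^2 + <sin DPhi>^2)  in [0, 1].

A constant phase difference gives 1; a monotonically drifting one tends to 0.
Phases come from the full transforms, not from extracted ridges.  Phase
convention: in cardiorespiratory calls signal 1 is the IHR and signal 2 the
respiration, so a positive circular-mean phase difference means respiration
leads.  The convention is pinned in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavelet import TimeFrequencyRepresentation

__all__ = [
    "CoherenceSpectrum",
    "BandStatistic",
    "phase_coherence",
    "band_mean",
    "lead_lag",
    "MODULATION_BAND",
]

#: Frequency band (Hz) over which coherence is averaged to quantify
#: periodic breathing.
MODULATION_BAND = (0.03, 0.15)

PHASE_CONVENTION = "phase_diff = Phi(signal2) - Phi(signal1); CR call order: (ihr, resp)"


@dataclass(frozen=True)
class CoherenceSpectrum:
    """Per-frequency coherence, optional surrogate threshold, and phase difference."""

    freqs: np.ndarray
    raw_coh: np.ndarray  # in [0, 1]; NaN where no jointly valid times
    phase_diff: np.ndarray  # circular mean of Phi2 - Phi1, in (-pi, pi]
    n_valid: np.ndarray  # jointly valid times per frequency
    threshold: np.ndarray | None = None  # surrogate 95th percentile
    convention: str = PHASE_CONVENTION

    @property
    def adj_coh(self) -> np.ndarray:
        """Raw coherence minus the surrogate threshold (may be negative).

        Equal to the raw coherence when no threshold has been applied.
        Deliberately not clipped at zero: clipping would bias band means.
        """
        if self.threshold is None:
            return self.raw_coh
        return self.raw_coh - self.threshold

    @property
    def significant(self) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("no surrogate threshold attached")
        return self.raw_coh > self.threshold

    def nearest_freq_index(self, f: float) -> int:
        return int(np.argmin(np.abs(np.log(self.freqs) - np.log(f))))

    def to_tsv(self, path) -> None:
        thr = self.threshold if self.threshold is not None else np.full_like(self.raw_coh, np.nan)
        adj = self.adj_coh
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {self.convention}\n")
            fh.write("freq\traw\tthreshold\tadjusted\tphase_diff\n")
            for row in zip(self.freqs, self.raw_coh, thr, adj, self.phase_diff):
                fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")


@dataclass(frozen=True)
class BandStatistic:
    """One subject x condition modulation-band coherence value."""

    subject_id: str
    condition: str
    value: float  # mean adjusted coherence over the band
    band: tuple[float, float] = MODULATION_BAND
    gene_context: str | None = None


def phase_coherence(
    tfr1: TimeFrequencyRepresentation, tfr2: TimeFrequencyRepresentation
) -> CoherenceSpectrum:
    """Raw wavelet phase coherence between two transforms on identical grids."""
    if tfr1.coeffs.shape != tfr2.coeffs.shape or not np.allclose(tfr1.freqs, tfr2.freqs):
        raise ValueError("transforms must share frequency and time grids")
    if not np.allclose(tfr1.times, tfr2.times):
        raise ValueError("transforms must cover the same times")
    K = tfr1.freqs.size
    T = tfr1.times.size
    raw = np.full(K, np.nan)
    pd = np.full(K, np.nan)
    n_valid = np.zeros(K, dtype=int)
    # row-wise with reused buffers to keep memory flat on long records:
    # Phi2 - Phi1 is the argument of W2 * conj(W1)
    cross = np.empty(T, dtype=complex)
    mag = np.empty(T)
    valid = np.empty(T, dtype=bool)
    for k in range(K):
        np.conjugate(tfr1.coeffs[k], out=cross)
        np.multiply(tfr2.coeffs[k], cross, out=cross)
        np.abs(cross, out=mag)
        np.greater(mag, 0.0, out=valid)
        valid &= tfr1.valid_mask[k]
        valid &= tfr2.valid_mask[k]
        n = int(valid.sum())
        n_valid[k] = n
        if n == 0:
            continue
        np.divide(cross, mag, out=cross, where=valid)
        mean_phasor = cross.sum(where=valid) / n
        raw[k] = np.abs(mean_phasor)
        pd[k] = np.angle(mean_phasor)
    return CoherenceSpectrum(
        freqs=tfr1.freqs.copy(), raw_coh=raw, phase_diff=pd, n_valid=n_valid
    )


def band_mean(
    coh: CoherenceSpectrum, f_lo: float, f_hi: float, which: str = "adjusted"
) -> float:
    """Unweighted mean coherence over grid frequencies in the closed band."""
    sel = (coh.freqs >= f_lo - 1e-12) & (coh.freqs <= f_hi + 1e-12)
    if not sel.any():
        raise ValueError(f"no grid frequencies in band [{f_lo}, {f_hi}] Hz")
    values = coh.adj_coh if which == "adjusted" else coh.raw_coh
    return float(np.nanmean(values[sel]))


def lead_lag(phase_diff: float, in_phase_tol: float = 0.1) -> str:
    """Classify a circular-mean phase difference under the pinned convention.

    Returns ``"signal2_leads"`` for positive differences (respiration leads,
    in the cardiorespiratory call order), ``"signal1_leads"`` for negative,
    and ``"in_phase"`` when |phase_diff| < ``in_phase_tol`` rad.
    """
    if abs(phase_diff) < in_phase_tol:
        return "in_phase"
    return "signal2_leads" if phase_diff > 0 else "signal1_leads"
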