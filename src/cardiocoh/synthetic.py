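"""Synthetic cohort generator for hypoxia-style cardiorespiratory recordings.

Emulates the statistical structure the analysis assumes, so every downstream
stage is testable without access to the deposited recordings:

* respiration near 0.3 Hz whose amplitude is modulated at the periodic-
  breathing (PB) frequency near 0.058 Hz, with apnoea epochs;
* heart rate near 1 Hz, frequency-modulated by respiration (respiratory
  sinus arrhythmia, RSA) and at the PB frequency, with an imposed phase lag
  behind the respiratory PB component;
* an ECG as a train of narrow Gaussian pulses whose beat times integrate the
  instantaneous heart rate;
* laser-Doppler flowmetry (LDF) as a sum of narrowband phase-diffusing
  oscillators in the cardiac, respiratory, myogenic (0.052-0.145 Hz),
  neurogenic (0.021-0.052 Hz) and endothelial (0.005-0.021 Hz) bands plus a
  PB-locked component;
* a cohort layer with five exposure conditions (NN, NHa, NH, HHa, HH) and
  genotype-dependent PB depth (NOTCH4 carriers deeper in hypoxia, CAT
  carriers shallower in hypobaric conditions).

A pure amplitude-modulated carrier has no spectral line at the modulation
frequency (only sidebands at f_resp +/- f_mod); real PB respiration spectra
show a genuine low-frequency peak, so the generator adds an explicit
baseline component ``b_base`` at f_mod, representing the slow thoracic-
volume drift across hyperpnoea/apnoea cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .signals import UniformSignal

__all__ = [
    "SyntheticConfig",
    "SubjectRecord",
    "CONDITIONS",
    "TABLE_ATTENDANCE",
    "generate_respiration",
    "generate_heart",
    "generate_ldf",
    "generate_record",
    "generate_cohort",
]

CONDITIONS = ("NN", "NHa", "NH", "HHa", "HH")

#: Fraction of the full-PB modulation depth present in each exposure
#: condition: absent in normoxia, shallow in acute normobaric hypoxia,
#: full in the sustained/hypobaric hypoxic conditions.
CONDITION_PB_SCALE = {"NN": 0.0, "NHa": 0.15, "NH": 1.0, "HHa": 1.0, "HH": 1.0}

#: Study-style attendance per condition (dropouts at altitude).
TABLE_ATTENDANCE = {"NN": 22, "NHa": 22, "NH": 18, "HHa": 16, "HH": 13}

RESP_BAND = (0.145, 0.6)
HEART_BAND = (0.5, 2.0)

#: Genotype code frequencies: NOTCH4 and CAT reproduce the empirical cohort
#: proportions; the remaining genes are Hardy-Weinberg null markers.
DEFAULT_GENOTYPE_FREQS: dict[str, dict[str, float]] = {
    "NOTCH4": {"GG": 7 / 22, "GA": 12 / 22, "AA": 3 / 22},
    "CAT": {"CC": 10 / 22, "CT": 11 / 22, "TT": 1 / 22},
    "SOD2": {"CC": 0.25, "CT": 0.50, "TT": 0.25},
    "BDNF": {"GG": 0.65, "GA": 0.30, "AA": 0.05},
    "GPX1": {"CC": 0.50, "CT": 0.40, "TT": 0.10},
}

#: Multiplicative effect of carrier status on PB depth.  NOTCH4 carriers
#: (GA/AA) scale up in all hypoxic conditions; CAT carriers (CT/TT) scale
#: down in the hypobaric conditions (HHa/HH) only.
DEFAULT_EFFECT_SIZES = {"NOTCH4": 1.5, "CAT": 0.67}

_CARRIER_CODES = {"NOTCH4": ("GA", "AA"), "CAT": ("CT", "TT")}
_NOTCH4_CONDITIONS = ("NHa", "NH", "HHa", "HH")
_CAT_CONDITIONS = ("HHa", "HH")


@dataclass(frozen=True)
class SyntheticConfig:
    """Per-recording generator parameters.

    Frequencies are in Hz; modulation depths of the heart rate (``a_rsa``,
    ``a_pb_hr``) are in Hz as well, being frequency-modulation amplitudes.
    Defaults describe one 30-minute recording at 40 Hz with fully developed
    periodic breathing (the sustained-hypoxia profile).
    """

    f_resp: float = 0.30  # respiration carrier
    f_mod: float = 0.058  # PB modulation frequency
    f_heart: float = 1.0  # baseline heart rate
    m_pb: float = 0.6  # PB amplitude-modulation depth in [0, 1]
    a_rsa: float = 0.05  # RSA frequency-modulation depth, Hz
    a_pb_hr: float = 0.05  # PB heart-rate modulation depth, Hz
    b_base: float = 0.3  # respiration baseline component at f_mod
    apnoea_duty: float = 0.3  # fraction of each PB cycle with near-zero breathing
    phi_lag: float = 0.5  # heart PB component lags respiration PB by this, rad
    noise_sd: float = 0.1  # additive white noise SD per channel
    duration_s: float = 1800.0
    fs: float = 40.0
    freq_jitter_sd: float = 0.01  # stationary SD of the slow frequency drifts, Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f_mod < self.f_resp < self.f_heart):
            raise ValueError("need 0 < f_mod < f_resp < f_heart")
        if not (0 <= self.m_pb <= 1):
            raise ValueError("m_pb must lie in [0, 1]")
        if not (0 <= self.apnoea_duty < 1):
            raise ValueError("apnoea_duty must lie in [0, 1)")
        if self.duration_s * self.f_mod < 10:
            raise ValueError("need duration_s * f_mod >= 10 (enough PB cycles)")

    @property
    def n(self) -> int:
        return int(round(self.duration_s * self.fs))

    def _streams(self) -> dict[str, np.random.Generator]:
        """Named independent RNG streams, all derived from the one seed.

        Respiration and heart generation share the ``resp_walk`` stream so
        the RSA term in the heart rate follows the same respiratory phase
        that the respiration channel carries.
        """
        names = ("resp_walk", "pb_walk", "resp_noise", "heart_walk", "heart_noise", "ldf")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}


@dataclass(frozen=True)
class SubjectRecord:
    """One subject x condition bundle of signals plus the genotype map."""

    subject_id: str
    condition: str
    signals: dict[str, UniformSignal]
    genotypes: dict[str, str]

    def __post_init__(self) -> None:
        durations = [s.duration for s in self.signals.values()]
        if durations and max(durations) - min(durations) > 1.0 / min(s.fs for s in self.signals.values()):
            raise ValueError("channels must share duration within one sample")


# ---------------------------------------------------------------------------
# Component generators
# ---------------------------------------------------------------------------


#: Correlation time (s) of the slow instantaneous-frequency drifts.
DRIFT_TAU_S = 30.0


def _bounded_walk(
    rng: np.random.Generator, n: int, dt: float, mean: float,
    sd_stationary: float, lo: float, hi: float,
) -> np.ndarray:
    """Mean-reverting (Ornstein-Uhlenbeck) frequency drift, clipped to [lo, hi].

    Exact discretisation with correlation time ``DRIFT_TAU_S`` and
    stationary SD ``sd_stationary``; started at the mean.  Mean reversion —
    rather than a free random walk — keeps the occupation density of the
    instantaneous frequency peaked at its configured value, so the
    time-averaged spectra of generated records peak where they should while
    the accumulated phase still decoheres from any fixed-frequency
    reference over a few correlation times.
    """
    if sd_stationary == 0 or n == 0:
        return np.full(n, mean)
    a = np.exp(-dt / DRIFT_TAU_S)
    innov_sd = sd_stationary * np.sqrt(1.0 - a * a)
    eps = rng.normal(0.0, innov_sd, size=n)
    # dev[i] = a dev[i-1] + eps[i-1], dev[0] = 0  (AR(1) via lfilter)
    from scipy.signal import lfilter

    dev = np.concatenate(([0.0], lfilter([1.0], [1.0, -a], eps[:-1])))
    return np.clip(mean + dev, lo, hi)


def _pb_phase(cfg: SyntheticConfig, streams: dict[str, np.random.Generator]) -> np.ndarray:
    """Shared instantaneous phase of the PB oscillation, radians.

    The modulation frequency performs a slow bounded random walk around
    f_mod (jitter proportional to the carrier jitter, bounds +/-30%), as the
    observed modulation frequency varies slightly within and between
    records.  Respiration, heart rate and LDF all read this one phase, so
    their PB components stay mutually phase-locked while drifting relative
    to any fixed-frequency reference — the regime in which surrogate testing
    separates genuine coupling from shared periodicity.
    """
    sd = cfg.freq_jitter_sd * cfg.f_mod / cfg.f_resp
    f_inst = _bounded_walk(
        streams["pb_walk"], cfg.n, 1.0 / cfg.fs, cfg.f_mod,
        sd, 0.7 * cfg.f_mod, 1.3 * cfg.f_mod,
    )
    return 2 * np.pi * np.cumsum(f_inst) / cfg.fs


def _pb_envelope(cfg: SyntheticConfig, theta_pb: np.ndarray) -> np.ndarray:
    """Amplitude envelope of PB: hyperpnoea bursts separated by apnoea.

    The clipping level c is chosen so the modulated term is zero for exactly
    ``apnoea_duty`` of each PB cycle; the residual envelope there is
    ``1 - m_pb`` (shallow breathing between bursts).
    """
    c = np.cos(np.pi * (1.0 - cfg.apnoea_duty))
    burst = np.maximum(0.0, np.cos(theta_pb) - c) / (1.0 - c)
    return (1.0 - cfg.m_pb) + cfg.m_pb * burst


def generate_respiration(cfg: SyntheticConfig) -> UniformSignal:
    """Respiratory-effort signal with PB amplitude modulation.

    resp(t) = E(t) sin(2 pi int f_resp dt) + b_base cos(2 pi f_mod t) + noise,
    where the instantaneous respiration frequency performs a bounded random
    walk inside the respiratory band (0.145-0.6 Hz).
    """
    streams = cfg._streams()
    f_inst = _bounded_walk(
        streams["resp_walk"], cfg.n, 1.0 / cfg.fs, cfg.f_resp,
        cfg.freq_jitter_sd, *RESP_BAND,
    )
    phase = 2 * np.pi * np.cumsum(f_inst) / cfg.fs
    theta_pb = _pb_phase(cfg, streams)
    env = _pb_envelope(cfg, theta_pb)
    x = env * np.sin(phase) + cfg.b_base * np.cos(theta_pb)
    x = x + streams["resp_noise"].normal(0.0, cfg.noise_sd, size=cfg.n)
    return UniformSignal(samples=x, fs=cfg.fs, label="resp")


def instantaneous_heart_rate_truth(cfg: SyntheticConfig) -> np.ndarray:
    """Ground-truth f_h(t) used by both the IHR channel and the ECG beats."""
    streams = cfg._streams()
    f_resp_inst = _bounded_walk(
        streams["resp_walk"], cfg.n, 1.0 / cfg.fs, cfg.f_resp,
        cfg.freq_jitter_sd, *RESP_BAND,
    )
    resp_phase = 2 * np.pi * np.cumsum(f_resp_inst) / cfg.fs
    theta_pb = _pb_phase(cfg, streams)
    jitter = _bounded_walk(
        streams["heart_walk"], cfg.n, 1.0 / cfg.fs, 0.0,
        cfg.freq_jitter_sd, -0.1, 0.1,
    )
    f_h = (
        cfg.f_heart
        + cfg.a_rsa * np.sin(resp_phase)
        + cfg.a_pb_hr * np.cos(theta_pb - cfg.phi_lag)
        + jitter
    )
    clipped = (f_h < HEART_BAND[0]) | (f_h > HEART_BAND[1])
    if clipped.mean() > 0.01:
        warnings.warn(
            f"instantaneous heart rate clipped to {HEART_BAND} Hz for "
            f"{clipped.mean():.1%} of the record", stacklevel=2,
        )
    return np.clip(f_h, *HEART_BAND)


def generate_heart(cfg: SyntheticConfig) -> tuple[UniformSignal, UniformSignal]:
    """(ihr, ecg): instantaneous heart rate and a schematic ECG.

    Beat times t_i satisfy ``int_{t_i}^{t_{i+1}} f_h dt = 1``; the ECG is a
    train of unit-amplitude Gaussian pulses (SD 20 ms) at those times, each
    followed by a broad low repolarisation bump (0.3 amplitude, SD 80 ms,
    0.32 s after the beat), plus noise.  The bump is not an attempt at
    clinical morphology: a bare narrow-pulse comb has harmonics as strong as
    its fundamental, which makes band-limited ridge extraction ill-posed in
    a way real ECG (whose broad deflections concentrate energy at the
    fundamental) is not.
    """
    streams = cfg._streams()
    f_h = instantaneous_heart_rate_truth(cfg)
    ihr = UniformSignal(samples=f_h, fs=cfg.fs, label="ihr")

    t = np.arange(cfg.n) / cfg.fs
    cum_beats = np.cumsum(f_h) / cfg.fs  # beats elapsed
    n_beats = int(np.floor(cum_beats[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), cum_beats, t)
    ecg = np.zeros(cfg.n)
    for amp, sd, delay in ((1.0, 0.02, 0.0), (0.3, 0.08, 0.32)):
        half = max(int(np.ceil(4 * sd * cfg.fs)), 1)
        for tb in beat_times:
            i = int(round((tb + delay) * cfg.fs))
            lo, hi = max(i - half, 0), min(i + half + 1, cfg.n)
            ecg[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - tb - delay) / sd) ** 2)
    ecg += streams["heart_noise"].normal(0.0, cfg.noise_sd, size=cfg.n)
    return ihr, UniformSignal(samples=ecg, fs=cfg.fs, label="ecg")


#: LDF component amplitudes and centre frequencies (geometric band centres).
LDF_COMPONENTS = {
    "cardiac": (0.3, None),  # centre = f_heart
    "respiratory": (0.5, None),  # centre = f_resp
    "myogenic": (1.0, np.sqrt(0.052 * 0.145)),
    "neurogenic": (0.8, np.sqrt(0.021 * 0.052)),
    "endothelial": (0.6, np.sqrt(0.005 * 0.021)),
}


def generate_ldf(
    cfg: SyntheticConfig,
    amplitudes: dict[str, float] | None = None,
    pb_amp: float = 0.8,
    pb_lag: float = 0.0,
    label: str = "ldf_left",
    phase_diffusion_sd: float = 0.05,
) -> UniformSignal:
    """LDF perfusion signal: narrowband oscillators plus a PB-locked component.

    Each oscillator is ``a cos(2 pi f_c t + phi(t))`` with slowly diffusing
    phase; the PB component is phase-locked to the respiratory PB cycle with
    lag ``pb_lag`` (near zero in the microvascular observations being
    emulated).  The PB amplitude scales with the configured PB depth so the
    component vanishes in normoxic profiles.
    """
    amps = {k: v[0] for k, v in LDF_COMPONENTS.items()}
    if amplitudes:
        amps.update(amplitudes)
    centres = {
        "cardiac": cfg.f_heart,
        "respiratory": cfg.f_resp,
        "myogenic": LDF_COMPONENTS["myogenic"][1],
        "neurogenic": LDF_COMPONENTS["neurogenic"][1],
        "endothelial": LDF_COMPONENTS["endothelial"][1],
    }
    streams = cfg._streams()
    theta_pb = _pb_phase(cfg, streams)
    rng = streams["ldf"]
    t = np.arange(cfg.n) / cfg.fs
    x = np.zeros(cfg.n)
    for name in sorted(amps):
        a = amps[name]
        if a == 0:
            continue
        drift = np.cumsum(rng.normal(0, phase_diffusion_sd / np.sqrt(cfg.fs), cfg.n))
        x += a * np.cos(2 * np.pi * centres[name] * t + drift)
    if pb_amp:
        x += pb_amp * cfg.m_pb * np.cos(theta_pb - pb_lag)
    x += rng.normal(0.0, cfg.noise_sd, size=cfg.n)
    return UniformSignal(samples=x, fs=cfg.fs, label=label)


DEFAULT_CHANNELS = ("resp", "ihr", "ecg", "ldf_left", "ldf_right")


def generate_record(
    cfg: SyntheticConfig,
    subject_id: str = "S01",
    condition: str = "NN",
    genotypes: dict[str, str] | None = None,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> SubjectRecord:
    """Bundle the requested channels from one config into a SubjectRecord."""
    signals: dict[str, UniformSignal] = {}
    if "resp" in channels:
        signals["resp"] = generate_respiration(cfg)
    if "ihr" in channels or "ecg" in channels:
        ihr, ecg = generate_heart(cfg)
        if "ihr" in channels:
            signals["ihr"] = ihr
        if "ecg" in channels:
            signals["ecg"] = ecg
    for side in ("ldf_left", "ldf_right"):
        if side in channels:
            side_cfg = replace(cfg, seed=cfg.seed + (1 if side == "ldf_right" else 0))
            signals[side] = generate_ldf(side_cfg, label=side)
    return SubjectRecord(
        subject_id=subject_id, condition=condition,
        signals=signals, genotypes=genotypes or {},
    )


def _draw_genotypes(rng: np.random.Generator, freqs: dict[str, dict[str, float]]) -> dict[str, str]:
    out = {}
    for gene in sorted(freqs):
        codes = sorted(freqs[gene])
        p = np.array([freqs[gene][c] for c in codes], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies for {gene} must sum to 1")
        out[gene] = codes[rng.choice(len(codes), p=p)]
    return out


def _apply_genotype_effect(
    depth_scale: float, condition: str, genotypes: dict[str, str],
    effect_sizes: dict[str, float],
) -> float:
    if genotypes.get("NOTCH4") in _CARRIER_CODES["NOTCH4"] and condition in _NOTCH4_CONDITIONS:
        depth_scale *= effect_sizes.get("NOTCH4", 1.0)
    if genotypes.get("CAT") in _CARRIER_CODES["CAT"] and condition in _CAT_CONDITIONS:
        depth_scale *= effect_sizes.get("CAT", 1.0)
    return depth_scale


def generate_cohort(
    n_subjects: int = 22,
    conditions: tuple[str, ...] = CONDITIONS,
    genotype_freqs: dict[str, dict[str, float]] | None = None,
    effect_sizes: dict[str, float] | None = None,
    seed: int = 0,
    base_config: SyntheticConfig | None = None,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    attendance: dict[str, int] | None = None,
) -> list[SubjectRecord]:
    """Generate a reproducible cohort of subject x condition recordings.

    Genotypes are drawn once per subject and shared across conditions.  The
    PB depth (``m_pb``), the PB heart-rate modulation (``a_pb_hr``) and the
    f_mod respiratory baseline (``b_base``) are scaled per condition
    (absent in NN, shallow in NHa, full in NH/HHa/HH), then multiplied by
    the genotype effects.  ``attendance`` maps condition to the number of
    attending subjects (a reproducible subset), emulating dropouts.
    """
    freqs = genotype_freqs or DEFAULT_GENOTYPE_FREQS
    effects = DEFAULT_EFFECT_SIZES if effect_sizes is None else effect_sizes
    base = base_config or SyntheticConfig()
    master = np.random.SeedSequence(seed)
    geno_rng = np.random.default_rng(master.spawn(1)[0])
    genotypes = [_draw_genotypes(geno_rng, freqs) for _ in range(n_subjects)]

    attend_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    attending: dict[str, np.ndarray] = {}
    for cond in conditions:
        n_att = (attendance or {}).get(cond, n_subjects)
        if n_att > n_subjects:
            raise ValueError(f"attendance for {cond} exceeds cohort size")
        attending[cond] = np.sort(attend_rng.choice(n_subjects, size=n_att, replace=False))

    records: list[SubjectRecord] = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        for j, cond in enumerate(conditions):
            if i not in attending[cond]:
                continue
            scale = CONDITION_PB_SCALE.get(cond, 1.0)
            scale = _apply_genotype_effect(scale, cond, genotypes[i], effects)
            m_pb = base.m_pb * scale
            if m_pb > 1.0:
                warnings.warn(
                    f"{sid}/{cond}: genotype effect pushed m_pb to {m_pb:.2f}; clipped to 1",
                    stacklevel=2,
                )
                m_pb = 1.0
            cfg = replace(
                base,
                m_pb=m_pb,
                a_pb_hr=base.a_pb_hr * scale,
                b_base=base.b_base * scale,
                seed=int(np.random.SeedSequence([seed, 2, i, j]).generate_state(1)[0] % (2**31)),
            )
            records.append(generate_record(cfg, sid, cond, genotypes[i], channels))
    return records
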