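"""Paired PPG/ECG waveform simulator with exact ground-truth annotations.

The simulator produces synchronized two-channel records in which every
beat is known: R-peak times, systolic-peak times and the RR series are
returned alongside the waveforms, so peak detectors, cycle segmentation
and the reconstruction pipeline can all be validated against analytic
truth.

Model
-----
* RR intervals follow a first-order autoregressive process around a
  mean heart rate, optionally with an abrupt heart-rate burst (mean HR
  overridden during a configured time window) of the kind seen in
  intra-operative recordings.
* Each ECG beat is a sum of five Gaussian bumps (P, Q, R, S, T) whose
  offsets and widths scale with the local RR interval; the R bump is
  the per-beat global maximum.
* Each PPG beat is a systolic Gaussian (plus an optional dicrotic
  bump) delayed relative to its R peak by the pulse-arrival time
  (PAT), with optional beat-to-beat PAT jitter.
* Channel-wise white Gaussian noise is added to reach a configured
  signal-to-noise ratio.

Everything is driven by a single :class:`numpy.random.Generator`
seeded from the config, so records are bit-reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import RecordPair, Signal

__all__ = [
    "MorphParams",
    "SimConfig",
    "SimRecord",
    "simulate_rr_series",
    "simulate_record",
    "simulate_linear_pairs",
    "simulate_subject_population",
]

# Wave tables: amplitude (a.u.), center offset and Gaussian sigma, the
# latter two as fractions of the local RR interval.  ECG offsets are
# relative to the R peak; PPG offsets relative to the systolic peak.
_DEF_ECG_WAVES = {
    "P": (0.15, -0.200, 0.040),
    "Q": (-0.10, -0.030, 0.012),
    "R": (1.00, 0.000, 0.016),
    "S": (-0.15, 0.030, 0.014),
    "T": (0.35, 0.280, 0.065),
}
_DEF_PPG_WAVES = {
    "systolic": (1.00, 0.000, 0.130),
    "dicrotic": (0.25, 0.250, 0.110),
}


@dataclass
class MorphParams:
    """Per-beat morphology templates.

    Each wave is ``name -> (amplitude, center_frac, width_frac)`` where
    the center offset and Gaussian sigma are fractions of the local RR
    interval.  ECG centers are relative to the R peak, PPG centers
    relative to the systolic peak.
    """

    ecg_waves: dict = field(default_factory=lambda: copy.deepcopy(_DEF_ECG_WAVES))
    ppg_waves: dict = field(default_factory=lambda: copy.deepcopy(_DEF_PPG_WAVES))
    include_dicrotic: bool = True


@dataclass
class SimConfig:
    """Simulation conditions for one record.

    Parameters
    ----------
    fs
        Sampling rate in Hz.
    duration_s
        Record length in seconds.
    hr_mean_bpm, hr_sd_bpm
        Mean heart rate and its beat-to-beat standard deviation in BPM.
        The RR-interval standard deviation is ``60 * hr_sd / hr_mean**2``
        seconds (first-order propagation of HR variability to RR).
    hr_burst
        Optional ``(onset_s, burst_bpm, length_s)``: the mean HR is
        overridden during that window, emulating an abrupt HR change.
    pat_s, pat_sd_s
        Mean pulse-arrival time (R peak to systolic peak) and its
        beat-to-beat jitter, in seconds.
    noise_snr_db
        Additive white-noise level per channel; ``None`` disables noise.
    ar_coeff
        Lag-1 autoregressive coefficient of the RR series.
    """

    fs: float = 300.0
    duration_s: float = 60.0
    hr_mean_bpm: float = 70.0
    hr_sd_bpm: float = 0.0
    hr_burst: Optional[tuple] = None  # (onset_s, burst_bpm, length_s)
    pat_s: float = 0.25
    pat_sd_s: float = 0.0
    noise_snr_db: Optional[float] = None
    ar_coeff: float = 0.6
    morph: MorphParams = field(default_factory=MorphParams)
    subject_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (30 <= self.hr_mean_bpm <= 220):
            raise ValueError(f"hr_mean_bpm out of range: {self.hr_mean_bpm}")
        if self.pat_s < 0:
            raise ValueError("pat_s must be non-negative")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")


@dataclass
class SimRecord:
    """A simulated record plus its ground-truth annotations."""

    record: RecordPair
    r_times_s: np.ndarray
    systolic_times_s: np.ndarray
    rr_series_s: np.ndarray
    config: SimConfig


_FIRST_R_S = 0.4  # time of the first simulated R peak


def simulate_rr_series(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Generate an AR(1) RR-interval series covering the record duration.

    The marginal standard deviation equals the configured beat-to-beat
    RR variability; during a burst window the process mean switches to
    the burst heart rate.  With ``hr_sd_bpm == 0`` and no noise source
    the series is exactly constant at ``60 / hr_mean_bpm``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rr_mean = 60.0 / config.hr_mean_bpm
    rr_sd = 60.0 * config.hr_sd_bpm / config.hr_mean_bpm**2
    phi = config.ar_coeff
    innov_sd = rr_sd * np.sqrt(max(0.0, 1.0 - phi**2))

    def mean_at(t: float) -> float:
        if config.hr_burst is not None:
            onset, burst_bpm, length = config.hr_burst
            if onset <= t < onset + length:
                return 60.0 / burst_bpm
        return rr_mean

    rrs: list[float] = []
    t = _FIRST_R_S
    dev = rng.normal(0.0, rr_sd) if rr_sd > 0 else 0.0
    while t <= config.duration_s + 1.0:
        m = mean_at(t)
        rr = float(np.clip(m + dev, 0.25, 3.0))
        rrs.append(rr)
        t += rr
        eps = rng.normal(0.0, innov_sd) if innov_sd > 0 else 0.0
        dev = phi * dev + eps
    return np.asarray(rrs)


def _add_gaussians(
    out: np.ndarray, fs: float, centers_s: np.ndarray, amps: np.ndarray, sigmas_s: np.ndarray
) -> None:
    """Accumulate Gaussian bumps into ``out`` (in-place), windowed at 5 sigma."""
    n = out.size
    for c, a, s in zip(centers_s, amps, sigmas_s):
        i0 = max(0, int(np.floor((c - 5 * s) * fs)))
        i1 = min(n, int(np.ceil((c + 5 * s) * fs)) + 1)
        if i1 <= i0:
            continue
        t = np.arange(i0, i1) / fs
        out[i0:i1] += a * np.exp(-0.5 * ((t - c) / s) ** 2)


def simulate_record(config: SimConfig) -> SimRecord:
    """Simulate one synchronized PPG/ECG record with annotations."""
    rng = np.random.default_rng(config.seed)
    rr = simulate_rr_series(config, rng)
    r_times = _FIRST_R_S + np.concatenate([[0.0], np.cumsum(rr)])
    # local RR for scaling wave widths/offsets: interval following each beat
    local_rr = np.concatenate([rr, [rr[-1]]])

    if config.pat_sd_s > 0:
        jitter = rng.normal(0.0, config.pat_sd_s, size=r_times.size)
    else:
        jitter = np.zeros(r_times.size)
    sys_times = r_times + config.pat_s + jitter

    keep = (r_times >= 0) & (sys_times < config.duration_s - 0.05)
    r_times = r_times[keep]
    sys_times = sys_times[keep]
    local_rr = local_rr[keep]
    rr_out = np.diff(r_times)

    n = int(round(config.duration_s * config.fs))
    ecg = np.zeros(n)
    ppg = np.zeros(n)
    for name, (a, off, wid) in config.morph.ecg_waves.items():
        _add_gaussians(ecg, config.fs, r_times + off * local_rr, np.full_like(r_times, a), wid * local_rr)
    for name, (a, off, wid) in config.morph.ppg_waves.items():
        if name == "dicrotic" and not config.morph.include_dicrotic:
            continue
        _add_gaussians(ppg, config.fs, sys_times + off * local_rr, np.full_like(sys_times, a), wid * local_rr)

    if config.noise_snr_db is not None:
        factor = 10.0 ** (config.noise_snr_db / 10.0)
        for chan in (ppg, ecg):
            p_sig = float(np.var(chan))
            sd = np.sqrt(p_sig / factor)
            chan += rng.normal(0.0, sd, size=n)

    record = RecordPair(
        ppg=Signal(ppg, fs=config.fs, label="ppg"),
        ecg=Signal(ecg, fs=config.fs, label="ecg"),
        subject_id=config.subject_id,
        t0=0.0,
    )
    return SimRecord(
        record=record,
        r_times_s=r_times,
        systolic_times_s=sys_times,
        rr_series_s=rr_out,
        config=config,
    )


def simulate_linear_pairs(
    n: int,
    n_ppg: int = 11,
    n_ecg: int = 100,
    L: int = 300,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Generate cycle pairs that are exactly linearly related in DCT space.

    Draws ``n`` smooth random "PPG" cycles band-limited to the first
    ``n_ppg`` DCT coefficients, fixes a random transfer matrix ``M`` of
    shape ``(n_ppg, n_ecg)``, and builds "ECG" cycles as the inverse
    DCT of ``X @ M`` plus optional sample-domain noise.  Because the
    generating map is exactly the model class, a ridge fit with a tiny
    penalty must recover ``M``; this is the end-to-end oracle for the
    transfer model.

    Returns
    -------
    (ppg_cycles, ecg_cycles, M)
        Arrays of shape ``(n, L)`` and the true map ``(n_ppg, n_ecg)``.
    """
    from scipy.fft import idct

    if n < n_ppg:
        import warnings

        warnings.warn("n < n_ppg: the design matrix is rank-deficient", stacklevel=2)
    rng = np.random.default_rng(seed)
    # decaying coefficient spectrum -> smooth cycles
    decay = 1.0 / (1.0 + np.arange(n_ppg))
    X = rng.standard_normal((n, n_ppg)) * decay
    M = rng.standard_normal((n_ppg, n_ecg)) / np.sqrt(n_ppg)
    Xf = np.zeros((n, L))
    Xf[:, :n_ppg] = X
    ppg_cycles = idct(Xf, type=2, norm="ortho", axis=1)
    Yc = X @ M
    Yf = np.zeros((n, L))
    Yf[:, :n_ecg] = Yc
    ecg_cycles = idct(Yf, type=2, norm="ortho", axis=1)
    if noise_sd > 0:
        ecg_cycles = ecg_cycles + rng.normal(0.0, noise_sd, size=ecg_cycles.shape)
    return ppg_cycles, ecg_cycles, M


def _perturbed(base: float, variation: float, rng: np.random.Generator) -> float:
    return base * (1.0 + variation * rng.uniform(-1.0, 1.0))


def simulate_subject_population(
    n_subjects: int,
    base_config: SimConfig | None = None,
    subject_variation: float = 0.3,
    seed: int = 0,
) -> list[SimRecord]:
    """Simulate a population with subject-specific morphology and PAT.

    Every non-R wave's amplitude, offset and width, the PPG wave
    shapes, and the pulse-arrival time are perturbed multiplicatively
    by up to ``+/- subject_variation`` per subject (uniform).  The R
    bump is left untouched so it stays the per-beat maximum and the
    beat anchor.  At ``subject_variation = 0`` subjects differ only in
    their noise/HRV realizations.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if base_config is None:
        base_config = SimConfig()
    master = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        cfg = copy.deepcopy(base_config)
        cfg.subject_id = f"S{i:02d}"
        cfg.seed = int(master.integers(0, 2**31 - 1))
        for name in list(cfg.morph.ecg_waves):
            if name == "R":
                continue
            a, off, wid = cfg.morph.ecg_waves[name]
            cfg.morph.ecg_waves[name] = (
                _perturbed(a, subject_variation, master),
                _perturbed(off, subject_variation, master),
                _perturbed(wid, 0.5 * subject_variation, master),
            )
        for name in list(cfg.morph.ppg_waves):
            a, off, wid = cfg.morph.ppg_waves[name]
            amp_var = 0.0 if name == "systolic" else subject_variation
            cfg.morph.ppg_waves[name] = (
                _perturbed(a, amp_var, master),
                _perturbed(off, subject_variation, master) if off else off,
                _perturbed(wid, 0.5 * subject_variation, master),
            )
        cfg.pat_s = max(0.05, _perturbed(cfg.pat_s, 0.4 * subject_variation, master))
        records.append(simulate_record(cfg))
    return records
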