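"""Peak detection and cycle segmentation of synchronized records.

A cycle is the span between two consecutive PPG systolic peaks.  Its
paired ECG segment can be chosen two ways:

* **direct** — the ECG samples at the *same timestamps* as the PPG
  cycle.  The R peak keeps its true temporal position inside the
  segment (shifted from the systolic boundary by the pulse-arrival
  time), so timing information survives, at the cost of the QRS
  landing at a slightly different position in every cycle.
* **semantic** — the ECG between the two R peaks of the *same beats*.
  Morphology is aligned beat-for-beat (every segment starts at an R
  peak), but the R peak's true timing relative to the PPG cycle is
  discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError, SegmentationError
from .io import RecordPair, Signal

__all__ = [
    "PeakTrain",
    "CyclePair",
    "detect_systolic_peaks",
    "detect_r_peaks",
    "segment_direct",
    "segment_semantic",
    "filter_cycles",
]


@dataclass
class PeakTrain:
    """Detected fiducial peaks of one channel."""

    indices: np.ndarray  # strictly increasing sample positions
    kind: str  # "systolic" | "R"
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ParameterError("peak indices must be strictly increasing")

    def times_s(self, t0: float = 0.0) -> np.ndarray:
        return t0 + self.indices / self.fs

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class CyclePair:
    """One PPG cycle and its paired ECG segment.

    ``r_time_true_s`` is the absolute time of the ground-truth R peak
    governing this cycle; it is carried only for evaluation and plays
    no role in training.
    """

    ppg_raw: np.ndarray
    ecg_raw: np.ndarray
    ppg_start_s: float
    ecg_start_s: float
    fs: float
    r_time_true_s: float
    subject_id: str
    mode: str  # "direct" | "semantic"

    @property
    def ppg_duration_s(self) -> float:
        return len(self.ppg_raw) / self.fs

    @property
    def ecg_duration_s(self) -> float:
        return len(self.ecg_raw) / self.fs


def _detect_peaks(
    x: np.ndarray,
    fs: float,
    kind: str,
    max_hr_bpm: float,
    prominence_frac: float,
    presmooth_s: float = 0.0,
    min_peaks: int = 2,
) -> PeakTrain:
    if not (30 < max_hr_bpm <= 300):
        raise ParameterError(f"max_hr_bpm must be in (30, 300], got {max_hr_bpm}")
    if not (0 < prominence_frac <= 1):
        raise ParameterError(f"prominence_frac must be in (0, 1], got {prominence_frac}")
    if presmooth_s > 0:
        # centered moving average: zero phase, stabilizes the argmax of
        # broad peaks under noise
        w = max(1, int(round(presmooth_s * fs)) | 1)
        kernel = np.ones(w) / w
        xs = np.convolve(np.pad(x, w // 2, mode="reflect"), kernel, mode="valid")
    else:
        xs = x
    distance = max(1, int(round(fs * 60.0 / max_hr_bpm)))
    lo, hi = np.percentile(xs, [5, 95])
    prominence = prominence_frac * (hi - lo)
    if prominence <= 0:
        raise SegmentationError(f"{kind}: signal has no amplitude range")
    idx, _ = find_peaks(xs, distance=distance, prominence=prominence)
    if idx.size < min_peaks:
        raise SegmentationError(f"{kind}: fewer than {min_peaks} peaks detected")
    return PeakTrain(indices=idx, kind=kind, fs=fs)


def detect_systolic_peaks(
    ppg: Signal,
    max_hr_bpm: float = 200.0,
    prominence_frac: float = 0.3,
    presmooth_s: float = 0.05,
) -> PeakTrain:
    """Detect PPG systolic peaks.

    Local maxima with a minimum inter-peak distance of
    ``60 / max_hr_bpm`` seconds and prominence at least
    ``prominence_frac`` of the robust (5th-95th percentile) amplitude
    range.  The systolic peak is broad, so the trace is pre-smoothed
    with a short centered moving average (zero phase) before the
    argmax is taken; set ``presmooth_s=0`` to disable.
    """
    return _detect_peaks(
        ppg.samples, ppg.fs, "systolic", max_hr_bpm, prominence_frac, presmooth_s
    )


def detect_r_peaks(
    ecg: Signal,
    max_hr_bpm: float = 200.0,
    prominence_frac: float = 0.3,
    polarity: str = "positive",
) -> PeakTrain:
    """Detect ECG R peaks with the same prominence/distance detector.

    The R wave is the dominant sharp deflection, so no pre-smoothing
    is applied.  For leads with a negative R deflection pass
    ``polarity="negative"`` to detect on the negated trace.  A single
    detected R is returned as-is (segmentation itself requires two).
    """
    x = ecg.samples if polarity == "positive" else -ecg.samples
    return _detect_peaks(
        x, ecg.fs, "R", max_hr_bpm, prominence_frac, presmooth_s=0.0, min_peaks=1
    )


def segment_direct(
    record: RecordPair, systolic_peaks: PeakTrain, r_peaks: PeakTrain
) -> list[CyclePair]:
    """Cut both channels at the systolic-peak timestamps.

    For each consecutive systolic-peak pair the PPG and ECG segments
    cover identical sample indices, so the segments tile the record.
    The governing ground-truth R time of a segment is the detected R
    peak closest to the segment's dominant ECG maximum.
    """
    s = systolic_peaks.indices
    if s.size < 2:
        raise SegmentationError("need at least 2 systolic peaks")
    r_times = r_peaks.times_s(record.t0)
    pairs = []
    for i in range(s.size - 1):
        s0, s1 = int(s[i]), int(s[i + 1])
        ecg_seg = record.ecg.samples[s0:s1]
        t_max = record.t0 + (s0 + int(np.argmax(ecg_seg))) / record.fs
        r_true = float(r_times[np.argmin(np.abs(r_times - t_max))])
        start = record.t0 + s0 / record.fs
        pairs.append(
            CyclePair(
                ppg_raw=record.ppg.samples[s0:s1].copy(),
                ecg_raw=ecg_seg.copy(),
                ppg_start_s=start,
                ecg_start_s=start,
                fs=record.fs,
                r_time_true_s=r_true,
                subject_id=record.subject_id,
                mode="direct",
            )
        )
    return pairs


def segment_semantic(
    record: RecordPair, systolic_peaks: PeakTrain, r_peaks: PeakTrain
) -> list[CyclePair]:
    """Pair each PPG cycle with the R-to-R interval of the same beat.

    The R peak generating a PPG cycle precedes its systolic peak by
    the pulse-arrival time, so the paired ECG segment is
    ``[R_j, R_{j+1})`` where ``R_j`` is the latest R peak at or before
    the cycle's first systolic peak.  Cycles with no such R, with no
    following R, or whose R interval is claimed by more than one PPG
    cycle (a missed or doubled detection) are dropped so the pairing
    stays one-to-one.
    """
    s = systolic_peaks.indices
    r = r_peaks.indices
    if s.size < 2 or r.size < 2:
        raise SegmentationError("need at least 2 systolic and 2 R peaks")
    assignments: list[tuple[int, int]] = []  # (cycle index i, r index j)
    for i in range(s.size - 1):
        j = int(np.searchsorted(r, s[i], side="right")) - 1
        if j < 0 or j + 1 >= r.size:
            continue
        assignments.append((i, j))
    if not assignments:
        raise SegmentationError("no PPG cycle has a preceding R peak")
    counts = np.bincount(np.array([j for _, j in assignments]), minlength=r.size)
    pairs = []
    for i, j in assignments:
        if counts[j] != 1:
            continue
        s0, s1 = int(s[i]), int(s[i + 1])
        r0, r1 = int(r[j]), int(r[j + 1])
        pairs.append(
            CyclePair(
                ppg_raw=record.ppg.samples[s0:s1].copy(),
                ecg_raw=record.ecg.samples[r0:r1].copy(),
                ppg_start_s=record.t0 + s0 / record.fs,
                ecg_start_s=record.t0 + r0 / record.fs,
                fs=record.fs,
                r_time_true_s=record.t0 + r0 / record.fs,
                subject_id=record.subject_id,
                mode="semantic",
            )
        )
    if not pairs:
        raise SegmentationError("no one-to-one PPG/ECG cycle pairs survived")
    return pairs


def filter_cycles(
    pairs: list[CyclePair], min_dur_s: float = 0.33, max_dur_s: float = 2.0
) -> list[CyclePair]:
    """Drop cycles whose PPG duration falls outside a physiologic band.

    Defaults 0.33-2.0 s (roughly 180 down to 30 BPM) guard the
    fixed-length resampling step against detector-artifact cycles.
    """
    if min_dur_s >= max_dur_s:
        raise ParameterError("min_dur_s must be < max_dur_s")
    return [p for p in pairs if min_dur_s <= p.ppg_duration_s <= max_dur_s]
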