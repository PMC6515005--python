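"""QRS detection on the band-passed ECG (Pan-Tompkins style).

Chain: five-point derivative -> point-wise squaring -> 150-ms moving-window
integration -> adaptive two-threshold peak decision with search-back.  Each
accepted detection is finally relocated to the local maximum of the
band-passed ECG so that the reported index is the R-peak itself, not the
peak of the integrated pulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["RPeakSeries", "RRStats", "detect_r_peaks", "rr_statistics"]

# Integration window: close to the average QRS duration in normal subjects.
INTEGRATION_WINDOW_MS = 150.0
REFRACTORY_MS = 200.0
SEARCHBACK_FACTOR = 1.66
R_RELOCATE_MS = 75.0
INIT_SECONDS = 2.0
# QRS pulses concentrate the record's energy into a small duty cycle, so a
# genuine beat towers over the integrated signal's median (the diastolic
# baseline); structureless noise never rises far above its own median.
# Candidates below this multiple of the median are rejected, which keeps
# the detector silent on records with no cardiac content.
NOISE_FLOOR_FACTOR = 5.0


@dataclass
class RPeakSeries:
    """Strictly increasing R-peak sample indices with their sampling rate."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) > 1:
            d = np.diff(self.indices)
            if np.any(d <= 0):
                raise ValueError("R-peak indices must be strictly increasing")
            if np.any(d < REFRACTORY_MS * self.fs / 1000.0):
                raise ValueError(
                    "consecutive R-peaks violate the 200-ms refractory period"
                )

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def times_ms(self) -> np.ndarray:
        return self.indices * 1000.0 / self.fs

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"sample_index": self.indices, "time_ms": self.times_ms}
        )


@dataclass
class RRStats:
    """Per-beat RR intervals (ms) and their arithmetic mean."""

    mean_rr: float
    per_beat_rr: np.ndarray


def _five_point_derivative(x: np.ndarray) -> np.ndarray:
    # H(z) = (1/8)(2 + z^-1 - z^-3 - 2 z^-4); linear phase, 2-sample delay.
    b = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0
    return signal.lfilter(b, 1.0, x)


def detect_r_peaks(filtered_ecg: np.ndarray, fs: float = 1000.0) -> RPeakSeries:
    """Detect R-peaks on the band-passed, delay-compensated ECG.

    Thresholds are initialised from the first 2 s of the record.  Candidate
    peaks of the integrated signal are accepted when they exceed
    ``noise + 0.25 * (signal - noise)`` (running estimates); when more than
    1.66x the running mean RR elapses without a detection, a search-back
    pass re-examines the gap at half threshold.  Accepted detections are
    mapped back to the ECG local maximum within +-75 ms of the
    delay-corrected pulse peak.
    """
    x = np.asarray(filtered_ecg, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("record shorter than 2 s: cannot initialise thresholds")

    deriv = _five_point_derivative(x)
    squared = deriv**2
    win = max(int(round(INTEGRATION_WINDOW_MS * fs / 1000.0)), 1)
    integrated = signal.lfilter(np.ones(win) / win, 1.0, squared)
    # Deterministic chain delay: 2 samples (derivative) + (win-1)/2 (MWI).
    chain_delay = 2 + (win - 1) // 2

    # Candidate peaks: local maxima of the integrated signal separated by at
    # least the refractory period.
    refr = int(round(REFRACTORY_MS * fs / 1000.0))
    cand, _ = signal.find_peaks(integrated, distance=refr)
    if len(cand) == 0:
        return RPeakSeries(indices=np.array([], dtype=int), fs=fs)

    init_n = int(INIT_SECONDS * fs)
    init_seg = integrated[:init_n]
    spki = float(np.max(init_seg)) * 0.5 if np.max(init_seg) > 0 else 0.0
    npki = float(np.mean(init_seg)) * 0.5
    floor = NOISE_FLOOR_FACTOR * float(np.median(integrated))

    accepted: list[int] = []
    rr_history: list[float] = []

    def threshold1() -> float:
        return max(npki + 0.25 * (spki - npki), floor)

    def accept(idx: int, amp: float, from_searchback: bool) -> None:
        nonlocal spki, npki
        if from_searchback:
            spki = 0.25 * amp + 0.75 * spki
        else:
            spki = 0.125 * amp + 0.875 * spki
        if accepted:
            rr_history.append(float(idx - accepted[-1]))
            if len(rr_history) > 8:
                rr_history.pop(0)
        accepted.append(idx)

    for idx in cand:
        amp = integrated[idx]
        # Search-back: the expected beat window elapsed without a detection.
        if accepted and rr_history:
            mean_rr = float(np.mean(rr_history))
            if idx - accepted[-1] > SEARCHBACK_FACTOR * mean_rr:
                gap = cand[(cand > accepted[-1] + refr) & (cand < idx)]
                if len(gap):
                    best = gap[np.argmax(integrated[gap])]
                    if integrated[best] > max(0.5 * threshold1(), floor):
                        accept(int(best), float(integrated[best]),
                               from_searchback=True)
        if amp > threshold1():
            if accepted and idx - accepted[-1] < refr:
                # Two candidates inside the refractory window: keep the
                # larger integrated amplitude.
                if amp > integrated[accepted[-1]]:
                    accepted[-1] = int(idx)
                continue
            accept(int(idx), float(amp), from_searchback=False)
        else:
            npki = 0.125 * amp + 0.875 * npki

    # Relocate each accepted pulse peak to the local ECG maximum.
    half = int(round(R_RELOCATE_MS * fs / 1000.0))
    peaks: list[int] = []
    for idx in accepted:
        center = idx - chain_delay
        lo = max(center - half, 0)
        hi = min(center + half + 1, len(x))
        if hi <= lo:
            continue
        peaks.append(lo + int(np.argmax(x[lo:hi])))

    # Deduplicate after relocation, honouring the refractory period.
    uniq: list[int] = []
    for p in sorted(set(peaks)):
        if uniq and p - uniq[-1] < refr:
            if x[p] > x[uniq[-1]]:
                uniq[-1] = p
        else:
            uniq.append(p)
    return RPeakSeries(indices=np.array(uniq, dtype=int), fs=fs)


def rr_statistics(peaks: RPeakSeries) -> RRStats:
    """Per-beat RR intervals in ms and their arithmetic mean."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 R-peaks for RR statistics")
    rr = np.diff(peaks.indices) * 1000.0 / peaks.fs
    return RRStats(mean_rr=float(np.mean(rr)), per_beat_rr=rr)
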