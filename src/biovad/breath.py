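"""Respiration filtering and breath (trough/peak) detection.

Respiration waveforms are band-pass filtered (second-order Butterworth,
zero-phase; 0.05-0.60 Hz for belt signals, 0.05-0.55 Hz for impedance) and
breath cycles are then read off the extrema: local maxima under a minimum
peak distance (default 1.65 s) are peaks, minima between consecutive peaks
(plus the minimum preceding the first and following the last peak) are
troughs.  Partial boundary cycles are dropped, so the event sequence always
starts at a trough and every retained peak is enclosed by two troughs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["BreathSeries", "bandpass", "detect_breaths",
           "BELT_BAND", "IMPEDANCE_BAND", "MIN_PEAK_DISTANCE_S"]

BELT_BAND = (0.05, 0.60)
IMPEDANCE_BAND = (0.05, 0.55)
MIN_PEAK_DISTANCE_S = 1.65


def bandpass(
    x: np.ndarray, fs: float, low: float = 0.05, high: float = 0.60, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward ``sosfiltfilt``)."""
    if not 0.0 < low < high < fs / 2:
        raise ValueError(f"invalid band edges ({low}, {high}) for fs={fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


@dataclass
class BreathSeries:
    """Alternating trough/peak events with per-cycle timing and amplitude.

    Cycle ``i`` runs trough ``i`` -> peak ``i`` -> trough ``i+1``:
    ``ti = peak_times - trough_times[:-1]`` (inspiration),
    ``te = trough_times[1:] - peak_times`` (expiration),
    ``amp_insp = peak_values - trough_values[:-1]`` and
    ``amp_exp = peak_values - trough_values[1:]``.
    A series with fewer than two cycles is flagged invalid so callers can
    emit a placeholder feature row for within-subject imputation.
    """

    trough_times: np.ndarray
    peak_times: np.ndarray
    trough_values: np.ndarray
    peak_values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.trough_times) != len(self.peak_times) + 1 and self.n_cycles > 0:
            raise ValueError("troughs must bracket peaks (n_troughs = n_peaks + 1)")
        events = np.empty(len(self.trough_times) + len(self.peak_times))
        events[0::2] = self.trough_times
        events[1::2] = self.peak_times
        if np.any(np.diff(events) <= 0):
            raise ValueError("trough/peak events must strictly alternate in time")

    @property
    def n_cycles(self) -> int:
        return len(self.peak_times)

    @property
    def valid(self) -> bool:
        return self.n_cycles >= 2

    @property
    def ti(self) -> np.ndarray:
        return self.peak_times - self.trough_times[:-1]

    @property
    def te(self) -> np.ndarray:
        return self.trough_times[1:] - self.peak_times

    @property
    def duration(self) -> np.ndarray:
        return self.ti + self.te

    @property
    def amp_insp(self) -> np.ndarray:
        return self.peak_values - self.trough_values[:-1]

    @property
    def amp_exp(self) -> np.ndarray:
        return self.peak_values - self.trough_values[1:]

    def to_dict(self) -> dict:
        """JSON-serialisable event export for offline QC of the detection."""
        return {
            "trough_times": self.trough_times.tolist(),
            "peak_times": self.peak_times.tolist(),
            "trough_values": self.trough_values.tolist(),
            "peak_values": self.peak_values.tolist(),
            "valid": self.valid,
        }

    @classmethod
    def empty(cls) -> "BreathSeries":
        z = np.empty(0)
        return cls(z, z, z.copy(), z.copy())

    @classmethod
    def from_cycles(cls, ti, te, amp_insp, t0: float = 0.0) -> "BreathSeries":
        """Build a series from per-cycle Ti/Te/amplitude arrays (troughs at 0)."""
        ti = np.asarray(ti, dtype=float)
        te = np.asarray(te, dtype=float)
        amp = np.asarray(amp_insp, dtype=float)
        starts = t0 + np.concatenate([[0.0], np.cumsum(ti + te)])
        return cls(starts, starts[:-1] + ti, np.zeros(len(starts)), amp)


def detect_breaths(
    x: np.ndarray,
    fs: float,
    min_peak_distance: float = MIN_PEAK_DISTANCE_S,
) -> BreathSeries:
    """Detect breath troughs and peaks in a (band-passed) segment.

    Peaks are local maxima at least ``min_peak_distance`` seconds apart
    (ties within the distance window keep the earlier, larger maximum, as
    ``scipy.signal.find_peaks`` removes the smaller neighbour first).
    Troughs are the minima between consecutive peaks plus the minimum before
    the first and after the last peak; a trailing minimum at the very last
    sample is ambiguous and drops the final cycle instead.  The
    ``min_peak_distance`` can be overridden per subject when a participant's
    breathing rate makes the default miss cycles.
    """
    x = np.asarray(x, dtype=float)
    dist = max(1, int(round(min_peak_distance * fs)))
    peaks, _ = sps.find_peaks(x, distance=dist)
    if len(peaks) > 0 and peaks[0] == 0:
        peaks = peaks[1:]
    if len(peaks) < 2:
        return BreathSeries.empty()

    troughs = [int(np.argmin(x[: peaks[0]]))]  # minimum preceding the first peak
    for a, b in zip(peaks[:-1], peaks[1:]):
        troughs.append(a + int(np.argmin(x[a : b + 1])))
    # minimum following the last peak; a minimum on the very boundary is
    # ambiguous (still descending) and drops the final cycle instead
    post = peaks[-1] + int(np.argmin(x[peaks[-1] :]))
    if peaks[-1] < post < len(x) - 1:
        troughs.append(post)
    else:
        peaks = peaks[:-1]
        troughs = troughs[: len(peaks) + 1]
    if len(peaks) < 2:
        return BreathSeries.empty()
    troughs = np.asarray(troughs)
    return BreathSeries(
        trough_times=troughs / fs,
        peak_times=peaks / fs,
        trough_values=x[troughs],
        peak_values=x[peaks],
    )
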