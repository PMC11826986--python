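"""Spectral/temporal feature bank for sternal vibration channels.

Voiced speech deposits a harmonic stack (85-255 Hz fundamental) on the
sternal accelerometer and gyroscope channels.  After a zero-phase 75-Hz
high-pass that removes motion content, each channel is described by 14
features per segment: eight short-frame descriptors (centroid, bandwidth,
three roll-off points, flatness, zero-crossing rate, RMS) averaged over
2048-sample frames hopped by 512 samples, plus six descriptors of the
full-segment FFT (entropy, crest, skewness, kurtosis, variance, mean
magnitude).  Six channels x 14 = 84 features.

All spectra are one-sided magnitude spectra with the DC bin excluded (DC is
meaningless after high-pass filtering); magnitude (not power) weighting is
used for the frequency moments, while flatness follows its standard
definition on the power spectrum.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.stats import entropy as _scipy_entropy

__all__ = [
    "FRAMED_FEATURE_NAMES",
    "FULLFFT_FEATURE_NAMES",
    "SPECTRAL_FEATURE_NAMES",
    "highpass_voicing",
    "framed_features",
    "fullsegment_fft_features",
    "accgyro_feature_vector",
]

FRAMED_FEATURE_NAMES = (
    "centroid", "bandwidth", "rolloff25", "rolloff50", "rolloff85",
    "flatness", "zcr", "rms",
)
FULLFFT_FEATURE_NAMES = (
    "entropy", "crest", "skewness", "kurtosis", "variance", "mean_mag",
)
SPECTRAL_FEATURE_NAMES = FRAMED_FEATURE_NAMES + FULLFFT_FEATURE_NAMES


def highpass_voicing(
    x: np.ndarray, fs: float, cutoff: float = 75.0, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth high-pass isolating the voiced band."""
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz invalid for fs={fs} Hz")
    sos = sps.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def _mag_spectrum(frame: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum excluding the DC bin."""
    mag = np.abs(np.fft.rfft(frame))[1:]
    freqs = np.fft.rfftfreq(len(frame), d=1.0 / fs)[1:]
    return freqs, mag


def framed_features(
    x: np.ndarray, fs: float, frame: int = 2048, hop: int = 512
) -> dict[str, float]:
    """Frame-averaged spectral descriptors plus ZCR and RMS.

    Rectangular frames of ``frame`` samples every ``hop`` samples; per-frame
    values are simply averaged over the segment.  Roll-off points are the
    lowest frequency below which 25/50/85 % of the cumulative magnitude lies.
    ZCR is reported per sample (sign changes / frame length).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < frame:
        raise ValueError(f"segment of {len(x)} samples shorter than one frame ({frame})")
    starts = range(0, len(x) - frame + 1, hop)
    acc = {k: 0.0 for k in FRAMED_FEATURE_NAMES}
    n_frames = 0
    for s in starts:
        seg = x[s : s + frame]
        freqs, mag = _mag_spectrum(seg, fs)
        total = mag.sum()
        if total > 0:
            w = mag / total
            centroid = float(freqs @ w)
            bandwidth = float(np.sqrt(((freqs - centroid) ** 2) @ w))
            cum = np.cumsum(w)
            rolloffs = [float(freqs[np.searchsorted(cum, p)]) for p in (0.25, 0.50, 0.85)]
            power = mag**2
            flatness = float(
                np.exp(np.mean(np.log(power + 1e-300))) / np.mean(power)
            )
        else:
            centroid = bandwidth = flatness = 0.0
            rolloffs = [0.0, 0.0, 0.0]
        acc["centroid"] += centroid
        acc["bandwidth"] += bandwidth
        acc["rolloff25"] += rolloffs[0]
        acc["rolloff50"] += rolloffs[1]
        acc["rolloff85"] += rolloffs[2]
        acc["flatness"] += flatness
        acc["zcr"] += float(np.count_nonzero(np.diff(np.signbit(seg)))) / frame
        acc["rms"] += float(np.sqrt(np.mean(seg**2)))
        n_frames += 1
    return {k: v / n_frames for k, v in acc.items()}


def fullsegment_fft_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """Whole-segment FFT descriptors.

    On the one-sided magnitude spectrum (DC excluded): Shannon entropy in
    bits of the magnitude-normalised distribution; crest = max magnitude over
    summed magnitude; skewness and kurtosis as the 3rd/4th magnitude-weighted
    frequency moments about the centroid, normalised by bandwidth^3 and
    bandwidth^4; variance of the raw bin magnitudes (unweighted by
    frequency); and the mean bin magnitude.
    """
    x = np.asarray(x, dtype=float)
    freqs, mag = _mag_spectrum(x, fs)
    total = mag.sum()
    if total == 0:
        raise ValueError("all-zero segment has no spectrum")
    w = mag / total
    ent = float(_scipy_entropy(w, base=2))
    crest = float(mag.max() / total)
    centroid = float(freqs @ w)
    bw = float(np.sqrt(((freqs - centroid) ** 2) @ w))
    if bw > 0:
        skew = float((((freqs - centroid) ** 3) @ w) / bw**3)
        kurt = float((((freqs - centroid) ** 4) @ w) / bw**4)
    else:
        skew, kurt = 0.0, 0.0
    return {
        "entropy": ent,
        "crest": crest,
        "skewness": skew,
        "kurtosis": kurt,
        "variance": float(np.var(mag)),
        "mean_mag": float(total / len(mag)),
    }


def accgyro_feature_vector(
    channels: dict[str, np.ndarray], fs: float, *, frame: int = 2048, hop: int = 512
) -> dict[str, float]:
    """Compute the 84-field vector (14 features per vibration channel).

    ``channels`` must contain exactly the six sensor channels of one
    segment, already high-pass filtered.  Axis convention: z = sagittal
    (anterior-posterior, perpendicular to the sternum), y =
    superior-inferior, x = medial-lateral.
    """
    expected = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")
    if set(channels) != set(expected):
        raise ValueError(f"expected channels {expected}, got {sorted(channels)}")
    out: dict[str, float] = {}
    for name in expected:
        feats = framed_features(channels[name], fs, frame=frame, hop=hop)
        feats.update(fullsegment_fft_features(channels[name], fs))
        out.update({f"{name}_{k}": v for k, v in feats.items()})
    return out
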