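"""Device alignment, fixed-window segmentation, and display normalization."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .protocol import ProtocolBlock
from .recording import Channel, MultiChannelRecording

__all__ = [
    "Segment",
    "align_by_crosscorrelation",
    "segmentize",
    "robust_minmax_normalize",
]


@dataclass
class Segment:
    """One fixed-length labeled analysis window across all channels.

    ``channels`` maps channel name to ``(samples, fs)`` for exactly
    ``window_s`` seconds; ``label`` is the enclosing block's speech flag.
    """

    subject_id: str
    index: int
    t_start: float
    window_s: float
    label: int
    block: ProtocolBlock
    channels: dict[str, tuple[np.ndarray, float]]


def _resample_to(x: np.ndarray, fs: float, fs_target: float) -> np.ndarray:
    if fs == fs_target:
        return np.asarray(x, dtype=float)
    frac = Fraction(fs_target / fs).limit_denominator(10_000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


def align_by_crosscorrelation(
    reference: Channel, other: Channel, *, min_overlap_s: float = 60.0,
    warn_threshold: float = 0.5,
) -> float:
    """Lag (seconds) of ``other`` relative to ``reference`` maximising their
    normalized cross-correlation.

    A positive lag means ``other`` is delayed: ``other(t) = reference(t - lag)``.
    Both channels are polyphase-resampled to the lower of the two rates and
    z-scored before correlating.  The returned lag is meant to be applied to
    *all* channels of the other device.  A warning is emitted when the peak
    correlation coefficient falls below ``warn_threshold`` (alignment
    unreliable).
    """
    if reference.duration_s < min_overlap_s or other.duration_s < min_overlap_s:
        raise ValueError(f"channels must overlap at least {min_overlap_s} s")
    fs = min(reference.fs, other.fs)
    a = _resample_to(other.samples, other.fs, fs)
    b = _resample_to(reference.samples, reference.fs, fs)
    a = (a - a.mean()) / (a.std() + 1e-12)
    b = (b - b.mean()) / (b.std() + 1e-12)
    c = sps.correlate(a, b, mode="full")
    lags = sps.correlation_lags(len(a), len(b), mode="full")
    best = int(np.argmax(c))
    overlap = np.minimum(
        np.minimum(np.arange(1, len(c) + 1), np.arange(len(c), 0, -1)),
        min(len(a), len(b)),
    )
    peak_r = c[best] / overlap[best]
    if peak_r < warn_threshold:
        warnings.warn(
            f"peak cross-correlation {peak_r:.2f} below {warn_threshold}; "
            "alignment may be unreliable",
            UserWarning,
            stacklevel=2,
        )
    return float(lags[best] / fs)


def segmentize(
    recording: MultiChannelRecording, window_s: float = 30.0
) -> list[Segment]:
    """Cut a recording into contiguous non-overlapping labeled windows.

    Windows are half-open ``[t, t + window_s)`` with 0-based sample indexing
    and never straddle block boundaries; every block duration must be
    divisible by ``window_s`` (a partial trailing window raises).  The
    default laboratory schedule yields 66 windows at 30 s and 660 at 3 s.
    """
    segments: list[Segment] = []
    idx = 0
    for start, block in recording.annotations:
        n_win, rem = divmod(block.duration_s, window_s)
        if rem != 0:
            raise ValueError(
                f"block of {block.duration_s}s not divisible by window {window_s}s"
            )
        for w in range(int(n_win)):
            t0 = start + w * window_s
            chans = {}
            for name, ch in recording.channels.items():
                i0 = int(round(t0 * ch.fs))
                i1 = int(round((t0 + window_s) * ch.fs))
                chans[name] = (ch.samples[i0:i1], ch.fs)
            segments.append(
                Segment(
                    subject_id=recording.subject_id,
                    index=idx,
                    t_start=t0,
                    window_s=window_s,
                    label=int(block.speech),
                    block=block,
                    channels=chans,
                )
            )
            idx += 1
    return segments


def robust_minmax_normalize(x: np.ndarray, sd_clip: float = 4.5) -> np.ndarray:
    """Min-max scale to [0, 1] with outlier-robust range estimation.

    Samples deviating more than ``sd_clip`` standard deviations from the mean
    are excluded when estimating the min and max; the affine map is then
    applied to *all* samples, so clipped-range outliers may map outside
    [0, 1].  Raises on a constant signal (zero range).
    """
    x = np.asarray(x, dtype=float)
    mu, sd = x.mean(), x.std()
    keep = np.abs(x - mu) <= sd_clip * sd
    if not np.any(keep):
        keep = np.ones_like(x, dtype=bool)
    mn, mx = x[keep].min(), x[keep].max()
    if mx == mn:
        raise ValueError("constant signal has zero range; cannot normalize")
    return (x - mn) / (mx - mn)
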