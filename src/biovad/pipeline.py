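"""End-to-end feature extraction: recordings -> per-method feature tables.

A *method* is one sensing modality evaluated for speech detection:

* ``rip1``    — thorax respiration belt only (21 features),
* ``rip2``    — thorax + abdomen belts (42 features),
* ``imp``     — impedance pneumography (21 features),
* ``accgyro`` — six sternal vibration channels (84 features).

Each method yields one row per 30-s window with ``subject_id``,
``segment_idx`` and the speech ``label``; invalid respiration windows (fewer
than two detected breaths) become missing rows imputed within subject.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .breath import BELT_BAND, IMPEDANCE_BAND, MIN_PEAK_DISTANCE_S, bandpass, detect_breaths
from .recording import MultiChannelRecording
from .resp_features import (
    dual_band_vector,
    impute_within_subject,
    missing_feature_vector,
    resp_feature_vector,
)
from .spectral import accgyro_feature_vector, highpass_voicing
from .windowing import Segment, segmentize

__all__ = ["METHODS", "segment_features", "features_for_recording", "cohort_feature_table"]

METHODS = ("rip1", "rip2", "imp", "accgyro")

_VIB_NAMES = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")


def _resp_vector(
    samples: np.ndarray, fs: float, band: tuple[float, float], min_peak_distance: float
) -> dict[str, float]:
    filtered = bandpass(samples, fs, *band)
    breaths = detect_breaths(filtered, fs, min_peak_distance)
    if not breaths.valid:
        return missing_feature_vector()
    return resp_feature_vector(breaths)


def segment_features(
    seg: Segment, method: str, *, min_peak_distance: float = MIN_PEAK_DISTANCE_S
) -> dict[str, float]:
    """Feature vector of one window for one method."""
    if method == "rip1":
        x, fs = seg.channels["rip_thorax"]
        return _resp_vector(x, fs, BELT_BAND, min_peak_distance)
    if method == "rip2":
        thx, fs_t = seg.channels["rip_thorax"]
        abd, fs_a = seg.channels["rip_abdomen"]
        return dual_band_vector(
            _resp_vector(thx, fs_t, BELT_BAND, min_peak_distance),
            _resp_vector(abd, fs_a, BELT_BAND, min_peak_distance),
            thorax_segment=seg.index,
            abdomen_segment=seg.index,
        )
    if method == "imp":
        x, fs = seg.channels["imp"]
        return _resp_vector(x, fs, IMPEDANCE_BAND, min_peak_distance)
    if method == "accgyro":
        fs = seg.channels["acc_z"][1]
        filtered = {
            name: highpass_voicing(seg.channels[name][0], fs) for name in _VIB_NAMES
        }
        return accgyro_feature_vector(filtered, fs)
    raise ValueError(f"unknown method '{method}' (expected one of {METHODS})")


def features_for_recording(
    rec: MultiChannelRecording,
    method: str,
    window_s: float = 30.0,
    *,
    min_peak_distance: float = MIN_PEAK_DISTANCE_S,
) -> pd.DataFrame:
    """One row per window for one subject (no imputation yet)."""
    rows = []
    for seg in segmentize(rec, window_s):
        vec = segment_features(seg, method, min_peak_distance=min_peak_distance)
        rows.append(
            {"subject_id": seg.subject_id, "segment_idx": seg.index, "label": seg.label, **vec}
        )
    return pd.DataFrame(rows)


def cohort_feature_table(
    recordings: Iterable[MultiChannelRecording],
    method: str,
    window_s: float = 30.0,
    *,
    impute: bool = True,
) -> pd.DataFrame:
    """Stack per-subject feature tables and impute missing cells within subject.

    ``recordings`` may be a lazy iterator; subjects are processed one at a
    time so full cohorts never need to be materialised in memory.
    """
    frames = [features_for_recording(rec, method, window_s) for rec in recordings]
    table = pd.concat(frames, ignore_index=True)
    if impute:
        table = impute_within_subject(table)
    return table
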