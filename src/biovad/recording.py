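"""In-memory containers for synchronized multi-channel recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import ProtocolBlock

__all__ = ["Channel", "MultiChannelRecording"]


@dataclass
class Channel:
    """A single uniformly sampled signal (arbitrary physical units)."""

    samples: np.ndarray
    fs: float
    t0_offset: float = 0.0

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class MultiChannelRecording:
    """Synchronized named channels for one subject plus block annotations.

    ``annotations`` holds ``(start_s, block)`` pairs covering the schedule;
    ``ground_truth`` is the per-30-s-segment speech label (1/0).  ``truth``
    carries simulator-internal ground truth (breath event times, subject
    profile) when the recording is synthetic; it is empty for ingested data.
    """

    subject_id: str
    channels: dict[str, Channel]
    annotations: list[tuple[float, ProtocolBlock]]
    ground_truth: np.ndarray
    truth: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return float(sum(b.duration_s for _, b in self.annotations))

    def channel(self, name: str) -> Channel:
        return self.channels[name]
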