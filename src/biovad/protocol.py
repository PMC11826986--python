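"""Laboratory speech-task protocol: labeled condition blocks.

The protocol alternates vocalised and silent versions of several everyday
speech tasks (reading, conversation, mental arithmetic) across postures, so
that a detector trained on it sees speech and silence under matched cognitive
and postural load.  Every block lasts a multiple of 30 s, which makes the
30-s windowing exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Condition",
    "Posture",
    "ProtocolBlock",
    "make_default_protocol",
    "schedule_duration",
    "segment_labels",
]


class Condition(str, enum.Enum):
    BASELINE = "baseline"
    READING = "reading"
    CONVERSATION = "conversation"
    WALKING_READING = "walking_reading"
    SERIAL_SUBTRACTION = "serial_subtraction"


class Posture(str, enum.Enum):
    SUPINE = "supine"
    SITTING = "sitting"
    STANDING = "standing"
    WALKING = "walking"


@dataclass(frozen=True)
class ProtocolBlock:
    """One homogeneous condition block.

    ``speech`` is constant within a block; ``duration_s`` must be a positive
    multiple of 30 so blocks cut exactly into 30-s analysis windows.
    """

    condition: Condition
    posture: Posture
    speech: bool
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.duration_s % 30 != 0:
            raise ValueError(
                f"block duration must be a positive multiple of 30 s, got {self.duration_s}"
            )


def make_default_protocol() -> list[ProtocolBlock]:
    """Return the default laboratory schedule (1980 s, 66 30-s segments).

    Structure per subject:

    * silent baseline: 180 s in each of supine, sitting, standing;
    * reading a neutral text: per posture, 90 s aloud then 90 s silent;
    * semi-structured conversation: 18 questions of 30 s each, alternating
      aloud / silent (in thought), six per posture;
    * reading while walking: 90 s aloud then 90 s silent on a treadmill;
    * serial subtraction (seated): 6 x 30 s alternating aloud / silent.

    Speech-labeled time totals 24 of the 66 segments (36.4 %).
    """
    blocks: list[ProtocolBlock] = []
    postures = (Posture.SUPINE, Posture.SITTING, Posture.STANDING)

    for posture in postures:
        blocks.append(ProtocolBlock(Condition.BASELINE, posture, False, 180))

    for posture in postures:
        blocks.append(ProtocolBlock(Condition.READING, posture, True, 90))
        blocks.append(ProtocolBlock(Condition.READING, posture, False, 90))

    for posture in postures:
        for q in range(6):
            blocks.append(
                ProtocolBlock(Condition.CONVERSATION, posture, q % 2 == 0, 30)
            )

    blocks.append(ProtocolBlock(Condition.WALKING_READING, Posture.WALKING, True, 90))
    blocks.append(ProtocolBlock(Condition.WALKING_READING, Posture.WALKING, False, 90))

    for q in range(6):
        blocks.append(
            ProtocolBlock(Condition.SERIAL_SUBTRACTION, Posture.SITTING, q % 2 == 0, 30)
        )

    return blocks


def schedule_duration(schedule: list[ProtocolBlock]) -> float:
    """Total duration of a schedule in seconds."""
    return float(sum(b.duration_s for b in schedule))


def segment_labels(schedule: list[ProtocolBlock], window_s: float = 30.0) -> list[int]:
    """Per-window speech labels (1 = speech, 0 = no speech) for a schedule.

    Raises if any block duration is not divisible by ``window_s``.
    """
    labels: list[int] = []
    for block in schedule:
        n, rem = divmod(block.duration_s, window_s)
        if rem != 0:
            raise ValueError(
                f"block duration {block.duration_s}s not divisible by window {window_s}s"
            )
        labels.extend([int(block.speech)] * int(n))
    return labels
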