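"""Synthetic cohort simulator for respiration and sternal vibration channels.

The simulator emulates the statistical structure a speech detector exploits:

* **Respiration** — speech shortens inspiration relative to expiration
  (lower Ti/Te ratio), slightly lowers the respiratory rate, and roughly
  doubles breath-to-breath variability of the expiratory time.  Each breath
  is rendered as a half-cosine rise over the inspiratory time Ti followed by
  a half-cosine fall over the expiratory time Te, scaled by a per-breath
  amplitude draw, with additive Gaussian noise and slow baseline drift.
  The impedance-style variant adds a small cardiac-frequency artifact.
* **Sternal vibration** — voiced speech adds a harmonic stack at the vocal
  fundamental f0 (85-255 Hz) to broadband sensor noise, strongest on the
  sagittal (anterior-posterior) accelerometer axis, gated on/off at the
  voicing duty cycle.  Walking adds large sub-10-Hz gait components to all
  six channels regardless of speech.

Amplitudes are arbitrary units throughout: the signals are uncalibrated, as
belt and impedance respiration traces are in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .protocol import (
    Posture,
    ProtocolBlock,
    make_default_protocol,
    schedule_duration,
    segment_labels,
)
from .recording import Channel, MultiChannelRecording

__all__ = [
    "SubjectProfile",
    "BreathCycle",
    "simulate_breath_cycles",
    "render_respiration",
    "simulate_respiration",
    "simulate_accgyro",
    "draw_profile",
    "simulate_cohort",
    "simulate_free_living",
    "VIB_CHANNELS",
]

#: voiced-stack gain per vibration channel; the sagittal accelerometer axis
#: (perpendicular to the sternum) picks up vocal-fold vibration best, the
#: gyroscope channels carry the same content at much lower SNR.
VIB_CHANNELS: dict[str, float] = {
    "acc_x": 0.35,
    "acc_y": 0.35,
    "acc_z": 1.0,
    "gyro_x": 0.12,
    "gyro_y": 0.12,
    "gyro_z": 0.12,
}

F0_MALE = (85.0, 155.0)
F0_FEMALE = (165.0, 255.0)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generative parameters.

    Respiratory-state defaults follow typical laboratory task means: silent
    breathing around 16 breaths/min with Ti/Te ~ 0.85, speech around
    14.5 breaths/min with Ti/Te ~ 0.65 and about twice the expiratory-time
    variability.  ``f0`` is the vocal fundamental in Hz (85-155 Hz for adult
    males, 165-255 Hz for females).
    """

    rr_silent: float = 16.0
    rr_speech: float = 14.5
    ie_silent: float = 0.85
    ie_speech: float = 0.65
    ie_sd_silent: float = 0.09
    ie_sd_speech: float = 0.13
    te_sd_silent: float = 0.15
    te_sd_speech: float = 0.30
    amp_mean: float = 1.0
    amp_sd: float = 0.12
    f0: float = 120.0
    n_harmonics: int = 3
    voicing_duty: float = 0.5
    voice_amp: float = 0.15
    motion_amp: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rr_silent", "rr_speech"):
            v = getattr(self, name)
            if not 4.0 < v < 40.0:
                raise ValueError(f"{name}={v} outside plausible (4, 40) breaths/min")
        if self.ie_speech >= self.ie_silent:
            raise ValueError("speech must shorten inspiration: ie_speech < ie_silent")
        if not 85.0 <= self.f0 <= 255.0:
            raise ValueError(f"f0={self.f0} outside the voiced band [85, 255] Hz")
        if self.te_sd_speech <= self.te_sd_silent:
            raise ValueError("speech must increase Te variability")
        if not 0.0 <= self.voicing_duty <= 1.0:
            raise ValueError("voicing_duty must lie in [0, 1]")


@dataclass(frozen=True)
class BreathCycle:
    """One breath: trough at ``t0``, peak at ``t0 + ti``, next trough at
    ``t0 + ti + te``; ``amp`` is the inspiratory (= expiratory) excursion."""

    t0: float
    ti: float
    te: float
    amp: float

    @property
    def peak_time(self) -> float:
        return self.t0 + self.ti

    @property
    def end(self) -> float:
        return self.t0 + self.ti + self.te

    @property
    def duration(self) -> float:
        return self.ti + self.te


def _state_params(profile: SubjectProfile, speech: bool):
    if speech:
        return (
            profile.rr_speech,
            profile.ie_speech,
            profile.ie_sd_speech,
            profile.te_sd_speech,
        )
    return (
        profile.rr_silent,
        profile.ie_silent,
        profile.ie_sd_silent,
        profile.te_sd_silent,
    )


def simulate_breath_cycles(
    profile: SubjectProfile,
    schedule: list[ProtocolBlock],
    seed: int | np.random.SeedSequence,
) -> list[BreathCycle]:
    """Draw the ground-truth breath-cycle sequence for a schedule.

    Per breath in a block, the expiratory time Te is drawn around the
    state's base value with the state's SD, the ratio Ti/Te around the
    state's IE ratio, so the mean total period approximates 60/RR.  Only
    cycles that complete inside their block are kept; block boundaries
    therefore reset the breathing phase.
    """
    rng = np.random.default_rng(seed)
    cycles: list[BreathCycle] = []
    block_start = 0.0
    for block in schedule:
        rr, ie, ie_sd, te_sd = _state_params(profile, block.speech)
        d_target = 60.0 / rr
        te_base = d_target / (1.0 + ie)
        t = 0.0
        while True:
            te = max(0.4, rng.normal(te_base, te_sd))
            ratio = max(0.2, rng.normal(ie, ie_sd))
            ti = ratio * te
            if t + ti + te > block.duration_s:
                break
            amp = max(0.05 * profile.amp_mean, rng.normal(profile.amp_mean, profile.amp_sd))
            cycles.append(BreathCycle(block_start + t, ti, te, amp))
            t += ti + te
        block_start += block.duration_s
    return cycles


def render_respiration(
    cycles: list[BreathCycle],
    duration_s: float,
    fs: float,
    seed: int | np.random.SeedSequence | None = None,
    *,
    amp_scale: float = 1.0,
    noise_sd: float = 0.02,
    drift_amp: float = 0.08,
    drift_freq: float = 0.01,
    cardiac: bool = False,
    cardiac_freq: float = 1.2,
    cardiac_rel_amp: float = 0.05,
) -> np.ndarray:
    """Render a breath-cycle sequence to a sampled waveform.

    Each cycle rises from baseline 0 to ``amp`` with a half cosine over Ti
    and falls back over Te.  Noise, drift and (optionally) a sinusoidal
    cardiac artifact are additive.
    """
    if cardiac and fs <= 2.0 * cardiac_freq:
        raise ValueError(
            f"fs={fs} Hz cannot represent a {cardiac_freq} Hz cardiac artifact"
        )
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    for c in cycles:
        i0 = int(math.ceil(c.t0 * fs))
        i1 = int(math.ceil(c.peak_time * fs))
        i2 = min(int(math.ceil(c.end * fs)), n)
        a = amp_scale * c.amp
        t_rise = np.arange(i0, i1) / fs - c.t0
        x[i0:i1] = a * 0.5 * (1.0 - np.cos(np.pi * t_rise / c.ti))
        t_fall = np.arange(i1, i2) / fs - c.peak_time
        x[i1:i2] = a * 0.5 * (1.0 + np.cos(np.pi * t_fall / c.te))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    if drift_amp > 0:
        x += drift_amp * np.sin(2 * np.pi * drift_freq * t + rng.uniform(0, 2 * np.pi))
    if cardiac:
        mean_amp = amp_scale * float(np.mean([c.amp for c in cycles])) if cycles else 1.0
        x += cardiac_rel_amp * mean_amp * np.sin(
            2 * np.pi * cardiac_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
    return x


def simulate_respiration(
    profile: SubjectProfile,
    schedule: list[ProtocolBlock],
    fs: float,
    seed: int | np.random.SeedSequence,
    **render_kwargs,
) -> np.ndarray:
    """Simulate one respiration channel over a schedule.

    Convenience wrapper: draws breath cycles and renders them.  The cycle
    draw and the noise use independent sub-streams of ``seed``, so
    :func:`simulate_breath_cycles` with the same seed returns exactly the
    ground-truth cycles underlying the waveform.
    """
    if fs < 25:
        raise ValueError(f"respiration sampling rate {fs} Hz too low (need >= 25)")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cycles, s_noise = seq.spawn(2)
    cycles = simulate_breath_cycles(profile, schedule, s_cycles)
    return render_respiration(
        cycles, schedule_duration(schedule), fs, s_noise, **render_kwargs
    )


def _voiced_intervals(
    duration_s: float, duty: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Random on/off voicing bursts with the requested duty cycle."""
    if duty <= 0:
        return []
    if duty >= 1:
        return [(0.0, duration_s)]
    mean_on = 1.0
    mean_off = mean_on * (1.0 - duty) / duty
    out: list[tuple[float, float]] = []
    t = float(rng.exponential(mean_off / 2))
    while t < duration_s:
        on = float(np.clip(rng.exponential(mean_on), 0.3, 3.0))
        end = min(t + on, duration_s)
        out.append((t, end))
        t = end + float(np.clip(rng.exponential(mean_off), 0.2, 3.0 * mean_off + 0.2))
    return out


def simulate_accgyro(
    profile: SubjectProfile,
    schedule: list[ProtocolBlock],
    fs: float,
    seed: int | np.random.SeedSequence,
    *,
    noise_sd: float = 0.02,
    gait_freq: float = 1.8,
) -> dict[str, np.ndarray]:
    """Simulate the six sternal accelerometer/gyroscope channels.

    During speech blocks, voiced bursts add a harmonic stack at f0, 2 f0, ...
    with amplitudes halving per harmonic, scaled per channel by
    :data:`VIB_CHANNELS`.  Walking blocks add gait components at the step
    frequency and its first harmonic (all below 10 Hz) to every channel.
    """
    if fs < 510:
        raise ValueError(f"fs={fs} Hz too low to represent the voiced band (need >= 510)")
    if profile.f0 * profile.n_harmonics >= fs / 2:
        raise ValueError(
            f"highest harmonic {profile.f0 * profile.n_harmonics:.0f} Hz aliases at fs={fs} Hz"
        )
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seq)
    n_total = int(round(schedule_duration(schedule) * fs))
    channels = {
        name: rng.normal(0.0, noise_sd, n_total) for name in VIB_CHANNELS
    }

    harmonic_amps = np.array([0.5**k for k in range(profile.n_harmonics)])
    block_start = 0.0
    for block in schedule:
        i0 = int(round(block_start * fs))
        i1 = int(round((block_start + block.duration_s) * fs))
        t_block = np.arange(i1 - i0) / fs
        if block.speech:
            for on, off in _voiced_intervals(block.duration_s, profile.voicing_duty, rng):
                j0, j1 = int(round(on * fs)), int(round(off * fs))
                t = t_block[j0:j1]
                stack = np.zeros(j1 - j0)
                for k, a in enumerate(harmonic_amps, start=1):
                    stack += a * np.sin(
                        2 * np.pi * k * profile.f0 * t + rng.uniform(0, 2 * np.pi)
                    )
                for name, gain in VIB_CHANNELS.items():
                    channels[name][i0 + j0 : i0 + j1] += (
                        profile.voice_amp * gain * stack
                    )
        if block.posture is Posture.WALKING:
            for name in VIB_CHANNELS:
                gait = profile.motion_amp * (
                    np.sin(2 * np.pi * gait_freq * t_block + rng.uniform(0, 2 * np.pi))
                    + 0.4
                    * np.sin(2 * np.pi * 2 * gait_freq * t_block + rng.uniform(0, 2 * np.pi))
                )
                channels[name][i0:i1] += gait
        block_start += block.duration_s
    return channels


def draw_profile(rng: np.random.Generator, seed: int = 0) -> SubjectProfile:
    """Draw one subject's profile from the population distributions.

    The population is 75 % female (f0 uniform on 165-255 Hz) and 25 % male
    (85-155 Hz); respiratory-state parameters vary around the laboratory
    task means with between-subject SDs of about 2 breaths/min (rate) and
    0.07 (IE ratio).
    """
    rr_silent = float(np.clip(rng.normal(16.0, 2.0), 10.0, 28.0))
    rr_speech = float(np.clip(rng.normal(14.5, 1.8), 8.0, rr_silent + 1.0))
    ie_silent = float(np.clip(rng.normal(0.85, 0.07), 0.6, 1.1))
    ie_speech = float(np.clip(rng.normal(0.65, 0.07), 0.35, ie_silent - 0.08))
    te_sd_silent = float(rng.uniform(0.10, 0.20))
    te_sd_speech = te_sd_silent * float(rng.uniform(1.8, 2.4))
    female = rng.random() < 0.75
    lo, hi = F0_FEMALE if female else F0_MALE
    f0 = float(rng.uniform(lo, hi))
    # keep the harmonic stack below the 500 Hz Nyquist of 1000-Hz sensors
    n_harmonics = int(min(3, max(1, 499.0 // f0)))
    return SubjectProfile(
        rr_silent=rr_silent,
        rr_speech=rr_speech,
        ie_silent=ie_silent,
        ie_speech=ie_speech,
        te_sd_silent=te_sd_silent,
        te_sd_speech=te_sd_speech,
        amp_mean=float(rng.uniform(0.8, 1.2)),
        amp_sd=float(rng.uniform(0.08, 0.15)),
        f0=f0,
        n_harmonics=n_harmonics,
        voicing_duty=float(rng.uniform(0.45, 0.65)),
        voice_amp=float(rng.uniform(0.12, 0.20)),
        motion_amp=float(rng.uniform(0.3, 0.7)),
        seed=seed,
    )


def simulate_cohort(
    n_subjects: int,
    seed: int,
    *,
    fs_resp: float = 128.0,
    fs_imp: float = 250.0,
    fs_vib: float = 1000.0,
    include_vib: bool = True,
    schedule: list[ProtocolBlock] | None = None,
) -> Iterator[MultiChannelRecording]:
    """Yield ``n_subjects`` synthetic recordings, one subject at a time.

    Channels per subject: ``rip_thorax`` and ``rip_abdomen`` belts (default
    128 Hz, same breath cycles, abdomen at 80 % amplitude), ``imp`` impedance
    (default 250 Hz, with cardiac artifact), and the six vibration channels
    (default 1000 Hz; ``include_vib=False`` skips them, e.g. for label or
    respiration-only work).  Lazily evaluated: a full cohort of 1000-Hz
    six-channel data is large, so callers stream subject by subject
    (``list()`` materialises it when small).  Bit-reproducible under a fixed
    seed.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if schedule is None:
        schedule = make_default_protocol()
    labels = np.asarray(segment_labels(schedule), dtype=int)
    starts = np.concatenate([[0.0], np.cumsum([b.duration_s for b in schedule])])[:-1]
    annotations = list(zip(starts.tolist(), schedule))
    duration = schedule_duration(schedule)

    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(n_subjects)):
        s_prof, s_cyc, s_thx, s_abd, s_imp, s_vib = child.spawn(6)
        profile = draw_profile(np.random.default_rng(s_prof), seed=i)
        cycles = simulate_breath_cycles(profile, schedule, s_cyc)
        channels = {
            "rip_thorax": Channel(
                render_respiration(cycles, duration, fs_resp, s_thx), fs_resp
            ),
            "rip_abdomen": Channel(
                render_respiration(cycles, duration, fs_resp, s_abd, amp_scale=0.8),
                fs_resp,
            ),
            "imp": Channel(
                render_respiration(
                    cycles, duration, fs_imp, s_imp, amp_scale=0.9, cardiac=True
                ),
                fs_imp,
            ),
        }
        if include_vib:
            for name, x in simulate_accgyro(profile, schedule, fs_vib, s_vib).items():
                channels[name] = Channel(x, fs_vib)
        yield MultiChannelRecording(
            subject_id=f"S{i:03d}",
            channels=channels,
            annotations=annotations,
            ground_truth=labels.copy(),
            truth={"profile": profile, "cycles": cycles},
        )


def simulate_free_living(
    duration_s: float,
    seed: int,
    *,
    profile: SubjectProfile | None = None,
    fs_resp: float = 128.0,
    fs_vib: float = 1000.0,
    mean_episode_s: float = 20.0,
    window_s: float = 30.0,
) -> MultiChannelRecording:
    """Simulate a free-living recording with partial-speech windows.

    Speech episodes start at random times with exponential durations, so a
    30-s window may contain any fraction of speech; ``ground_truth`` holds
    that fraction per window rather than a binary label.  Intended for
    exploring detector behaviour on mixed windows; the laboratory protocol
    (pure blocks) remains the default everywhere else.
    """
    seq = np.random.SeedSequence(seed)
    s_prof, s_sched, s_resp, s_vib = seq.spawn(4)
    if profile is None:
        profile = draw_profile(np.random.default_rng(s_prof))
    rng = np.random.default_rng(s_sched)
    # carve the timeline into alternating silent/speech episodes (1-s grid)
    blocks: list[ProtocolBlock] = []
    t, speech = 0.0, False
    spans: list[tuple[float, float, bool]] = []
    while t < duration_s:
        d = max(2.0, round(rng.exponential(mean_episode_s)))
        d = min(d, duration_s - t)
        spans.append((t, t + d, speech))
        t += d
        speech = not speech
    # render respiration by stitching per-span cycles
    cycles: list[BreathCycle] = []
    cyc_rng = np.random.default_rng(s_resp)
    for t0, t1, sp in spans:
        span_block = ProtocolBlock.__new__(ProtocolBlock)
        object.__setattr__(span_block, "condition", None)
        object.__setattr__(span_block, "posture", Posture.SITTING)
        object.__setattr__(span_block, "speech", sp)
        object.__setattr__(span_block, "duration_s", t1 - t0)
        sub = simulate_breath_cycles(profile, [span_block], cyc_rng.integers(2**31))
        cycles.extend(replace(c, t0=c.t0 + t0) for c in sub)
    resp = render_respiration(cycles, duration_s, fs_resp, cyc_rng.integers(2**31))
    # vibration: voiced bursts only inside speech spans
    vib_rng = np.random.default_rng(s_vib)
    n = int(round(duration_s * fs_vib))
    channels = {name: vib_rng.normal(0.0, 0.02, n) for name in VIB_CHANNELS}
    amps = np.array([0.5**k for k in range(profile.n_harmonics)])
    for t0, t1, sp in spans:
        if not sp:
            continue
        for on, off in _voiced_intervals(t1 - t0, profile.voicing_duty, vib_rng):
            j0, j1 = int(round((t0 + on) * fs_vib)), int(round((t0 + off) * fs_vib))
            tt = np.arange(j1 - j0) / fs_vib
            stack = np.zeros(j1 - j0)
            for k, a in enumerate(amps, start=1):
                stack += a * np.sin(2 * np.pi * k * profile.f0 * tt + vib_rng.uniform(0, 2 * np.pi))
            for name, gain in VIB_CHANNELS.items():
                channels[name][j0:j1] += profile.voice_amp * gain * stack
    # per-window speech fraction
    n_win = int(duration_s // window_s)
    frac = np.zeros(n_win)
    for t0, t1, sp in spans:
        if not sp:
            continue
        for w in range(n_win):
            w0, w1 = w * window_s, (w + 1) * window_s
            frac[w] += max(0.0, min(t1, w1) - max(t0, w0)) / window_s
    chans = {"rip_thorax": Channel(resp, fs_resp)}
    chans.update({k: Channel(v, fs_vib) for k, v in channels.items()})
    return MultiChannelRecording(
        subject_id="FL000",
        channels=chans,
        annotations=[],
        ground_truth=frac,
        truth={"profile": profile, "cycles": cycles, "spans": spans},
    )
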