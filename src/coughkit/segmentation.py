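"""Energy-threshold event segmentation and cough phase counting.

A labeled clip often carries several cough events separated by silence.
``segment_events`` frames the waveform, computes per-frame RMS energy, and
keeps maximal runs of frames whose RMS exceeds a fraction of the clip's
peak frame RMS.  The threshold is relative, so segmentation is invariant
to global gain.  ``classify_phases`` counts the distinct energy lobes
(explosive burst / intermediate / voiced tail) of a cough event — 2 or 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from coughkit.audio_core import AudioClip, TARGET_RATE


@dataclass(frozen=True)
class SegmenterConfig:
    """Parameters of the energy-threshold segmenter.

    Defaults are chosen so that typical cough events (0.36 ± 0.14 s)
    survive intact: 25 ms frames with 10 ms hop, activity threshold at
    10% of the clip's peak frame RMS, events shorter than 100 ms dropped,
    sub-threshold gaps under 50 ms merged.
    """

    frame_s: float = 0.025
    hop_s: float = 0.010
    energy_threshold_frac: float = 0.10
    min_event_s: float = 0.10
    merge_gap_s: float = 0.05

    def __post_init__(self) -> None:
        if not (self.frame_s >= self.hop_s > 0):
            raise ValueError("require frame_s >= hop_s > 0")
        if not (0 < self.energy_threshold_frac < 1):
            raise ValueError("energy_threshold_frac must be in (0, 1)")
        if self.min_event_s <= 0:
            raise ValueError("min_event_s must be positive")


@dataclass
class SoundEvent:
    """A segmented, labeled audio interval — the unit of modeling.

    ``clip`` holds the extracted samples at 44.1 kHz; ``start_s``/``end_s``
    locate the half-open interval [start, end) in the source clip.
    ``phase_count`` is curation metadata (2, 3, or None for unknown); it
    never gates modeling.
    """

    clip: AudioClip
    start_s: float
    end_s: float
    sound_type: str
    phase_count: int | None = None
    variant: str = "orig"

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError("require 0 <= start_s < end_s")

    @property
    def duration_s(self) -> float:
        return self.clip.duration_s


def _frame_rms(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    n_frames = 1 + (len(x) - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return np.sqrt(np.mean(x[idx] ** 2, axis=1))


def segment_events(clip: AudioClip, cfg: SegmenterConfig | None = None) -> list[SoundEvent]:
    """Cut a clip into non-overlapping events in time order.

    Frames with RMS below ``energy_threshold_frac`` × (peak frame RMS)
    never start an event; active runs separated by a sub-threshold gap
    shorter than ``merge_gap_s`` are merged; events shorter than
    ``min_event_s`` are discarded.

    Raises
    ------
    ValueError
        If the clip is shorter than one analysis frame.
    """
    cfg = cfg or SegmenterConfig()
    sr = clip.sample_rate
    frame = max(1, round(cfg.frame_s * sr))
    hop = max(1, round(cfg.hop_s * sr))
    x = clip.samples
    if len(x) < frame:
        raise ValueError("clip shorter than one analysis frame")

    rms = _frame_rms(x, frame, hop)
    peak = rms.max()
    if peak <= 0:
        return []
    active = rms >= cfg.energy_threshold_frac * peak

    # maximal runs of active frames
    edges = np.flatnonzero(np.diff(active.astype(np.int8)))
    starts = list(np.flatnonzero(np.diff(np.r_[0, active.astype(np.int8)]) == 1))
    ends = list(np.flatnonzero(np.diff(np.r_[active.astype(np.int8), 0]) == -1) + 1)
    del edges

    runs: list[list[int]] = []
    max_gap = cfg.merge_gap_s / cfg.hop_s
    for s, e in zip(starts, ends):
        if runs and (s - runs[-1][1]) * 1.0 < max_gap:
            runs[-1][1] = e
        else:
            runs.append([s, e])

    events: list[SoundEvent] = []
    for s, e in runs:
        i0 = s * hop
        i1 = min(len(x), (e - 1) * hop + frame)
        if (i1 - i0) / sr < cfg.min_event_s:
            continue
        seg = x[i0:i1]
        events.append(
            SoundEvent(
                clip=AudioClip(seg, sr, label=clip.label, source_id=clip.source_id),
                start_s=i0 / sr,
                end_s=i1 / sr,
                sound_type=clip.label,
            )
        )
    return events


def classify_phases(event: SoundEvent) -> int:
    """Count the energy-envelope lobes of a cough event (2 or 3).

    The smoothed frame-RMS envelope is scanned for local maxima above a
    relative prominence floor; the count is clamped into [2, 3], so a
    degenerate single-lobe burst maps to 2.

    Raises
    ------
    ValueError
        If the event is not a cough.
    """
    if event.sound_type != "cough":
        raise ValueError("phase classification applies to cough events only")
    sr = event.clip.sample_rate
    frame = max(1, round(0.020 * sr))
    hop = max(1, frame // 2)
    x = event.clip.samples
    if len(x) < frame:
        return 2
    env = _frame_rms(x, frame, hop)
    # light smoothing: 3-point moving average
    if env.size >= 3:
        env = np.convolve(env, np.ones(3) / 3, mode="same")
    peaks, _ = find_peaks(np.r_[0.0, env, 0.0], prominence=0.15 * env.max())
    return int(min(3, max(2, peaks.size)))
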