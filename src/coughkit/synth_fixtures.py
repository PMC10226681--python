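"""Deterministic synthetic corpus: coughs plus 15 non-cough archetypes.

The generator emulates the *structure* of a labeled environmental-sound
corpus — m cough events with 2–3 energy lobes and durations drawn from
N(0.36 s, 0.14 s), and five sound types in each of three categories
(animal, human-made, hardware) — so the whole pipeline is exercisable
with no external audio.  The archetypes are acoustic caricatures, not
recordings: animal types are harmonic tonal calls with high spectral
centroids, human-made types are breathy band-limited noise and burst
trains, hardware types are stationary low-frequency hums.  Category mean
spectral centroids are ordered hardware < human-made < animal by
construction, which makes categories separable and lets cross-environment
ordering properties be tested; numbers measured on this corpus
characterize the pipeline, not any real-world dataset.

All generation flows from one seed; each event derives its own stream
from a (type, counter) label, so corpora are reproducible event-by-event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from coughkit.audio_core import (
    AudioClip,
    CATEGORY_TYPES,
    SOUND_TYPES,
    TARGET_RATE,
    stream_rng,
    write_wav,
)
from coughkit.segmentation import SoundEvent

COUGH_DURATION_MEAN_S = 0.36
COUGH_DURATION_SD_S = 0.14


@dataclass(frozen=True)
class FixtureConfig:
    """Corpus recipe: seed, per-type counts, duration statistics.

    Defaults give 106 coughs and 22 events per non-cough type — enough
    for any class-0 composition (per-type quotas up to 22).
    ``rms_jitter_db`` is the half-width of the uniform per-event loudness
    jitter around the nominal RMS of 0.1.
    """

    seed: int = 0
    n_coughs: int = 106
    n_per_noise_type: int = 22
    cough_mean_s: float = COUGH_DURATION_MEAN_S
    cough_sd_s: float = COUGH_DURATION_SD_S
    noise_mean_s: float = 1.0
    noise_sd_s: float = 0.25
    sample_rate: int = TARGET_RATE
    rms_jitter_db: float = 3.0

    def __post_init__(self) -> None:
        if self.n_coughs < 0 or self.n_per_noise_type < 0:
            raise ValueError("counts must be non-negative")
        if self.cough_mean_s <= 0:
            raise ValueError("cough_mean_s must be positive")


def _bandnoise(rng, n, sr, lo, hi, order=4):
    x = rng.standard_normal(n)
    nyq = sr / 2.0
    sos = butter(order, [max(lo, 1.0) / nyq, min(hi, nyq * 0.99) / nyq], btype="band", output="sos")
    return sosfilt(sos, x)


def _lownoise(rng, n, sr, cutoff):
    x = rng.standard_normal(n)
    sos = butter(4, cutoff / (sr / 2.0), btype="low", output="sos")
    return sosfilt(sos, x)


def _harmonics(rng, n, sr, f0, n_harm=6, decay=0.6):
    t = np.arange(n) / sr
    y = np.zeros(n)
    for h in range(1, n_harm + 1):
        y += decay ** (h - 1) * np.sin(2 * np.pi * f0 * h * t + rng.uniform(0, 2 * np.pi))
    return y


def _am(y, sr, freq, depth=0.8):
    t = np.arange(len(y)) / sr
    return y * (1.0 - depth / 2 + (depth / 2) * np.sin(2 * np.pi * freq * t))


def _burst_train(rng, n, sr, rate_hz, burst_s, carrier):
    env = np.zeros(n)
    period = int(sr / rate_hz)
    blen = int(burst_s * sr)
    for start in range(0, n, period):
        seg = min(blen, n - start)
        env[start : start + seg] = np.exp(-np.linspace(0, 5, seg))
    return carrier * env


def _normalize_rms(y, target_rms):
    rms = np.sqrt(np.mean(y**2))
    return y * (target_rms / max(rms, 1e-12))


def gen_cough(rng: np.random.Generator, duration_s: float | None = None,
              n_phases: int | None = None, sr: int = TARGET_RATE) -> SoundEvent:
    """One synthetic cough: sharp broadband burst plus 1–2 trailing lobes.

    The first lobe is an explosive attack with exponential decay; later
    lobes (intermediate / voiced tail) are shorter and weaker, separated
    by near-silent gaps so the phase ground truth is recoverable from the
    energy envelope.
    """
    if duration_s is None:
        duration_s = float(rng.normal(COUGH_DURATION_MEAN_S, COUGH_DURATION_SD_S))
    duration_s = max(duration_s, 0.12)
    if n_phases is None:
        n_phases = int(rng.choice([2, 3], p=[0.6, 0.4]))
    if not (2 <= n_phases <= 3):
        raise ValueError("cough phase count must be 2 or 3")
    n = max(int(round(duration_s * sr)), int(0.12 * sr))
    y = np.zeros(n)
    # lobe layout: fractions of the event occupied by each lobe, gaps between
    weights = [1.0, 0.45, 0.3][:n_phases]
    gap = 0.10
    lobe_frac = (1.0 - gap * (n_phases - 1)) / n_phases
    pos = 0.0
    for p in range(n_phases):
        l0 = int(pos * n)
        l1 = min(n, int((pos + lobe_frac) * n))
        m = l1 - l0
        if m < 8:
            break
        burst = _bandnoise(rng, m, sr, 400, 6000)
        attack = int(max(2, 0.01 * sr))
        env = np.exp(-np.linspace(0, 6, m))
        env[:attack] *= np.linspace(0, 1, attack)
        y[l0:l1] += weights[p] * burst * env
        pos += lobe_frac + gap
    peak = np.max(np.abs(y))
    y = y * (0.9 / max(peak, 1e-12))
    clip = AudioClip(y, sr, label="cough")
    return SoundEvent(clip=clip, start_s=0.0, end_s=n / sr, sound_type="cough",
                      phase_count=n_phases)


# per-type synthesis recipes; centroid bands: hardware < human-made < animal
def _gen_noise_samples(rng, sound_type: str, n: int, sr: int) -> np.ndarray:
    if sound_type == "frog":
        return _am(_harmonics(rng, n, sr, 900), sr, 15)
    if sound_type == "crow":
        return _am(_harmonics(rng, n, sr, 1300) + 0.2 * _bandnoise(rng, n, sr, 1000, 4000), sr, 4)
    if sound_type == "cricket":
        return _am(_harmonics(rng, n, sr, 4800, n_harm=2), sr, 20, depth=1.0)
    if sound_type == "rooster":
        t = np.arange(n) / sr
        f0 = 1800 + 400 * np.sin(2 * np.pi * 0.8 * t)
        return np.sin(2 * np.pi * np.cumsum(f0) / sr) + 0.3 * _harmonics(rng, n, sr, 1800, 3)
    if sound_type == "dog":
        return _burst_train(rng, n, sr, 3.0, 0.15, _harmonics(rng, n, sr, 1100, 5))
    if sound_type == "snoring":
        return _burst_train(rng, n, sr, 1.2, 0.4, _bandnoise(rng, n, sr, 150, 1200))
    if sound_type == "breathing":
        return _am(_bandnoise(rng, n, sr, 300, 2000), sr, 0.5, depth=0.9)
    if sound_type == "sneezing":
        env = np.exp(-np.linspace(0, 4, n))
        return _bandnoise(rng, n, sr, 500, 3000) * env + 0.2 * _bandnoise(rng, n, sr, 300, 1500)
    if sound_type == "laughing":
        return _burst_train(rng, n, sr, 5.0, 0.1, _harmonics(rng, n, sr, 260, 5)
                            + 0.5 * _bandnoise(rng, n, sr, 400, 2500))
    if sound_type == "throat_clearing":
        return _am(_bandnoise(rng, n, sr, 200, 2500), sr, 30, depth=0.6)
    if sound_type == "washing_machine":
        return _harmonics(rng, n, sr, 60, 4) + 0.3 * _lownoise(rng, n, sr, 400)
    if sound_type == "door_knock":
        return _burst_train(rng, n, sr, 3.0, 0.08, _lownoise(rng, n, sr, 250))
    if sound_type == "vacuum_cleaner":
        return _harmonics(rng, n, sr, 180, 4) + 0.5 * _lownoise(rng, n, sr, 1200)
    if sound_type == "engine":
        return _am(_harmonics(rng, n, sr, 90, 6), sr, 10, depth=0.4) + 0.2 * _lownoise(rng, n, sr, 500)
    if sound_type == "air_conditioner":
        return _lownoise(rng, n, sr, 800)
    raise ValueError(f"unknown sound type {sound_type!r}")


def gen_noise(rng: np.random.Generator, sound_type: str, duration_s: float = 1.0,
              sr: int = TARGET_RATE, rms_jitter_db: float = 3.0) -> SoundEvent:
    """One synthetic non-cough event of the given type.

    Events are RMS-normalized to 0.1 with a uniform per-event jitter of
    ±``rms_jitter_db`` dB.
    """
    if sound_type == "cough":
        raise ValueError("gen_noise generates non-cough types only")
    if sound_type not in SOUND_TYPES:
        raise ValueError(f"unknown sound type {sound_type!r}")
    n = max(int(round(duration_s * sr)), int(0.12 * sr))
    y = _gen_noise_samples(rng, sound_type, n, sr)
    jitter = rng.uniform(-rms_jitter_db, rms_jitter_db)
    y = _normalize_rms(y, 0.1 * 10 ** (jitter / 20.0))
    y = np.clip(y, -1.0, 1.0)
    clip = AudioClip(y, sr, label=sound_type)
    return SoundEvent(clip=clip, start_s=0.0, end_s=n / sr, sound_type=sound_type)


@dataclass
class Corpus:
    """An in-memory event store: events grouped by sound type, plus manifest."""

    events: dict[str, list[SoundEvent]]
    manifest: pd.DataFrame
    config: FixtureConfig

    @property
    def coughs(self) -> list[SoundEvent]:
        return self.events.get("cough", [])

    def pool(self) -> dict[str, list[SoundEvent]]:
        """Non-cough events by type (the class-0 sampling pool)."""
        return {t: evs for t, evs in self.events.items() if t != "cough"}


def gen_corpus(cfg: FixtureConfig | None = None, out_dir=None) -> Corpus:
    """Generate the default labeled corpus; optionally write WAVs + manifest.

    Two runs with the same config produce byte-identical manifests and
    waveforms.
    """
    cfg = cfg or FixtureConfig()
    events: dict[str, list[SoundEvent]] = {t: [] for t in SOUND_TYPES}
    rows = []
    for i in range(cfg.n_coughs):
        rng = stream_rng(cfg.seed, f"corpus/cough/{i}")
        dur = float(rng.normal(cfg.cough_mean_s, cfg.cough_sd_s))
        ev = gen_cough(rng, duration_s=dur, sr=cfg.sample_rate)
        sid = f"cough_{i:04d}"
        ev.clip.source_id = sid
        events["cough"].append(ev)
        rows.append((sid, "cough", ev.duration_s, ev.phase_count))
    for t in SOUND_TYPES:
        if t == "cough":
            continue
        for i in range(cfg.n_per_noise_type):
            rng = stream_rng(cfg.seed, f"corpus/{t}/{i}")
            dur = max(0.3, float(rng.normal(cfg.noise_mean_s, cfg.noise_sd_s)))
            ev = gen_noise(rng, t, duration_s=dur, sr=cfg.sample_rate,
                           rms_jitter_db=cfg.rms_jitter_db)
            sid = f"{t}_{i:04d}"
            ev.clip.source_id = sid
            events[t].append(ev)
            rows.append((sid, t, ev.duration_s, None))
    manifest = pd.DataFrame(rows, columns=["source_id", "sound_type", "duration_s", "phase_count"])
    corpus = Corpus(events=events, manifest=manifest, config=cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for t, evs in events.items():
            for ev in evs:
                write_wav(ev.clip, out / f"{t}__{ev.clip.source_id}.wav")
        manifest.to_csv(out / "manifest.csv", index=False)
    return corpus
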