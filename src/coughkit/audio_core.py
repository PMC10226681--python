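"""Audio data model, WAV I/O, resampling, and seeded randomness.

Every downstream stage operates on :class:`AudioClip` objects — mono
floating-point waveforms in [-1, 1] at a known sample rate.  All clips are
normalized to 44.1 kHz before segmentation/feature extraction; the
``resample`` helper does that with polyphase band-limited interpolation.

Randomness is organized as named streams derived from one master seed
(:func:`stream_rng`), so that splits, class-0 sampling, and synthetic-corpus
generation are individually reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

TARGET_RATE = 44_100

#: Canonical sound-type taxonomy: one positive type (cough) and three
#: categories of five environmental non-cough types each.
CATEGORY_TYPES: dict[str, tuple[str, ...]] = {
    "animal": ("frog", "crow", "cricket", "rooster", "dog"),
    "human_made": ("snoring", "breathing", "sneezing", "laughing", "throat_clearing"),
    "hardware": ("washing_machine", "door_knock", "vacuum_cleaner", "engine", "air_conditioner"),
}

SOUND_TYPES: tuple[str, ...] = ("cough",) + tuple(
    t for types in CATEGORY_TYPES.values() for t in types
)

CATEGORY_OF: dict[str, str] = {"cough": "cough"}
for _cat, _types in CATEGORY_TYPES.items():
    for _t in _types:
        CATEGORY_OF[_t] = _cat


class AudioDecodeError(RuntimeError):
    """Raised when a WAV file cannot be decoded or contains no audio."""


@dataclass
class AudioClip:
    """A mono waveform with provenance.

    Parameters
    ----------
    samples : ndarray
        1-D float array, nominal range [-1, 1], all values finite.
    sample_rate : int
        Sampling frequency in Hz, positive.
    label : str
        Sound-type tag (one of :data:`SOUND_TYPES`) or ``"unlabeled"``.
    source_id : str
        Opaque provenance string (file stem, generator tag, ...).
    """

    samples: np.ndarray
    sample_rate: int
    label: str = "unlabeled"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be 1-D (mono)")
        if self.samples.size < 1:
            raise ValueError("AudioClip must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioClip samples must be finite")
        if int(self.sample_rate) <= 0:
            raise ValueError("sample_rate must be positive")
        self.sample_rate = int(self.sample_rate)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def with_samples(self, samples: np.ndarray, sample_rate: int | None = None) -> "AudioClip":
        return replace(
            self, samples=samples,
            sample_rate=self.sample_rate if sample_rate is None else sample_rate,
        )


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Return a Generator for a named stream under one master seed.

    The same (seed, stream) pair always produces the same draws; distinct
    stream labels give statistically independent streams.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    tag = zlib.crc32(stream.encode("utf-8"))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), tag])))


def read_wav(path) -> AudioClip:
    """Read a PCM/float WAV file as a mono :class:`AudioClip`.

    Multichannel audio is reduced to mono by the arithmetic mean of channels;
    integer PCM is scaled to [-1, 1]. The native sample rate is preserved.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # corrupt header, not a RIFF file, ...
        raise AudioDecodeError(f"cannot decode WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise AudioDecodeError(f"WAV file {path!r} contains no audio")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if data.dtype == np.uint8:  # unsigned 8-bit PCM is offset binary
            x = (data.astype(np.float64) - 128.0) / 127.0
        else:
            x = data.astype(np.float64) / float(info.max)
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    return AudioClip(samples=x, sample_rate=int(rate))


def write_wav(clip: AudioClip, path) -> None:
    """Write a clip as 16-bit PCM WAV; ``read_wav`` recovers it up to quantization."""
    x = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    try:
        wavfile.write(path, clip.sample_rate, pcm)
    except Exception as exc:
        raise OSError(f"cannot write WAV file {path!r}: {exc}") from exc


def resample(clip: AudioClip, target_rate: int = TARGET_RATE) -> AudioClip:
    """Resample a clip with polyphase band-limited interpolation.

    Duration is conserved within one output sample period; label and
    provenance carry over. A clip already at ``target_rate`` is returned
    unchanged.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    target_rate = int(target_rate)
    if clip.sample_rate == target_rate:
        return clip
    g = math.gcd(target_rate, clip.sample_rate)
    up, down = target_rate // g, clip.sample_rate // g
    y = resample_poly(clip.samples, up, down)
    return clip.with_samples(y, sample_rate=target_rate)
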