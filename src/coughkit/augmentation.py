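"""Fixed deterministic augmentation: 14 pitch shifts + 3 time stretches.

Every event expands to 18 instances: the original plus 17 single-operator
variants — pitch shifts of ±0.5, ±1, ±1.5, ±2, ±2.5, ±3, ±3.5 semitones
(duration-preserving) and time stretches at rates 0.25, 0.5 and 0.75.

Rate convention: a stretch at rate f slows playback, so the output
duration is input_duration / f (rate 0.25 quadruples the duration).

Both operators are built on a phase vocoder (STFT magnitude interpolation
with phase accumulation); a pitch shift of n semitones is a time stretch
by 2^(n/12) followed by band-limited resampling back to the original
length, which scales all spectral content by the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import get_window, resample as _fft_resample

from coughkit.segmentation import SoundEvent

PITCH_SEMITONES: tuple[float, ...] = (
    -3.5, -3.0, -2.5, -2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5
)
STRETCH_RATES: tuple[float, ...] = (0.25, 0.5, 0.75)

_N_FFT = 2048
_HOP = 512


@dataclass(frozen=True)
class AugmentationSpec:
    """One deterministic variant: kind and magnitude.

    ``magnitude`` is semitones for ``pitch_shift`` and the rate factor for
    ``time_stretch``.
    """

    kind: str  # {"pitch_shift", "time_stretch"}
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ("pitch_shift", "time_stretch"):
            raise ValueError(f"unknown augmentation kind {self.kind!r}")

    @property
    def tag(self) -> str:
        if self.kind == "pitch_shift":
            return f"ps{self.magnitude:+g}"
        return f"ts{self.magnitude:g}"


def default_augmentation_set() -> list[AugmentationSpec]:
    """The fixed 17-spec set, in documented order.

    Pitch shifts come first in ascending semitone order (-3.5 … +3.5,
    zero excluded), followed by the stretches in ascending rate order
    (0.25, 0.5, 0.75).
    """
    specs = [AugmentationSpec("pitch_shift", s) for s in PITCH_SEMITONES]
    specs += [AugmentationSpec("time_stretch", r) for r in STRETCH_RATES]
    return specs


def _stft(x: np.ndarray, n_fft: int = _N_FFT, hop: int = _HOP) -> np.ndarray:
    if len(x) < n_fft:
        x = np.pad(x, (0, n_fft - len(x)))
    n_frames = 1 + (len(x) - n_fft) // hop
    win = get_window("hann", n_fft, fftbins=True)
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    return np.fft.rfft(x[idx] * win, axis=1).T  # (freq, time)


def _istft(S: np.ndarray, hop: int = _HOP) -> np.ndarray:
    n_fft = 2 * (S.shape[0] - 1)
    n_frames = S.shape[1]
    win = get_window("hann", n_fft, fftbins=True)
    frames = np.fft.irfft(S.T, n=n_fft, axis=1) * win
    total = n_fft + hop * (n_frames - 1)
    out = np.zeros(total)
    norm = np.zeros(total)
    w2 = win**2
    # hop divides n_fft, so overlap-add reduces to a few strided block adds
    assert n_fft % hop == 0
    for j in range(n_fft // hop):
        view = out[j * hop : j * hop + n_frames * hop].reshape(n_frames, hop)
        view += frames[:, j * hop : (j + 1) * hop]
        nview = norm[j * hop : j * hop + n_frames * hop].reshape(n_frames, hop)
        nview += w2[j * hop : (j + 1) * hop]
    return out / np.maximum(norm, 1e-8)


def _phase_vocoder(S: np.ndarray, rate: float, hop: int = _HOP) -> np.ndarray:
    """Resample STFT frames in time by ``rate`` with phase continuity."""
    n_freq, n_frames = S.shape
    n_fft = 2 * (n_freq - 1)
    steps = np.arange(0, n_frames, rate)
    omega = 2 * np.pi * hop * np.arange(n_freq) / n_fft
    Sp = np.concatenate([S, np.zeros((n_freq, 2), dtype=S.dtype)], axis=1)
    i = steps.astype(int)
    frac = steps - i
    A = np.angle(Sp)
    M = np.abs(Sp)
    mag = (1 - frac)[None, :] * M[:, i] + frac[None, :] * M[:, i + 1]
    # heterodyned phase increment per step, wrapped to (-pi, pi]
    dphi = A[:, i + 1] - A[:, i] - omega[:, None]
    dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
    incr = omega[:, None] + dphi
    phase = A[:, 0][:, None] + np.concatenate(
        [np.zeros((n_freq, 1)), np.cumsum(incr, axis=1)[:, :-1]], axis=1
    )
    return mag * np.exp(1j * phase)


def time_stretch(x: np.ndarray, rate: float) -> np.ndarray:
    """Stretch a waveform to duration len(x)/rate (same pitch)."""
    if rate <= 0:
        raise ValueError("stretch rate must be positive")
    target = max(1, round(len(x) / rate))
    # zero-pad so the overlap-add edges (where the window sum is tiny and
    # phase-modified frames no longer taper) fall outside the kept region
    pad = _N_FFT
    y = _istft(_phase_vocoder(_stft(np.pad(x, (pad, pad))), rate))
    start = round(pad / rate)
    seg = y[start : start + target]
    if len(seg) < target:
        seg = np.pad(seg, (0, target - len(seg)))
    return seg


def pitch_shift(x: np.ndarray, semitones: float) -> np.ndarray:
    """Shift spectral content by ``semitones``; duration is preserved."""
    k = 2.0 ** (semitones / 12.0)
    stretched = time_stretch(x, rate=1.0 / k)  # length ≈ len(x) * k, pitch unchanged
    return _fft_resample(stretched, len(x))  # compress time by k → pitch × k


def apply_augmentation(event: SoundEvent, spec: AugmentationSpec, strict: bool = True) -> SoundEvent:
    """Apply one variant to an event; type and provenance are preserved.

    With ``strict`` on, magnitudes outside the default sets are rejected;
    turn it off to use arbitrary magnitudes (e.g. whole-octave shifts in
    diagnostics).
    """
    if strict:
        allowed = PITCH_SEMITONES if spec.kind == "pitch_shift" else STRETCH_RATES
        if spec.magnitude not in allowed:
            raise ValueError(f"magnitude {spec.magnitude} not in default {spec.kind} set")
    x = event.clip.samples
    if spec.kind == "pitch_shift":
        y = pitch_shift(x, spec.magnitude)
    else:
        y = time_stretch(x, spec.magnitude)
    # phase-vocoder overlap-add is not energy-exact; pin the variant's RMS
    # to the original's so augmentation never introduces a gain change
    rms_in = np.sqrt(np.mean(x**2))
    rms_out = np.sqrt(np.mean(y**2))
    if rms_out > 0:
        y = y * (rms_in / rms_out)
    new_clip = event.clip.with_samples(y)
    return replace(event, clip=new_clip, variant=spec.tag)


def augment_event(event: SoundEvent) -> list[SoundEvent]:
    """Expand one event into [original] + the 17 default variants.

    Deterministic: calling twice yields element-wise identical waveforms.
    """
    return [event] + [apply_augmentation(event, spec) for spec in default_augmentation_set()]
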