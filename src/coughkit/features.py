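"""120-dimensional cepstral event descriptors and feature selection.

Each event maps to a fixed-order vector of 120 values:
40 mel-frequency cepstral coefficients (MFCCs), their 40 first temporal
derivatives (delta) and 40 second derivatives (delta-delta), each averaged
over analysis frames.  Concatenation order is
``[mfcc_01..40, d_01..40, dd_01..40]``.

Analysis defaults: 2048-sample frames with 512-sample hop at 44.1 kHz,
Hann window, 40-band HTK-style mel filterbank over 0..Nyquist,
orthonormal DCT-II cepstrum.  Deltas use local linear regression over a
9-frame window with edge replication, so a stationary signal has
identically zero delta blocks.

Two selection procedures are provided: univariate "select the K best" by
ANOVA F score (binary detectors) and per-feature variance ranking on the
cough class alone (one-class detectors).
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct
from scipy.signal import get_window
from sklearn.feature_selection import f_classif

from coughkit.segmentation import SoundEvent

N_MFCC = 40
N_MELS = 40
FRAME = 2048
HOP = 512


from dataclasses import dataclass


@dataclass(frozen=True)
class SelectionSpec:
    """A feature-selection recipe: method, count, and variance direction.

    ``method`` is ``"k_best"`` (ANOVA F on both classes) or ``"variance"``
    (ranking on cough-class rows); ``variance_mode`` ("smallest" or
    "largest") applies only to the variance method.
    """

    method: str
    k: int
    variance_mode: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("k_best", "variance"):
            raise ValueError(f"unknown selection method {self.method!r}")
        if not (1 <= self.k <= 120):
            raise ValueError("K must be in [1, 120]")
        if (self.method == "variance") != (self.variance_mode is not None):
            raise ValueError("variance_mode required iff method == 'variance'")
        if self.variance_mode not in (None, "smallest", "largest"):
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{block}_{i:02d}" for block in ("mfcc", "d", "dd") for i in range(1, N_MFCC + 1)
)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


from functools import lru_cache


@lru_cache(maxsize=8)
def _mel_filterbank(sr: int, n_fft: int, n_mels: int) -> np.ndarray:
    n_freq = n_fft // 2 + 1
    freqs = np.linspace(0.0, sr / 2.0, n_freq)
    pts = _mel_to_hz(np.linspace(_hz_to_mel(0.0), _hz_to_mel(sr / 2.0), n_mels + 2))
    fb = np.zeros((n_mels, n_freq))
    for i in range(n_mels):
        lo, mid, hi = pts[i], pts[i + 1], pts[i + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def _delta(c: np.ndarray, m: int = 4) -> np.ndarray:
    """Regression delta over a (2m+1)-frame window, edges replicated."""
    t = c.shape[0]
    padded = np.pad(c, ((m, m), (0, 0)), mode="edge")
    k = np.arange(1, m + 1)
    denom = 2.0 * np.sum(k**2)
    out = np.zeros_like(c)
    for kk in k:
        out += kk * (padded[m + kk : m + kk + t] - padded[m - kk : m - kk + t])
    return out / denom


def mfcc_frames(x: np.ndarray, sr: int, frame: int = FRAME, hop: int = HOP) -> np.ndarray:
    """Per-frame MFCC matrix of shape (n_frames, 40)."""
    if len(x) < frame:
        raise ValueError("signal shorter than one analysis frame")
    n_frames = 1 + (len(x) - frame) // hop
    win = get_window("hann", frame, fftbins=True)
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    spec = np.abs(np.fft.rfft(x[idx] * win, axis=1)) ** 2
    mel = spec @ _mel_filterbank(sr, frame, N_MELS).T
    logmel = np.log(np.maximum(mel, 1e-10))
    return dct(logmel, type=2, axis=1, norm="ortho")[:, :N_MFCC]


def extract_features(
    event: SoundEvent,
    frame_s: float = FRAME / 44100.0,
    hop_s: float = HOP / 44100.0,
) -> np.ndarray:
    """Compute the 120-value descriptor of one event.

    Raises
    ------
    ValueError
        If the event is shorter than one analysis frame.
    """
    sr = event.clip.sample_rate
    frame = max(1, round(frame_s * sr))
    hop = max(1, round(hop_s * sr))
    c = mfcc_frames(event.clip.samples, sr, frame, hop)
    d = _delta(c)
    dd = _delta(d)
    vec = np.concatenate([c.mean(axis=0), d.mean(axis=0), dd.mean(axis=0)])
    assert vec.shape == (3 * N_MFCC,)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature values")
    return vec


def _ranked_take(order: np.ndarray, k: int) -> np.ndarray:
    return np.sort(order[:k])


def select_k_best(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the K features with highest ANOVA F class separation.

    Deterministic; ties broken toward the lower index.  Returns a sorted
    index array.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(np.unique(y)) < 2:
        raise ValueError("select_k_best requires both classes present")
    if not (1 <= k <= X.shape[1]):
        raise ValueError(f"K must be in [1, {X.shape[1]}]")
    scores, _ = f_classif(X, y)
    scores = np.where(np.isfinite(scores), scores, -np.inf)
    order = np.argsort(-scores, kind="stable")
    return _ranked_take(order, k)


def select_by_variance(X: np.ndarray, k: int, mode: str = "smallest") -> np.ndarray:
    """Indices of the K features with smallest (or largest) sample variance.

    Used with cough-class rows only when configuring one-class detectors.
    Ties broken toward the lower index; returns a sorted index array.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    if not (1 <= k <= X.shape[1]):
        raise ValueError(f"K must be in [1, {X.shape[1]}]")
    if mode not in ("smallest", "largest"):
        raise ValueError("mode must be 'smallest' or 'largest'")
    var = X.var(axis=0, ddof=1)
    order = np.argsort(var if mode == "smallest" else -var, kind="stable")
    return _ranked_take(order, k)
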