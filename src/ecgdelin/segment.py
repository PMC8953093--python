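"""R-peak detection and fixed-length beat windowing.

The delineation network consumes fixed 370-sample windows at 250 Hz.  Two
anchoring modes exist: ``p_onset`` starts each window at the beat's P-onset
(model building against ground-truth annotations), ``rpeak_offset`` starts
0.2 s before a detected R-peak and keeps 0.45 s after it (deployment, where
only R-peaks are known).  Content past the beat (or record end) is filled
with amplitude 0 and the PAD class, so every window is exactly 370 samples.

R-peaks are found Pan-Tompkins style: 5-15 Hz band-pass, squaring, a 0.15 s
moving-average energy envelope, adaptive-threshold peak picking with a 0.3 s
refractory distance, then refinement to the local amplitude extremum of the
signal itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .errors import ValidationError
from .records import N_CLASSES, NOWAVE, PAD, EcgRecord, LabelMask

WINDOW_LEN = 370  # samples per beat window at 250 Hz


@dataclass(frozen=True)
class SegmentationConfig:
    window_len: int = WINDOW_LEN
    anchor: str = "rpeak_offset"  # or "p_onset"
    pre_r: float = 0.2   # s kept before the R-peak in rpeak_offset mode
    post_r: float = 0.45  # s kept after the R-peak
    target_fs: float = 250.0

    def __post_init__(self) -> None:
        if self.anchor not in ("p_onset", "rpeak_offset"):
            raise ValidationError(f"unknown anchor mode {self.anchor!r}")
        if self.window_len < int(np.ceil((self.pre_r + self.post_r) * self.target_fs)):
            raise ValidationError("window_len too small for pre_r + post_r")


@dataclass
class BeatWindow:
    """A fixed-length beat segment with aligned labels and one-hot target."""

    samples: np.ndarray          # (window_len,) mV
    mask: LabelMask              # aligned classes, PAD past the beat
    onehot: np.ndarray           # (window_len, 5)
    pad_start: int               # first PAD index; window_len if none
    source: tuple[str, int]      # (record_id, absolute start index)

    def __post_init__(self) -> None:
        n = self.samples.size
        if len(self.mask) != n or self.onehot.shape != (n, N_CLASSES):
            raise ValidationError("window samples/mask/onehot lengths disagree")
        pad = self.mask.classes == PAD
        expected = np.arange(n) >= self.pad_start
        if not np.array_equal(pad, expected):
            raise ValidationError("PAD region must be exactly the tail from pad_start")


def one_hot(mask: LabelMask) -> np.ndarray:
    """One-hot encode a window mask as an (n, 5) indicator matrix."""
    c = mask.classes
    if c.size == 0:
        raise ValidationError("mask must be non-empty")
    return np.eye(N_CLASSES)[c]


def detect_rpeaks(record: EcgRecord) -> np.ndarray:
    """Detect R-peak sample indices; strictly increasing, 0.3 s refractory."""
    if record.duration_s < 1.0:
        raise ValidationError("record must be at least 1 s long for R-peak detection")
    fs = record.fs
    x = record.samples - np.mean(record.samples)
    sos = butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sosfiltfilt(sos, x)
    energy = bp * bp
    win = max(1, round(0.15 * fs))
    envelope = np.convolve(energy, np.ones(win) / win, mode="same")

    refractory = max(1, round(0.3 * fs))
    cand, _ = find_peaks(envelope, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)
    # adaptive threshold: a fraction of the typical strong peak height
    strong = np.quantile(envelope[cand], 0.75)
    height = max(0.2 * strong, 1e-12)
    cand = cand[envelope[cand] >= height]

    # refine to the amplitude extremum of the raw signal near each candidate
    half = round(0.06 * fs)
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    peaks = np.unique(np.asarray(peaks, dtype=int))
    # enforce refractory spacing after refinement, keeping the larger peak
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < refractory:
            if np.abs(x[p]) > np.abs(x[kept[-1]]):
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return np.asarray(kept, dtype=int)


def segment_beats(
    record: EcgRecord,
    mask: LabelMask | None,
    anchors,
    config: SegmentationConfig | None = None,
) -> list[BeatWindow]:
    """Cut one zero-padded window per anchor.

    ``anchors`` are P-onset indices (``p_onset`` mode) or R-peak indices
    (``rpeak_offset`` mode).  The caller must already have resampled the
    record to ``config.target_fs``.  In ``p_onset`` mode a beat extends to
    the next anchor (or record end); in ``rpeak_offset`` mode it is the
    [anchor - pre_r, anchor + post_r) slice.  When ``mask`` is None the data
    region is labeled NOWAVE as an inference placeholder.
    """
    config = config or SegmentationConfig()
    if record.fs != config.target_fs:
        raise ValidationError(
            f"record fs {record.fs} != target_fs {config.target_fs}; resample first"
        )
    if mask is not None and len(mask) != len(record):
        raise ValidationError("mask length differs from record length")
    anchors = np.asarray(anchors, dtype=int)
    n = len(record)
    for a in anchors:
        if a < 0 or a >= n:
            raise ValidationError(f"anchor {a} outside record of {n} samples")

    fs = record.fs
    wl = config.window_len
    windows = []
    for i, a in enumerate(anchors):
        if config.anchor == "p_onset":
            start = int(a)
            beat_end = int(anchors[i + 1]) if i + 1 < len(anchors) else n
        else:
            start = max(0, int(a) - round(config.pre_r * fs))
            beat_end = min(n, int(a) + round(config.post_r * fs))
        data_end = min(beat_end, start + wl, n)
        content = record.samples[start:data_end]
        pad_start = content.size
        samples = np.zeros(wl)
        samples[:pad_start] = content
        classes = np.full(wl, PAD, dtype=np.int64)
        if mask is not None:
            classes[:pad_start] = mask.classes[start:data_end]
        else:
            classes[:pad_start] = NOWAVE
        wmask = LabelMask(classes)
        windows.append(
            BeatWindow(
                samples=samples,
                mask=wmask,
                onehot=one_hot(wmask),
                pad_start=pad_start,
                source=(record.record_id, start),
            )
        )
    return windows


def windows_to_arrays(windows) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (X, y): X (n, L) float, y (n, L) int class masks."""
    X = np.stack([w.samples for w in windows])
    y = np.stack([w.mask.classes for w in windows])
    return X, y
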