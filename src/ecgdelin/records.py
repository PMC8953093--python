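"""ECG record / label-mask data model, file formats, and resampling.

An :class:`EcgRecord` is a uniformly sampled single-lead voltage trace in
millivolts with a sampling frequency in Hz.  A :class:`LabelMask` assigns each
sample one of five waveform classes:

====  ==========================
code  meaning
====  ==========================
0     P-wave
1     QRS complex
2     T-wave
3     isoelectric line (no wave)
4     zero padding
====  ==========================

All indices are 0-based and class runs are half-open ``[start, end)``
intervals.  Two on-disk formats are supported for signals: a plain CSV dialect
(header line ``# fs=<float>``, then ``index,amplitude_mV`` rows) and a minimal
single-signal WFDB record (text ``.hea`` + format-16 ``.dat``).  Masks are
stored either per-sample (one class integer per line) or as interval CSVs of
``class,start,end`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from ._wfdb import read_wfdb, write_wfdb
from .errors import FormatError, ValidationError

P, QRS, T, NOWAVE, PAD = 0, 1, 2, 3, 4
N_CLASSES = 5
CLASS_NAMES = ("P", "QRS", "T", "NOWAVE", "PAD")
WAVE_CLASSES = (P, QRS, T)


@dataclass
class EcgRecord:
    """A uniformly sampled single-lead voltage trace.

    Parameters
    ----------
    samples : array-like
        Voltage values in millivolts; must be non-empty and finite.
    fs : float
        Sampling frequency in Hz; must be positive.
    lead : str
        Free-text lead name (default ``"II"``).
    record_id : str
        Opaque identifier.
    """

    samples: np.ndarray
    fs: float
    lead: str = "II"
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must all be finite")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class LabelMask:
    """Per-sample waveform classes, values in {0,1,2,3,4}."""

    classes: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int64)
        if self.classes.ndim != 1:
            raise ValidationError("mask must be 1-D")
        if self.classes.size and (
            self.classes.min() < 0 or self.classes.max() >= N_CLASSES
        ):
            bad = self.classes[(self.classes < 0) | (self.classes >= N_CLASSES)][0]
            raise ValidationError(f"mask class {bad} outside 0..{N_CLASSES - 1}")

    def __len__(self) -> int:
        return self.classes.size

    def runs(self) -> list[tuple[int, int, int]]:
        """Maximal contiguous runs as ``(class, start, end)`` with [start, end)."""
        c = self.classes
        if c.size == 0:
            return []
        edges = np.flatnonzero(np.diff(c)) + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [c.size]))
        return [(int(c[s]), int(s), int(e)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# interval <-> per-sample conversion


def intervals_to_mask(intervals, n_samples: int) -> LabelMask:
    """Convert ``(class, start, end)`` wave intervals to a per-sample mask.

    Samples not covered by any interval become NOWAVE (class 3).  Overlapping
    intervals are rejected: delineation ground truth must partition the beat.
    """
    classes = np.full(n_samples, NOWAVE, dtype=np.int64)
    claimed = np.zeros(n_samples, dtype=bool)
    for cls, start, end in intervals:
        cls, start, end = int(cls), int(start), int(end)
        if not 0 <= cls < N_CLASSES:
            raise ValidationError(f"interval class {cls} outside 0..{N_CLASSES - 1}")
        if start < 0 or end > n_samples or start > end:
            raise ValidationError(
                f"interval [{start},{end}) outside record of {n_samples} samples"
            )
        seg = claimed[start:end]
        if seg.any():
            at = start + int(np.flatnonzero(seg)[0])
            raise ValidationError(f"overlapping wave intervals at sample {at}")
        claimed[start:end] = True
        classes[start:end] = cls
    return LabelMask(classes)


def mask_to_intervals(mask: LabelMask, include_nowave: bool = False):
    """Inverse of :func:`intervals_to_mask`: maximal runs, NOWAVE omitted."""
    keep = set(range(N_CLASSES)) if include_nowave else set(WAVE_CLASSES) | {PAD}
    return [(c, s, e) for c, s, e in mask.runs() if c in keep]


# ---------------------------------------------------------------------------
# file I/O


def write_record(path: str, record: EcgRecord, format: str = "csv") -> None:
    """Write a record as CSV (``# fs=`` header) or minimal WFDB."""
    if format == "csv":
        with open(path, "w") as fh:
            fh.write(f"# fs={record.fs:g}\n")
            for i, v in enumerate(record.samples):
                fh.write(f"{i},{v:.6f}\n")
    elif format == "wfdb":
        write_wfdb(path, record.samples, record.fs, lead=record.lead)
    else:
        raise ValidationError(f"unknown record format {format!r}")


def read_record(path: str, format: str = "csv") -> EcgRecord:
    """Read an :class:`EcgRecord` from ``csv`` or ``wfdb`` format.

    Raises ``FileNotFoundError`` for a missing file, ``FormatError`` for a
    malformed file (naming the offending line), and ``ValidationError`` for a
    non-positive sampling frequency.
    """
    if format == "csv":
        return _read_csv_record(path)
    if format == "wfdb":
        samples, fs, lead = read_wfdb(path)
        return EcgRecord(samples, fs, lead=lead, record_id=path)
    raise ValidationError(f"unknown record format {format!r}")


def _read_csv_record(path: str) -> EcgRecord:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#") or "fs=" not in header:
            raise FormatError(f"{path} line 1: expected '# fs=<float>' header")
        try:
            fs = float(header.split("fs=")[1].split()[0])
        except (ValueError, IndexError):
            raise FormatError(f"{path} line 1: unparseable fs in {header!r}") from None
        if fs <= 0:
            raise ValidationError(f"{path}: fs must be positive, got {fs}")
        values = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{path} line {lineno}: expected 'index,amplitude_mV'")
            try:
                values.append(float(parts[1]))
            except ValueError:
                raise FormatError(
                    f"{path} line {lineno}: non-numeric amplitude {parts[1]!r}"
                ) from None
    if not values:
        raise FormatError(f"{path}: no samples")
    return EcgRecord(np.array(values), fs, record_id=path)


def write_mask(path: str, mask: LabelMask) -> None:
    """Write a per-sample mask CSV: one class integer per line."""
    with open(path, "w") as fh:
        for c in mask.classes:
            fh.write(f"{int(c)}\n")


def read_mask(path: str, n_samples: int) -> LabelMask:
    """Read a mask covering ``n_samples`` samples.

    Two encodings are accepted: a per-sample file of one class integer per
    line, or an interval CSV of ``class,start,end`` rows (optionally with a
    header).  Interval files are converted with uncovered samples defaulting
    to NOWAVE; an interval file shorter than the record is therefore legal,
    a per-sample file must match the record length.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines and lines[0].lower().replace(" ", "") in ("class,start,end",):
        lines = lines[1:]
    if not lines:
        return intervals_to_mask([], n_samples)
    if "," in lines[0]:
        intervals = []
        for lineno, line in enumerate(lines, start=1):
            parts = line.split(",")
            if len(parts) != 3:
                raise FormatError(f"{path} line {lineno}: expected 'class,start,end'")
            try:
                intervals.append((int(parts[0]), int(parts[1]), int(parts[2])))
            except ValueError:
                raise FormatError(f"{path} line {lineno}: non-integer field") from None
        return intervals_to_mask(intervals, n_samples)
    try:
        classes = np.array([int(ln) for ln in lines], dtype=np.int64)
    except ValueError:
        raise FormatError(f"{path}: non-integer class value") from None
    if classes.size != n_samples:
        raise ValidationError(
            f"{path}: per-sample mask has {classes.size} entries, expected {n_samples}"
        )
    return LabelMask(classes)


# ---------------------------------------------------------------------------
# resampling


def resample(record: EcgRecord, target_fs: float) -> EcgRecord:
    """Resample to ``target_fs`` with an anti-aliased polyphase filter.

    Output length is ``round(n * target_fs / fs)``.  The rate ratio is
    approximated by a rational with denominator <= 1000, exact for the
    integer/decimal rates ECG devices use.
    """
    if not target_fs > 0:
        raise ValidationError(f"target_fs must be positive, got {target_fs}")
    if target_fs == record.fs:
        return replace(record, samples=record.samples.copy())
    ratio = Fraction(target_fs / record.fs).limit_denominator(1000)
    # long kaiser window: passband error ~1e-4 so down-up round trips stay clean
    out = resample_poly(record.samples, ratio.numerator, ratio.denominator,
                        window=("kaiser", 12.0))
    n_out = int(round(len(record) * target_fs / record.fs))
    if out.size >= n_out:
        out = out[:n_out]
    else:
        out = np.pad(out, (0, n_out - out.size), mode="edge")
    return EcgRecord(out, target_fs, lead=record.lead, record_id=record.record_id)
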