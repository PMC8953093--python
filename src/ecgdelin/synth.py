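"""Labeled synthetic single-lead ECG generator.

Generates normal-sinus-rhythm (NSR) or atrial-fibrillation-like (AF) records
with exact per-sample ground truth so every downstream stage — denoising,
R-peak detection, beat segmentation, the delineation network and the AF rule
engine — is testable without any database download.

Waves are smooth parametric bumps (raised-cosine P and T, a biphasic
Q-R-S spike) rather than biophysically realistic morphology: the point is
that wave boundaries are unambiguous, so label recovery is checkable.  NSR
records draw RR intervals from a narrow truncated normal and render a P-wave
before every QRS; AF-like records draw from a wide truncated normal (the
"irregularly irregular" rhythm) and omit the P-wave, optionally replacing it
with a low-amplitude 6-8 Hz fibrillatory oscillation that stays labeled
NOWAVE.  Baseline wander (a slow sinusoid) and white Gaussian noise are added
to the samples only — the mask and true R-peak list are noise-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .records import NOWAVE, P, QRS, T, EcgRecord, LabelMask

#: physiological refractory lower bound on RR draws (seconds)
RR_TRUNCATION_S = 0.3


@dataclass(frozen=True)
class BeatTemplate:
    """Durations (s) and amplitudes (mV) of one synthetic P-QRS-T beat.

    ``pr_gap`` is the isoelectric gap between P offset and QRS onset;
    ``st_gap`` between QRS offset and T onset.  Defaults give a 0.08 s P-wave
    (the upper edge of the 0.06-0.08 s presence band used by the AF rules),
    a 0.08 s QRS with a 1 mV R-peak, and a 0.45 s total beat.
    """

    p_duration: float = 0.08
    p_amplitude: float = 0.15
    pr_gap: float = 0.05
    qrs_duration: float = 0.08
    r_amplitude: float = 1.0
    st_gap: float = 0.10
    t_duration: float = 0.14
    t_amplitude: float = 0.30

    def __post_init__(self) -> None:
        for name in ("p_duration", "pr_gap", "qrs_duration", "st_gap", "t_duration"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def beat_duration_s(self) -> float:
        return (self.p_duration + self.pr_gap + self.qrs_duration
                + self.st_gap + self.t_duration)


@dataclass(frozen=True)
class RhythmSpec:
    """Rhythm-level generation parameters.

    ``kind`` is "NSR" or "AF"; use the :meth:`nsr` / :meth:`af` constructors
    for the canonical defaults (NSR: rr_cv 0.02, every beat has a P-wave;
    AF: rr_cv 0.30, no P-waves).  ``mean_rr`` in seconds maps to
    BPM = 60/mean_rr.  ``fibrillatory_amp``/``fibrillatory_freq`` add the
    optional f-wave oscillation in place of the P-wave (AF only; default off).
    """

    kind: str
    mean_rr: float
    rr_cv: float
    p_present_prob: float
    fs: float = 250.0
    n_beats: int = 20
    noise_sd: float = 0.02
    baseline_amp: float = 0.05
    baseline_freq: float = 0.25
    fibrillatory_amp: float = 0.0
    fibrillatory_freq: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("NSR", "AF"):
            raise ValidationError(f"kind must be NSR or AF, got {self.kind!r}")
        if not self.mean_rr > 0:
            raise ValidationError("mean_rr must be positive")
        if self.rr_cv < 0 or not 0 <= self.p_present_prob <= 1:
            raise ValidationError("rr_cv must be >= 0 and p_present_prob in [0,1]")
        if self.fs < 100:
            raise ValidationError("fs must be >= 100 Hz")
        if self.n_beats < 1:
            raise ValidationError("n_beats must be >= 1")

    @classmethod
    def nsr(cls, seed: int = 0, **kw) -> "RhythmSpec":
        defaults = dict(kind="NSR", mean_rr=0.8, rr_cv=0.02, p_present_prob=1.0)
        defaults.update(kw)
        return cls(seed=seed, **defaults)

    @classmethod
    def af(cls, seed: int = 0, **kw) -> "RhythmSpec":
        defaults = dict(kind="AF", mean_rr=0.75, rr_cv=0.30, p_present_prob=0.0)
        defaults.update(kw)
        return cls(seed=seed, **defaults)


def _raised_cosine(n: int) -> np.ndarray:
    """Smooth bump of length n, zero at both ends, peak 1 at the centre."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def _qrs_shape(n: int) -> np.ndarray:
    """Biphasic Q-R-S spike of length n, normalized so max equals 1."""
    t = np.linspace(-1.0, 1.0, n)
    r = np.exp(-(t / 0.22) ** 2)
    q = -0.18 * np.exp(-((t + 0.55) / 0.18) ** 2)
    s = -0.25 * np.exp(-((t - 0.55) / 0.18) ** 2)
    w = r + q + s
    return w / w.max()


def generate_beat(template: BeatTemplate, fs: float,
                  include_p: bool = True) -> tuple[np.ndarray, LabelMask]:
    """Render one beat; returns samples (mV) and the aligned label mask.

    Each wave occupies ``round(duration * fs)`` samples.  The rendered R
    amplitude equals ``template.r_amplitude`` exactly at the QRS argmax.  With
    ``include_p=False`` the P interval is flat and labeled NOWAVE.
    """
    if fs < 100:
        raise ValidationError("fs must be >= 100 Hz")
    n_p = round(template.p_duration * fs)
    n_pr = round(template.pr_gap * fs)
    n_qrs = round(template.qrs_duration * fs)
    n_st = round(template.st_gap * fs)
    n_t = round(template.t_duration * fs)
    n = n_p + n_pr + n_qrs + n_st + n_t
    samples = np.zeros(n)
    classes = np.full(n, NOWAVE, dtype=np.int64)

    if include_p:
        samples[0:n_p] = template.p_amplitude * _raised_cosine(n_p)
        classes[0:n_p] = P
    q0 = n_p + n_pr
    samples[q0:q0 + n_qrs] = template.r_amplitude * _qrs_shape(n_qrs)
    classes[q0:q0 + n_qrs] = QRS
    t0 = q0 + n_qrs + n_st
    samples[t0:t0 + n_t] = template.t_amplitude * _raised_cosine(n_t)
    classes[t0:t0 + n_t] = T
    return samples, LabelMask(classes)


def _draw_rr(rng: np.random.Generator, spec: RhythmSpec, lower: float) -> np.ndarray:
    """Truncated-normal RR draws: rejection sampling below ``lower`` seconds."""
    sd = spec.rr_cv * spec.mean_rr
    rr = np.empty(spec.n_beats)
    for i in range(spec.n_beats):
        x = rng.normal(spec.mean_rr, sd)
        while x < lower:
            x = rng.normal(spec.mean_rr, sd)
        rr[i] = x
    return rr


def generate_record(
    spec: RhythmSpec, template: BeatTemplate | None = None
) -> tuple[EcgRecord, LabelMask, np.ndarray]:
    """Generate a labeled record; returns (record, mask, true R-peak indices).

    RR intervals are i.i.d. truncated normal (mean ``mean_rr``, sd
    ``rr_cv*mean_rr``), truncated below at max(0.3 s, beat duration) so beats
    never overlap.  Beat structure and noise come from independent seeded
    streams, so the mask and R-peak list do not change with ``noise_sd``.
    """
    template = template or BeatTemplate()
    if template.beat_duration_s >= spec.mean_rr:
        raise ValidationError(
            f"template beat ({template.beat_duration_s:.3f}s) does not fit the "
            f"mean RR interval ({spec.mean_rr:.3f}s)"
        )
    rng_structure = np.random.default_rng([int(spec.seed), 0])
    rng_noise = np.random.default_rng([int(spec.seed), 1])
    lower = max(RR_TRUNCATION_S, template.beat_duration_s)
    rr = _draw_rr(rng_structure, spec, lower)
    p_flags = rng_structure.random(spec.n_beats) < spec.p_present_prob

    fs = spec.fs
    lead_in = round(0.2 * fs)
    starts = lead_in + np.concatenate(([0], np.cumsum(np.round(rr[:-1] * fs)))).astype(int)
    n_total = int(starts[-1] + round(rr[-1] * fs)) + lead_in

    samples = np.zeros(n_total)
    classes = np.full(n_total, NOWAVE, dtype=np.int64)
    rpeaks = np.empty(spec.n_beats, dtype=int)
    for i, s0 in enumerate(starts):
        beat, mask = generate_beat(template, fs, include_p=bool(p_flags[i]))
        samples[s0:s0 + beat.size] = beat
        classes[s0:s0 + beat.size] = mask.classes
        qrs = np.flatnonzero(mask.classes == QRS)
        rpeaks[i] = s0 + qrs[np.argmax(np.abs(beat[qrs]))]

    if spec.fibrillatory_amp > 0:
        tgrid = np.arange(n_total) / fs
        fwave = spec.fibrillatory_amp * np.sin(2 * np.pi * spec.fibrillatory_freq * tgrid)
        samples = samples + np.where(classes == NOWAVE, fwave, 0.0)

    tgrid = np.arange(n_total) / fs
    if spec.baseline_amp > 0:
        samples = samples + spec.baseline_amp * np.sin(
            2 * np.pi * spec.baseline_freq * tgrid
        )
    if spec.noise_sd > 0:
        samples = samples + rng_noise.normal(0.0, spec.noise_sd, n_total)

    record = EcgRecord(samples, fs, record_id=f"synth-{spec.kind}-{spec.seed}")
    return record, LabelMask(classes), rpeaks


def generate_training_windows(n_windows: int, seed: int = 0,
                              af_fraction: float = 0.5,
                              template: BeatTemplate | None = None,
                              denoise: bool = True):
    """Labeled beat windows for model building: a mixed NSR/AF window set.

    Generates records alternating between NSR and AF specs (so the network
    sees beats both with and without P-waves), denoises them, and cuts
    deployment-style R-peak-anchored windows against the ground-truth mask,
    until ``n_windows`` windows are collected.  Deterministic in ``seed``.
    """
    from .denoise import dwt_denoise
    from .segment import SegmentationConfig, segment_beats

    if n_windows < 1:
        raise ValidationError("n_windows must be >= 1")
    seg = SegmentationConfig(anchor="rpeak_offset")
    windows = []
    i = 0
    while len(windows) < n_windows:
        sub = int(seed) * 1009 + i  # distinct per-record seeds, < 2**31 for small i
        make = RhythmSpec.af if (i % 2 and af_fraction > 0) else RhythmSpec.nsr
        if af_fraction >= 1.0:
            make = RhythmSpec.af
        spec = make(seed=sub, n_beats=25)
        record, mask, rpeaks = generate_record(spec, template)
        if denoise:
            record = dwt_denoise(record)
        windows.extend(segment_beats(record, mask, rpeaks, seg))
        i += 1
    return windows[:n_windows]
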