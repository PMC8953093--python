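"""Rule-based atrial-fibrillation screening from delineated ECG.

After delineation, a record is screened with clinical-style rules rather
than another learned model:

1. RR intervals from consecutive R-peaks: ``rr_ms = (r[i+1]-r[i]) / fs * 1000``
   and instantaneous rate ``bpm = 60000 / rr_ms``.
2. Ventricular-response banding per interval: slow (< 60 BPM),
   normal (60-100 BPM, boundaries inclusive), rapid (> 100 BPM).
3. Rhythm regularity over sliding windows of 5-7 beats: a window is
   "patterned" when every interval lies within a relative tolerance of the
   window median and all intervals share a response band; the record is
   regular when at least half the windows are patterned.
4. P-wave presence: a beat carries a P-wave when its longest predicted
   P run lasts at least 0.06 s; the record has P-waves when at least half
   its beats do.
5. Decision table: a regular rhythm is NSR and an irregular rhythm is AF,
   independent of P-wave presence (P evidence is still recorded) — the
   irregularly irregular rhythm is the decisive hallmark.

Screening performance over labeled record sets is summarized as PPV/NPV/F1
with AF as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .delineator import CnnBiLstmDelineator, DelineatorModel, predict as _predict_window
from .denoise import DenoiseConfig, dwt_denoise
from .errors import InsufficientDataError, ValidationError
from .records import P, EcgRecord, LabelMask, resample
from .segment import SegmentationConfig, detect_rpeaks, segment_beats

AF, NSR = "AF", "NSR"


@dataclass
class RRSeries:
    """R-peak indices with derived interval (ms) and rate (BPM) series."""

    rpeaks: np.ndarray
    fs: float
    rr_ms: np.ndarray
    bpm: np.ndarray


@dataclass
class AfAssessment:
    """Per-record screening evidence and decision.

    ``decision`` is "AF", "NSR", or None when the screener abstained
    (``abstained`` then carries the reason).  ``evidence`` is a structured
    trace of every rule fired, sufficient to reproduce the decision.
    """

    decision: str | None
    rr: RRSeries | None = None
    regular: bool | None = None
    p_present: bool | None = None
    response_pattern: list[str] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)
    abstained: str | None = None


def rr_intervals(rpeaks, fs: float) -> RRSeries:
    """RR series from strictly increasing R-peak sample indices."""
    rpeaks = np.asarray(rpeaks, dtype=int)
    if rpeaks.size < 2:
        raise ValidationError("need at least 2 R-peaks for RR intervals")
    if fs <= 0:
        raise ValidationError("fs must be positive")
    if np.any(np.diff(rpeaks) <= 0):
        raise ValidationError("R-peak indices must be strictly increasing")
    rr_ms = np.diff(rpeaks) / fs * 1000.0
    return RRSeries(rpeaks=rpeaks, fs=fs, rr_ms=rr_ms, bpm=60000.0 / rr_ms)


def classify_response(bpm: float) -> str:
    """Ventricular-response band: 'slow' (<60), 'normal' (60-100), 'rapid' (>100)."""
    if bpm <= 0:
        raise ValidationError("bpm must be positive")
    if bpm < 60.0:
        return "slow"
    if bpm <= 100.0:
        return "normal"
    return "rapid"


def assess_regularity(rr: RRSeries, window_beats: int = 6,
                      rel_tol: float = 0.10) -> tuple[bool, list[dict]]:
    """Sliding-window rhythm-pattern assessment.

    Each window of ``window_beats`` consecutive intervals is patterned iff
    every interval is within ``rel_tol`` of the window median and all its
    response bands agree.  The record is regular iff at least 50% of windows
    are patterned.  Raises :class:`InsufficientDataError` with fewer than
    ``window_beats`` intervals so callers can abstain.
    """
    if not 5 <= window_beats <= 7:
        raise ValidationError("window_beats must be in [5, 7]")
    if rel_tol <= 0:
        raise ValidationError("rel_tol must be positive")
    rr_ms = rr.rr_ms
    if rr_ms.size < window_beats:
        raise InsufficientDataError(
            f"need >= {window_beats} RR intervals, have {rr_ms.size}"
        )
    trace = []
    for s in range(rr_ms.size - window_beats + 1):
        w = rr_ms[s:s + window_beats]
        med = float(np.median(w))
        within = bool(np.all(np.abs(w - med) <= rel_tol * med))
        bands = [classify_response(60000.0 / v) for v in w]
        same_band = len(set(bands)) == 1
        trace.append({
            "start_interval": s,
            "median_rr_ms": med,
            "within_tolerance": within,
            "bands": bands,
            "patterned": within and same_band,
        })
    frac = np.mean([w["patterned"] for w in trace])
    return bool(frac >= 0.5), trace


def detect_p_presence(beat_masks, fs: float, min_dur: float = 0.06,
                      beat_fraction: float = 0.5) -> tuple[bool, list[dict]]:
    """Record-level P-wave presence from per-beat predicted masks.

    A beat has a P-wave iff its longest P run lasts at least ``min_dur``
    seconds (the lower edge of the 0.06-0.08 s presence band); the record is
    P-positive iff at least ``beat_fraction`` of beats are.
    """
    beat_masks = list(beat_masks)
    if not beat_masks:
        raise ValidationError("need at least one beat mask")
    if fs <= 0:
        raise ValidationError("fs must be positive")
    min_samples = min_dur * fs
    trace = []
    for i, mask in enumerate(beat_masks):
        mask = mask if isinstance(mask, LabelMask) else LabelMask(mask)
        p_runs = [e - s for c, s, e in mask.runs() if c == P]
        longest = max(p_runs, default=0)
        trace.append({
            "beat": i,
            "longest_p_run_samples": int(longest),
            "has_p": bool(longest >= min_samples),
        })
    frac = np.mean([b["has_p"] for b in trace])
    return bool(frac >= beat_fraction), trace


def identify_af(p_present: bool, regular: bool) -> AfAssessment:
    """Four-rule decision table; regularity alone decides, P is evidence.

    (present, regular) -> NSR; (absent, regular) -> NSR;
    (present, irregular) -> AF; (absent, irregular) -> AF.
    """
    decision = NSR if regular else AF
    rule = {
        (True, True): "P present + regular rhythm -> normal",
        (False, True): "P absent + regular rhythm -> normal",
        (True, False): "P present + irregular rhythm -> AF",
        (False, False): "P absent + irregular rhythm -> AF",
    }[(bool(p_present), bool(regular))]
    return AfAssessment(
        decision=decision, regular=bool(regular), p_present=bool(p_present),
        evidence={"rule": rule, "inputs": {"p_present": bool(p_present),
                                           "regular": bool(regular)}},
    )


@dataclass(frozen=True)
class ScreenConfig:
    """End-to-end screening settings (deployment-mode segmentation)."""

    target_fs: float = 250.0
    pre_r: float = 0.2
    post_r: float = 0.45
    window_beats: int = 6
    rel_tol: float = 0.10
    p_min_dur: float = 0.06
    p_beat_fraction: float = 0.5
    min_beats: int = 8
    denoise: DenoiseConfig = DenoiseConfig()


def screen_record(record: EcgRecord, model, config: ScreenConfig | None = None) -> AfAssessment:
    """Full pipeline: denoise -> R-peaks -> segment -> delineate -> rules.

    ``model`` is a trained :class:`DelineatorModel` or
    :class:`CnnBiLstmDelineator`.  Records with fewer than ``min_beats``
    detected beats produce an abstention (decision None) rather than a guess.
    """
    config = config or ScreenConfig()
    rec = resample(record, config.target_fs) if record.fs != config.target_fs else record
    rec = dwt_denoise(rec, config.denoise)
    rpeaks = detect_rpeaks(rec)
    if rpeaks.size < config.min_beats:
        return AfAssessment(
            decision=None,
            abstained=f"only {rpeaks.size} beats detected, need {config.min_beats}",
        )
    seg = SegmentationConfig(anchor="rpeak_offset", pre_r=config.pre_r,
                             post_r=config.post_r, target_fs=config.target_fs)
    windows = segment_beats(rec, None, rpeaks, seg)
    if isinstance(model, CnnBiLstmDelineator):
        masks = [LabelMask(m) for m in model.predict(
            np.stack([w.samples for w in windows]))]
    elif isinstance(model, DelineatorModel):
        masks = [_predict_window(model, w)[1] for w in windows]
    else:
        raise ValidationError(f"unsupported model type {type(model).__name__}")

    rr = rr_intervals(rpeaks, config.target_fs)
    try:
        regular, reg_trace = assess_regularity(rr, config.window_beats, config.rel_tol)
    except InsufficientDataError as exc:
        return AfAssessment(decision=None, rr=rr, abstained=str(exc))
    p_present, p_trace = detect_p_presence(
        masks, config.target_fs, config.p_min_dur, config.p_beat_fraction
    )
    result = identify_af(p_present, regular)
    result.rr = rr
    result.response_pattern = [classify_response(b) for b in rr.bpm]
    result.evidence["regularity_trace"] = reg_trace
    result.evidence["p_trace"] = p_trace
    return result


def ppv_npv(decisions, truth):
    """Screening summary with AF as the positive class.

    Returns ``(ppv, npv, f1, counts)``; a ratio with a zero denominator is
    ``None``.  ``counts`` holds TP/FP/TN/FN.
    """
    decisions, truth = list(decisions), list(truth)
    if len(decisions) != len(truth) or not decisions:
        raise ValidationError("decisions and truth must be equal-length, non-empty")
    for v in decisions + truth:
        if v not in (AF, NSR):
            raise ValidationError(f"labels must be 'AF' or 'NSR', got {v!r}")
    tp = sum(d == AF and t == AF for d, t in zip(decisions, truth))
    fp = sum(d == AF and t == NSR for d, t in zip(decisions, truth))
    tn = sum(d == NSR and t == NSR for d, t in zip(decisions, truth))
    fn = sum(d == NSR and t == AF for d, t in zip(decisions, truth))
    ppv = tp / (tp + fp) if (tp + fp) else None
    npv = tn / (tn + fn) if (tn + fn) else None
    sens = tp / (tp + fn) if (tp + fn) else None
    f1 = (2 * ppv * sens / (ppv + sens)
          if ppv is not None and sens is not None and (ppv + sens) > 0 else None)
    return ppv, npv, f1, {"TP": tp, "FP": fp, "TN": tn, "FN": fn}


class AfScreener(BaseEstimator):
    """Estimator facade over :func:`screen_record` for record batches.

    ``predict`` maps a list of :class:`EcgRecord` to "AF"/"NSR" labels
    (abstentions surface as None); ``assess`` returns the full
    :class:`AfAssessment` objects.  The delineation model is a constructor
    argument — typically a fitted :class:`CnnBiLstmDelineator`.
    """

    def __init__(self, model=None, config: ScreenConfig | None = None):
        self.model = model
        self.config = config

    def fit(self, X=None, y=None):
        if self.model is None:
            raise ValidationError("AfScreener requires a trained delineation model")
        self.config_ = self.config or ScreenConfig()
        return self

    def assess(self, records) -> list[AfAssessment]:
        if not hasattr(self, "config_"):
            self.fit()
        return [screen_record(r, self.model, self.config_) for r in records]

    def predict(self, records):
        return [a.decision for a in self.assess(records)]

    def score(self, records, truth):
        """Record-level screening accuracy over non-abstained decisions."""
        pairs = [(d, t) for d, t in zip(self.predict(records), truth) if d is not None]
        if not pairs:
            raise InsufficientDataError("all records abstained")
        return float(np.mean([d == t for d, t in pairs]))
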