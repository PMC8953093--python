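# Methods

This note records the scientific and numerical choices behind the package:
what each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Signal model and data

A record is a uniformly sampled single-lead voltage trace in millivolts
with sampling frequency `fs` (Hz).  Delineation ground truth is a
per-sample class mask over {P=0, QRS=1, T=2, no-wave=3, pad=4}; class runs
are maximal half-open `[start, end)` intervals on 0-based sample indices.
Ground-truth wave intervals must partition the labeled region — an
annotation claiming a sample for two waves is a hard error rather than a
silent priority, because every downstream metric assumes a partition.

Supported formats are a plain CSV dialect (`# fs=<float>` header, then
`index,amplitude_mV` rows), a minimal single-signal WFDB record (text
`.hea` header plus little-endian 16-bit `.dat`, gain 200 ADC units/mV on
write), per-sample mask files (one class integer per line) and interval
mask files (`class,start,end` rows, uncovered samples defaulting to
no-wave).  Resampling uses an anti-aliased polyphase filter
(`scipy.signal.resample_poly`) with a long Kaiser window (β = 12) so that
passband error is ~10⁻⁴ and down–up round trips of band-limited signals
stay below 10⁻³ relative L2 error; output length is
`round(n·target_fs/fs)`.

## Synthetic generator

The generator exists so that every stage — denoising, R-peak detection,
segmentation, the network, the rule engine — can be tested against exact
ground truth without downloading annotated databases.

A beat template fixes wave durations and amplitudes: by default a 0.08 s,
0.15 mV raised-cosine P-wave; 0.05 s PR gap; 0.08 s biphasic QRS whose
rendered maximum equals the 1.0 mV R amplitude exactly; 0.10 s ST gap; and
a 0.14 s, 0.30 mV raised-cosine T-wave (total beat 0.45 s).  These sit in
the textbook ranges for lead II at rest; the P duration matches the upper
edge of the 0.06–0.08 s presence band the AF rules use.

A rhythm spec draws RR intervals i.i.d. from a truncated normal with mean
`mean_rr` and sd `rr_cv·mean_rr`.  NSR defaults: mean 0.8 s (75 BPM),
CV 0.02, every beat carries a P-wave.  AF defaults: mean 0.75 s, CV 0.30,
no P-waves (an optional low-amplitude 6–8 Hz fibrillatory oscillation can
replace them; it stays labeled no-wave).  Draws are rejected below
max(0.3 s, beat duration): 0.3 s is a physiological refractory bound, and
the beat-length bound prevents overlapping beats, which the ground-truth
partition cannot represent.  Templates whose beat does not fit the mean RR
are rejected outright.  Baseline wander (0.05 mV sinusoid at 0.25 Hz) and
white Gaussian noise (sd 0.02 mV by default) are added to the samples from
a random stream separate from the beat-structure stream, so the mask and
the true R-peak list are invariant to the noise settings.

What the generator does *not* emulate: real morphology variation between
beats and patients, pathological wave shapes, muscle-artifact noise with
its 1/f structure, electrode motion, or arrhythmias beyond the NSR/AF
dichotomy.  Tests passing on this generator therefore demonstrate that the
pipeline recovers known structure under controlled noise — not clinical
performance.  Benchmarks on annotated clinical databases are the user's to
supply through the generic readers.

## Denoising

Multilevel DWT with a `sym8` wavelet (symmetric shape limits QRS
distortion), default 8 levels, symmetric signal extension (which changes a
few edge samples; documented rather than hidden).  Records too short for
the requested depth reduce it to the feasible maximum with a warning.

Shrinkage uses the soft threshold with the universal rule
`t = σ̂·√(2 ln N)` where `σ̂` is the MAD-about-the-median of the level's
own coefficients divided by 0.6745.  That rule assumes the coefficients it
sees are noise.  In an 8-level decomposition of ECG at 250 Hz the detail
levels below ~30 Hz are signal-dominated — applying the rule there inflates
`σ̂` with P/T-wave energy and measurably *increases* error against the
clean signal while flattening the P-wave (in our experiments the P peak
shrank from 0.149 to 0.037 mV and RMSE rose from 0.051 to 0.097 mV).
Shrinkage is therefore applied only to the finest `noise_levels` detail
levels (default 2, covering ≳31 Hz), where the assumption holds; deeper
details pass through.  With this choice RMSE against the clean signal
improves (0.051 → 0.037 mV in the same experiment).  Baseline wander is
removed by zeroing the deepest approximation band (≲0.5 Hz at 8 levels and
250 Hz), which also removes the DC offset.  The module is fully
deterministic.

## Segmentation

R-peak detection follows the Pan–Tompkins recipe: zero-phase 5–15 Hz
Butterworth band-pass, squaring, 0.15 s moving-average envelope, peak
picking with a 0.3 s refractory distance and an adaptive height threshold
(20% of the upper-quartile candidate height), then refinement to the
absolute amplitude extremum of the signal within ±0.06 s.  On noise-free
synthetic records detections land within ±2 samples of truth; at 0.05 mV
noise sensitivity stays ≥95% at a ±5-sample tolerance.

Windows are exactly 370 samples at 250 Hz.  Two anchor modes are
first-class: `p_onset` starts at the beat's P-onset and extends to the next
anchor (model building with ground truth), `rpeak_offset` keeps 0.2 s
before to 0.45 s after the R-peak (deployment, where only R-peaks are
known).  Content beyond the beat or record is zero amplitude with the PAD
class, so PAD is always a (possibly empty) suffix.  Windows at record
edges are padded rather than dropped — short strips lose too many beats
otherwise — and consecutive windows may overlap, since per-window
classification is independent.  Training windows are cut in
`rpeak_offset` mode so the network sees exactly the windows the screener
will feed it.

## Network

Shapes for a (370, 1) input: conv stack (370, 8) → (370, 16) → (370, 32) →
(370, 64), Bi-LSTM (370, 1024), head (370, 5).  Convolutions are kernel-3,
stride-1, zero-padded to preserve length, ReLU, no pooling.  The recurrent
layer is a standard LSTM cell per direction — logistic input/forget/output
gates, tanh candidate, `c_t = f_t⊙c_{t−1} + i_t⊙g_t`, `h_t = o_t⊙tanh c_t`,
zero initial state — with the two directions' hidden sequences concatenated
per timestep (hence width 2·512).  The head is a per-timestep affine map
with softmax; predictions take the argmax per sample, ties resolving to the
lowest class index.

Forward pass, backpropagation through time, and Adam are implemented in
numpy.  Weights are Glorot-uniform from a seeded generator; the forget-gate
bias starts at 1.  Training is mini-batch (default 32) categorical
cross-entropy; PAD positions stay in the 5-class target during training and
are excluded only from reported waveform metrics.  A non-finite loss aborts
with a diagnostic naming the learning rate.  With a fixed seed, training is
bit-reproducible on one machine.  There is no early stopping by default;
epochs are a config field.  An empty convolution list yields the
recurrent-only baselines (Bi-LSTM, or unidirectional LSTM via a flag) so
comparison architectures can be built from the same constructor.

The canonical recipe (512 units, 300 epochs, lr 10⁻⁴) reflects GPU-scale
training.  The package's own tests and the acceptance script train a
reduced-scale configuration — the same four-layer conv stack with 48 units
per direction, 15 epochs of Adam at 2·10⁻³ on 500 windows — which a single
CPU handles in about a minute and which reaches >99% held-out per-node
accuracy on the synthetic task.  Problem sizes in the tests (500 training
windows, 100 held-out windows, 40 screening records) were chosen to keep
the full suite comfortably runnable on a laptop-class machine.

Predicted masks convert to fiducials (onset, offset, duration, peak) per
maximal P/QRS/T run; runs shorter than 0.02 s are discarded as spurious —
shorter than any physiological wave and typically single-sample prediction
flicker.

## Evaluation

Confusion matrices count nodes (samples), rows true, columns predicted.
No boundary-tolerance window is applied: a sample predicted one index off
a wave boundary counts as an error.  One-vs-rest per-class metrics come
with explicit null flagging — a zero-denominator ratio is reported as None
and named, never coerced to 0.  Summaries are macro-averaged by default
(micro available) and the macro mean skips undefined classes.  The
precision–recall curve emits one point per distinct score threshold with
AUC by trapezoidal integration over recall, anchored at recall 0 with the
first point's precision; a truth stream that is all one class is an error
since the curve is undefined.

## AF rules

RR intervals in ms are `(r[i+1]−r[i])/fs·1000` and instantaneous rate is
`60000/rr_ms` BPM.  Ventricular-response bands: slow < 60, normal 60–100
(boundaries inclusive — "between 60 and 100" read as a closed interval),
rapid > 100 BPM.

"Has a pattern" is operationalized as: in a sliding window of
`window_beats` consecutive intervals (default 6, valid range 5–7), every
interval lies within `rel_tol` (default 10%) of the window median *and*
all intervals share one response band; the record is regular when at least
half the windows are patterned.  All three constants are configuration
fields.  The median is used as the window center for robustness to a
single ectopic-like interval; 10% is well above respiratory sinus
arrhythmia at rest and well below AF-scale variation.  Note that the band
agreement term makes the rule depend on absolute rate: a steady rhythm
oscillating across the 60 BPM boundary counts as unpatterned.  The
relative-tolerance term alone is invariant to uniform time rescaling, and
that is the component the property tests pin down.

P-wave presence uses only the lower edge of the 0.06–0.08 s band: a beat
has a P-wave when its longest predicted P run lasts ≥ 0.06 s (no upper
cut — an upper cut would mislabel long-but-real P-waves), and the record
is P-positive when ≥ 50% of beats are.

The decision table is total over (p_present, regular): a regular rhythm is
NSR and an irregular rhythm is AF, regardless of P-wave presence.  P
evidence therefore never changes the outcome; it is still computed,
reported and traced, because it is one of the two classic hallmarks and a
consumer of the assessment may weigh it differently.  This tension with
the clinical definition of AF (where P absence is constitutive) is noted,
not resolved — the rule table is implemented as stated.  Records with
fewer than 8 detected beats, or too few intervals for one regularity
window, yield an abstention with a reason instead of a decision.
Screening batches are summarized as PPV, NPV and F1 with AF as the
positive class.

## Known limitations

* The synthetic task is much easier than clinical delineation: fixed beat
  template, stationary Gaussian noise, sinusoidal wander.  Numbers from
  the acceptance script characterize correctness of the machinery, not
  expected clinical performance.
* The WFDB support is a deliberate minimal subset (one signal, format 16);
  it reads and writes its own output and simple third-party headers but is
  not a general WFDB implementation.
* The screener distinguishes only regular from irregular rhythm; atrial
  flutter, frequent ectopy and other irregular rhythms would screen as AF.
* The numpy network is single-threaded BLAS-bound; the canonical 512-unit
  model is practical for inference but training it at scale calls for a
  GPU framework reimplementation of the same architecture.
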