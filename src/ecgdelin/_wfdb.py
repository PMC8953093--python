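"""Minimal single-signal WFDB record support.

Reads and writes the subset of the WFDB format this package needs: a text
``.hea`` header describing one signal plus a little-endian 16-bit ``.dat``
file (WFDB format 16).  Amplitudes are stored as ADC units and converted to
millivolts with the header's gain/baseline on read.

Header layout written here::

    <record> 1 <fs> <n_samples>
    <record>.dat 16 <gain>(<baseline>)/mV 16 0 <first> 0 0 <lead>

Only format 16 and a single signal are accepted on read; anything else raises
:class:`~ecgdelin.errors.FormatError`.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .errors import FormatError, ValidationError

DEFAULT_GAIN = 200.0  # ADC units per mV, the conventional WFDB default


def write_wfdb(path: str, samples: np.ndarray, fs: float, lead: str = "II",
               gain: float = DEFAULT_GAIN) -> None:
    """Write ``samples`` (mV) as <path>.hea / <path>.dat (format 16)."""
    if fs <= 0:
        raise ValidationError(f"fs must be positive, got {fs}")
    base = os.path.basename(path)
    adc = np.round(np.asarray(samples, dtype=float) * gain).astype(np.int16)
    first = int(adc[0]) if adc.size else 0
    with open(path + ".hea", "w") as fh:
        fh.write(f"{base} 1 {fs:g} {len(adc)}\n")
        fh.write(f"{base}.dat 16 {gain:g}(0)/mV 16 0 {first} 0 0 {lead}\n")
    adc.astype("<i2").tofile(path + ".dat")


_SPEC_RE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)\s+(?P<gain>[-\d.eE]+)"
    r"(?:\((?P<baseline>[-\d]+)\))?(?:/(?P<units>\S+))?"
)


def read_wfdb(path: str) -> tuple[np.ndarray, float, str]:
    """Read <path>.hea / <path>.dat; return (samples in mV, fs, lead name)."""
    hea = path + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(hea)
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise FormatError(f"{hea}: expected a record line and one signal line")
    rec_fields = lines[0].split()
    if len(rec_fields) < 4:
        raise FormatError(f"{hea} line 1: need 'name n_sig fs n_samples'")
    try:
        n_sig = int(rec_fields[1])
        fs = float(rec_fields[2])
        n_samples = int(rec_fields[3])
    except ValueError as exc:
        raise FormatError(f"{hea} line 1: non-numeric field ({exc})") from None
    if n_sig != 1:
        raise FormatError(f"{hea}: only single-signal records supported, got {n_sig}")
    if fs <= 0:
        raise ValidationError(f"{hea}: fs must be positive, got {fs}")
    m = _SPEC_RE.match(lines[1])
    if m is None:
        raise FormatError(f"{hea} line 2: unparseable signal specification")
    if int(m.group("fmt")) != 16:
        raise FormatError(f"{hea}: only WFDB format 16 supported, got {m.group('fmt')}")
    gain = float(m.group("gain"))
    if gain == 0:
        gain = DEFAULT_GAIN
    baseline = int(m.group("baseline") or 0)
    lead = lines[1].split()[-1]
    dat = os.path.join(os.path.dirname(path), m.group("file"))
    adc = np.fromfile(dat, dtype="<i2")
    if adc.size < n_samples:
        raise FormatError(f"{dat}: expected {n_samples} samples, found {adc.size}")
    samples = (adc[:n_samples].astype(float) - baseline) / gain
    return samples, fs, lead
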