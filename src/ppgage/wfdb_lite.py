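"""Minimal reader/writer for single-channel physiological waveform records.

Implements the subset of the classic header + binary signal convention needed
to bridge public single-pulse PPG windows into this package: a ``.hea`` text
header naming one signal stored in 16-bit little-endian integers (format 16)
in a companion ``.dat`` file, with gain and baseline for unit conversion.
Multi-segment records, multiplexed channels and other storage formats are out
of scope.
"""

from __future__ import annotations

import os

import numpy as np

__all__ = ["read_record", "write_record"]


def write_record(basepath, signal, fs: float, gain: float = 1000.0,
                 units: str = "au"):
    """Write ``signal`` (physical units) as a format-16 record pair.

    ``basepath`` is the path without extension; ``basepath.hea`` and
    ``basepath.dat`` are produced.  Values are quantized by ``gain`` counts
    per physical unit.
    """
    basepath = os.fspath(basepath)
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    baseline = 0
    digital = np.clip(np.rint(signal * gain) + baseline, -32768, 32767)
    digital = digital.astype("<i2")
    name = os.path.basename(basepath)
    header = (f"{name} 1 {fs:g} {signal.size}\n"
              f"{name}.dat 16 {gain:g}({baseline})/{units} 16 0 "
              f"{int(digital[0])} 0 0 signal\n")
    with open(basepath + ".hea", "w") as fh:
        fh.write(header)
    with open(basepath + ".dat", "wb") as fh:
        fh.write(digital.tobytes())


def read_record(basepath):
    """Read a single-channel format-16 record pair -> (signal, fs).

    ``basepath`` may include the ``.hea`` extension or not.  The signal is
    returned in physical units ((digital - baseline) / gain).
    """
    basepath = os.fspath(basepath)
    if basepath.endswith(".hea"):
        basepath = basepath[:-4]
    with open(basepath + ".hea") as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise ValueError("header must declare a record line and one signal line")
    rec = lines[0].split()
    n_sig = int(rec[1])
    if n_sig != 1:
        raise ValueError(f"only single-channel records supported, got {n_sig}")
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else None

    sig = lines[1].split()
    filename, fmt, gain_spec = sig[0], sig[1], sig[2]
    if fmt != "16":
        raise ValueError(f"only format 16 supported, got format {fmt}")
    baseline = 0
    if "(" in gain_spec:
        gain = float(gain_spec[: gain_spec.index("(")])
        baseline = int(gain_spec[gain_spec.index("(") + 1: gain_spec.index(")")])
    else:
        gain = float(gain_spec.split("/")[0])
    datapath = os.path.join(os.path.dirname(basepath) or ".", filename)
    digital = np.frombuffer(open(datapath, "rb").read(), dtype="<i2")
    if n_samples is not None:
        digital = digital[:n_samples]
    return (digital.astype(float) - baseline) / gain, fs
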