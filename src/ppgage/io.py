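"""Readers and writers for cohort metadata, waveforms and analysis artefacts.

Two waveform dialects are supported — an HDF5 dataset (n x length matrix with
a ``dt_sample`` attribute) and a wide CSV — and both round-trip to identical
in-memory objects.  All writes are atomic (write to a temporary file in the
same directory, then rename), so an interrupted run never leaves a partially
written artefact behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager

import h5py
import numpy as np
import pandas as pd

from .cohort import PulseWaveform, Subject

__all__ = [
    "write_cohort_csv", "read_cohort_csv",
    "write_waveforms_h5", "read_waveforms_h5",
    "write_waveforms_csv", "read_waveforms_csv",
    "read_cohort", "atomic_write", "write_json_atomic",
    "import_record_window", "resample_pulse",
]

COHORT_COLUMNS = ["id", "age", "sex", "stature_m", "true_asi", "true_dt",
                  "morphology_class"]


@contextmanager
def atomic_write(path, mode="w"):
    """Write-temp-then-rename: the target appears only when complete."""
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json_atomic(obj, path):
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------

def write_cohort_csv(subjects, path):
    frame = pd.DataFrame(
        [(s.id, s.age, s.sex, s.stature, s.true_asi, s.true_dt,
          s.morphology_class) for s in subjects],
        columns=COHORT_COLUMNS)
    with atomic_write(path) as fh:
        frame.to_csv(fh, index=False)


def read_cohort_csv(path):
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return [Subject(id=str(r.id), age=float(r.age), sex=str(r.sex),
                    stature=float(r.stature_m), true_asi=float(r.true_asi),
                    true_dt=float(r.true_dt),
                    morphology_class=int(r.morphology_class))
            for r in frame.itertuples(index=False)]


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def write_waveforms_h5(waveforms, path):
    if not waveforms:
        raise ValueError("no waveforms to write")
    dt_sample = waveforms[0].dt_sample
    mat = np.stack([w.samples for w in waveforms])
    ids = np.array([w.subject_id for w in waveforms], dtype="S")
    d = os.path.dirname(os.path.abspath(os.fspath(path)))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".h5.tmp")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            dset = f.create_dataset("waveforms", data=mat)
            dset.attrs["dt_sample"] = dt_sample
            f.create_dataset("subject_id", data=ids)
        os.replace(tmp, os.fspath(path))
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_waveforms_h5(path, expected_length=None):
    with h5py.File(path, "r") as f:
        mat = np.asarray(f["waveforms"], dtype=float)
        dt_sample = float(f["waveforms"].attrs["dt_sample"])
        ids = [i.decode() for i in f["subject_id"][()]]
    return _to_waveforms(mat, ids, dt_sample, expected_length)


def write_waveforms_csv(waveforms, path):
    if not waveforms:
        raise ValueError("no waveforms to write")
    n = len(waveforms[0])
    frame = pd.DataFrame(np.stack([w.samples for w in waveforms]),
                         columns=[f"s{k:03d}" for k in range(n)])
    frame.insert(0, "id", [w.subject_id for w in waveforms])
    frame.insert(1, "dt_sample", [w.dt_sample for w in waveforms])
    with atomic_write(path) as fh:
        frame.to_csv(fh, index=False)


def read_waveforms_csv(path, expected_length=None):
    frame = pd.read_csv(path, float_precision="round_trip")
    ids = frame["id"].astype(str).tolist()
    dt_sample = float(frame["dt_sample"].iloc[0])
    mat = frame.drop(columns=["id", "dt_sample"]).to_numpy(dtype=float)
    return _to_waveforms(mat, ids, dt_sample, expected_length)


def _to_waveforms(mat, ids, dt_sample, expected_length):
    if expected_length is not None and mat.shape[1] != expected_length:
        raise ValueError(f"waveform length {mat.shape[1]} != declared "
                         f"{expected_length}")
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite waveform samples in file")
    return [PulseWaveform(subject_id=i, samples=row, dt_sample=dt_sample)
            for i, row in zip(ids, mat)]


def read_cohort(metadata_path, waveform_path, expected_length=None):
    """Load and cross-validate a cohort (metadata CSV + waveform file).

    The waveform dialect is chosen by extension (.h5/.hdf5 vs .csv).  Any id
    present in one file but not the other is an itemized error.
    """
    subjects = read_cohort_csv(metadata_path)
    wp = os.fspath(waveform_path)
    if wp.endswith((".h5", ".hdf5")):
        waveforms = read_waveforms_h5(wp, expected_length)
    else:
        waveforms = read_waveforms_csv(wp, expected_length)
    meta_ids = {s.id for s in subjects}
    wave_ids = {w.subject_id for w in waveforms}
    if meta_ids != wave_ids:
        only_meta = sorted(meta_ids - wave_ids)[:10]
        only_wave = sorted(wave_ids - meta_ids)[:10]
        raise ValueError(
            "cohort id mismatch: "
            + (f"missing waveforms for {only_meta}; " if only_meta else "")
            + (f"missing metadata for {only_wave}" if only_wave else ""))
    order = {s.id: k for k, s in enumerate(subjects)}
    waveforms.sort(key=lambda w: order[w.subject_id])
    return subjects, waveforms


# ---------------------------------------------------------------------------
# external single-pulse records
# ---------------------------------------------------------------------------

def resample_pulse(samples, target_length: int) -> np.ndarray:
    """Linear-interpolation resampling of a pulse to ``target_length`` samples.

    Preserves relative peak positions: a peak at fraction f of the source
    stays at fraction f of the output (within one sample).
    """
    y = np.asarray(samples, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 samples to resample")
    src = np.linspace(0.0, 1.0, y.size)
    dst = np.linspace(0.0, 1.0, target_length)
    return np.interp(dst, src, y)


def import_record_window(record_path, start: int, stop: int,
                         target_length: int = 100,
                         subject_id: str = "record") -> PulseWaveform:
    """Import one annotated single-pulse window from an external record.

    The record is read with :mod:`ppgage.wfdb_lite` (header + format-16
    signal pair); the half-open sample window [start, stop) is extracted and
    resampled to ``target_length`` samples.  The waveform's ``dt_sample`` is
    the window duration divided by the output length.
    """
    from .wfdb_lite import read_record

    signal, fs = read_record(record_path)
    if not 0 <= start < stop <= signal.size:
        raise ValueError(
            f"window [{start}, {stop}) outside record of {signal.size} samples")
    pulse = resample_pulse(signal[start:stop], target_length)
    duration = (stop - start) / fs
    return PulseWaveform(subject_id=subject_id, samples=pulse,
                         dt_sample=duration / target_length)
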