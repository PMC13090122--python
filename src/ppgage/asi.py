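"""Arterial stiffness index extraction from single-pulse PPG waveforms.

The arterial stiffness index is

    ASI = stature / peak-to-peak distance   (m/s),

where the peak-to-peak distance is the time between the initial systolic peak
and the subsequent reflected peak, a surrogate for pulse-wave transit time
through the arterial tree.  Peak detection handles the common failure mode of
older, stiffer pulses where the reflected wave degenerates into a shoulder:
when no post-systolic local maximum of sufficient prominence exists, the most
concave point of the decay (minimum of the second difference) is used instead
and the result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .buckets import make_age_buckets
from .cohort import PulseWaveform

__all__ = [
    "PeakPair",
    "ASIResult",
    "PeakDetectionError",
    "detect_peaks",
    "compute_asi",
    "extract_asi_table",
    "quantile_summary",
    "robust_quartiles",
]

#: Reflected-peak prominence threshold, as a fraction of waveform amplitude.
DEFAULT_PROMINENCE_FRAC = 0.01
#: Shoulder fallback: second difference must dip below this fraction of
#: amplitude (per sample^2) to count as curvature rather than flat decay.
DEFAULT_SHOULDER_FRAC = 1e-3

QUALITY_OK = "ok"
QUALITY_SHOULDER = "shoulder_fallback"
QUALITY_REJECTED = "rejected"


class PeakDetectionError(ValueError):
    """Raised when no usable peak structure exists in a waveform."""


@dataclass(frozen=True)
class PeakPair:
    systolic_idx: int
    reflected_idx: int
    dt: float  # seconds

    def __post_init__(self):
        if not 0 <= self.systolic_idx < self.reflected_idx:
            raise ValueError("need 0 <= systolic_idx < reflected_idx")


@dataclass(frozen=True)
class ASIResult:
    asi: float | None      # m/s, None when rejected
    peaks: PeakPair | None
    quality_flag: str

    def __post_init__(self):
        if self.quality_flag != QUALITY_REJECTED and not (self.asi and self.asi > 0):
            raise ValueError("accepted results must carry a positive ASI")


def _parabolic_refine(y: np.ndarray, idx: int) -> float:
    """Sub-sample peak location via a parabola through three points."""
    if idx <= 0 or idx >= y.size - 1:
        return float(idx)
    a, b, c = y[idx - 1], y[idx], y[idx + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(idx)
    return idx + 0.5 * (a - c) / denom


def detect_peaks(waveform: PulseWaveform,
                 prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                 shoulder_frac: float = DEFAULT_SHOULDER_FRAC,
                 refine: bool = False):
    """Locate the systolic and reflected peaks of a single pulse.

    Returns (PeakPair, quality_flag).  The systolic peak is the earliest
    global maximum; the reflected peak is the most prominent local maximum
    strictly after it.  If no candidate reaches ``prominence_frac`` of the
    amplitude range, the shoulder fallback is used.  Flat or structureless
    signals raise PeakDetectionError.

    ``refine=True`` applies parabolic sub-sample interpolation to ``dt`` only;
    the returned indices stay integral.
    """
    y = np.asarray(waveform.samples, dtype=float)
    rng_amp = float(np.ptp(y))
    if not np.all(np.isfinite(y)) or rng_amp == 0.0:
        raise PeakDetectionError("constant or non-finite waveform")
    sys_idx = int(np.argmax(y))  # argmax returns the earliest tie
    tail = y[sys_idx:]
    if tail.size < 3:
        raise PeakDetectionError("no samples after the systolic peak")

    flag = QUALITY_OK
    peaks, props = find_peaks(tail, prominence=prominence_frac * rng_amp)
    keep = peaks > 0  # interior maxima strictly after the systolic sample
    peaks, prominences = peaks[keep], props["prominences"][keep]
    if peaks.size:
        ref_rel = int(peaks[np.argmax(prominences)])
    else:
        # Shoulder fallback: most concave-down point of the post-systolic
        # decay, searched only after curvature first turns convex so the
        # systolic bump's own concave core is excluded.
        d2 = np.diff(tail, 2)
        if d2.size == 0:
            raise PeakDetectionError("waveform too short for shoulder analysis")
        past_systolic = np.nonzero(d2 >= 0)[0]
        if past_systolic.size == 0:
            raise PeakDetectionError("no post-systolic structure")
        start = int(past_systolic[0])
        j = start + int(np.argmin(d2[start:]))
        if d2[j] > -shoulder_frac * rng_amp:
            raise PeakDetectionError("no reflected peak or shoulder found")
        ref_rel = j + 1  # diff(.., 2) is centred one sample in
        flag = QUALITY_SHOULDER

    ref_idx = sys_idx + ref_rel
    if refine:
        s = _parabolic_refine(y, sys_idx)
        r = _parabolic_refine(y, ref_idx)
        dt = (r - s) * waveform.dt_sample
    else:
        dt = (ref_idx - sys_idx) * waveform.dt_sample
    return PeakPair(systolic_idx=sys_idx, reflected_idx=ref_idx, dt=dt), flag


def compute_asi(waveform: PulseWaveform, stature: float,
                refine: bool = False) -> ASIResult:
    """ASI = stature / peak-to-peak distance, with the detection quality flag.

    Waveforms whose peak detection fails yield ``quality_flag='rejected'`` and
    no ASI rather than an exception: attrition is data, not an error.
    """
    if stature <= 0:
        raise ValueError("stature must be positive")
    try:
        peaks, flag = detect_peaks(waveform, refine=refine)
    except PeakDetectionError:
        return ASIResult(asi=None, peaks=None, quality_flag=QUALITY_REJECTED)
    return ASIResult(asi=stature / peaks.dt, peaks=peaks, quality_flag=flag)


def extract_asi_table(waveforms, subjects, refine: bool = False) -> pd.DataFrame:
    """Run ASI extraction over a cohort.

    Returns a DataFrame with columns (id, asi, systolic_idx, reflected_idx,
    dt, quality_flag); rejected waveforms carry NaN in the numeric columns.
    """
    stature = {s.id: s.stature for s in subjects}
    rows = []
    for w in waveforms:
        res = compute_asi(w, stature[w.subject_id], refine=refine)
        if res.quality_flag == QUALITY_REJECTED:
            rows.append((w.subject_id, np.nan, np.nan, np.nan, np.nan, res.quality_flag))
        else:
            rows.append((w.subject_id, res.asi, res.peaks.systolic_idx,
                         res.peaks.reflected_idx, res.peaks.dt, res.quality_flag))
    return pd.DataFrame(rows, columns=["id", "asi", "systolic_idx",
                                       "reflected_idx", "dt", "quality_flag"])


def robust_quartiles(values):
    """Quartiles after the 3-IQR outlier rule, on one group of values.

    Q1/Q3/IQR are computed on the raw values (linear interpolation between
    order statistics); values below Q1 - 3*IQR or above Q3 + 3*IQR are
    removed; the reported quartiles are recomputed on what remains.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return None
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    kept = v[(v >= q1 - 3 * iqr) & (v <= q3 + 3 * iqr)]
    rq1, med, rq3 = np.percentile(kept, [25, 50, 75])
    return {"q1": float(rq1), "median": float(med), "q3": float(rq3),
            "n_retained": int(kept.size), "n_removed": int(v.size - kept.size)}


def quantile_summary(values, ages=None, age_range=(40.0, 70.0),
                     width=5.0) -> pd.DataFrame:
    """Per-age-bucket Q1/median/Q3 of ASI after outlier removal.

    With ``ages=None`` all values form a single group.  Empty buckets are
    reported with NaN statistics rather than raised.
    """
    values = np.asarray(values, dtype=float)
    if ages is None:
        groups = [("all", np.ones(values.size, dtype=bool))]
    else:
        ages = np.asarray(ages, dtype=float)
        buckets = make_age_buckets(ages, ids=np.arange(ages.size),
                                   age_range=age_range, width=width)
        groups = [(b.label, np.isin(np.arange(values.size), b.member_ids))
                  for b in buckets]
    rows = []
    for label, mask in groups:
        stats = robust_quartiles(values[mask])
        if stats is None:
            rows.append({"bucket": label, "q1": np.nan, "median": np.nan,
                         "q3": np.nan, "n_retained": 0, "n_removed": 0})
        else:
            rows.append({"bucket": label, **stats})
    return pd.DataFrame(rows)
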