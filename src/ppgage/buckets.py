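"""Half-open 5-year age buckets used throughout the analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AgeBucket", "make_age_buckets", "assign_bucket"]


@dataclass
class AgeBucket:
    """A half-open age interval [lo, hi) with the subject ids that fall in it."""

    lo: float
    hi: float
    member_ids: list = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"[{self.lo:g},{self.hi:g})"

    def contains(self, age: float) -> bool:
        return self.lo <= age < self.hi


def make_age_buckets(ages, ids=None, age_range=(40.0, 70.0), width=5.0):
    """Tile ``age_range`` with half-open buckets of the given width.

    The final bucket is closed on the right so the top of the range is not
    dropped (a subject aged exactly 70 belongs to [65, 70)).
    """
    lo, hi = float(age_range[0]), float(age_range[1])
    if hi <= lo:
        raise ValueError("age_range must be increasing")
    edges = np.arange(lo, hi + 1e-9, width)
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    ages = np.asarray(ages, dtype=float)
    if ids is None:
        ids = np.arange(ages.size)
    ids = np.asarray(ids)
    buckets = [AgeBucket(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    for sid, age in zip(ids, ages):
        k = assign_bucket(age, edges)
        if k is not None:
            buckets[k].member_ids.append(sid)
    return buckets


def assign_bucket(age, edges):
    """Index of the bucket containing ``age``, or None if outside the range."""
    edges = np.asarray(edges, dtype=float)
    if age < edges[0] or age > edges[-1]:
        return None
    k = int(np.searchsorted(edges, age, side="right") - 1)
    return min(k, len(edges) - 2)
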