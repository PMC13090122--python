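"""Cross-bucket morphology similarity and per-bucket waveform summaries.

The striking qualitative feature of single-pulse PPG cohorts is that pulse
shape barely tracks age: one can assemble groups of near-identical waveforms
whose members come from *different* 5-year age buckets, while waveforms
within a single bucket vary widely.  This module reconstructs that analysis:
a greedy seed-and-extend search for low-spread groups with one member per
bucket (with an exhaustive-search reference for small instances), and
per-bucket mean/spread overlays.

All comparisons use Euclidean distance on min-max-normalized waveforms, so
group membership is invariant to amplitude rescaling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .buckets import AgeBucket, make_age_buckets

__all__ = [
    "AgeBucket", "make_age_buckets", "SimilarityGroup",
    "normalize_waveform", "cross_bucket_groups", "bucket_mean_overlay",
]

#: A selected group must be at least this many times farther from every other
#: selected group than its own internal spread.
DEFAULT_INTER_INTRA_RATIO = 2.0


@dataclass(frozen=True)
class SimilarityGroup:
    member_ids: tuple
    source_buckets: tuple       # bucket labels, aligned with member_ids
    intra_distance: float       # mean pairwise distance within the group
    one_per_bucket: bool = True

    def __post_init__(self):
        if self.one_per_bucket and len(set(self.source_buckets)) != len(self.source_buckets):
            raise ValueError("one-per-bucket group has a repeated bucket")


def normalize_waveform(samples) -> np.ndarray:
    """Min-max scale to [0, 1]; constant signals are an error."""
    y = np.asarray(samples, dtype=float)
    rng = np.ptp(y)
    if rng == 0.0:
        raise ValueError("cannot normalize a constant waveform")
    return (y - y.min()) / rng


def _normalized_matrix(waveforms):
    ids, rows = [], []
    for w in waveforms:
        ids.append(w.subject_id)
        rows.append(normalize_waveform(w.samples))
    return ids, np.stack(rows)


def _group_score(dist, members):
    pairs = list(itertools.combinations(members, 2))
    return float(np.mean([dist[i, j] for i, j in pairs]))


def _inter_distance(dist, a, b):
    return float(np.mean([[dist[i, j] for j in b] for i in a]))


def _select_groups(dist, candidates, n_groups, ratio):
    """Pick the lowest-spread candidates subject to mutual dissimilarity."""
    seen, selected = set(), []
    for members, score in sorted(candidates, key=lambda c: c[1]):
        key = frozenset(members)
        if key in seen:
            continue
        seen.add(key)
        ok = True
        for other, other_score in selected:
            intra = 0.5 * (score + other_score)
            if set(members) & set(other) or \
                    _inter_distance(dist, members, other) <= ratio * max(intra, 1e-12):
                ok = False
                break
        if ok:
            selected.append((members, score))
            if len(selected) == n_groups:
                break
    return selected


def _refine(dist, members, bucket_members):
    """Coordinate descent: swap each member for the best same-bucket choice."""
    members = list(members)
    for _ in range(20):
        changed = False
        for slot, pool in enumerate(bucket_members):
            rest = members[:slot] + members[slot + 1:]
            best = min(pool, key=lambda c: sum(dist[c, r] for r in rest))
            if best != members[slot]:
                members[slot] = best
                changed = True
        if not changed:
            break
    return tuple(members)


def cross_bucket_groups(waveforms, buckets, group_size: int = 6,
                        n_groups: int = 2,
                        ratio: float = DEFAULT_INTER_INTRA_RATIO,
                        method: str = "greedy"):
    """Find groups of near-identical waveforms with one member per age bucket.

    Greedy search: every waveform seeds a candidate group built from its
    nearest neighbour in each other bucket (keeping the ``group_size`` - 1
    closest buckets when fewer than all are wanted), then refined by
    coordinate descent on the group's mean pairwise distance.  The
    ``n_groups`` lowest-spread candidates are returned, subject to every pair
    of selected groups being mutually dissimilar (mean inter-group distance
    > ``ratio`` x their intra-group spread).

    ``method="exhaustive"`` scores every one-per-bucket combination instead;
    it is combinatorial and intended as a small-instance reference.
    """
    nonempty = [b for b in buckets if b.member_ids]
    empty = [b.label for b in buckets if not b.member_ids]
    if empty:
        raise ValueError(f"empty age buckets: {', '.join(empty)}")
    if group_size > len(nonempty):
        raise ValueError("group_size cannot exceed the number of buckets")

    ids, X = _normalized_matrix(waveforms)
    index_of = {sid: i for i, sid in enumerate(ids)}
    dist = np.sqrt(np.maximum(
        ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1), 0.0))
    bucket_rows = [np.array([index_of[sid] for sid in b.member_ids])
                   for b in nonempty]
    labels = [b.label for b in nonempty]

    candidates = []
    if method == "exhaustive":
        for combo in itertools.combinations(range(len(nonempty)), group_size):
            pools = [bucket_rows[c] for c in combo]
            for members in itertools.product(*pools):
                candidates.append((tuple(members), _group_score(dist, members)))
    elif method == "greedy":
        for b_idx, rows in enumerate(bucket_rows):
            for seed_row in rows:
                others = [(c, int(bucket_rows[c][np.argmin(dist[seed_row, bucket_rows[c]])]))
                          for c in range(len(nonempty)) if c != b_idx]
                others.sort(key=lambda cn: dist[seed_row, cn[1]])
                chosen = others[: group_size - 1]
                combo = sorted([b_idx] + [c for c, _ in chosen])
                members = [seed_row if c == b_idx
                           else dict(chosen)[c] for c in combo]
                pools = [bucket_rows[c] for c in combo]
                members = _refine(dist, members, pools)
                candidates.append((members, _group_score(dist, members)))
    else:
        raise ValueError(f"unknown method {method!r}")

    bucket_of_row = {}
    for lbl, rows in zip(labels, bucket_rows):
        for r in rows:
            bucket_of_row[int(r)] = lbl
    selected = _select_groups(dist, candidates, n_groups, ratio)
    return [SimilarityGroup(
        member_ids=tuple(ids[m] for m in members),
        source_buckets=tuple(bucket_of_row[int(m)] for m in members),
        intra_distance=score)
        for members, score in selected]


def bucket_mean_overlay(waveforms, buckets):
    """Pointwise mean and SD of normalized waveforms per age bucket.

    Returns {bucket label: (mean, sd)}; an empty bucket is an error.
    """
    ids, X = _normalized_matrix(waveforms)
    index_of = {sid: i for i, sid in enumerate(ids)}
    out = {}
    for b in buckets:
        if not b.member_ids:
            raise ValueError(f"empty age bucket {b.label}")
        rows = X[[index_of[sid] for sid in b.member_ids]]
        out[b.label] = (rows.mean(axis=0), rows.std(axis=0))
    return out


def plot_bucket_overlay(waveforms, buckets, ax=None):
    """Fig.-2-style panel: per-bucket mean pulse with a +/-1 SD band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    summaries = bucket_mean_overlay(waveforms, buckets)
    for label, (mean, sd) in summaries.items():
        t = np.arange(mean.size)
        (line,) = ax.plot(t, mean, label=label)
        ax.fill_between(t, mean - sd, mean + sd, alpha=0.15,
                        color=line.get_color())
    ax.set_xlabel("sample")
    ax.set_ylabel("normalized amplitude")
    ax.legend(title="age bucket", fontsize=8)
    return ax
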