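"""Two-dimensional projection of learned embeddings for age-gradient checks.

After training a waveform-to-age network, the pooled pre-head embeddings are
projected to 2-D with UMAP (a pairwise-structure-preserving manifold
approximation method) for visual inspection of whether age dominates the
learned representation.  The ``age_gradient_score`` summarizes the question
as a scalar: the strongest monotone association between either projected
axis and age.  This stage is diagnostic; no quantitative claims hang on the
projection coordinates themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

__all__ = ["Projection2D", "project", "age_gradient_score", "plot_projection"]


@dataclass(frozen=True)
class Projection2D:
    coords: np.ndarray          # (n, 2), finite
    ages: np.ndarray | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("projection coordinates must be finite")
        if self.ages is not None:
            ages = np.asarray(self.ages, dtype=float)
            if ages.size != coords.shape[0]:
                raise ValueError("ages must align with coords")
            object.__setattr__(self, "ages", ages)


def project(embeddings, seed: int, ages=None, n_neighbors: int = 15,
            min_dist: float = 0.1, n_epochs: int | None = None) -> Projection2D:
    """Project an embedding matrix to 2-D, deterministically per seed."""
    X = np.asarray(embeddings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10 or X.shape[1] < 2:
        raise ValueError("need an (n >= 10, dim >= 2) embedding matrix")
    if X.shape[0] <= n_neighbors:
        raise ValueError(
            f"need more rows ({X.shape[0]}) than neighbours ({n_neighbors})")
    # The projection is a function of the embedding: identical rows must land
    # on identical coordinates, so duplicates are collapsed before fitting.
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    k = min(n_neighbors, max(2, uniq.shape[0] - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced determinism
        import umap

        reducer = umap.UMAP(n_components=2, n_neighbors=k,
                            min_dist=min_dist, n_epochs=n_epochs,
                            random_state=seed & 0x7FFFFFFF)
        coords = np.asarray(reducer.fit_transform(uniq), dtype=float)[inverse]
    return Projection2D(coords=coords,
                        ages=None if ages is None else np.asarray(ages, float))


def age_gradient_score(projection: Projection2D, ages=None) -> float:
    """max over the two axes of |Spearman rho| between coordinate and age.

    1 means one axis orders subjects exactly by age; ~0 means neither axis
    carries a monotone age gradient.  A constant axis contributes 0.
    """
    a = projection.ages if ages is None else np.asarray(ages, dtype=float)
    if a is None:
        raise ValueError("ages required, either on the projection or passed in")
    if a.size < 10:
        raise ValueError("need at least 10 points")
    score = 0.0
    for axis in range(2):
        coord = projection.coords[:, axis]
        if np.ptp(coord) == 0.0:
            continue
        rho = spearmanr(coord, a).statistic
        if np.isfinite(rho):
            score = max(score, abs(float(rho)))
    return score


def plot_projection(projection: Projection2D, ax=None, title=None):
    """Scatter the 2-D projection coloured by age (Fig.-4-style panel)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    c = projection.ages
    sc = ax.scatter(projection.coords[:, 0], projection.coords[:, 1],
                    c=c, s=8, cmap="viridis")
    if c is not None:
        plt.colorbar(sc, ax=ax, label="age (years)")
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    if title:
        ax.set_title(title)
    return ax
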