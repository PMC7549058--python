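"""Reliability analysis and PCA of the 18-adjective impression ratings.

Mean ratings over raters are standardized per item and decomposed by PCA of
the item correlation matrix.  The first two components are interpreted as the
valence (emotionally negative-positive) and dominance (obedient-dominant)
dimensions of facial impression space.  Loadings are unit eigenvector weights;
component signs are fixed by anchor items so that, e.g., "lively" loads
positively on valence and "dignified" on dominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmark_io import RatingTable

__all__ = [
    "ImpressionSpace",
    "cronbach_alpha",
    "mean_over_raters",
    "impression_pca",
    "DEFAULT_ANCHORS",
]

#: default sign anchors: item whose loading is forced positive on each component
DEFAULT_ANCHORS: tuple[str, ...] = ("lively", "dignified")


@dataclass
class ImpressionSpace:
    """PCA decomposition of the faces x items mean-rating matrix."""

    scores: np.ndarray  # (faces, C): PC1 = valence, PC2 = dominance
    loadings: np.ndarray  # (items, C), unit-norm columns
    variance_explained: np.ndarray  # (C,)
    item_order: list[str] = field(default_factory=list)

    @property
    def valence(self) -> np.ndarray:
        return self.scores[:, 0]

    @property
    def dominance(self) -> np.ndarray:
        return self.scores[:, 1]


def cronbach_alpha(item_slice: np.ndarray) -> float:
    """Cronbach's alpha for one item's faces x raters score matrix.

    Raters play the role of the k scale "items" and faces are the cases:

        alpha = k/(k-1) * (1 - sum_r var_r / var_total)

    with sample variances (n-1 denominator); ``var_total`` is the variance of
    the per-face rater sums.
    """
    x = np.asarray(item_slice, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 faces and 2 raters")
    k = x.shape[1]
    var_total = x.sum(axis=1).var(ddof=1)
    if var_total == 0:
        raise ValueError("total score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / var_total))


def mean_over_raters(ratings: RatingTable) -> np.ndarray:
    """Arithmetic mean over the rater axis, giving the faces x items matrix."""
    return ratings.values.mean(axis=2)


def impression_pca(
    means: np.ndarray,
    item_order: list[str] | None = None,
    anchors: tuple[str, ...] = DEFAULT_ANCHORS,
) -> ImpressionSpace:
    """Correlation-matrix PCA of the faces x items mean ratings.

    Items are z-scored across faces (so the analysis is invariant to item
    scale), and the eigenvectors of the item correlation matrix give the
    loadings; ``variance_explained[c]`` is eigenvalue_c / n_items, and scores
    are the z-matrix projected on the loadings.  For component ``c`` with an
    anchor item, the sign is flipped so that the anchor's loading is positive.
    """
    x = np.asarray(means, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("impression PCA needs at least 3 faces")
    n_faces, n_items = x.shape
    if item_order is None:
        item_order = [f"item_{i}" for i in range(n_items)]
    if len(item_order) != n_items:
        raise ValueError("item_order length does not match the item axis")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = item_order[int(np.argmin(sd))]
        raise ValueError(f"item {bad!r} is constant across faces")
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (n_faces - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    loadings = eigvec[:, order]
    strict_anchors = tuple(anchors) != DEFAULT_ANCHORS
    for c, anchor in enumerate(anchors):
        if c >= loadings.shape[1]:
            break
        matches = [i for i, name in enumerate(item_order) if anchor in name]
        if not matches:
            if strict_anchors:
                raise ValueError(f"anchor item {anchor!r} not found among items")
            # default anchors on unnamed items: orient by the loading sum
            if loadings[:, c].sum() < 0:
                loadings[:, c] = -loadings[:, c]
            continue
        if loadings[matches[0], c] < 0:
            loadings[:, c] = -loadings[:, c]
    scores = z @ loadings
    return ImpressionSpace(
        scores=scores,
        loadings=loadings,
        variance_explained=eigval / n_items,
        item_order=list(item_order),
    )
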