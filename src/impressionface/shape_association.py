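"""Permutational multivariate regression of shape scores on impression scores.

Association between the multivariate shape-PC response and impression
predictors is tested with a distance-based pseudo-F: Euclidean distances among
response rows are Gower-centered, sums of squares are partitioned sequentially
(Type I) over the predictors via hat-matrix projections of nested design
matrices, and significance comes from permuting response rows.  With
Euclidean distances this decomposition coincides with redundancy-analysis
sums of squares, which is used as an internal cross-check.

Shape-regression displacement fields (per-landmark slopes of aligned
coordinates on an impression score) provide the visualization/transformation
vectors used downstream to build shape-transformed stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AssociationResult",
    "ShapeRegressionVector",
    "permanova_regression",
    "shape_score_regression",
]


@dataclass
class AssociationResult:
    """Sequential pseudo-F table for a distance-based multivariate regression."""

    terms: list[str]
    df: np.ndarray  # per-term, then residual df appended
    SS: np.ndarray  # per-term, then residual, then total
    pseudo_F: np.ndarray  # per-term
    R2: np.ndarray  # per-term SS / total SS
    p_perm: np.ndarray  # per-term permutation p-values
    n_perm: int
    seed: int

    def summary(self) -> "pd.DataFrame":  # noqa: F821 - optional pandas
        import pandas as pd

        rows = list(self.terms) + ["Residual", "Total"]
        df_col = list(self.df) + [""]
        ss = list(self.SS)
        f_col = list(self.pseudo_F) + ["", ""]
        r2 = list(self.R2) + [self.SS[-2] / self.SS[-1], 1.0]
        p = list(self.p_perm) + ["", ""]
        return pd.DataFrame(
            {"df": df_col, "SS": ss, "pseudo_F": f_col, "R2": r2, "p_perm": p},
            index=rows,
        )


def _chunked(iterable, size):
    import itertools

    it = iter(iterable)
    while True:
        block = list(itertools.islice(it, size))
        if not block:
            return
        yield block


def _hat(X: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of X."""
    q, r = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    q = q[:, :rank]
    return q @ q.T


def permanova_regression(
    response: np.ndarray,
    predictors: np.ndarray,
    labels: Sequence[str] | None = None,
    n_perm: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> AssociationResult:
    """Distance-based multivariate regression with permutation tests.

    Parameters
    ----------
    response : ndarray, shape (n, M)
        Multivariate response (e.g. retained shape-PC scores).
    predictors : ndarray, shape (n, q)
        Predictor columns entered sequentially in the given order (Type I
        sums of squares); enter a covariate first to control for it.
    labels : sequence of str, optional
        One label per predictor column.
    n_perm : int
        Number of random permutations of the response rows; the p-value uses
        the (count + 1)/(n_perm + 1) estimator and is never zero.
    seed : int
        Seed for the permutation stream.
    exhaustive : bool
        Enumerate all n! row permutations (identity included) instead of
        sampling; the p-value is then the exact permutation p,
        ``#{F* >= F} / n!``.  Only sensible for very small n.

    Notes
    -----
    For a univariate response the pseudo-F of a single predictor equals the
    classical regression F statistic.
    """
    Y = np.atleast_2d(np.asarray(response, dtype=float))
    if Y.ndim == 2 and Y.shape[0] == 1 and np.asarray(response).ndim == 1:
        Y = Y.T
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, q = X.shape
    if Y.shape[0] != n:
        raise ValueError("response and predictors disagree on n")
    if n <= q + 1:
        raise ValueError("need n > number of predictors + 1")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if labels is None:
        labels = [f"x{j+1}" for j in range(q)]
    labels = list(labels)
    if len(labels) != q:
        raise ValueError("one label per predictor column required")

    ones = np.ones((n, 1))
    full = np.column_stack([ones, X])
    if np.linalg.matrix_rank(full) < q + 1:
        raise ValueError("rank-deficient design (collinear predictors)")

    # Gower-centered inner-product matrix of the Euclidean response distances;
    # for Euclidean D this is just the double-centered Gram matrix of Y.
    Yc = Y - Y.mean(axis=0)
    G = Yc @ Yc.T

    hats = [_hat(ones)]
    dfs = []
    for j in range(q):
        hats.append(_hat(np.column_stack([ones, X[:, : j + 1]])))
        dfs.append(1)
    H_full = hats[-1]
    df_res = n - 1 - q

    A = np.stack([hats[j + 1] - hats[j] for j in range(q)])  # per-term projectors
    dfs_arr = np.array(dfs, dtype=float)

    SS_terms = np.einsum("qij,ij->q", A, G)
    SS_res = float(np.trace(G) - np.sum(H_full * G))
    SS_total = float(np.trace(G))
    F_obs = (SS_terms / dfs_arr) / (SS_res / df_res)

    def f_for_perms(P: np.ndarray) -> np.ndarray:
        """Pseudo-F per term for a (chunk, n) array of row permutations."""
        Gp = G[P[:, :, None], P[:, None, :]]
        ss_t = np.einsum("qij,cij->cq", A, Gp)
        ss_r = np.einsum("cii->c", Gp) - np.einsum("ij,cij->c", H_full, Gp)
        return (ss_t / dfs_arr) / (ss_r / df_res)[:, None]

    exceed = np.zeros(q)
    # F is permutation-invariant only in distribution; tolerate float jitter
    # when comparing against the observed statistic
    eps = 1e-12 * max(1.0, np.abs(F_obs).max())
    if exhaustive:
        import itertools
        import math

        total = math.factorial(n)
        for chunk_iter in _chunked(itertools.permutations(range(n)), 512):
            exceed += (f_for_perms(np.asarray(chunk_iter)) >= F_obs - eps).sum(axis=0)
        p_perm = exceed / total
        n_perm = total
    else:
        rng = np.random.default_rng(seed)
        done = 0
        while done < n_perm:
            chunk = min(256, n_perm - done)
            P = np.stack([rng.permutation(n) for _ in range(chunk)])
            exceed += (f_for_perms(P) >= F_obs - eps).sum(axis=0)
            done += chunk
        p_perm = (exceed + 1) / (n_perm + 1)

    return AssociationResult(
        terms=labels,
        df=np.array(dfs + [df_res]),
        SS=np.concatenate([SS_terms, [SS_res, SS_total]]),
        pseudo_F=F_obs,
        R2=SS_terms / SS_total,
        p_perm=p_perm,
        n_perm=n_perm,
        seed=seed,
    )


@dataclass
class ShapeRegressionVector:
    """Per-landmark displacement per unit predictor, in Procrustes units."""

    field: np.ndarray = None  # (K, 2)
    predictor_sd: float = 0.0
    intercept_shape: np.ndarray = None  # (K, 2): fitted shape at the mean score

    def displacement(self, k_sd: float) -> np.ndarray:
        """Displacement field at ``k_sd`` standard deviations of the predictor."""
        return k_sd * self.predictor_sd * self.field


def shape_score_regression(aligned: np.ndarray, score: np.ndarray) -> ShapeRegressionVector:
    """Simple linear regression of every aligned coordinate on one score.

    ``field[k]`` is the (dx, dy) slope of landmark ``k`` per unit score;
    ``intercept_shape`` is the fitted shape at the mean score (the consensus
    for centered scores).
    """
    arr = np.asarray(aligned, dtype=float)
    s = np.asarray(score, dtype=float)
    if arr.ndim != 3 or arr.shape[0] != s.shape[0]:
        raise ValueError("aligned must be (n, K, 2) matching score length")
    sd = s.std(ddof=1)
    if sd == 0:
        raise ValueError("score is constant; regression undefined")
    sc = s - s.mean()
    flat = arr.reshape(arr.shape[0], -1)
    slopes = (sc @ (flat - flat.mean(axis=0))) / (sc @ sc)
    mean_shape = flat.mean(axis=0)
    return ShapeRegressionVector(
        field=slopes.reshape(arr.shape[1], 2),
        predictor_sd=float(sd),
        intercept_shape=mean_shape.reshape(arr.shape[1], 2),
    )
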