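"""Geometric-morphometric core: GPA, sliding semilandmarks, symmetrization, shape PCA.

The pipeline order mirrors standard landmark-based morphometric practice for
faces digitized with fixed landmarks plus outline semilandmarks:

1. slide semilandmarks along their curve tangents to minimize thin-plate-spline
   bending energy against the sample consensus,
2. symmetrize each configuration by averaging it with its relabeled reflection
   (faces are treated as objects with bilateral symmetry),
3. generalized Procrustes superimposition (translation, scale, proper rotation),
4. covariance PCA of the superimposed coordinates ("relative warps"),
5. retention of the smallest leading component set reaching a cumulative
   variance threshold (default 95%).

All operations are pure functions of their inputs; nothing reads global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .landmark_io import LandmarkConfiguration

__all__ = [
    "LandmarkScheme",
    "ProcrustesResult",
    "ShapeSpace",
    "centroid_size",
    "align_pair",
    "generalized_procrustes",
    "bending_energy_matrix",
    "slide_semilandmarks",
    "symmetrize",
    "shape_pca",
    "select_components",
]


# ---------------------------------------------------------------------------
# scheme


@dataclass
class LandmarkScheme:
    """Roles of the K landmarks: semilandmarks, curves, bilateral pairing.

    Parameters
    ----------
    n_landmarks : int
        Total point count K.
    semilandmarks : sequence of int
        Indices whose tangential position is optimized during sliding.
    curves : sequence of sequence of int
        Ordered index lists; every semilandmark lies on exactly one curve.
        Curves may include fixed landmarks as anchors (used for tangents only).
    pairs : sequence of (int, int)
        Bilateral (left, right) index pairs.
    midline : sequence of int
        Unpaired landmarks on the symmetry axis.
    """

    n_landmarks: int
    semilandmarks: tuple[int, ...]
    curves: tuple[tuple[int, ...], ...]
    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]

    def __post_init__(self) -> None:
        self.semilandmarks = tuple(self.semilandmarks)
        self.curves = tuple(tuple(c) for c in self.curves)
        self.pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        self.midline = tuple(self.midline)
        covered = sorted([i for p in self.pairs for i in p] + list(self.midline))
        if covered != list(range(self.n_landmarks)):
            raise ValueError("pairs and midline must cover every index exactly once")
        owner: dict[int, int] = {}
        for ci, curve in enumerate(self.curves):
            for idx in curve:
                if idx in self.semilandmarks:
                    if idx in owner:
                        raise ValueError(f"semilandmark {idx} lies on more than one curve")
                    owner[idx] = ci
        missing = set(self.semilandmarks) - set(owner)
        if missing:
            raise ValueError(f"semilandmarks {sorted(missing)} belong to no curve")

    @property
    def fixed(self) -> tuple[int, ...]:
        sl = set(self.semilandmarks)
        return tuple(i for i in range(self.n_landmarks) if i not in sl)

    def reflection_permutation(self) -> np.ndarray:
        """Index permutation swapping left and right labels (an involution)."""
        perm = np.arange(self.n_landmarks)
        for a, b in self.pairs:
            perm[a], perm[b] = b, a
        return perm

    def to_dict(self) -> dict:
        return {
            "n_landmarks": self.n_landmarks,
            "semilandmarks": list(self.semilandmarks),
            "curves": [list(c) for c in self.curves],
            "pairs": [list(p) for p in self.pairs],
            "midline": list(self.midline),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkScheme":
        return cls(
            n_landmarks=int(d["n_landmarks"]),
            semilandmarks=tuple(d["semilandmarks"]),
            curves=tuple(tuple(c) for c in d["curves"]),
            pairs=tuple(tuple(p) for p in d["pairs"]),
            midline=tuple(d["midline"]),
        )

    def curve_of(self, semilandmark: int) -> tuple[int, ...]:
        for curve in self.curves:
            if semilandmark in curve:
                return curve
        raise KeyError(semilandmark)


# ---------------------------------------------------------------------------
# Procrustes


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks from their centroid."""
    pts = np.asarray(points, dtype=float)
    return float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum()))


def _as_array(configs: Sequence[LandmarkConfiguration] | np.ndarray) -> np.ndarray:
    if isinstance(configs, np.ndarray):
        arr = configs.astype(float)
    else:
        arr = np.stack([c.points for c in configs]).astype(float)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError(f"expected (n, K, 2) configurations, got {arr.shape}")
    return arr


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||source @ R - target||_F.

    Both inputs must be centered.  Reflections are excluded: bilateral
    asymmetry is handled explicitly by symmetrization, not absorbed here.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def align_pair(moving: np.ndarray, fixed: np.ndarray, scale: bool = True) -> np.ndarray:
    """Ordinary (two-shape) Procrustes fit of ``moving`` onto ``fixed``.

    Centers both, optionally scales ``moving`` to the centroid size of
    ``fixed``, and applies the optimal proper rotation.  Returns the fitted
    copy of ``moving`` positioned at the centroid of ``fixed``.
    """
    fc = fixed.mean(axis=0)
    m = moving - moving.mean(axis=0)
    f = fixed - fc
    if scale:
        ms = np.sqrt((m**2).sum())
        if ms == 0:
            raise ValueError("degenerate configuration with zero centroid size")
        m = m * (np.sqrt((f**2).sum()) / ms)
    return m @ _optimal_rotation(m, f) + fc


@dataclass
class ProcrustesResult:
    """Output of generalized Procrustes superimposition."""

    aligned: np.ndarray  # (n, K, 2), Procrustes units
    mean_shape: np.ndarray  # (K, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    converged: bool


def generalized_procrustes(
    configs: Sequence[LandmarkConfiguration] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Iterative superimposition removing translation, scale and rotation.

    Each configuration is centered and scaled to unit centroid size, then
    repeatedly rotated to the running consensus (itself rescaled to unit
    centroid size each round) until the consensus moves by less than ``tol``
    in Frobenius norm or ``max_iter`` rounds elapse.
    """
    arr = _as_array(configs)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("generalized Procrustes needs at least 2 configurations")
    if arr.shape[1] < 3:
        raise ValueError("need at least 3 landmarks")
    sizes = np.array([centroid_size(a) for a in arr])
    if np.any(sizes == 0):
        bad = int(np.argmin(sizes))
        raise ValueError(f"configuration {bad} has zero centroid size")
    work = (arr - arr.mean(axis=1, keepdims=True)) / sizes[:, None, None]
    consensus = work[0].copy()
    consensus /= np.sqrt((consensus**2).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            work[i] = work[i] @ _optimal_rotation(work[i], consensus)
        new = work.mean(axis=0)
        new /= np.sqrt((new**2).sum())
        delta = np.linalg.norm(new - consensus)
        consensus = new
        if delta < tol:
            converged = True
            break
    return ProcrustesResult(
        aligned=work,
        mean_shape=consensus,
        centroid_sizes=sizes,
        iterations=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# bending energy and sliding


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending-energy matrix of a reference configuration.

    With kernel U(r) = r^2 log r^2 the TPS system matrix is::

        L = [[U, Q],     Q = [1 | x | y]   (K x 3)
             [Q', 0]]

    The returned K x K matrix is the upper-left block of L^-1.  It is
    symmetric, positive semi-definite, and annihilates affine displacement
    fields; v' E v is the bending energy of the scalar displacement v.
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    if np.any(d2[~np.eye(k, dtype=bool)] == 0):
        raise ValueError("coincident reference points make the TPS kernel singular")
    with np.errstate(divide="ignore", invalid="ignore"):
        U = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    Q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = U
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.inv(L)
    E = Linv[:k, :k]
    return (E + E.T) / 2.0


def _tangents(points: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Unit tangent direction at each semilandmark (zeros at fixed landmarks).

    Central difference of the curve neighbors; one-sided at curve endpoints.
    """
    t = np.zeros_like(points)
    for j in scheme.semilandmarks:
        curve = scheme.curve_of(j)
        pos = curve.index(j)
        lo = curve[pos - 1] if pos > 0 else j
        hi = curve[pos + 1] if pos < len(curve) - 1 else j
        vec = points[hi] - points[lo]
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise ValueError(f"zero-length tangent at semilandmark {j}")
        t[j] = vec / norm
    return t


def slide_semilandmarks(
    configs: Sequence[LandmarkConfiguration] | np.ndarray,
    scheme: LandmarkScheme,
    n_iter: int = 3,
) -> np.ndarray:
    """Slide semilandmarks to minimize bending energy against the consensus.

    Input should already be superimposed (or at least commensurate); each
    outer iteration recomputes the GPA consensus, solves for the sliding
    amounts of every configuration along its curve tangents, applies them,
    and re-runs GPA.  Fixed landmarks never move relative to their
    configuration.  Returns the (n, K, 2) slid, superimposed coordinates.
    """
    arr = _as_array(configs)
    res = generalized_procrustes(arr)
    work = res.aligned
    slid_idx = np.asarray(scheme.semilandmarks, dtype=int)
    if slid_idx.size == 0:
        return work
    k = scheme.n_landmarks
    for _ in range(n_iter):
        consensus = res.mean_shape
        E = bending_energy_matrix(consensus)
        # stacked-coordinate bending form: block diag(E, E) over (x..., y...)
        for i in range(work.shape[0]):
            tang = _tangents(work[i], scheme)
            # design: one column per sliding landmark; rows are stacked coords
            T = np.zeros((2 * k, slid_idx.size))
            for c, j in enumerate(slid_idx):
                T[j, c] = tang[j, 0]
                T[k + j, c] = tang[j, 1]
            d = np.concatenate([work[i, :, 0] - consensus[:, 0],
                                work[i, :, 1] - consensus[:, 1]])
            E2T = np.vstack([E @ T[:k], E @ T[k:]])
            A = T.T @ E2T
            b = -E2T.T @ d
            lam, *_ = np.linalg.lstsq(A, b, rcond=None)
            work[i, slid_idx, 0] += tang[slid_idx, 0] * lam
            work[i, slid_idx, 1] += tang[slid_idx, 1] * lam
        res = generalized_procrustes(work)
        work = res.aligned
    return work


# ---------------------------------------------------------------------------
# symmetrization


def _reflect_relabel(points: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Mirror about the vertical axis through the centroid, then swap labels."""
    c = points.mean(axis=0)
    mirrored = points.copy()
    mirrored[:, 0] = 2 * c[0] - mirrored[:, 0]
    return mirrored[perm]


def symmetrize(
    configs: Sequence[LandmarkConfiguration] | np.ndarray,
    scheme: LandmarkScheme,
    tol: float = 1e-12,
    max_iter: int = 50,
) -> np.ndarray:
    """Average each configuration with its relabeled reflection.

    For each configuration the mirror image (x negated about the centroid)
    is relabeled through the bilateral pairing, fitted back onto the original
    by a two-shape Procrustes rotation, and averaged with it.  The fit and
    average are iterated to a fixed point and finished with an exact
    reflect-relabel projection, so the output satisfies
    ``reflect_relabel(out) == out`` to machine precision.
    """
    arr = _as_array(configs)
    perm = scheme.reflection_permutation()
    if not np.array_equal(perm[perm], np.arange(scheme.n_landmarks)):
        raise ValueError("bilateral pairing is not an involution")
    out = np.empty_like(arr)
    for i, pts in enumerate(arr):
        y = pts.copy()
        for _ in range(max_iter):
            mirror = _reflect_relabel(y, perm)
            fitted = align_pair(mirror, y, scale=False)
            new = (y + fitted) / 2.0
            if np.linalg.norm(new - y) < tol:
                y = new
                break
            y = new
        out[i] = (y + _reflect_relabel(y, perm)) / 2.0
    return out


# ---------------------------------------------------------------------------
# shape PCA


@dataclass
class ShapeSpace:
    """Principal components of superimposed shape coordinates."""

    scores: np.ndarray  # (n, M)
    components: np.ndarray = field(repr=False)  # (M, 2K) orthonormal rows
    variance_explained: np.ndarray  # (M,)
    mean_shape: np.ndarray = field(repr=False)  # (K, 2)

    def component_field(self, m: int) -> np.ndarray:
        """Component ``m`` reshaped to a (K, 2) displacement field."""
        k2 = self.components.shape[1]
        return self.components[m].reshape(k2 // 2, 2)


def shape_pca(proc: ProcrustesResult | np.ndarray) -> ShapeSpace:
    """Covariance PCA of the flattened aligned coordinates (relative warps)."""
    aligned = proc.aligned if isinstance(proc, ProcrustesResult) else _as_array(proc)
    n, k, _ = aligned.shape
    if n < 3:
        raise ValueError("shape PCA needs at least 3 configurations")
    flat = aligned.reshape(n, 2 * k)
    mean = flat.mean(axis=0)
    centered = flat - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    m = min(n - 1, 2 * k)
    scores = u[:, :m] * s[:m]
    var = eig[:m] / total if total > 0 else np.zeros(m)
    return ShapeSpace(
        scores=scores,
        components=vt[:m],
        variance_explained=var,
        mean_shape=mean.reshape(k, 2),
    )


def select_components(space: ShapeSpace, threshold: float = 0.95) -> list[int]:
    """Smallest leading component set whose cumulative variance reaches ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(space.variance_explained)
    nonzero = int(np.sum(space.variance_explained > 1e-12))
    for m in range(1, nonzero + 1):
        if cum[m - 1] >= threshold - 1e-12:
            return list(range(m))
    return list(range(nonzero))
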