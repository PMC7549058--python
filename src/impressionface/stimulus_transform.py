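"""Average-face construction and TPS-warped shape-transformed stimuli.

The validation-study stimuli are built by (1) averaging the sample images
after warping each onto the Procrustes mean configuration, and (2) warping
that average along the valence/dominance shape-regression fields at signed
multiples of the impression-score standard deviation (by default -3, 0, +3 SD
on each dimension, a 3 x 3 grid of nine faces).

Image warping uses an exact thin-plate-spline interpolant (affine part plus
U(r) = r^2 log r^2 kernel, zero regularization) fitted backward from target
to source landmarks, with bilinear sampling of the source.  Landmark files
keep the bottom-left-origin, y-up TPS convention; conversion to raster
row/column order happens only here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .landmark_io import LandmarkConfiguration
from .shape_pipeline import generalized_procrustes
from .shape_association import ShapeRegressionVector

__all__ = [
    "WarpSpec",
    "PixelFrame",
    "transform_shape",
    "tps_fit",
    "tps_map",
    "tps_warp_image",
    "average_image",
    "stimulus_grid",
]


@dataclass
class PixelFrame:
    """Similarity map from Procrustes units into an image's pixel space."""

    centroid: np.ndarray  # (2,) pixel position of the shape centroid
    size: float  # centroid size in pixels

    def to_pixels(self, shape: np.ndarray) -> np.ndarray:
        return np.asarray(shape) * self.size + self.centroid

    def to_procrustes(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.centroid) / self.size


@dataclass
class WarpSpec:
    """Landmark correspondence driving one TPS image warp (pixel space, y-up)."""

    src_landmarks: np.ndarray  # (K, 2)
    dst_landmarks: np.ndarray  # (K, 2)
    image_size: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        self.src_landmarks = np.asarray(self.src_landmarks, dtype=float)
        self.dst_landmarks = np.asarray(self.dst_landmarks, dtype=float)
        if self.src_landmarks.shape != self.dst_landmarks.shape:
            raise ValueError("source and target landmark sets must match in shape")
        if self.src_landmarks.shape[0] < 3:
            raise ValueError("need at least 3 landmarks")


def transform_shape(
    mean_shape: np.ndarray,
    reg: ShapeRegressionVector,
    k_sd: float,
    frame: PixelFrame | None = None,
    face_id: str | None = None,
) -> LandmarkConfiguration:
    """Displace the mean shape along a regression field by ``k_sd`` SD units.

    ``mean_shape + k_sd * predictor_sd * field`` in Procrustes units; if a
    :class:`PixelFrame` is given the result is rescaled into that image frame.
    """
    shape = np.asarray(mean_shape, dtype=float) + reg.displacement(k_sd)
    if frame is not None:
        shape = frame.to_pixels(shape)
    return LandmarkConfiguration(
        face_id=face_id or f"transform_{k_sd:+g}SD", points=shape
    )


def tps_fit(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit the TPS interpolant sending ``src`` points to ``dst`` values.

    Returns (weights, affine) such that :func:`tps_map` reproduces ``dst``
    exactly at ``src``.  Raises on coincident source points (singular kernel).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    k = src.shape[0]
    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
    if np.any(d2[~np.eye(k, dtype=bool)] == 0):
        raise ValueError("coincident landmarks make the TPS system singular")
    with np.errstate(divide="ignore", invalid="ignore"):
        U = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    Q = np.column_stack([np.ones(k), src])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = U
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    rhs = np.zeros((k + 3, dst.shape[1]))
    rhs[:k] = dst
    sol = np.linalg.solve(L, rhs)
    return sol[:k], sol[k:]


def tps_map(points: np.ndarray, src: np.ndarray, weights: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS at arbitrary points."""
    pts = np.asarray(points, dtype=float)
    d2 = ((pts[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        U = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    Q = np.column_stack([np.ones(pts.shape[0]), pts])
    return U @ weights + Q @ affine


def tps_warp_image(image: np.ndarray, spec: WarpSpec, background: float | None = None) -> np.ndarray:
    """Warp an image so its ``src_landmarks`` move to ``dst_landmarks``.

    Backward mapping: a TPS is fitted from the target landmarks to the source
    landmarks and every output pixel samples the source bilinearly at its
    mapped position; out-of-range samples take the ``background`` value
    (default: the image's corner value).
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    if background is None:
        background = float(img.flat[0])
    weights, affine = tps_fit(spec.dst_landmarks, spec.src_landmarks)
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    # raster (row, col) -> TPS canvas (x, y-up); pixel centers sit at
    # half-integers, matching the schematic renderer's convention
    xy = np.column_stack([cols.ravel() + 0.5, h - (rows.ravel() + 0.5)])
    mapped = tps_map(xy, spec.dst_landmarks, weights, affine)
    src_cols = mapped[:, 0] - 0.5
    src_rows = h - mapped[:, 1] - 0.5
    coords = np.vstack([src_rows, src_cols])

    def sample(channel: np.ndarray) -> np.ndarray:
        return map_coordinates(
            channel, coords, order=1, mode="constant", cval=background
        ).reshape(h, w)

    if img.ndim == 2:
        out = sample(img)
    else:
        out = np.dstack([sample(img[..., c]) for c in range(img.shape[2])])
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        out = np.clip(np.round(out), 0, 255).astype(np.asarray(image).dtype)
    return out


def average_image(
    images: Sequence[np.ndarray],
    configs: Sequence[LandmarkConfiguration],
) -> tuple[np.ndarray, LandmarkConfiguration]:
    """Average faces: warp every image onto the GPA mean shape and average.

    The mean configuration is the Procrustes consensus mapped back into pixel
    space using the mean centroid size and mean centroid position of the
    inputs, so the average stays in register with the source images.
    """
    if len(images) < 2 or len(images) != len(configs):
        raise ValueError("need >= 2 images with matching landmark sets")
    shape0 = np.asarray(images[0]).shape
    for im in images:
        if np.asarray(im).shape != shape0:
            raise ValueError("all images must share the same size")
    res = generalized_procrustes(configs)
    frame = PixelFrame(
        centroid=np.stack([c.points.mean(axis=0) for c in configs]).mean(axis=0),
        size=float(res.centroid_sizes.mean()),
    )
    mean_px = frame.to_pixels(res.mean_shape)
    h, w = shape0[:2]
    acc = np.zeros(np.asarray(images[0], dtype=float).shape)
    for im, cfg in zip(images, configs):
        spec = WarpSpec(src_landmarks=cfg.points, dst_landmarks=mean_px, image_size=(w, h))
        acc += tps_warp_image(np.asarray(im, dtype=float), spec)
    avg = acc / len(images)
    if np.issubdtype(np.asarray(images[0]).dtype, np.integer):
        avg = np.clip(np.round(avg), 0, 255).astype(np.asarray(images[0]).dtype)
    return avg, LandmarkConfiguration(face_id="average", points=mean_px)


def stimulus_grid(
    avg_image: np.ndarray,
    mean_config: LandmarkConfiguration,
    reg_valence: ShapeRegressionVector,
    reg_dominance: ShapeRegressionVector,
    levels: Sequence[float] = (-3.0, 0.0, 3.0),
    frame: PixelFrame | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Build the grid of shape-transformed average faces.

    For every (valence, dominance) level pair the target configuration is
    ``mean + v*sd_V*field_V + d*sd_D*field_D`` and the average image is warped
    once from the mean to the target (warps are never composed).  Returns the
    images and a manifest recording the level pairs and filenames.
    """
    if frame is None:
        pts = mean_config.points
        c = pts.mean(axis=0)
        frame = PixelFrame(centroid=c, size=float(np.sqrt(((pts - c) ** 2).sum())))
    mean_proc = frame.to_procrustes(mean_config.points)
    h, w = np.asarray(avg_image).shape[:2]
    images: list[np.ndarray] = []
    rows = []
    for v in levels:
        for d in levels:
            target_proc = (
                mean_proc
                + reg_valence.displacement(v)
                + reg_dominance.displacement(d)
            )
            target = frame.to_pixels(target_proc)
            if v == 0 and d == 0:
                out = np.asarray(avg_image).copy()
            else:
                spec = WarpSpec(
                    src_landmarks=mean_config.points,
                    dst_landmarks=target,
                    image_size=(w, h),
                )
                out = tps_warp_image(avg_image, spec)
            name = f"stimulus_v{v:+g}_d{d:+g}.png"
            images.append(out)
            rows.append({"valence_sd": v, "dominance_sd": d, "filename": name})
    return images, pd.DataFrame(rows)
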