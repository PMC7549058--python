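"""Readers and writers for TPS landmark files and long-format rating tables.

This module is the pipeline's only contact with on-disk formats.  TPS files
follow the tpsDig dialect: each record is an ``LM=<k>`` line followed by ``k``
whitespace-separated ``x y`` coordinate lines and optional ``IMAGE=``, ``ID=``
and ``SCALE=`` metadata lines.  Coordinates keep the TPS convention of a
bottom-left origin with the y axis pointing up; raster code converts to
row/column order only at the image-warp boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "RatingTable",
    "TPSParseError",
    "RatingTableError",
    "read_tps",
    "write_tps",
    "read_rating_table",
    "write_rating_table",
]


class TPSParseError(ValueError):
    """Raised when a TPS file violates the dialect or its invariants."""


class RatingTableError(ValueError):
    """Raised when a rating table is malformed (range, duplicates, missing cells)."""


@dataclass
class LandmarkConfiguration:
    """One face's ordered 2D landmark set.

    Parameters
    ----------
    face_id : str
        Text label identifying the face.
    points : ndarray, shape (K, 2)
        Landmark coordinates ``(x, y)`` in pixel units, bottom-left origin.
    scale : float, optional
        Pixels-per-unit factor from a ``SCALE=`` line.
    image_ref : str, optional
        Image filename from an ``IMAGE=`` line.
    """

    face_id: str
    points: np.ndarray
    scale: float | None = None
    image_ref: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"points must be (K, 2), got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"non-finite coordinates in configuration {self.face_id!r}")

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]


@dataclass
class RatingTable:
    """Dense faces x items x raters array of scores on the 0-100 visual analog scale."""

    faces: list[str]
    items: list[str]
    raters: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.faces), len(self.items), len(self.raters))
        if self.values.shape != expected:
            raise RatingTableError(
                f"values shape {self.values.shape} does not match labels {expected}"
            )
        if np.any(np.isnan(self.values)):
            raise RatingTableError("rating table contains missing cells")
        if self.values.min() < 0 or self.values.max() > 100:
            raise RatingTableError("ratings must lie in [0, 100]")

    def to_long(self) -> pd.DataFrame:
        """Long-format DataFrame with columns face, item, rater, score."""
        idx = pd.MultiIndex.from_product(
            [self.faces, self.items, self.raters], names=["face", "item", "rater"]
        )
        return pd.DataFrame({"score": self.values.ravel()}, index=idx).reset_index()


_KNOWN_KEYS = {"LM", "IMAGE", "ID", "SCALE"}


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file into a list of configurations.

    Every record must carry the same number of landmarks; a mismatch is a
    parse error naming the offending record.  Unknown ``KEY=`` lines are
    skipped with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"{path.name}: expected LM= line, got {line!r}")
        record_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(
                f"{path.name}: record {record_no}: malformed count line {line!r}"
            ) from exc
        pts = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= len(lines):
                raise TPSParseError(
                    f"{path.name}: record {record_no}: truncated after {j} of {k} points"
                )
            fields = lines[i].split()
            i += 1
            if len(fields) != 2:
                raise TPSParseError(
                    f"{path.name}: record {record_no}: expected 'x y', got {lines[i-1]!r}"
                )
            try:
                pts[j] = [float(fields[0]), float(fields[1])]
            except ValueError as exc:
                raise TPSParseError(
                    f"{path.name}: record {record_no}: non-numeric coordinate {lines[i-1]!r}"
                ) from exc
        face_id = f"face_{record_no}"
        scale = None
        image_ref = None
        while i < len(lines):
            meta = lines[i].strip()
            if not meta:
                i += 1
                continue
            if meta.upper().startswith("LM="):
                break
            key, _, value = meta.partition("=")
            key = key.strip().upper()
            i += 1
            if key == "ID":
                face_id = value.strip()
            elif key == "IMAGE":
                image_ref = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TPSParseError(
                        f"{path.name}: record {record_no}: bad SCALE value {value!r}"
                    ) from exc
            elif key not in _KNOWN_KEYS:
                warnings.warn(
                    f"{path.name}: record {record_no}: ignoring unknown key {key!r}",
                    stacklevel=2,
                )
        configs.append(
            LandmarkConfiguration(face_id=face_id, points=pts, scale=scale, image_ref=image_ref)
        )
    if not configs:
        raise TPSParseError(f"{path.name}: no landmark records found")
    k0 = configs[0].n_landmarks
    for idx, cfg in enumerate(configs, start=1):
        if cfg.n_landmarks != k0:
            raise TPSParseError(
                f"{path.name}: record {idx} ({cfg.face_id!r}) has LM={cfg.n_landmarks}, "
                f"expected {k0} as in record 1"
            )
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as a TPS file readable by :func:`read_tps`.

    Coordinates are printed with 9 significant digits so a read/write round
    trip is an identity well below 1e-6 relative tolerance.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("write_tps requires at least one configuration")
    ks = {c.n_landmarks for c in configs}
    if len(ks) != 1:
        raise ValueError(f"mixed landmark counts {sorted(ks)}; TPS datasets must be uniform")
    out = []
    for cfg in configs:
        out.append(f"LM={cfg.n_landmarks}")
        for x, y in cfg.points:
            out.append(f"{x:.9g} {y:.9g}")
        if cfg.image_ref is not None:
            out.append(f"IMAGE={cfg.image_ref}")
        out.append(f"ID={cfg.face_id}")
        if cfg.scale is not None:
            out.append(f"SCALE={cfg.scale:.9g}")
    Path(path).write_text("\n".join(out) + "\n")


def read_rating_table(path: str | Path) -> RatingTable:
    """Load a long-format delimited rating file into a dense :class:`RatingTable`.

    The file must have a header with columns ``face``, ``item``, ``rater``,
    ``score`` (comma- or tab-delimited).  Every (face, item, rater) cell must
    appear exactly once; duplicates and missing cells are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"face", "item", "rater", "score"}
    if not required.issubset(df.columns):
        raise RatingTableError(
            f"{path.name}: missing columns {sorted(required - set(df.columns))}"
        )
    df = df.astype({"face": str, "item": str, "rater": str})
    scores = pd.to_numeric(df["score"], errors="raise")
    if scores.min() < 0 or scores.max() > 100:
        bad = df.loc[(scores < 0) | (scores > 100)].iloc[0]
        raise RatingTableError(
            f"{path.name}: score {bad['score']} for ({bad['face']}, {bad['item']}, "
            f"{bad['rater']}) outside [0, 100]"
        )
    dup = df.duplicated(subset=["face", "item", "rater"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise RatingTableError(
            f"{path.name}: duplicate row for ({bad['face']}, {bad['item']}, {bad['rater']})"
        )
    faces = sorted(df["face"].unique())
    items = sorted(df["item"].unique())
    raters = sorted(df["rater"].unique())
    cube = (
        df.set_index(["face", "item", "rater"])["score"]
        .reindex(pd.MultiIndex.from_product([faces, items, raters]))
        .to_numpy()
        .reshape(len(faces), len(items), len(raters))
    )
    if np.any(np.isnan(cube)):
        f, it, r = np.argwhere(np.isnan(cube))[0]
        raise RatingTableError(
            f"{path.name}: missing cell (face={faces[f]}, item={items[it]}, rater={raters[r]})"
        )
    return RatingTable(faces=faces, items=items, raters=raters, values=cube)


def write_rating_table(table: RatingTable, path: str | Path) -> None:
    """Write a rating table in long format (CSV with header)."""
    table.to_long().to_csv(path, index=False)
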