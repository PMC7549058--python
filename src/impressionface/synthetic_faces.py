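"""Synthetic face generator with known ground truth.

No photographs or landmark templates are distributed with facial-impression
rating studies of this design, so every downstream stage is exercised on
synthetic data with planted structure:

* a bilaterally symmetric 72-point face template (36 fixed landmarks,
  36 semilandmarks on the outline, brow, lip and nose curves);
* low-rank shape variation: a small set of orthonormal symmetric displacement
  fields (a "smile-like" valence field, a "brow-lowering" dominance field,
  plus impression-orthogonal nuisance fields) scaled by per-face latent
  scores, with iid landmark noise on top (the noise is asymmetric, so
  symmetrization does real work);
* rater-level ratings of 18 adjectives driven linearly by the first two
  latent dimensions with rater random intercepts and residual noise, clipped
  to the 0-100 visual analog scale;
* a deterministic schematic renderer so image warping can be tested.

All randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .landmark_io import LandmarkConfiguration, RatingTable
from .shape_pipeline import LandmarkScheme, centroid_size

__all__ = [
    "FaceTemplate",
    "ShapeSimConfig",
    "RatingSimConfig",
    "FeatureSpec",
    "build_template",
    "default_factor_fields",
    "default_shape_sim_config",
    "planted_component_count",
    "simulate_shapes",
    "simulate_ratings",
    "simulate_stimulus_ratings",
    "render_schematic",
    "DEFAULT_ITEMS",
    "default_item_loadings",
    "default_item_intercepts",
]

#: the 18 trait adjectives (English glosses) rated on the 0-100 scale
DEFAULT_ITEMS: tuple[str, ...] = (
    "lively",
    "irritated",
    "cute",
    "beautiful",
    "rich",
    "open-minded",
    "not-niggled",
    "sociable",
    "graceful",
    "fresh",
    "cheerful",
    "reliable",
    "intelligent",
    "tired",
    "humanly",
    "approachable",
    "easily-influenced",
    "dignified",
)


# ---------------------------------------------------------------------------
# template


@dataclass
class FeatureSpec:
    """Geometry parameters (template units) placing the facial features.

    The template spans roughly [-70, 70] x [-95, 75] before normalization;
    proportions follow a typical frontal female face.
    """

    face_width: float = 70.0
    face_height_chin: float = 95.0
    face_height_top: float = 75.0
    eye_y: float = 18.0
    eye_dx: float = 30.0
    eye_half_width: float = 13.0
    eye_half_height: float = 5.0
    brow_y: float = 34.0
    brow_half_width: float = 16.0
    brow_arch: float = 5.0
    nose_tip_y: float = -12.0
    nose_width: float = 13.0
    mouth_y: float = -40.0
    mouth_half_width: float = 22.0
    lip_thickness: float = 7.0


@dataclass
class FaceTemplate:
    """A symmetric base configuration plus the landmark scheme describing it.

    ``raw_scale`` is the centroid size of the template in :class:`FeatureSpec`
    units before normalization, so feature-scale parameters (e.g. Gaussian
    influence radii) can be stated in anatomical units.
    """

    scheme: LandmarkScheme
    base: LandmarkConfiguration
    names: tuple[str, ...] = ()
    raw_scale: float = 1.0


def _normalize(points: np.ndarray) -> np.ndarray:
    pts = points - points.mean(axis=0)
    return pts / np.sqrt((pts**2).sum())


def build_template(n_outline: int = 20, feature_spec: FeatureSpec | None = None) -> FaceTemplate:
    """Construct the 72-point symmetric face template and its scheme.

    ``n_outline`` semilandmarks (must be even) sit on the jaw/temple outline;
    3 per brow, 3 per lip curve and 2 per nose side complete the 36
    semilandmarks when ``n_outline`` is 20.  Left-side and midline points are
    declared once and mirrored, so the template is symmetric by construction;
    the base is normalized to centroid 0 and centroid size 1.
    """
    if n_outline % 2 != 0:
        raise ValueError("n_outline must be even (bilateral pairing)")
    spec = feature_spec or FeatureSpec()

    names: list[str] = []
    coords: list[tuple[float, float]] = []
    roles: list[str] = []  # "fixed" | "semi"

    def add(name: str, x: float, y: float, role: str) -> int:
        names.append(name)
        coords.append((x, y))
        roles.append(role)
        return len(names) - 1

    def add_lr(name: str, x: float, y: float, role: str) -> tuple[int, int]:
        il = add(name + "_L", -abs(x), y, role)
        ir = add(name + "_R", abs(x), y, role)
        return il, ir

    s = spec
    # --- outline: left temple -> chin -> right temple, chin fixed on midline
    temple_l, temple_r = add_lr("temple", s.face_width * 0.92, s.eye_y + 14, "fixed")
    chin = add("chin", 0.0, -s.face_height_chin, "fixed")
    half = n_outline // 2
    out_l: list[int] = []
    # angles from the temple (~158 deg) down the left cheek to just short of
    # the chin (~265 deg); mirrored for the right side
    for j in range(half):
        t = (j + 1) / (half + 1)
        ang = np.pi * (0.88 + 0.59 * t)
        x = s.face_width * np.cos(ang)
        y0 = np.sin(ang)
        y = (s.face_height_chin if y0 < 0 else s.face_height_top) * y0
        out_l.append(add(f"outline{j}_L", x, y, "semi"))
    out_r = [add(f"outline{j}_R", -coords[i][0], coords[i][1], "semi") for j, i in enumerate(out_l)]
    outline_curve = [temple_l] + out_l + [chin] + list(reversed(out_r)) + [temple_r]

    # --- brows: fixed endpoints, 3 semis each
    brow_in_l, brow_in_r = add_lr("brow_inner", s.eye_dx - s.brow_half_width * 0.7, s.brow_y, "fixed")
    brow_out_l, brow_out_r = add_lr("brow_outer", s.eye_dx + s.brow_half_width * 0.9, s.brow_y - 2, "fixed")
    brow_curves = []
    for side, (bi, bo) in (("L", (brow_in_l, brow_out_l)), ("R", (brow_in_r, brow_out_r))):
        xi, yi = coords[bi]
        xo, yo = coords[bo]
        semis = []
        for j, t in enumerate((0.25, 0.5, 0.75)):
            x = xi + (xo - xi) * t
            y = yi + (yo - yi) * t + s.brow_arch * np.sin(np.pi * t)
            semis.append(add(f"brow{j}_{side}", x, y, "semi"))
        brow_curves.append([bi] + semis + [bo])

    # --- eyes: 4 corners/midpoints + pupil per side (all fixed)
    eye_in = add_lr("eye_inner", s.eye_dx - s.eye_half_width, s.eye_y, "fixed")
    eye_out = add_lr("eye_outer", s.eye_dx + s.eye_half_width, s.eye_y, "fixed")
    eye_top = add_lr("eye_top", s.eye_dx, s.eye_y + s.eye_half_height, "fixed")
    eye_bot = add_lr("eye_bottom", s.eye_dx, s.eye_y - s.eye_half_height, "fixed")
    pupil = add_lr("pupil", s.eye_dx, s.eye_y, "fixed")

    # --- nose: midline bridge/tip/subnasale, alae, nostrils, side curves
    nose_bridge = add("nose_bridge", 0.0, s.eye_y + 2, "fixed")
    nose_tip = add("nose_tip", 0.0, s.nose_tip_y, "fixed")
    subnasale = add("subnasale", 0.0, s.nose_tip_y - 5, "fixed")
    ala_l, ala_r = add_lr("ala", s.nose_width, s.nose_tip_y - 2, "fixed")
    nostril_l, nostril_r = add_lr("nostril", s.nose_width * 0.5, s.nose_tip_y - 4, "fixed")
    nose_curves = []
    for side, ala in (("L", ala_l), ("R", ala_r)):
        xa, ya = coords[ala]
        xb, yb = coords[nose_bridge]
        semis = []
        for j, t in enumerate((0.4, 0.7)):
            x = xb + (xa - xb) * t * 0.8
            y = yb + (ya - yb) * t
            semis.append(add(f"nose{j}_{side}", x, y, "semi"))
        nose_curves.append([nose_bridge] + semis + [ala])

    # --- mouth: corners fixed; 3 semis per lip curve (midpoint on midline)
    mouth_l, mouth_r = add_lr("mouth_corner", s.mouth_half_width, s.mouth_y, "fixed")
    lip_curves = []
    lip_mid_ids = {}
    for part, dy in (("upper", s.lip_thickness), ("lower", -s.lip_thickness)):
        xl, yl = coords[mouth_l]
        l1 = add(f"lip_{part}_L", xl * 0.5, s.mouth_y + dy * 0.85, "semi")
        mid = add(f"lip_{part}_mid", 0.0, s.mouth_y + dy, "semi")
        r1 = add(f"lip_{part}_R", -xl * 0.5, s.mouth_y + dy * 0.85, "semi")
        lip_curves.append([mouth_l, l1, mid, r1, mouth_r])
        lip_mid_ids[part] = mid
    lip_inner_up = add("lip_inner_upper", 0.0, s.mouth_y + 1.5, "fixed")
    lip_inner_lo = add("lip_inner_lower", 0.0, s.mouth_y - 1.5, "fixed")

    # --- remaining fixed midline / paired anatomical points
    glabella = add("glabella", 0.0, s.brow_y + 1, "fixed")
    forehead = add("forehead", 0.0, s.face_height_top * 0.85, "fixed")
    philtrum = add("philtrum", 0.0, (s.nose_tip_y - 5 + s.mouth_y + s.lip_thickness) / 2, "fixed")
    sulcus = add("sulcus", 0.0, s.mouth_y - s.lip_thickness - 8, "fixed")
    cheek = add_lr("cheek", s.face_width * 0.6, s.nose_tip_y + 4, "fixed")
    jaw = add_lr("jaw", s.face_width * 0.62, s.mouth_y - 10, "fixed")

    pts = np.asarray(coords, dtype=float)
    k = pts.shape[0]
    semis = tuple(i for i, r in enumerate(roles) if r == "semi")
    pairs = []
    midline = []
    by_name = {n: i for i, n in enumerate(names)}
    for i, n in enumerate(names):
        if n.endswith("_L"):
            pairs.append((i, by_name[n[:-2] + "_R"]))
        elif not n.endswith("_R"):
            midline.append(i)
    curves = [outline_curve] + brow_curves + nose_curves + lip_curves
    scheme = LandmarkScheme(
        n_landmarks=k,
        semilandmarks=semis,
        curves=tuple(tuple(c) for c in curves),
        pairs=tuple(pairs),
        midline=tuple(midline),
    )
    base = _normalize(pts)
    perm = scheme.reflection_permutation()
    mirror = base.copy()
    mirror[:, 0] = -mirror[:, 0]
    resid = np.abs(mirror[perm] - base).max()
    if resid > 1e-9:
        raise ValueError(f"template pairing inconsistent with geometry (residual {resid:.2e})")
    return FaceTemplate(
        scheme=scheme,
        base=LandmarkConfiguration(face_id="template", points=base),
        names=tuple(names),
        raw_scale=centroid_size(pts),
    )


# ---------------------------------------------------------------------------
# shape simulation


@dataclass
class ShapeSimConfig:
    """Low-rank shape-variation model: D orthonormal fields + landmark noise.

    ``factor_sd`` values are in template (centroid-size-1) units; the default
    fields put the valence factor at roughly 8% of total shape variance and
    keep landmark noise below a quarter of the planted signal.
    """

    n_faces: int = 102
    factor_fields: np.ndarray = None  # (D, K, 2), orthonormal
    factor_sd: np.ndarray = None  # (D,)
    landmark_noise_sd: float = 5e-4
    seed: int = 0

    def validate(self) -> None:
        f = np.asarray(self.factor_fields, dtype=float)
        flat = f.reshape(f.shape[0], -1)
        gram = flat @ flat.T
        if not np.allclose(gram, np.eye(f.shape[0]), atol=1e-8):
            raise ValueError("factor fields must be mutually orthonormal")
        if np.any(np.asarray(self.factor_sd) <= 0):
            raise ValueError("factor spreads must be positive")


def _bump_field(
    template: FaceTemplate,
    bumps: Sequence[tuple[tuple[float, float], tuple[float, float], float]],
) -> np.ndarray:
    """Smooth symmetric displacement field from Gaussian influence bumps.

    Each bump is ``((cx, cy), (ax, ay), scale)`` in :class:`FeatureSpec`
    units: landmarks within ~``scale`` of the center move along ``(ax, ay)``.
    Off-midline bumps are mirrored automatically (center x and amplitude x
    negated); a midline bump must have ``ax == 0``.  Smooth fields keep
    bending energy low, mirroring how real facial variation deforms whole
    regions rather than single points.
    """
    raw = template.base.points * template.raw_scale
    field = np.zeros_like(raw)
    for (cx, cy), (ax, ay), scale in bumps:
        copies = [((cx, cy), (ax, ay))]
        if cx != 0.0:
            copies.append(((-cx, cy), (-ax, ay)))
        elif ax != 0.0:
            raise ValueError("midline bump must have zero x amplitude")
        for (bx, by), (dx, dy) in copies:
            w = np.exp(-(((raw[:, 0] - bx) ** 2 + (raw[:, 1] - by) ** 2) / (2 * scale**2)))
            field += w[:, None] * np.array([dx, dy])
    return field


def default_factor_fields(template: FaceTemplate, n_nuisance: int = 2) -> np.ndarray:
    """Valence and dominance fields plus nuisance fields, orthonormalized.

    The valence field resembles a smile: mouth corners and lips up, brows
    raised, cheeks lifted.  The dominance field resembles an angry/stern
    configuration: inner brows and glabella down, mouth corners down, chin
    extended.  Nuisance fields (face elongation; vertical placement of the
    nose/mouth block) carry shape variance unrelated to either impression
    dimension.  All fields are projected off the similarity group and the
    semilandmark tangent directions (neither survives superimposition and
    sliding), then orthonormalized preserving the valence direction.
    """
    s = FeatureSpec()
    valence = _bump_field(
        template,
        [
            ((s.mouth_half_width, s.mouth_y), (0.3, 1.0), 12.0),
            ((0.0, s.mouth_y + s.lip_thickness), (0.0, 0.5), 9.0),
            ((s.eye_dx, s.brow_y), (0.1, 0.7), 13.0),
            ((s.face_width * 0.6, s.nose_tip_y), (-0.4, 0.25), 20.0),
        ],
    )
    dominance = _bump_field(
        template,
        [
            ((s.eye_dx - s.brow_half_width * 0.7, s.brow_y), (0.15, -1.0), 10.0),
            ((0.0, s.brow_y + 1), (0.0, -0.6), 10.0),
            ((s.mouth_half_width, s.mouth_y), (0.05, -0.7), 10.0),
            ((0.0, -s.face_height_chin), (0.0, -0.5), 16.0),
        ],
    )
    elongation = template.base.points * np.array([-0.5, 1.0])
    placement = _bump_field(
        template,
        [((0.0, (s.nose_tip_y + s.mouth_y) / 2), (0.0, -1.0), 28.0)],
    )
    fields = [valence, dominance, elongation, placement][: 2 + n_nuisance]
    flat = np.stack([f.ravel() for f in fields])
    # Gram-Schmidt against the similarity directions first (translation,
    # rotation, scale are removed by Procrustes superimposition, so planted
    # fields must be pure shape directions to be recoverable), then against
    # each other, preserving the leading (valence) direction.
    fixed_basis = _unrecoverable_directions(template)
    q: list[np.ndarray] = []
    for v in flat:
        for w in fixed_basis + q:
            v = v - (v @ w) * w
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise ValueError("degenerate factor field set")
        q.append(v / norm)
    k = template.scheme.n_landmarks
    return np.stack(q).reshape(len(q), k, 2)


def _unrecoverable_directions(template: FaceTemplate) -> list[np.ndarray]:
    """Directions not preserved by superimposition and semilandmark sliding.

    The similarity-group tangent (translation, rotation, scale — removed by
    Procrustes superimposition) plus, for each semilandmark tangent direction
    ``t_j``, the direction ``E t_j`` where ``E`` is the template's
    bending-energy matrix: a displacement field ``f`` is a first-order fixed
    point of bending-energy sliding exactly when ``t_j' E f = 0`` for every
    semilandmark.  Planted factor fields are projected off this subspace so
    the generating model and the recovered shape space agree.
    """
    from .shape_pipeline import _tangents, bending_energy_matrix

    base = template.base.points
    k = base.shape[0]
    out = list(_similarity_directions(base))
    tang = _tangents(base, template.scheme)
    E = bending_energy_matrix(base)
    for j in template.scheme.semilandmarks:
        v = np.empty((k, 2))
        v[:, 0] = E[:, j] * tang[j, 0]
        v[:, 1] = E[:, j] * tang[j, 1]
        v = v.ravel()
        for w in out:
            v = v - (v @ w) * w
        n = np.linalg.norm(v)
        if n > 1e-10:
            out.append(v / n)
    return out


def _similarity_directions(base: np.ndarray) -> list[np.ndarray]:
    """Orthonormal basis of the similarity group's tangent at ``base``.

    Uniform x/y translation, infinitesimal rotation and uniform scaling of a
    centered configuration; displacement along these is absorbed by
    Procrustes superimposition and carries no shape information.
    """
    k = base.shape[0]
    c = base - base.mean(axis=0)
    dirs = [
        np.column_stack([np.ones(k), np.zeros(k)]).ravel(),
        np.column_stack([np.zeros(k), np.ones(k)]).ravel(),
        np.column_stack([-c[:, 1], c[:, 0]]).ravel(),
        c.ravel(),
    ]
    out: list[np.ndarray] = []
    for v in dirs:
        for w in out:
            v = v - (v @ w) * w
        out.append(v / np.linalg.norm(v))
    return out


#: planted variance shares: valence 8% (the association strength of
#: interest), dominance 7.5% (slightly weaker; both are sized so their fields
#: are recoverable by per-landmark regression at ~100 faces), then 2
#: structured + 11 random nuisance fields on a gently decaying spectrum; the
#: remaining 1.5% is iid landmark noise.  A flat-ish many-mode spectrum
#: reflects a demographically narrow, pose-controlled sample with no single
#: dominant shape mode, and it takes a double-digit number of shape PCs to
#: reach 95% cumulative variance.
_FACTOR_SHARES = np.concatenate([[0.08, 0.075], np.linspace(0.09, 0.0377, 13)])
_NOISE_SHARE = 1.0 - _FACTOR_SHARES.sum()


def _random_symmetric_fields(
    template: FaceTemplate,
    existing: np.ndarray,
    n_extra: int,
    seed: int = 7,
    smoothness: float = 18.0,
) -> np.ndarray:
    """Smooth random symmetric displacement fields orthonormal to ``existing``.

    White per-landmark fields are filtered through a Gaussian-process kernel
    over the template geometry (length scale ``smoothness`` in FeatureSpec
    units), symmetrized, projected off the unrecoverable directions and
    orthonormalized.  The fixed ``seed`` makes the fields a deterministic
    property of the template, independent of the simulation seed.
    """
    perm = template.scheme.reflection_permutation()
    k = template.scheme.n_landmarks
    raw = template.base.points * template.raw_scale
    d2 = ((raw[:, None, :] - raw[None, :, :]) ** 2).sum(axis=2)
    C = np.exp(-d2 / (2 * smoothness**2))
    rng = np.random.default_rng(seed)
    basis = _unrecoverable_directions(template) + [f.ravel() for f in existing]
    out = []
    while len(out) < n_extra:
        f = C @ rng.standard_normal((k, 2))
        mirror = f[perm].copy()
        mirror[:, 0] = -mirror[:, 0]
        f = ((f + mirror) / 2).ravel()
        for w in basis:
            f = f - (f @ w) * w
        norm = np.linalg.norm(f)
        if norm < 1e-8:
            continue
        f = f / norm
        basis.append(f)
        out.append(f.reshape(k, 2))
    return np.stack(out)


def default_shape_sim_config(template: FaceTemplate, n_faces: int = 102, seed: int = 0) -> ShapeSimConfig:
    """Study-scale defaults.

    Total shape variance is set so the valence factor carries 8% (the
    association-strength regime of interest) and dominance 3%; structured
    and random nuisance fields carry the rest on a decaying spectrum, and
    iid landmark noise stays well below a quarter of the planted signal.
    """
    structured = default_factor_fields(template, n_nuisance=2)
    n_extra = _FACTOR_SHARES.size - structured.shape[0]
    extra = _random_symmetric_fields(template, structured, n_extra)
    fields = np.concatenate([structured, extra])
    total_var = 1e-4 / _FACTOR_SHARES[0]  # valence sd fixed at 0.010
    sd = np.sqrt(_FACTOR_SHARES * total_var)
    noise_sd = float(np.sqrt(_NOISE_SHARE * total_var / (2 * template.scheme.n_landmarks)))
    return ShapeSimConfig(
        n_faces=n_faces, factor_fields=fields, factor_sd=sd,
        landmark_noise_sd=noise_sd, seed=seed,
    )


def planted_component_count(
    cfg: ShapeSimConfig,
    threshold: float = 0.95,
    latent: np.ndarray | None = None,
    n_semilandmarks: int = 36,
) -> int:
    """Ground-truth number of leading shape PCs reaching ``threshold`` variance.

    With ``latent=None`` the population spectrum is used: factor variances
    plus residual landmark-noise variance (noise spreads over many tiny
    components, so it only enters the denominator).  Passing the realized
    latent scores gives the dataset's own ground truth: the eigenvalues of
    the realized low-rank signal, which is what a finite sample's shape PCA
    actually decomposes.

    Of the isotropic noise variance, sliding removes the curve-tangent share
    at the semilandmarks and symmetrization halves the rest, so only
    ``(1 - n_semis/(2K)) / 2`` of it survives to the shape space.
    """
    sd = np.asarray(cfg.factor_sd)
    if latent is None:
        var = np.sort(sd**2)[::-1]
    else:
        z = np.asarray(latent, dtype=float)
        zc = (z - z.mean(axis=0)) * sd
        var = np.sort(np.linalg.svd(zc, compute_uv=False) ** 2)[::-1] / (z.shape[0] - 1)
    k2 = 2 * np.asarray(cfg.factor_fields).shape[1]
    noise_keep = (1.0 - n_semilandmarks / k2) / 2.0
    total = var.sum() + k2 * cfg.landmark_noise_sd**2 * noise_keep
    cum = np.cumsum(var) / total
    return int(np.searchsorted(cum, threshold) + 1)


def simulate_shapes(
    template: FaceTemplate, cfg: ShapeSimConfig
) -> tuple[list[LandmarkConfiguration], np.ndarray]:
    """Draw faces from the low-rank model; return configurations and latent scores.

    ``config_i = base + sum_d z_id * sd_d * field_d + noise`` with standard
    normal latents ``z`` and iid Gaussian landmark noise.  The same seed
    always yields identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fields = np.asarray(cfg.factor_fields, dtype=float)
    sd = np.asarray(cfg.factor_sd, dtype=float)
    d = fields.shape[0]
    z = rng.standard_normal((cfg.n_faces, d))
    base = template.base.points
    noise = rng.normal(0.0, cfg.landmark_noise_sd, size=(cfg.n_faces,) + base.shape)
    pts = base[None] + np.einsum("nd,dkc->nkc", z * sd, fields) + noise
    configs = [
        LandmarkConfiguration(face_id=f"synth_{i:03d}", points=pts[i])
        for i in range(cfg.n_faces)
    ]
    return configs, z


# ---------------------------------------------------------------------------
# rating simulation


def default_item_loadings() -> np.ndarray:
    """Planted 18 x 2 item loadings (score units per latent SD).

    Column 1 (valence) is strongly positive for most adjectives and negative
    for "irritated", "tired" and "easily-influenced"; column 2 (dominance) is
    positive for composed/refined adjectives and negative for warm/casual
    ones.  The dominance column is orthogonalized against the valence column
    so the two planted directions are identifiable by PCA.
    """
    v = np.array([6.5, -5.5, 5.5, 6.5, 5.0, 5.5, 4.5, 6.0, 5.8, 5.5,
                  6.2, 6.0, 5.8, -5.2, 5.3, 5.9, -3.0, 5.6])
    d = np.array([-2.0, 3.5, 1.5, 2.5, 2.2, -2.5, -0.5, -1.5, 2.4, 2.8,
                  -3.2, -0.5, 2.4, 0.4, -3.0, -2.6, -3.4, 3.3])
    d = d - (d @ v) / (v @ v) * v
    return np.column_stack([v, d])


def default_item_intercepts() -> np.ndarray:
    """Planted per-adjective baseline ratings, mid-scale so clipping is rare."""
    return np.array([47.0, 41.0, 40.0, 55.0, 53.0, 47.0, 55.0, 52.0, 56.0,
                     59.0, 41.0, 54.0, 54.0, 52.0, 56.0, 48.0, 39.0, 54.0])


@dataclass
class RatingSimConfig:
    """Rater-level rating model with random rater intercepts."""

    item_intercepts: np.ndarray = field(default_factory=default_item_intercepts)
    item_loadings: np.ndarray = field(default_factory=default_item_loadings)
    items: tuple[str, ...] = DEFAULT_ITEMS
    rater_sd: float = 6.0
    residual_sd: float = 8.0
    n_raters: int = 24
    seed: int = 0


def simulate_ratings(latent_scores: np.ndarray, cfg: RatingSimConfig) -> RatingTable:
    """Simulate the faces x items x raters rating cube.

    ``score_fir = clip(intercept_i + loadings_i . (V_f, D_f) + b_r + eps, 0, 100)``
    with rater effects ``b_r ~ N(0, rater_sd^2)`` and residuals
    ``eps ~ N(0, residual_sd^2)``.  Only the first two latent dimensions
    (valence, dominance) drive ratings; extra dimensions are nuisance shape
    variation invisible to raters.
    """
    z = np.asarray(latent_scores, dtype=float)
    if z.ndim != 2 or z.shape[1] < 2:
        raise ValueError("latent scores need at least 2 dimensions (valence, dominance)")
    if cfg.n_raters < 2:
        raise ValueError("need at least 2 raters")
    load = np.asarray(cfg.item_loadings, dtype=float)
    inter = np.asarray(cfg.item_intercepts, dtype=float)
    n_faces, n_items = z.shape[0], load.shape[0]
    rng = np.random.default_rng(cfg.seed)
    b = rng.normal(0.0, cfg.rater_sd, size=cfg.n_raters)
    eps = rng.normal(0.0, cfg.residual_sd, size=(n_faces, n_items, cfg.n_raters))
    signal = inter[None, :] + z[:, :2] @ load.T  # (faces, items)
    cube = np.clip(signal[:, :, None] + b[None, None, :] + eps, 0.0, 100.0)
    return RatingTable(
        faces=[f"synth_{i:03d}" for i in range(n_faces)],
        items=list(cfg.items[:n_items]),
        raters=[f"rater_{r:02d}" for r in range(cfg.n_raters)],
        values=cube,
    )


def simulate_stimulus_ratings(
    levels: Sequence[tuple[float, float]],
    cfg: RatingSimConfig,
    slope_sd: float = 1.0,
    gain: float = 1.0,
) -> "pd.DataFrame":  # noqa: F821
    """Simulate validation-study ratings of shape-transformed stimuli.

    Each stimulus carries nominal (valence, dominance) levels in SD units;
    raters respond with the planted item loadings scaled by ``gain``, with
    random intercepts (``rater_sd``) and random per-rater slopes
    (``slope_sd``) on both dimensions, plus residual noise.  Returns a
    long-format DataFrame with columns rater, item, valence_level,
    dominance_level, score.
    """
    import pandas as pd

    if cfg.n_raters < 2:
        raise ValueError("need at least 2 raters")
    rng = np.random.default_rng(cfg.seed)
    load = np.asarray(cfg.item_loadings, dtype=float) * gain
    inter = np.asarray(cfg.item_intercepts, dtype=float)
    n_items = load.shape[0]
    b0 = rng.normal(0.0, cfg.rater_sd, size=cfg.n_raters)
    bv = rng.normal(0.0, slope_sd, size=cfg.n_raters)
    bd = rng.normal(0.0, slope_sd, size=cfg.n_raters)
    rows = []
    for r in range(cfg.n_raters):
        for v, d in levels:
            mu = inter + load[:, 0] * v + load[:, 1] * d + b0[r] + bv[r] * v + bd[r] * d
            scores = np.clip(mu + rng.normal(0.0, cfg.residual_sd, n_items), 0.0, 100.0)
            for i in range(n_items):
                rows.append((f"rater_{r:02d}", cfg.items[i], v, d, scores[i]))
    return pd.DataFrame(
        rows, columns=["rater", "item", "valence_level", "dominance_level", "score"]
    )


# ---------------------------------------------------------------------------
# rendering


def _paint_segment(canvas: np.ndarray, xg: np.ndarray, yg: np.ndarray,
                   p: np.ndarray, q: np.ndarray, half_width: float, ink: float) -> None:
    """Darken pixels by their anti-aliased coverage of the segment p-q."""
    v = q - p
    vv = float(v @ v)
    if vv == 0:
        d = np.hypot(xg - p[0], yg - p[1])
    else:
        t = np.clip(((xg - p[0]) * v[0] + (yg - p[1]) * v[1]) / vv, 0.0, 1.0)
        d = np.hypot(xg - (p[0] + t * v[0]), yg - (p[1] + t * v[1]))
    cov = np.clip(half_width + 0.5 - d, 0.0, 1.0)
    np.minimum(canvas, 255.0 - cov * (255.0 - ink), out=canvas)


def render_schematic(
    config: LandmarkConfiguration,
    size: int = 256,
    fit: bool = True,
    line_width: float = 2.0,
    template: FaceTemplate | None = None,
) -> np.ndarray:
    """Render a face configuration as a grayscale schematic raster.

    Anti-aliased polylines are drawn through the curve landmarks (outline,
    brows, nose sides, lips), eye outlines and filled pupils.  Coverage is
    computed analytically from pixel-center distances, so rendering is
    deterministic, exactly mirror-symmetric for symmetric input, and
    equivariant under integer-pixel translation.  With ``fit=True`` the
    configuration is scaled and centered to the canvas; with ``fit=False``
    coordinates are taken as pixels (x right, y up, origin bottom-left).
    """
    pts = np.asarray(config.points, dtype=float)
    span = pts.max(axis=0) - pts.min(axis=0)
    if np.any(span == 0):
        raise ValueError("degenerate configuration with zero extent")
    tmpl = template or build_template()
    if pts.shape[0] != tmpl.scheme.n_landmarks:
        raise ValueError("configuration does not match the template scheme")
    if fit:
        scale = 0.82 * size / span.max()
        center = (pts.min(axis=0) + pts.max(axis=0)) / 2
        pix = (pts - center) * scale + size / 2
    else:
        pix = pts
    # pixel-center grid in canvas coordinates (x right, y up)
    cols, rows = np.meshgrid(np.arange(size), np.arange(size))
    xg = cols + 0.5
    yg = size - (rows + 0.5)
    canvas = np.full((size, size), 255.0)
    hw = line_width / 2.0
    by_name = {n: i for i, n in enumerate(tmpl.names)}
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    for curve in tmpl.scheme.curves:
        for a, b in zip(curve[:-1], curve[1:]):
            segments.append((pix[a], pix[b]))
    for side in ("_L", "_R"):
        ring = [by_name["eye_inner" + side], by_name["eye_top" + side],
                by_name["eye_outer" + side], by_name["eye_bottom" + side]]
        for a, b in zip(ring, ring[1:] + ring[:1]):
            segments.append((pix[a], pix[b]))
    for p, q in segments:
        _paint_segment(canvas, xg, yg, p, q, hw, 40.0)
    for side in ("_L", "_R"):
        c = pix[by_name["pupil" + side]]
        d = np.hypot(xg - c[0], yg - c[1])
        cov = np.clip(1.6 + 0.5 - d, 0.0, 1.0)
        np.minimum(canvas, 255.0 - cov * 255.0, out=canvas)
    return np.round(canvas).astype(np.uint8)
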