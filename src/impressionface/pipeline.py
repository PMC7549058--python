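"""End-to-end orchestration of the modeling and validation studies.

``run_modeling`` executes the Experiment-1 chain — rating reliability,
impression PCA, semilandmark sliding, symmetrization, generalized Procrustes,
shape PCA, 95%-variance component selection, permutational shape-impression
regression and the per-dimension shape-regression fields — and writes every
intermediate artifact in open formats (TPS, CSV, JSON) together with a run
manifest.  ``run_validation`` executes the Experiment-2 chain on top of it:
average face, nine shape-transformed stimuli, stimulus ratings (simulated or
ingested), the 18 per-item mixed models, and the four loadings-versus-slopes
correlations.

A single global seed is fanned out to per-stage child seeds at fixed offsets
so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .landmark_io import (
    LandmarkConfiguration,
    RatingTable,
    read_rating_table,
    read_tps,
    write_tps,
)
from .impression_space import (
    ImpressionSpace,
    cronbach_alpha,
    impression_pca,
    mean_over_raters,
    DEFAULT_ANCHORS,
)
from .shape_pipeline import (
    LandmarkScheme,
    generalized_procrustes,
    select_components,
    shape_pca,
    slide_semilandmarks,
    symmetrize,
)
from .shape_association import permanova_regression, shape_score_regression
from .stimulus_transform import average_image, stimulus_grid
from .synthetic_faces import (
    RatingSimConfig,
    build_template,
    render_schematic,
    simulate_stimulus_ratings,
)
from .validation_stats import correlate_loadings_coefficients, fit_all_items

__all__ = ["PipelineConfig", "ModelingReport", "ValidationReport", "run_modeling", "run_validation"]

# fixed child-seed offsets for stage-level reproducibility
SEED_PERMUTATION = 11
SEED_STIMULUS_RATINGS = 23


@dataclass
class PipelineConfig:
    """Paths, analysis parameters and the global seed for a pipeline run."""

    tps_path: str
    ratings_path: str
    out_dir: str
    scheme_path: str | None = None
    truth_path: str | None = None  # ground-truth sidecar from the simulator
    stimulus_ratings_path: str | None = None  # ingest instead of simulating
    covariates_path: str | None = None  # optional CSV: face, age entered first
    variance_threshold: float = 0.95
    n_perm: int = 9999
    slide_iterations: int = 3
    sd_levels: tuple[float, ...] = (-3.0, 0.0, 3.0)
    anchors: tuple[str, ...] = DEFAULT_ANCHORS
    image_size: int = 256
    n_validation_raters: int = 26
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        for name in ("tps_path", "ratings_path"):
            p = getattr(cfg, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sd_levels"] = list(self.sd_levels)
        d["anchors"] = list(self.anchors)
        Path(path).write_text(yaml.safe_dump(d))


@dataclass
class ModelingReport:
    """Objects and headline numbers from the modeling (Experiment-1) stage."""

    impressions: ImpressionSpace
    alphas: pd.DataFrame
    aligned: np.ndarray
    mean_shape: np.ndarray
    shape_variance: np.ndarray
    selected: list[int]
    association: "pd.DataFrame"
    association_raw: object
    reg_valence: object
    reg_dominance: object
    configs: list[LandmarkConfiguration]
    scheme: LandmarkScheme


@dataclass
class ValidationReport:
    """Objects and headline numbers from the validation (Experiment-2) stage."""

    avg_image: np.ndarray
    mean_config: LandmarkConfiguration
    stimuli: list[np.ndarray]
    manifest: pd.DataFrame
    lme_table: pd.DataFrame
    correlations: dict[str, dict]


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load_scheme(cfg: PipelineConfig) -> LandmarkScheme:
    if cfg.scheme_path is not None:
        return LandmarkScheme.from_dict(json.loads(Path(cfg.scheme_path).read_text()))
    return build_template().scheme


def run_modeling(cfg: PipelineConfig, write: bool = True) -> ModelingReport:
    """Execute the modeling study; optionally write artifacts under out_dir."""
    for name in ("tps_path", "ratings_path"):
        p = getattr(cfg, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"config error: {name} does not exist: {p}")
    out = Path(cfg.out_dir)
    scheme = _load_scheme(cfg)

    stage = "ratings"
    try:
        ratings: RatingTable = read_rating_table(cfg.ratings_path)
        alphas = pd.DataFrame(
            {
                "item": ratings.items,
                "alpha": [
                    cronbach_alpha(ratings.values[:, i, :])
                    for i in range(len(ratings.items))
                ],
            }
        )
        means = mean_over_raters(ratings)
        stage = "impression_pca"
        impressions = impression_pca(means, item_order=ratings.items, anchors=cfg.anchors)

        stage = "landmarks"
        configs = read_tps(cfg.tps_path)
        if [c.face_id for c in configs] != ratings.faces:
            order = {f: i for i, f in enumerate(ratings.faces)}
            try:
                configs = sorted(configs, key=lambda c: order[c.face_id])
            except KeyError as exc:
                raise ValueError(f"face {exc} present in TPS but not in ratings") from exc

        stage = "sliding"
        slid = slide_semilandmarks(configs, scheme, n_iter=cfg.slide_iterations)
        stage = "symmetrization"
        sym = symmetrize(slid, scheme)
        stage = "procrustes"
        proc = generalized_procrustes(sym)
        stage = "shape_pca"
        space = shape_pca(proc)
        selected = select_components(space, cfg.variance_threshold)

        stage = "association"
        predictors = [impressions.valence, impressions.dominance]
        labels = ["valence", "dominance"]
        if cfg.covariates_path is not None:
            cov = pd.read_csv(cfg.covariates_path).set_index("face").loc[ratings.faces]
            for col in cov.columns:  # covariates control first (sequential SS)
                predictors.insert(0, cov[col].to_numpy(dtype=float))
                labels.insert(0, col)
        assoc = permanova_regression(
            space.scores[:, selected],
            np.column_stack(predictors),
            labels=labels,
            n_perm=cfg.n_perm,
            seed=cfg.seed + SEED_PERMUTATION,
        )
        stage = "shape_regression"
        reg_v = shape_score_regression(proc.aligned, impressions.valence)
        reg_d = shape_score_regression(proc.aligned, impressions.dominance)
    except Exception as exc:
        raise RuntimeError(f"modeling stage {stage!r} failed: {exc}") from exc

    report = ModelingReport(
        impressions=impressions,
        alphas=alphas,
        aligned=proc.aligned,
        mean_shape=proc.mean_shape,
        shape_variance=space.variance_explained,
        selected=selected,
        association=assoc.summary(),
        association_raw=assoc,
        reg_valence=reg_v,
        reg_dominance=reg_d,
        configs=configs,
        scheme=scheme,
    )
    if write:
        out.mkdir(parents=True, exist_ok=True)
        alphas.to_csv(out / "cronbach_alpha.csv", index=False)
        pd.DataFrame(
            impressions.loadings[:, :2],
            index=impressions.item_order,
            columns=["pc1_valence", "pc2_dominance"],
        ).to_csv(out / "impression_loadings.csv", index_label="item")
        pd.DataFrame(
            impressions.scores[:, :2],
            index=ratings.faces,
            columns=["valence", "dominance"],
        ).to_csv(out / "impression_scores.csv", index_label="face")
        pd.DataFrame(
            {"variance_explained": space.variance_explained}
        ).to_csv(out / "shape_variance.csv", index_label="component")
        write_tps(
            [
                LandmarkConfiguration(face_id=c.face_id, points=a)
                for c, a in zip(configs, proc.aligned)
            ],
            out / "aligned.tps",
        )
        write_tps(
            [LandmarkConfiguration(face_id="consensus", points=proc.mean_shape)],
            out / "consensus.tps",
        )
        report.association.to_csv(out / "association.csv")
        for tag, reg in (("valence", reg_v), ("dominance", reg_d)):
            np.savetxt(out / f"field_{tag}.csv", reg.field, delimiter=",",
                       header="dx,dy", comments="")
        (out / "scheme.json").write_text(json.dumps(scheme.to_dict()))
        manifest = {
            "package_version": __version__,
            "seed": cfg.seed,
            "parameters": {
                "variance_threshold": cfg.variance_threshold,
                "n_perm": cfg.n_perm,
                "slide_iterations": cfg.slide_iterations,
                "anchors": list(cfg.anchors),
            },
            "inputs": {
                "tps": _digest(cfg.tps_path),
                "ratings": _digest(cfg.ratings_path),
            },
            "impression_variance": impressions.variance_explained[:4].tolist(),
            "n_selected_components": len(selected),
        }
        (out / "modeling_manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _pixel_configs(
    configs: list[LandmarkConfiguration], size: int
) -> list[LandmarkConfiguration]:
    """Map configurations into a shared pixel frame filling ~80% of the canvas."""
    allpts = np.stack([c.points for c in configs])
    span = allpts.reshape(-1, 2).max(axis=0) - allpts.reshape(-1, 2).min(axis=0)
    center = (allpts.reshape(-1, 2).max(axis=0) + allpts.reshape(-1, 2).min(axis=0)) / 2
    scale = 0.78 * size / span.max()
    return [
        LandmarkConfiguration(
            face_id=c.face_id, points=(c.points - center) * scale + size / 2
        )
        for c in configs
    ]


def run_validation(
    cfg: PipelineConfig, modeling: ModelingReport | None = None, write: bool = True
) -> ValidationReport:
    """Execute the validation study (requires the modeling stage's outputs)."""
    if modeling is None:
        modeling = run_modeling(cfg, write=False)
    out = Path(cfg.out_dir)
    template = build_template()
    stage = "average_image"
    try:
        px_configs = _pixel_configs(modeling.configs, cfg.image_size)
        images = [
            render_schematic(c, size=cfg.image_size, fit=False, template=template)
            for c in px_configs
        ]
        avg, mean_cfg = average_image(images, px_configs)
        stage = "stimuli"
        stimuli, manifest = stimulus_grid(
            avg,
            mean_cfg,
            modeling.reg_valence,
            modeling.reg_dominance,
            levels=cfg.sd_levels,
        )
        stage = "stimulus_ratings"
        if cfg.stimulus_ratings_path is not None:
            long = pd.read_csv(cfg.stimulus_ratings_path)
        else:
            sim = RatingSimConfig(
                n_raters=cfg.n_validation_raters,
                seed=cfg.seed + SEED_STIMULUS_RATINGS,
            )
            if cfg.truth_path is not None:
                truth = json.loads(Path(cfg.truth_path).read_text())
                sim.item_intercepts = np.asarray(truth["item_intercepts"])
                sim.item_loadings = np.asarray(truth["item_loadings"])
                sim.items = tuple(truth["items"])
                sim.rater_sd = float(truth["rater_sd"])
                sim.residual_sd = float(truth["residual_sd"])
            levels = [(v, d) for v in cfg.sd_levels for d in cfg.sd_levels]
            long = simulate_stimulus_ratings(levels, sim)
        stage = "mixed_models"
        lme = fit_all_items(long)
        stage = "correlations"
        item_to_row = {it: i for i, it in enumerate(modeling.impressions.item_order)}
        idx = [item_to_row[it] for it in lme["item"]]
        l1 = modeling.impressions.loadings[idx, 0]
        l2 = modeling.impressions.loadings[idx, 1]
        bv = lme["beta_valence"].to_numpy()
        bd = lme["beta_dominance"].to_numpy()
        correlations = {
            "valence_loadings_vs_valence_slopes": asdict(correlate_loadings_coefficients(l1, bv)),
            "valence_loadings_vs_dominance_slopes": asdict(correlate_loadings_coefficients(l1, bd)),
            "dominance_loadings_vs_dominance_slopes": asdict(correlate_loadings_coefficients(l2, bd)),
            "dominance_loadings_vs_valence_slopes": asdict(correlate_loadings_coefficients(l2, bv)),
        }
    except Exception as exc:
        raise RuntimeError(f"validation stage {stage!r} failed: {exc}") from exc

    report = ValidationReport(
        avg_image=avg,
        mean_config=mean_cfg,
        stimuli=stimuli,
        manifest=manifest,
        lme_table=lme,
        correlations=correlations,
    )
    if write:
        from PIL import Image

        out.mkdir(parents=True, exist_ok=True)
        Image.fromarray(avg).save(out / "average_face.png")
        for img, name in zip(stimuli, manifest["filename"]):
            Image.fromarray(img).save(out / name)
        manifest.to_csv(out / "stimulus_manifest.csv", index=False)
        lme.to_csv(out / "lme_coefficients.csv", index=False)
        (out / "correlations.json").write_text(json.dumps(correlations, indent=2))
    return report
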