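"""Config-driven orchestration of the full shape-and-thickness workflow.

Stages: (load or simulate cohort) -> correspondence -> subchondral node
identification + thickness maps -> SSFM fit -> demographic statistics ->
report. Intermediate results are cached on disk keyed by a content hash of
the stage inputs and the relevant configuration subset, so re-runs and
parameter sweeps only recompute affected stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .correspondence import (
    CorrespondentSet,
    RBFStage,
    build_correspondence,
    default_stages,
)
from .geometry import PointCloud, RigidTransform, TriangleMesh, kabsch_align, poisson_resample, vertex_normals
from .ssfm import ShapeFieldPCA, assemble_features, fit_pca
from .stats import (
    StepwiseSexClassifier,
    binomial_ci_exact,
    decision_geometry,
    regression_table,
    stratified_cv,
)
from .thickness import (
    SubchondralIndexSet,
    ThicknessMap,
    combine_subchondral,
    identify_subchondral_nodes,
    thickness_at_nodes,
    thickness_maps_to_csv,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunRecord", "run_pipeline", "report", "load_cohort"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (mm units throughout)."""

    cohort_dir: str | None = None
    output_dir: str = "kneessfm_output"
    bone_spacing: float = 0.5  # template resampling spacing (mm)
    cartilage_density: float = 16.0  # points per mm^2 (resampling real data)
    rbf_widths: tuple[float, ...] = (20.0, 10.0, 5.0)
    rbf_spacing_factors: tuple[float, ...] = (4.0, 2.0, 1.0)
    rbf_regularization: float = 1e-3
    correspondence_tol: float = 0.01  # mm
    correspondence: str = "rbf"  # "rbf" | "builtin" (vertex-correspondent meshes)
    subchondral_radius: float | None = None  # default: 2 x node spacing
    max_search: float = 10.0
    normalization: str = "per-column"  # | "per-block"
    variance_threshold: float = 0.90
    cv_folds: int = 10
    stepwise_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.variance_threshold < 1:
            raise ValueError("variance threshold must be in (0, 1)")
        for name in ("bone_spacing", "cartilage_density", "correspondence_tol",
                     "max_search", "cv_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def stages(self) -> list[RBFStage]:
        return [
            RBFStage(w, f * self.bone_spacing, self.rbf_regularization)
            for w, f in zip(self.rbf_widths, self.rbf_spacing_factors)
        ]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        for key in ("rbf_widths", "rbf_spacing_factors"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunRecord:
    config: dict
    version: str
    timings: dict[str, float] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _config_hash(config: PipelineConfig, *parts: str) -> str:
    payload = json.dumps([asdict(config), *parts], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_cohort(directory: str | Path):
    """Read a cohort directory written by `Cohort.save` (or same-layout real data).

    Expects per-subject subdirectories with <bone>.ply meshes and
    <bone>_subchondral.xyz / <bone>_articular.xyz clouds, plus
    demographics.csv at the top level.
    """
    directory = Path(directory)
    demo = pd.read_csv(directory / "demographics.csv")
    subjects = []
    for sid in demo["subject"]:
        d = directory / str(sid)
        bones, cart = {}, {}
        for mesh_path in sorted(d.glob("*.ply")):
            bone = mesh_path.stem
            bones[bone] = TriangleMesh.load(mesh_path, bone)
            cart[bone] = (
                PointCloud.load_xyz(d / f"{bone}_subchondral.xyz", f"{bone}_sub"),
                PointCloud.load_xyz(d / f"{bone}_articular.xyz", f"{bone}_art"),
            )
        subjects.append(
            synthetic.Subject(str(sid), bones, cart, RigidTransform())
        )
    return subjects, demo


def _builtin_correspondence(
    subjects, bone: str
) -> tuple[CorrespondentSet, list[RigidTransform]]:
    """Correspondence for vertex-correspondent meshes: Kabsch + one mean pass."""
    ref = subjects[0].bones[bone].vertices
    aligned = []
    for s in subjects:
        v = s.bones[bone].vertices
        aligned.append(kabsch_align(v, ref).apply(v))
    mean = np.mean(aligned, axis=0)
    transforms, clouds = [], []
    for s in subjects:
        v = s.bones[bone].vertices
        t = kabsch_align(v, mean)
        transforms.append(t)
        clouds.append(t.apply(v))
    ids = [s.subject_id for s in subjects]
    return CorrespondentSet(ids, np.stack(clouds), bone), transforms


def _rbf_correspondence(
    subjects, bone: str, config: PipelineConfig
) -> tuple[CorrespondentSet, list[RigidTransform]]:
    template = poisson_resample(
        subjects[0].bones[bone], config.bone_spacing, seed=config.seed, label=bone
    )
    training = [
        poisson_resample(
            s.bones[bone], config.bone_spacing, seed=config.seed + 1 + i,
            label=s.subject_id,
        )
        for i, s in enumerate(subjects)
    ]
    corr, log = build_correspondence(
        training,
        template,
        rms_tol=config.correspondence_tol,
        stages=config.stages(),
        bone=bone,
    )
    return corr, log["transforms"]


def _mean_node_spacing(points: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(points).query(points, k=2)
    return float(np.mean(d[:, 1]))


def run_pipeline(config: PipelineConfig, cohort=None) -> dict:
    """Execute the full workflow; returns a result dict and writes artifacts.

    `cohort` may be an in-memory synthetic `Cohort`; otherwise
    `config.cohort_dir` must point at a cohort directory. Results land in
    `config.output_dir` (model container, thickness CSV, regression table,
    classifier JSON, run record).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = out / "cache"
    cache.mkdir(exist_ok=True)
    record = RunRecord(config=asdict(config), version=_version())
    t0 = time.time()

    if cohort is not None:
        subjects, demo = cohort.subjects, cohort.demographics
    else:
        if config.cohort_dir is None:
            raise ValueError("either a cohort or cohort_dir is required")
        subjects, demo = load_cohort(config.cohort_dir)
        missing = [
            s.subject_id for s in subjects if not s.bones
        ]
        if missing:
            raise FileNotFoundError(f"subjects without mesh files: {missing}")
    bone_names = list(subjects[0].bones)
    record.log.append(f"{len(subjects)} subjects, bones: {bone_names}")

    # -- correspondence ------------------------------------------------------
    t = time.time()
    corr: dict[str, CorrespondentSet] = {}
    transforms: dict[str, list[RigidTransform]] = {}
    for bone in bone_names:
        key = _config_hash(config, "correspond", bone, _cohort_tag(subjects))
        cfile = cache / f"corr_{bone}_{key}.h5"
        if cfile.exists():
            corr[bone] = CorrespondentSet.load(cfile)
            with_np = np.load(cache / f"tf_{bone}_{key}.npz")
            transforms[bone] = [
                RigidTransform(r, tr)
                for r, tr in zip(with_np["rot"], with_np["trans"])
            ]
            record.log.append(f"correspondence[{bone}]: cache hit")
            continue
        if config.correspondence == "builtin":
            corr[bone], transforms[bone] = _builtin_correspondence(subjects, bone)
        else:
            corr[bone], transforms[bone] = _rbf_correspondence(subjects, bone, config)
        corr[bone].save(cfile)
        np.savez(
            cache / f"tf_{bone}_{key}.npz",
            rot=np.stack([t_.rotation for t_ in transforms[bone]]),
            trans=np.stack([t_.translation for t_ in transforms[bone]]),
        )
    record.timings["correspondence"] = time.time() - t

    # -- subchondral nodes + thickness --------------------------------------
    t = time.time()
    index_sets: dict[str, SubchondralIndexSet] = {}
    maps: dict[str, list[ThicknessMap]] = {}
    for bone in bone_names:
        spacing = _mean_node_spacing(corr[bone].arrays[0])
        radius = (
            config.subchondral_radius
            if config.subchondral_radius is not None
            else 2.0 * config.bone_spacing
            if config.correspondence == "rbf"
            else 0.4 * spacing
        )
        per_subject = []
        node_clouds = []
        for j, s in enumerate(subjects):
            nodes_subj = transforms[bone][j].inverse().apply(corr[bone].arrays[j])
            vn = vertex_normals(s.bones[bone])
            idx, _ = _nearest(nodes_subj, vn.points)
            cloud = PointCloud(nodes_subj, vn.normals[idx], bone)
            node_clouds.append(cloud)
            per_subject.append(
                identify_subchondral_nodes(cloud, s.cartilage[bone][0], radius)
            )
        index_sets[bone] = combine_subchondral(per_subject, bone)
        sub_idx = index_sets[bone].indices
        maps[bone] = []
        for j, s in enumerate(subjects):
            cloud = node_clouds[j]
            nodes = PointCloud(
                cloud.points[sub_idx], cloud.normals[sub_idx], bone
            )
            thick, flags = thickness_at_nodes(
                nodes, s.cartilage[bone][1], max_search=config.max_search
            )
            maps[bone].append(ThicknessMap(s.subject_id, bone, thick, flags))
        flagged = int(sum(m.flags.sum() for m in maps[bone]))
        record.log.append(
            f"thickness[{bone}]: {len(sub_idx)} subchondral nodes, "
            f"{flagged} flagged measurements"
        )
    record.timings["thickness"] = time.time() - t
    thickness_csv = out / "thickness_maps.csv"
    thickness_maps_to_csv(
        [m for bone in bone_names for m in maps[bone]], index_sets, thickness_csv
    )
    record.outputs["thickness_maps"] = str(thickness_csv)

    # -- SSFM ----------------------------------------------------------------
    t = time.time()
    fm = assemble_features(corr, maps, index_sets)
    model = fit_pca(fm, scaling=config.normalization)
    record.timings["ssfm"] = time.time() - t
    model_path = out / "ssfm_model.h5"
    model.save(model_path)
    record.outputs["model"] = str(model_path)
    scores_csv = out / "scores.csv"
    pd.DataFrame(
        model.scores_,
        index=fm.subject_ids,
        columns=[f"mode{k + 1}" for k in range(model.n_components_)],
    ).to_csv(scores_csv, index_label="subject")
    record.outputs["scores"] = str(scores_csv)

    # -- statistics ----------------------------------------------------------
    t = time.time()
    n_modes = model.modes_to_reach(config.variance_threshold)
    scores = model.scores_[:, :n_modes]
    reg = regression_table(scores, demo)
    reg_csv = out / "regression_table.csv"
    reg.to_csv(reg_csv)
    clf = StepwiseSexClassifier(alpha=config.stepwise_alpha).fit(
        scores, demo["sex"].to_numpy()
    )
    stats_result: dict = {
        "modes_for_variance_threshold": int(n_modes),
        "variance_threshold": config.variance_threshold,
        "selected_modes": [int(j) + 1 for j in clf.selected_],
        "training_accuracy": float(
            np.mean(clf.predict(scores) == demo["sex"].to_numpy())
        ),
    }
    sex_arr = demo["sex"].to_numpy()
    min_class = int(np.bincount(sex_arr.astype(int), minlength=2).min())
    folds = min(config.cv_folds, min_class)
    if folds < config.cv_folds:
        record.log.append(
            f"smallest class has {min_class} subjects; CV folds capped at {folds}"
        )
    if clf.selected_ and folds >= 2:
        cv = stratified_cv(
            scores[:, clf.selected_],
            sex_arr,
            folds=folds,
            seed=config.seed,
        )
        geom = decision_geometry(clf, scores, demo["sex"].to_numpy())
        stats_result.update(
            {
                "cv_accuracy": cv["accuracy"],
                "cv_correct": cv["correct"],
                "cv_n": cv["n"],
                "cv_ci95": list(cv["ci95"]),
                "cv_auc": cv["auc"],
                "decision_normal": geom["normal"].tolist(),
                "decision_offset": float(geom["offset"]),
                "male_female_axis": geom["male_female_axis"].tolist(),
            }
        )
        cv["folds"].assign(subject=list(fm.subject_ids)).to_csv(
            out / "cv_folds.csv", index=False
        )
        record.outputs["cv_folds"] = str(out / "cv_folds.csv")
    clf_json = out / "classifier.json"
    clf_json.write_text(json.dumps(stats_result, indent=2))
    record.timings["statistics"] = time.time() - t
    record.outputs["regression_table"] = str(reg_csv)
    record.outputs["classifier"] = str(clf_json)

    record.timings["total"] = time.time() - t0
    record.save(out / "run_record.json")
    missing = [p for p in record.outputs.values() if not Path(p).exists()]
    if missing:  # pragma: no cover - defensive
        raise RuntimeError(f"missing outputs: {missing}")
    return {
        "model": model,
        "features": fm,
        "correspondence": corr,
        "index_sets": index_sets,
        "thickness": maps,
        "regression": reg,
        "classifier": clf,
        "stats": stats_result,
        "record": record,
    }


def report(result: dict, path: str | Path) -> str:
    """Human-readable summary: variance spectrum, regression table, classifier."""
    model: ShapeFieldPCA = result["model"]
    lines = ["Shape-and-thickness model report", "=" * 34, ""]
    lines.append("Variance spectrum (top 10 modes):")
    cum = 0.0
    for k, frac in enumerate(model.explained_variance_ratio_[:10], start=1):
        cum += float(frac)
        lines.append(f"  mode {k:2d}: {100 * frac:6.2f}%   cumulative {100 * cum:6.2f}%")
    lines.append("")
    lines.append("Standardized regression of mode scores on demographics:")
    lines.append(result["regression"].round(4).to_string())
    lines.append("")
    stats = result["stats"]
    lines.append(
        f"Modes to reach {100 * stats['variance_threshold']:.0f}% variance: "
        f"{stats['modes_for_variance_threshold']}"
    )
    lines.append(f"Stepwise-selected modes: {stats['selected_modes']}")
    if "cv_accuracy" in stats:
        lo, hi = stats["cv_ci95"]
        lines.append(
            f"CV accuracy {100 * stats['cv_accuracy']:.1f}% "
            f"({stats['cv_correct']}/{stats['cv_n']}), "
            f"95% CI [{100 * lo:.1f}%, {100 * hi:.1f}%], "
            f"AUC {100 * stats['cv_auc']:.1f}%"
        )
    # +/- 2 SD synthesized shapes for the leading modes
    outdir = Path(path).parent
    for k in range(1, min(3, model.n_components_) + 1):
        for c in (-2.0, 2.0):
            clouds, fields = result["model"].split_features(
                model.synthesize_mode(k, c)
            ) if model.blocks_ else ({}, {})
            for bone, cloud in clouds.items():
                fname = outdir / f"mode{k}_{'plus' if c > 0 else 'minus'}2sd_{bone}.xyz"
                cloud.save_xyz(fname)
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text


def _nearest(query: np.ndarray, reference: np.ndarray):
    from .geometry import closest_points

    return closest_points(query, reference)


def _cohort_tag(subjects) -> str:
    h = hashlib.sha256()
    for s in subjects[: min(len(subjects), 4)]:
        for bone, mesh in s.bones.items():
            h.update(mesh.vertices[:16].tobytes())
    h.update(str(len(subjects)).encode())
    return h.hexdigest()[:12]


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("kneessfm")
    except Exception:  # pragma: no cover
        return "unknown"
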