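"""Synthetic pseudo-knee cohorts with known latent structure.

The generator emits cohorts of closed superellipsoid "bones" (femur, tibia,
patella stand-ins) carrying cartilage offset layers. Shape and thickness
variation is driven by a small number of latent modes — global size,
mediolateral aspect ratio, and a condylar-depth bump — linearly coupled to
simulated demographics (sex, height, mass, age drawn from per-sex normals
matching the study cohort) plus Gaussian residuals. Every quantity a recovery
test could want (latent scores, true node correspondence, true thickness,
applied rigid transforms) is emitted as ground truth.

Design notes
------------
* Pseudo-bones are analytic superellipsoids, not anatomical femora: the
  downstream pipeline is geometry-agnostic and analytic surfaces give exact
  oracles (area, offset shells). Real meshes can be substituted through the
  same file interfaces.
* Each latent mode acts through a fixed displacement field on the template
  vertices plus a thickness field on the cartilage patch. The raw fields
  (scale / aspect / bump) overlap geometrically, so they are Gram-Schmidt
  orthogonalised in feature space; mode variances are then calibrated by a
  fixed-point iteration so each mode hits its target share of the
  *normalised* (per-column unit variance) feature-space variance, with the
  remainder assigned to isotropic Gaussian noise.
* Vertex count is constant across subjects, so vertex index IS the true
  correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import trimesh
from scipy.special import ellipeinc, ellipkinc

from .geometry import PointCloud, RigidTransform, TriangleMesh, vertex_normals

__all__ = [
    "BoneSpec",
    "LatentMode",
    "SyntheticConfig",
    "SyntheticTruth",
    "Subject",
    "Cohort",
    "make_pseudo_bone",
    "make_cartilage",
    "generate_cohort",
    "ellipsoid_area",
    "default_config",
    "classifier_config",
    "sample_demographics",
    "sample_scores",
    "bayes_accuracy",
]

# Table-style demographic targets: (n-weight, age, height cm, mass kg) per sex
FEMALE_STATS = {"age": (28.2, 4.6), "height": (167.5, 5.9), "mass": (60.6, 7.7)}
MALE_STATS = {"age": (29.3, 3.7), "height": (178.4, 7.4), "mass": (72.7, 9.0)}
MALE_PREVALENCE = 21 / 51


def ellipsoid_area(a: float, b: float, c: float) -> float:
    """Exact surface area of an ellipsoid via incomplete elliptic integrals."""
    a, b, c = sorted((a, b, c), reverse=True)
    if abs(a - c) < 1e-12:
        return 4.0 * np.pi * a * a
    phi = np.arccos(c / a)
    m = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    s = np.sin(phi)
    return float(
        2 * np.pi * c * c
        + (2 * np.pi * a * b / s)
        * (ellipeinc(phi, m) * s * s + ellipkinc(phi, m) * np.cos(phi) ** 2)
    )


_UNIT_SPHERE_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _unit_sphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    if subdivisions not in _UNIT_SPHERE_CACHE:
        ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        _UNIT_SPHERE_CACHE[subdivisions] = (
            np.asarray(ico.vertices, float),
            np.asarray(ico.faces, np.int64),
        )
    return _UNIT_SPHERE_CACHE[subdivisions]


@dataclass(frozen=True)
class BoneSpec:
    """Template geometry of one pseudo-bone and its cartilage patch."""

    semiaxes: tuple[float, float, float]
    exponent: float = 2.0
    patch_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    patch_cos: float = 0.55  # patch = unit directions with u . axis > patch_cos
    bump_direction: tuple[float, float, float] = (0.0, -0.45, -0.9)
    bump_sharpness: float = 8.0
    has_bump: bool = False


DEFAULT_BONES: dict[str, BoneSpec] = {
    "femur": BoneSpec((22.0, 20.0, 28.0), patch_axis=(0.0, 0.0, -1.0), has_bump=True),
    "tibia": BoneSpec((20.0, 18.0, 24.0), patch_axis=(0.0, 0.0, 1.0)),
    "patella": BoneSpec((12.0, 10.0, 9.0), patch_axis=(0.0, 1.0, 0.0)),
}


def make_pseudo_bone(
    scale: float = 1.0,
    aspect: float = 1.0,
    bump_amplitude: float = 0.0,
    spec: BoneSpec = DEFAULT_BONES["femur"],
    subdivisions: int = 3,
    label: str = "",
) -> TriangleMesh:
    """Closed superellipsoid surface with an optional smooth condylar bump.

    Deterministic, with a vertex count independent of the parameters, so
    vertex indices are correspondent across any parameter settings. `aspect`
    scales the mediolateral (x) axis; the bump displaces vertices radially
    with a smooth angular falloff around ``spec.bump_direction``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    u, faces = _unit_sphere(subdivisions)
    q = 2.0 / spec.exponent
    p = np.sign(u) * np.abs(u) ** q
    v = p * np.asarray(spec.semiaxes, float)
    v[:, 0] *= aspect
    if bump_amplitude != 0.0:
        v = v + bump_amplitude * _bump_weights(u, spec)[:, None] * u
    return TriangleMesh(scale * v, faces.copy(), label)


def _bump_weights(u: np.ndarray, spec: BoneSpec) -> np.ndarray:
    b = np.asarray(spec.bump_direction, float)
    b = b / np.linalg.norm(b)
    return np.exp(-spec.bump_sharpness * (1.0 - u @ b))


def _patch_vertices(subdivisions: int, spec: BoneSpec) -> np.ndarray:
    u, _ = _unit_sphere(subdivisions)
    axis = np.asarray(spec.patch_axis, float)
    axis = axis / np.linalg.norm(axis)
    return np.nonzero(u @ axis > spec.patch_cos)[0].astype(np.int64)


def make_cartilage(
    bone: TriangleMesh,
    patch: np.ndarray,
    thickness_field: np.ndarray,
    density: float = 4.0,
    rng: int | np.random.Generator = 0,
) -> tuple[PointCloud, PointCloud]:
    """Subchondral and articular cartilage clouds over a bone vertex patch.

    The subchondral cloud densely samples (uniform by area, `density` points
    per mm^2) the faces whose vertices all belong to `patch`; the articular
    cloud offsets each sample along the barycentrically interpolated outward
    vertex normal by the interpolated thickness (mm).

    `thickness_field` gives thickness per patch vertex, aligned with `patch`.
    """
    patch = np.asarray(patch, np.int64)
    if patch.size == 0:
        raise ValueError("cartilage patch is empty")
    thickness_field = np.asarray(thickness_field, float)
    if thickness_field.shape != (patch.size,):
        raise ValueError("thickness_field must align with the patch vertices")
    if np.any(thickness_field < 0):
        raise ValueError("thickness must be non-negative")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    in_patch = np.zeros(bone.vertices.shape[0], dtype=bool)
    in_patch[patch] = True
    faces = bone.faces[in_patch[bone.faces].all(axis=1)]
    if faces.shape[0] == 0:
        raise ValueError("patch contains no complete faces")
    full_thickness = np.zeros(bone.vertices.shape[0])
    full_thickness[patch] = thickness_field
    normals = vertex_normals(bone).normals

    tri = bone.vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    n_samples = max(patch.size, int(round(density * areas.sum())))
    face_idx = rng.choice(faces.shape[0], size=n_samples, p=areas / areas.sum())
    r1 = np.sqrt(rng.random(n_samples))
    r2 = rng.random(n_samples)
    w = np.column_stack([1 - r1, r1 * (1 - r2), r1 * r2])  # barycentric weights
    fv = faces[face_idx]
    pts = np.einsum("nk,nkd->nd", w, bone.vertices[fv])
    nrm = np.einsum("nk,nkd->nd", w, normals[fv])
    nrm /= np.linalg.norm(nrm, axis=1)[:, None]
    thick = np.einsum("nk,nk->n", w, full_thickness[fv])
    sub = PointCloud(pts, nrm, f"{bone.label}_subchondral")
    art = PointCloud(pts + thick[:, None] * nrm, None, f"{bone.label}_articular")
    return sub, art


@dataclass(frozen=True)
class LatentMode:
    """One latent mode: geometric + thickness effects and demographic coupling.

    Geometric coefficients are per unit latent score before variance
    calibration: `scale_coef` multiplies all bones isotropically,
    `aspect_coef` widens the mediolateral axis (with a compensating
    proximodistal change), `bump_coef` (mm) deepens the condylar bump on
    bump-bearing bones. `thickness_offset` (mm) shifts all cartilage and
    `thickness_gradient` (mm) tilts it along the mediolateral direction.
    `demographic_coef` are the structural standardized coefficients on
    (sex, height, mass, age); `share` is the mode's target fraction of the
    normalised feature-space variance.
    """

    name: str
    share: float
    demographic_coef: tuple[float, float, float, float]
    scale_coef: float = 0.0
    aspect_coef: float = 0.0
    bump_coef: float = 0.0
    tilt_coef: float = 0.0  # proximodistal shear along x: plateau tilt / shaft angle
    skew_coef: float = 0.0  # anteroposterior shear along z: femoral skew
    thickness_offset: float = 0.0
    thickness_gradient: float = 0.0


def default_modes() -> list[LatentMode]:
    """Size / aspect / condylar-depth modes with study-like demographic signs.

    Negative latent score means a larger, wider, deeper-condyled knee with
    thicker cartilage, so male sex and height carry negative coefficients on
    the size mode, matching the polarity convention of the sex/height
    regression the model targets.
    """
    return [
        LatentMode(
            "size",
            0.60,
            (-0.323, -0.508, 0.0, 0.0),
            scale_coef=-0.04,
            thickness_offset=-0.15,
        ),
        LatentMode(
            "aspect",
            0.25,
            (-0.500, 0.548, 0.0, 0.0),
            aspect_coef=-0.05,
            thickness_gradient=0.08,
        ),
        LatentMode(
            "condyle",
            0.10,
            (-0.415, 0.0, 0.0, 0.0),
            bump_coef=-0.8,
            tilt_coef=-0.03,
            thickness_offset=-0.06,
        ),
    ]


def classifier_modes() -> list[LatentMode]:
    """Five modes with sex dimorphism confined to modes 1, 2 and 4."""
    return [
        LatentMode(
            "size",
            0.45,
            (-0.323, -0.508, 0.0, 0.0),
            scale_coef=-0.04,
            thickness_offset=-0.15,
        ),
        LatentMode(
            "aspect",
            0.22,
            (-0.500, 0.300, 0.0, 0.0),
            aspect_coef=-0.05,
            thickness_gradient=0.08,
        ),
        LatentMode(
            "skew", 0.12, (0.0, 0.0, 0.0, 0.0), skew_coef=0.035,
            thickness_gradient=-0.10,
        ),
        LatentMode(
            "condyle",
            0.10,
            (-0.415, 0.0, 0.0, 0.0),
            bump_coef=-0.8,
            tilt_coef=-0.03,
            thickness_offset=-0.06,
        ),
        LatentMode("offset", 0.06, (0.0, 0.0, 0.0, 0.0), thickness_offset=0.12,
                   tilt_coef=0.012),
    ]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 51
    seed: int = 0
    modes: list[LatentMode] = field(default_factory=default_modes)
    noise_share: float = 0.05
    male_prevalence: float = MALE_PREVALENCE
    female_stats: dict = field(default_factory=lambda: dict(FEMALE_STATS))
    male_stats: dict = field(default_factory=lambda: dict(MALE_STATS))
    bones: dict = field(default_factory=lambda: dict(DEFAULT_BONES))
    subdivisions: int = 3
    base_thickness: float = 2.0
    cartilage_density: float = 4.0  # points per mm^2
    max_transform_angle: float = 30.0  # deg
    max_transform_shift: float = 50.0  # mm
    apply_transforms: bool = True

    def __post_init__(self) -> None:
        shares = np.array([m.share for m in self.modes])
        if np.any(shares <= 0):
            raise ValueError("variance shares must be positive")
        if shares.sum() + self.noise_share > 1.0 + 1e-9:
            raise ValueError("variance shares plus noise share exceed 1")


def default_config(n_subjects: int = 60, seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(n_subjects=n_subjects, seed=seed)


def classifier_config(n_subjects: int = 200, seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(n_subjects=n_subjects, seed=seed, modes=classifier_modes())


# -- demographic population model -------------------------------------------


def _population_moments(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Analytic mean and SD of (sex, height, mass, age) under the mixture."""
    p = cfg.male_prevalence
    means, sds = [p], [np.sqrt(p * (1 - p))]
    for var in ("height", "mass", "age"):
        mf, sf = cfg.female_stats[var]
        mm, sm_ = cfg.male_stats[var]
        mu = (1 - p) * mf + p * mm
        second = (1 - p) * (sf**2 + mf**2) + p * (sm_**2 + mm**2)
        means.append(mu)
        sds.append(np.sqrt(second - mu**2))
    return np.array(means), np.array(sds)


def _demographic_correlation(cfg: SyntheticConfig) -> np.ndarray:
    """Correlation matrix of standardized (sex, height, mass, age).

    Height, mass and age are conditionally independent given sex, so all
    cross-covariances are mediated by the sex difference in means.
    """
    p = cfg.male_prevalence
    _, sds = _population_moments(cfg)
    delta = np.array(
        [
            1.0,
            cfg.male_stats["height"][0] - cfg.female_stats["height"][0],
            cfg.male_stats["mass"][0] - cfg.female_stats["mass"][0],
            cfg.male_stats["age"][0] - cfg.female_stats["age"][0],
        ]
    )
    pq = p * (1 - p)
    cov = pq * np.outer(delta, delta)  # all pairs are mediated by sex
    np.fill_diagonal(cov, sds**2)
    return cov / np.outer(sds, sds)


def sample_demographics(
    cfg: SyntheticConfig, rng: np.random.Generator, n: int | None = None
) -> pd.DataFrame:
    """Draw (sex, height, mass, age) per subject from the per-sex normals."""
    n = cfg.n_subjects if n is None else n
    sex = (rng.random(n) < cfg.male_prevalence).astype(int)
    out = {"sex": sex}
    for var in ("height", "mass", "age"):
        mf, sf = cfg.female_stats[var]
        mm, sm_ = cfg.male_stats[var]
        draws = rng.normal(np.where(sex == 1, mm, mf), np.where(sex == 1, sm_, sf))
        out[var] = draws
    df = pd.DataFrame(out)
    df.insert(0, "subject", [f"S{i:03d}" for i in range(n)])
    return df


def residual_covariance(cfg: SyntheticConfig) -> np.ndarray:
    """Residual covariance making the latent score vector white.

    Latent modes emulate principal-component scores of a population model,
    which are mutually uncorrelated with unit variance by construction; the
    demographic part B d induces cross-mode covariance B Sigma_d B^T, so the
    Gaussian residual carries covariance I - B Sigma_d B^T. Raises when the
    demographic coefficients alone already exceed unit variance (infeasible
    construction)."""
    sigma = _demographic_correlation(cfg)
    b = np.array([m.demographic_coef for m in cfg.modes], float)
    res = np.eye(len(cfg.modes)) - b @ sigma @ b.T
    eigvals = np.linalg.eigvalsh(res)
    if eigvals.min() < -1e-10:
        raise ValueError(
            "demographic coefficients imply negative residual variance "
            f"(min eigenvalue {eigvals.min():.3g})"
        )
    return res


def sample_scores(
    cfg: SyntheticConfig,
    demographics: pd.DataFrame,
    rng: np.random.Generator,
    unit_variance: bool = True,
) -> np.ndarray:
    """Latent scores: coefficient matrix x standardized demographics + residual.

    With ``unit_variance`` the scores have population variance 1 per mode
    (standardized betas equal the structural coefficients exactly);
    otherwise they are scaled to the calibrated feature-space variances.
    """
    means, sds = _population_moments(cfg)
    d = demographics[["sex", "height", "mass", "age"]].to_numpy(float)
    d_std = (d - means) / sds
    b = np.array([m.demographic_coef for m in cfg.modes])  # K x 4
    res = residual_covariance(cfg)
    chol = np.linalg.cholesky(res + 1e-12 * np.eye(res.shape[0]))
    z = d_std @ b.T + rng.normal(size=(d.shape[0], len(cfg.modes))) @ chol.T
    if not unit_variance:
        z = z * calibrate(cfg)[0]
    return z


# -- feature-space sensitivities and variance calibration --------------------


def _template_geometry(cfg: SyntheticConfig):
    """Template meshes, patch indices, and per-mode sensitivity fields."""
    bones = {}
    for name, spec in cfg.bones.items():
        mesh = make_pseudo_bone(spec=spec, subdivisions=cfg.subdivisions, label=name)
        u, _ = _unit_sphere(cfg.subdivisions)
        patch = _patch_vertices(cfg.subdivisions, spec)
        bones[name] = (spec, mesh, u, patch)
    return bones


def _raw_sensitivities(cfg: SyntheticConfig):
    """Per-mode displacement fields (mm per unit score) before orthogonalisation.

    Returns (coord sensitivity K x (3 * total vertices),
             thickness sensitivity K x total patch vertices,
             bookkeeping dict).
    """
    bones = _template_geometry(cfg)
    K = len(cfg.modes)
    coord_parts, thick_parts = [], []
    layout = {"bones": [], "patches": {}}
    for name, (spec, mesh, u, patch) in bones.items():
        layout["bones"].append(name)
        layout["patches"][name] = patch
        v = mesh.vertices
        n_v = v.shape[0]
        # compensating proximodistal coefficient keeps the aspect field
        # roughly volume-neutral (and decorrelated from pure scaling)
        gamma = float(np.sum(v[:, 0] ** 2) / np.sum(v[:, 2] ** 2))
        bump_w = _bump_weights(u, spec) if spec.has_bump else None
        xhat = u[patch, 0]  # mediolateral coordinate of patch directions
        c_block = np.zeros((K, n_v, 3))
        t_block = np.zeros((K, patch.size))
        for k, mode in enumerate(cfg.modes):
            d = np.zeros((n_v, 3))
            if mode.scale_coef:
                d += mode.scale_coef * v
            if mode.aspect_coef:
                d[:, 0] += mode.aspect_coef * v[:, 0]
                d[:, 2] -= mode.aspect_coef * gamma * v[:, 2]
            if mode.bump_coef and bump_w is not None:
                d += mode.bump_coef * bump_w[:, None] * u
            if mode.tilt_coef:
                d[:, 2] += mode.tilt_coef * v[:, 0]
            if mode.skew_coef:
                d[:, 1] += mode.skew_coef * v[:, 2]
            c_block[k] = d
            t_block[k] = mode.thickness_offset + mode.thickness_gradient * xhat
        coord_parts.append(c_block.reshape(K, -1))
        thick_parts.append(t_block)
    coords = np.hstack(coord_parts)
    thick = np.hstack(thick_parts)
    return coords, thick, layout


@dataclass
class Calibration:
    """Resolved generative model: orthogonal fields, score scales, noise SDs."""

    scales: np.ndarray  # per-mode latent score SD multiplier
    geometry_noise_sd: float  # mm, per vertex coordinate
    thickness_noise_sd: float  # mm, per patch vertex
    coords: np.ndarray  # K x (3 * total vertices) displacement fields
    thick: np.ndarray  # K x total patch vertices thickness fields
    layout: dict


def _calibration(cfg: SyntheticConfig) -> Calibration:
    """Orthogonalise mode fields and hit the target variance shares.

    The raw scale / aspect / bump fields overlap, and the relevant inner
    product is the one of the *normalised* feature space (each column
    divided by its SD), which itself depends on the field amplitudes. The
    fixed point alternates: (1) Gram-Schmidt the raw fields under the
    current diag(1/var) metric (earlier modes keep their character),
    (2) update score scales and the two noise SDs so mode k owns `share_k`
    of the normalised variance and isotropic noise owns `noise_share`
    (split between coordinate and thickness columns by column count). The
    leading mode's scale is pinned to 1: shares are invariant to a joint
    rescaling, and pinning keeps geometry magnitudes equal to the stated
    per-unit-score coefficients.
    """
    coords_raw, thick_raw, layout = _raw_sensitivities(cfg)
    raw = np.hstack([coords_raw, thick_raw])
    K, m = raw.shape
    m_c = coords_raw.shape[1]
    is_thick = np.zeros(m, dtype=bool)
    is_thick[m_c:] = True
    shares = np.array([mode.share for mode in cfg.modes])
    noise_c_target = cfg.noise_share * (m_c / m)
    noise_t_target = cfg.noise_share * ((m - m_c) / m)

    u = raw.copy()
    s2 = shares / np.maximum((u**2).sum(axis=1), 1e-300)
    sg2, st2 = 1e-4, 1e-4
    for _ in range(300):
        noise_col = np.where(is_thick, st2, sg2)
        v = (s2[:, None] * u**2).sum(axis=0) + noise_col
        # Gram-Schmidt of the raw fields in the diag(1/v) metric
        w = raw / np.sqrt(v)
        for k in range(K):
            for j in range(k):
                denom = float(w[j] @ w[j])
                if denom <= 1e-300:
                    raise ValueError(
                        f"latent mode '{cfg.modes[j].name}' is degenerate"
                    )
                w[k] = w[k] - (w[k] @ w[j]) / denom * w[j]
        u = w * np.sqrt(v)
        u2 = u**2
        v = (s2[:, None] * u2).sum(axis=0) + noise_col
        mode_share = (s2[:, None] * u2 / v).mean(axis=1)
        ng = float(np.sum(sg2 / v[~is_thick]) / m)
        nt = float(np.sum(st2 / v[is_thick]) / m) if is_thick.any() else 0.0
        s2_new = s2 * shares / np.maximum(mode_share, 1e-300)
        # noise floors: a column block with no mode signal is all noise, so
        # its noise share cannot drop below its column fraction; keep the SDs
        # strictly positive instead of chasing an unreachable target
        sg2_new = max(sg2 * noise_c_target / max(ng, 1e-300), 1e-18 * s2_new.max())
        st2_new = (
            max(st2 * noise_t_target / max(nt, 1e-300), 1e-18 * s2_new.max())
            if is_thick.any()
            else st2
        )
        pin = s2_new[0]
        s2_new, sg2_new, st2_new = s2_new / pin, sg2_new / pin, st2_new / pin
        done = (
            np.abs(np.log(s2_new / s2)).max() < 1e-10
            and abs(np.log(sg2_new / sg2)) < 1e-10
        )
        s2, sg2, st2 = s2_new, sg2_new, st2_new
        if done:
            break
    return Calibration(
        np.sqrt(s2),
        float(np.sqrt(sg2)),
        float(np.sqrt(st2)),
        u[:, :m_c],
        u[:, m_c:],
        layout,
    )


def calibrate(cfg: SyntheticConfig) -> tuple[np.ndarray, float, float]:
    """Latent-score scales and (geometry, thickness) noise SDs in mm."""
    cal = _calibration(cfg)
    return cal.scales, cal.geometry_noise_sd, cal.thickness_noise_sd


# -- cohort assembly ---------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every cohort."""

    latent_scores: np.ndarray  # n x K, feature-space scale
    latent_scores_unit: np.ndarray  # n x K, unit population variance
    true_thickness: dict[str, np.ndarray]  # bone -> n x patch_size (mm)
    patch_indices: dict[str, np.ndarray]
    transforms: list[RigidTransform]
    score_scales: np.ndarray
    geometry_noise_sd: float
    thickness_noise_sd: float

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("latent_scores", data=self.latent_scores)
            f.create_dataset("latent_scores_unit", data=self.latent_scores_unit)
            f.create_dataset("score_scales", data=self.score_scales)
            f.attrs["geometry_noise_sd"] = self.geometry_noise_sd
            f.attrs["thickness_noise_sd"] = self.thickness_noise_sd
            for bone, arr in self.true_thickness.items():
                f.create_dataset(f"thickness/{bone}", data=arr)
                f.create_dataset(f"patch/{bone}", data=self.patch_indices[bone])
            rot = np.stack([t.rotation for t in self.transforms])
            tr = np.stack([t.translation for t in self.transforms])
            f.create_dataset("transform_rotations", data=rot)
            f.create_dataset("transform_translations", data=tr)


@dataclass
class Subject:
    subject_id: str
    bones: dict[str, TriangleMesh]
    cartilage: dict[str, tuple[PointCloud, PointCloud]]  # (subchondral, articular)
    transform: RigidTransform


@dataclass
class Cohort:
    config: SyntheticConfig
    subjects: list[Subject]
    demographics: pd.DataFrame
    truth: SyntheticTruth

    @property
    def bone_names(self) -> list[str]:
        return list(self.config.bones)

    def save(self, directory: str | Path) -> None:
        """Write meshes (PLY), cartilage clouds (XYZ), demographics CSV, truth."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for subj in self.subjects:
            d = directory / subj.subject_id
            d.mkdir(exist_ok=True)
            for bone, mesh in subj.bones.items():
                mesh.save(d / f"{bone}.ply")
                sub, art = subj.cartilage[bone]
                sub.save_xyz(d / f"{bone}_subchondral.xyz")
                art.save_xyz(d / f"{bone}_articular.xyz")
        self.demographics.to_csv(directory / "demographics.csv", index=False)
        self.truth.save(directory / "truth.h5")


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Generate a full synthetic cohort from one seed.

    Demographics are drawn from the per-sex normals; latent scores follow the
    structural demographic coefficients plus residuals; each subject's bones
    are the template plus the score-weighted mode displacement fields plus
    isotropic vertex noise; cartilage is built on the perturbed bone from the
    (noisy) true thickness field; finally a bounded random rigid transform is
    applied per subject to exercise the alignment stages.
    """
    rng = np.random.default_rng(cfg.seed)
    cal = _calibration(cfg)
    scales, sg, st = cal.scales, cal.geometry_noise_sd, cal.thickness_noise_sd
    coords_sens, thick_sens, layout = cal.coords, cal.thick, cal.layout
    bones = _template_geometry(cfg)
    demo = sample_demographics(cfg, rng)
    z_unit = sample_scores(cfg, demo, rng, unit_variance=True)
    z = z_unit * scales

    # split sensitivity columns back per bone
    coord_slices, thick_slices = {}, {}
    c0 = t0 = 0
    for name in layout["bones"]:
        n_v = bones[name][1].vertices.shape[0]
        patch = layout["patches"][name]
        coord_slices[name] = slice(c0, c0 + 3 * n_v)
        thick_slices[name] = slice(t0, t0 + patch.size)
        c0 += 3 * n_v
        t0 += patch.size

    subjects: list[Subject] = []
    true_thickness: dict[str, list[np.ndarray]] = {n: [] for n in layout["bones"]}
    transforms: list[RigidTransform] = []
    for i in range(cfg.n_subjects):
        sid = demo["subject"].iloc[i]
        transform = (
            RigidTransform.random(rng, cfg.max_transform_angle, cfg.max_transform_shift)
            if cfg.apply_transforms
            else RigidTransform()
        )
        transforms.append(transform)
        subj_bones: dict[str, TriangleMesh] = {}
        subj_cart: dict[str, tuple[PointCloud, PointCloud]] = {}
        for name in layout["bones"]:
            spec, template, _, patch = bones[name]
            disp = (z[i] @ coords_sens[:, coord_slices[name]]).reshape(-1, 3)
            verts = template.vertices + disp + rng.normal(0.0, sg, template.vertices.shape)
            mesh = TriangleMesh(verts, template.faces, name)
            t_field = (
                cfg.base_thickness
                + z[i] @ thick_sens[:, thick_slices[name]]
                + rng.normal(0.0, st, patch.size)
            )
            t_field = np.maximum(t_field, 0.0)
            true_thickness[name].append(t_field)
            sub, art = make_cartilage(
                mesh, patch, t_field, density=cfg.cartilage_density, rng=rng
            )
            subj_bones[name] = TriangleMesh(
                transform.apply(mesh.vertices), mesh.faces, name
            )
            subj_cart[name] = (sub.transformed(transform), art.transformed(transform))
        subjects.append(Subject(sid, subj_bones, subj_cart, transform))

    truth = SyntheticTruth(
        latent_scores=z,
        latent_scores_unit=z_unit,
        true_thickness={n: np.stack(v) for n, v in true_thickness.items()},
        patch_indices=dict(layout["patches"]),
        transforms=transforms,
        score_scales=scales,
        geometry_noise_sd=sg,
        thickness_noise_sd=st,
    )
    return Cohort(cfg, subjects, demo, truth)


# -- analytic class-conditional model (classifier oracle) --------------------


def bayes_accuracy(cfg: SyntheticConfig, n_mc: int = 200_000, seed: int = 12345) -> float:
    """Bayes-optimal sex classification accuracy of the latent construction.

    Conditional on sex the unit-variance latent scores are exactly Gaussian
    (linear map of Gaussian demographics plus Gaussian residual), so the
    optimal rule is quadratic discriminant analysis between the two analytic
    class conditionals; the accuracy integral is evaluated by Monte Carlo.
    """
    means, sds = _population_moments(cfg)
    b = np.array([m.demographic_coef for m in cfg.modes])
    res_cov = residual_covariance(cfg)
    params = {}
    for sex, stats_ in ((0, cfg.female_stats), (1, cfg.male_stats)):
        mu_d = np.array(
            [sex, stats_["height"][0], stats_["mass"][0], stats_["age"][0]]
        )
        sd_d = np.array(
            [0.0, stats_["height"][1], stats_["mass"][1], stats_["age"][1]]
        )
        mu_std = (mu_d - means) / sds
        d_cov = np.diag((sd_d / sds) ** 2)
        params[sex] = (b @ mu_std, b @ d_cov @ b.T + res_cov)
    rng = np.random.default_rng(seed)
    p_male = cfg.male_prevalence
    n_male = int(round(n_mc * p_male))
    correct = 0
    from scipy.stats import multivariate_normal

    mvn = {s: multivariate_normal(params[s][0], params[s][1]) for s in (0, 1)}
    for sex, n_s in ((0, n_mc - n_male), (1, n_male)):
        mu, cov = params[sex]
        zs = rng.multivariate_normal(mu, cov, size=n_s)
        log_post_male = np.log(p_male) + mvn[1].logpdf(zs)
        log_post_female = np.log(1 - p_male) + mvn[0].logpdf(zs)
        pred = (log_post_male > log_post_female).astype(int)
        correct += int(np.sum(pred == sex))
    return correct / n_mc
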