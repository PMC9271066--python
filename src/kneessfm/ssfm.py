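"""Statistical shape and field model (SSFM).

The feature vector of one subject concatenates the correspondent bone node
coordinates (x, y, z per node, femur then tibia then patella by assembly
order) with the cartilage thickness at the shared subchondral nodes. Columns
are mean-centred and divided by their standard deviation (correlation-style
PCA; a per-block pooled variant is available), and a principal component
analysis of the n_subjects x m matrix yields orthonormal modes coupling bone
shape to the spatial distribution of cartilage thickness.

``ShapeFieldPCA`` follows the scikit-learn estimator contract (fit /
transform / inverse_transform, trailing-underscore fitted attributes) so it
composes with sklearn pipelines; ``fit_pca`` and friends are thin wrappers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .correspondence import CorrespondentSet
from .geometry import PointCloud
from .thickness import SubchondralIndexSet, ThicknessMap

__all__ = [
    "ColumnBlock",
    "FeatureMatrix",
    "ShapeFieldPCA",
    "assemble_features",
    "fit_pca",
    "modes_to_reach",
    "synthesize_mode",
    "project_subject",
]


@dataclass(frozen=True)
class ColumnBlock:
    """One contiguous block of feature columns (coords or thickness of a bone)."""

    bone: str
    kind: str  # "coords" | "thickness"
    size: int  # number of columns

    def __post_init__(self) -> None:
        if self.kind not in ("coords", "thickness"):
            raise ValueError("kind must be 'coords' or 'thickness'")


@dataclass
class FeatureMatrix:
    """Raw (un-normalised) subject-by-feature matrix with column provenance."""

    values: np.ndarray
    subject_ids: list[str]
    blocks: list[ColumnBlock] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        if self.blocks and sum(b.size for b in self.blocks) != self.values.shape[1]:
            raise ValueError("block sizes do not sum to the column count")

    def block_slices(self) -> list[tuple[ColumnBlock, slice]]:
        out, start = [], 0
        for b in self.blocks:
            out.append((b, slice(start, start + b.size)))
            start += b.size
        return out


def assemble_features(
    correspondence: dict[str, CorrespondentSet],
    thickness: dict[str, Sequence[ThicknessMap]],
    index_sets: dict[str, SubchondralIndexSet] | None = None,
) -> FeatureMatrix:
    """Concatenate nodal coordinates and thickness values into one matrix.

    Column order is deterministic: for each bone in the order given, all node
    coordinates flattened node-major (x, y, z); then, for each bone in the
    same order, thickness at its subchondral nodes. All inputs must list the
    same subjects in the same order.
    """
    bones = list(correspondence)
    ref_ids = correspondence[bones[0]].subject_ids
    for bone in bones:
        if correspondence[bone].subject_ids != ref_ids:
            raise ValueError(f"subject mismatch in correspondence for '{bone}'")
    for bone, maps in thickness.items():
        ids = [m.subject_id for m in maps]
        if ids != ref_ids:
            offenders = sorted(set(ids).symmetric_difference(ref_ids)) or ids
            raise ValueError(
                f"subject mismatch in thickness maps for '{bone}': {offenders}"
            )
    cols, blocks = [], []
    for bone in bones:
        arr = correspondence[bone].arrays  # n x nodes x 3
        cols.append(arr.reshape(arr.shape[0], -1))
        blocks.append(ColumnBlock(bone, "coords", 3 * arr.shape[1]))
    for bone in thickness:
        t = np.stack([m.thickness for m in thickness[bone]])
        cols.append(t)
        blocks.append(ColumnBlock(bone, "thickness", t.shape[1]))
    return FeatureMatrix(np.hstack(cols), list(ref_ids), blocks)


class ShapeFieldPCA(BaseEstimator, TransformerMixin):
    """PCA of the normalised shape+thickness feature matrix.

    Parameters
    ----------
    scaling : {"per-column", "per-block"}
        "per-column" divides every column by its own standard deviation
        (n-1 denominator). "per-block" divides all columns of a block by the
        pooled (RMS) standard deviation of that block, preserving relative
        amplitudes within coordinates and within thickness.

    Fitted attributes
    -----------------
    mean_ : (m,) column means.
    scale_ : (m,) divisors applied after centring; 1.0 for zero-SD columns.
    zero_sd_mask_ : (m,) bool, columns with no variance (centred only).
    components_ : (k, m) orthonormal modes, variance-descending; each mode's
        largest-|loading| entry is made positive so signs are reproducible.
    explained_variance_ : (k,) score variances (n-1 denominator).
    explained_variance_ratio_ : (k,) fractions summing to 1.
    scores_ : (n, k) training scores (= normalised matrix @ components_.T).
    """

    def __init__(self, scaling: str = "per-column"):
        self.scaling = scaling

    def fit(self, X, y=None, blocks: list[ColumnBlock] | None = None):
        subject_ids: list[str] = []
        if isinstance(X, FeatureMatrix):
            blocks = X.blocks
            subject_ids = list(X.subject_ids)
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need a 2D matrix with at least 3 subjects")
        if self.scaling not in ("per-column", "per-block"):
            raise ValueError("scaling must be 'per-column' or 'per-block'")
        n, m = X.shape
        self.mean_ = X.mean(axis=0)
        centred = X - self.mean_
        col_sd = centred.std(axis=0, ddof=1)
        self.zero_sd_mask_ = col_sd < 1e-14
        scale = np.ones(m)
        if self.scaling == "per-column":
            scale[~self.zero_sd_mask_] = col_sd[~self.zero_sd_mask_]
        else:
            if not blocks:
                raise ValueError("per-block scaling requires column blocks")
            start = 0
            for b in blocks:
                sl = slice(start, start + b.size)
                live = ~self.zero_sd_mask_[sl]
                if np.any(live):
                    pooled = float(np.sqrt(np.mean(col_sd[sl][live] ** 2)))
                    seg = scale[sl]
                    seg[live] = pooled
                    scale[sl] = seg
                start += b.size
        self.scale_ = scale
        z = centred / scale
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        k = min(n - 1, m)
        u, s, vt = u[:, :k], s[:k], vt[:k]
        # sign convention: dominant loading of each mode is positive
        signs = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
        signs[signs == 0] = 1.0
        vt = vt * signs[:, None]
        u = u * signs[None, :]
        self.components_ = vt
        self.explained_variance_ = s**2 / (n - 1)
        total = self.explained_variance_.sum()
        self.explained_variance_ratio_ = (
            self.explained_variance_ / total if total > 0 else self.explained_variance_
        )
        self.scores_ = u * s
        self.n_components_ = k
        self.n_features_in_ = m
        self.blocks_ = list(blocks) if blocks else []
        self.subject_ids_ = subject_ids
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "components_"):
            raise AttributeError("ShapeFieldPCA instance is not fitted yet")

    def transform(self, X) -> np.ndarray:
        """Mode scores of (possibly new) subjects given raw feature rows."""
        self._check_fitted()
        if isinstance(X, FeatureMatrix):
            X = X.values
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature layout mismatch: expected {self.n_features_in_} columns, "
                f"got {X.shape[1]}"
            )
        return (X - self.mean_) / self.scale_ @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Raw feature rows (mm coordinates, mm thickness) from mode scores."""
        self._check_fitted()
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return scores @ self.components_ * self.scale_ + self.mean_

    # -- model interrogation ------------------------------------------------

    def modes_to_reach(self, fraction: float) -> int:
        """Smallest mode count whose cumulative variance fraction exceeds `fraction`."""
        self._check_fitted()
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        cum = np.cumsum(self.explained_variance_ratio_)
        hits = np.nonzero(cum > fraction)[0]
        return int(hits[0]) + 1 if hits.size else self.n_components_

    def synthesize_mode(self, mode: int, c: float) -> np.ndarray:
        """Feature row at mean + c standard deviations along `mode` (1-based)."""
        self._check_fitted()
        if not 1 <= mode <= self.n_components_:
            raise ValueError(f"mode must be in [1, {self.n_components_}]")
        scores = np.zeros(self.n_components_)
        scores[mode - 1] = c * np.sqrt(self.explained_variance_[mode - 1])
        return self.inverse_transform(scores)[0]

    def split_features(
        self, row: np.ndarray
    ) -> tuple[dict[str, PointCloud], dict[str, np.ndarray]]:
        """Split one raw feature row into per-bone clouds and thickness arrays."""
        self._check_fitted()
        if not self.blocks_:
            raise ValueError("no column block metadata stored on this model")
        clouds: dict[str, PointCloud] = {}
        fields: dict[str, np.ndarray] = {}
        start = 0
        for b in self.blocks_:
            seg = np.asarray(row[start : start + b.size])
            if b.kind == "coords":
                clouds[b.bone] = PointCloud(seg.reshape(-1, 3), None, b.bone)
            else:
                fields[b.bone] = np.maximum(seg, 0.0)
            start += b.size
        return clouds, fields

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self._check_fitted()
        with h5py.File(path, "w") as f:
            for name in (
                "mean_",
                "scale_",
                "zero_sd_mask_",
                "components_",
                "explained_variance_",
                "explained_variance_ratio_",
                "scores_",
            ):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["scaling"] = self.scaling
            f.attrs["blocks"] = json.dumps(
                [(b.bone, b.kind, b.size) for b in self.blocks_]
            )

    @classmethod
    def load(cls, path: str | Path) -> "ShapeFieldPCA":
        with h5py.File(path, "r") as f:
            model = cls(scaling=str(f.attrs["scaling"]))
            for name in (
                "mean_",
                "scale_",
                "components_",
                "explained_variance_",
                "explained_variance_ratio_",
                "scores_",
            ):
                setattr(model, name, f[name][()])
            model.zero_sd_mask_ = f["zero_sd_mask_"][()].astype(bool)
            model.blocks_ = [
                ColumnBlock(bone, kind, int(size))
                for bone, kind, size in json.loads(f.attrs["blocks"])
            ]
        model.n_components_ = model.components_.shape[0]
        model.n_features_in_ = model.components_.shape[1]
        return model


# -- thin functional wrappers ----------------------------------------------


def fit_pca(fm: FeatureMatrix, scaling: str = "per-column") -> ShapeFieldPCA:
    model = ShapeFieldPCA(scaling=scaling).fit(fm)
    model.subject_ids_ = list(fm.subject_ids)
    return model


def modes_to_reach(model: ShapeFieldPCA, fraction: float) -> int:
    return model.modes_to_reach(fraction)


def synthesize_mode(model: ShapeFieldPCA, mode: int, c: float):
    """Per-bone point clouds and thickness fields at mean + c SD along a mode."""
    return model.split_features(model.synthesize_mode(mode, c))


def project_subject(model: ShapeFieldPCA, features: np.ndarray) -> np.ndarray:
    return model.transform(np.atleast_2d(features))[0]
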