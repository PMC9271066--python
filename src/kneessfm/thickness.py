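"""Cartilage thickness at correspondent subchondral bone nodes.

Subchondral nodes are the bone nodes lying within an inclusion radius of the
subchondral cartilage surface; the per-subject sets are combined (union) so
every subject carries values at the same node indices. Thickness at a node is
the projection, onto the node's outward normal, of the articular cartilage
point closest to that normal line — the normal-distance between the
subchondral and articular faces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import PointCloud

__all__ = [
    "SubchondralIndexSet",
    "ThicknessMap",
    "identify_subchondral_nodes",
    "combine_subchondral",
    "thickness_at_nodes",
    "thickness_maps_to_csv",
]


@dataclass
class SubchondralIndexSet:
    """Sorted node indices (into a correspondent set) covered by cartilage."""

    bone: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and (
            np.any(np.diff(np.sort(self.indices)) == 0) or self.indices.min() < 0
        ):
            raise ValueError("indices must be unique and non-negative")
        self.indices = np.sort(self.indices)

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class ThicknessMap:
    """Per-subject cartilage thickness (mm) aligned with a SubchondralIndexSet.

    ``flags`` marks nodes where no admissible articular point was found; those
    carry thickness 0 so the downstream feature matrix stays rectangular.
    """

    subject_id: str
    bone: str
    thickness: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.thickness.shape != self.flags.shape:
            raise ValueError("thickness and flags must align")
        if np.any(self.thickness < 0):
            raise ValueError("thickness must be non-negative")
        if np.any(self.thickness[self.flags] != 0):
            raise ValueError("flagged nodes must carry thickness 0")


def identify_subchondral_nodes(
    bone: PointCloud, subchondral_cartilage: PointCloud, radius: float
) -> np.ndarray:
    """Bone node indices within `radius` (mm) of the subchondral cartilage.

    Default radius in the pipeline is twice the bone node spacing.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(subchondral_cartilage) == 0:
        raise ValueError("subchondral cartilage cloud is empty")
    tree = cKDTree(subchondral_cartilage.points)
    dist, _ = tree.query(bone.points)
    idx = np.nonzero(dist <= radius)[0]
    if idx.size == 0:
        raise ValueError(
            "no bone nodes within the inclusion radius; increase `radius`"
        )
    return idx.astype(np.int64)


def combine_subchondral(
    per_subject_sets: Iterable[np.ndarray], bone: str = ""
) -> SubchondralIndexSet:
    """Union of per-subject subchondral node sets, sorted ascending."""
    sets = list(per_subject_sets)
    if not sets:
        return SubchondralIndexSet(bone, np.array([], dtype=np.int64))
    combined = np.unique(np.concatenate([np.asarray(s, np.int64) for s in sets]))
    return SubchondralIndexSet(bone, combined)


def thickness_at_nodes(
    nodes: PointCloud,
    articular: PointCloud,
    max_search: float = 10.0,
    perpendicular_tol: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Thickness (mm) at each subchondral node by projection onto its normal.

    Candidate articular points lie within ``max_search`` of the node, within
    ``perpendicular_tol`` of the node's normal line, and project strictly in
    front of the surface (positive projection up to ``max_search``); among
    candidates the one closest to the normal line wins and its projection
    magnitude is the thickness. Nodes without any candidate are flagged and
    set to 0. Returns (thickness, flags).
    """
    if nodes.normals is None:
        raise ValueError("node cloud must carry unit normals")
    if max_search <= 0:
        raise ValueError("max_search must be positive")
    pts = nodes.points
    nrm = nodes.normals
    art = articular.points
    tree = cKDTree(art)
    neighbours = tree.query_ball_point(pts, max_search)
    thickness = np.zeros(pts.shape[0])
    flags = np.ones(pts.shape[0], dtype=bool)
    for i, nb in enumerate(neighbours):
        if not nb:
            continue
        rel = art[nb] - pts[i]
        proj = rel @ nrm[i]
        perp = np.linalg.norm(rel - proj[:, None] * nrm[i], axis=1)
        ok = (proj > 0) & (proj <= max_search) & (perp <= perpendicular_tol)
        if not np.any(ok):
            continue
        best = np.argmin(np.where(ok, perp, np.inf))
        thickness[i] = max(proj[best], 0.0)
        flags[i] = False
    return thickness, flags


def thickness_maps_to_csv(
    maps: Sequence[ThicknessMap],
    index_sets: dict[str, SubchondralIndexSet],
    path: str | Path,
) -> pd.DataFrame:
    """Long-format export: subject, bone, node_index, thickness_mm, flag."""
    rows = []
    for m in maps:
        node_idx = index_sets[m.bone].indices
        for j, t, fl in zip(node_idx, m.thickness, m.flags):
            rows.append((m.subject_id, m.bone, int(j), float(t), bool(fl)))
    df = pd.DataFrame(
        rows, columns=["subject", "bone", "node_index", "thickness_mm", "flag"]
    )
    df.to_csv(path, index=False)
    return df
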