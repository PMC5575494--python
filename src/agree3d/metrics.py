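"""The four pairwise contour-agreement metrics and the per-vertex
deviation map.

DC    distance between volume centroids (mm, symmetric).
DSC   Dice similarity coefficient 2|A∩B| / (|A|+|B|) on a shared voxel
      grid (dimensionless, symmetric).
MSSD  directed mean, over A's vertices, of the Euclidean distance to the
      nearest vertex of B (mm).
UM95  smallest uniform margin m such that expanding A by m contains at
      least ``coverage`` of B's volume (mm, directed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateResolutionError
from .geometry import (
    DEFAULT_PAD,
    DEFAULT_SPACING,
    SurfaceContour,
    VoxelMask,
    distance_field,
    shared_grid,
    volume_centroid,
    voxelize,
)

__all__ = [
    "AgreementRecord",
    "dc",
    "dsc",
    "mssd",
    "um95",
    "deviation_map",
    "PairwiseEvaluator",
    "MANUAL_VS_MANUAL",
    "AGS_VS_MANUAL",
]

MANUAL_VS_MANUAL = "manual_vs_manual"
AGS_VS_MANUAL = "ags_vs_manual"

METRIC_LABELS = {
    "dc_mm": "DC (mm)",
    "dsc": "DSC",
    "mssd_mm": "MSSD (mm)",
    "um95_mm": "UM95 (mm)",
}

DISPLAY_CLAMP_MM = 10.0  # heatmap display ceiling


@dataclass(frozen=True)
class AgreementRecord:
    """One ordered pairwise comparison A (source) vs B (target)."""

    image_id: str
    source_label: str
    target_label: str
    comparison_kind: str
    dc_mm: float
    dsc: float
    mssd_mm: float
    um95_mm: float
    spacing_mm: float

    def __post_init__(self):
        vals = (self.dc_mm, self.dsc, self.mssd_mm, self.um95_mm)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite metric value")
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError(f"dsc out of [0,1]: {self.dsc}")
        if min(self.dc_mm, self.mssd_mm, self.um95_mm) < 0:
            raise ValueError("distance metrics must be >= 0")


def dc(a: SurfaceContour, b: SurfaceContour) -> float:
    """Euclidean distance between the volume centroids of A and B (mm)."""
    return float(np.linalg.norm(volume_centroid(a) - volume_centroid(b)))


def dsc(
    a: SurfaceContour,
    b: SurfaceContour,
    spacing: float = DEFAULT_SPACING,
    pad: float = DEFAULT_PAD,
) -> float:
    origin, shape = shared_grid([a, b], spacing, pad)
    ma = voxelize(a, spacing, origin=origin, shape=shape)
    mb = voxelize(b, spacing, origin=origin, shape=shape)
    return mask_dsc(ma, mb)


def mask_dsc(ma: VoxelMask, mb: VoxelMask) -> float:
    na, nb = int(ma.occupancy.sum()), int(mb.occupancy.sum())
    if na == 0 or nb == 0:
        raise DegenerateResolutionError("empty mask in DSC")
    inter = int((ma.occupancy & mb.occupancy).sum())
    return 2.0 * inter / (na + nb)


def mssd(a: SurfaceContour, b: SurfaceContour, point_to_surface: bool = False) -> float:
    """Directed mean surface-to-surface distance A -> B (mm).

    Default is the vertex-to-nearest-vertex mean.  ``point_to_surface``
    switches to exact point-to-triangle distances (sensitivity analysis
    only; not the default definition).
    """
    if len(a.vertices) == 0 or len(b.vertices) == 0:
        raise ValueError("empty vertex set")
    if point_to_surface:
        return float(np.mean(_point_triangle_distances(a.vertices, b)))
    d, _ = cKDTree(b.vertices).query(a.vertices)
    return float(np.mean(d))


def um95(
    a: SurfaceContour,
    b: SurfaceContour,
    coverage: float = 0.95,
    spacing: float = DEFAULT_SPACING,
    pad: float = DEFAULT_PAD,
) -> float:
    """Uniform margin (mm) expanding A so that >= ``coverage`` of B's
    volume is contained.

    Computed as the nearest-rank ``coverage``-quantile of the distance
    field of A's mask over B's occupied voxels; this is the smallest
    grid-realizable margin meeting the coverage, so the expansion
    certificate |B ∩ expand(A, m)| >= coverage * |B| holds exactly.
    """
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must be in (0, 1]")
    origin, shape = shared_grid([a, b], spacing, pad)
    ma = voxelize(a, spacing, origin=origin, shape=shape)
    mb = voxelize(b, spacing, origin=origin, shape=shape)
    return mask_um(ma, mb, coverage)


def mask_um(ma: VoxelMask, mb: VoxelMask, coverage: float = 0.95,
            dist_a: np.ndarray | None = None) -> float:
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must be in (0, 1]")
    if not mb.occupancy.any():
        raise DegenerateResolutionError("target mask empty in UM")
    if dist_a is None:
        dist_a = distance_field(ma)
    d = np.sort(dist_a[mb.occupancy])
    k = int(np.ceil(coverage * d.size))  # nearest-rank quantile
    return float(max(d[k - 1], 0.0))


def deviation_map(reference: SurfaceContour, others) -> np.ndarray:
    """Per-vertex interobserver deviation on the reference surface.

    For each reference vertex, the maximum over the other contours of the
    distance to that contour's nearest vertex (mm, unclamped; clamp at
    ``DISPLAY_CLAMP_MM`` for display only).
    """
    others = list(others)
    if not others:
        raise ValueError("deviation_map needs at least one other contour")
    out = np.zeros(len(reference.vertices))
    for other in others:
        d, _ = cKDTree(other.vertices).query(reference.vertices)
        np.maximum(out, d, out=out)
    return out


def _point_triangle_distances(points: np.ndarray, mesh: SurfaceContour,
                              chunk: int = 256) -> np.ndarray:
    """Exact distance from each point to the closest triangle of ``mesh``."""
    tv = mesh.vertices[mesh.faces]
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        d = _pt_tri_block(p, tv)
        out[s:s + chunk] = d
    return out


def _pt_tri_block(p, tv):
    # Ericson-style closest point on triangle, vectorized over
    # (n points) x (m triangles).
    a, b, c = tv[:, 0], tv[:, 1], tv[:, 2]
    ab, ac = b - a, c - a
    pp = p[:, None, :]
    ap = pp - a
    d1 = np.einsum("mk,nmk->nm", ab, ap)
    d2 = np.einsum("mk,nmk->nm", ac, ap)
    bp = pp - b
    d3 = np.einsum("mk,nmk->nm", ab, bp)
    d4 = np.einsum("mk,nmk->nm", ac, bp)
    cp = pp - c
    d5 = np.einsum("mk,nmk->nm", ab, cp)
    d6 = np.einsum("mk,nmk->nm", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(np.abs(denom) > 0, vb / denom, 0.0)
        w = np.where(np.abs(denom) > 0, vc / denom, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_bc_n = d4 - d3
        w_bc = np.where((w_bc_n + (d5 - d6)) != 0, w_bc_n / (w_bc_n + (d5 - d6)), 0.0)

    # region masks, applied in priority order
    close = a + v[..., None] * ab + w[..., None] * ac  # interior default

    on_bc = (vc <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    t_bc = np.clip(w_bc, 0, 1)[..., None]
    close = np.where(on_bc[..., None], b + t_bc * (c - b), close)

    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t_ac = np.clip(w_ac, 0, 1)[..., None]
    close = np.where(on_ac[..., None], a + t_ac * ac, close)

    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t_ab = np.clip(v_ab, 0, 1)[..., None]
    close = np.where(on_ab[..., None], a + t_ab * ab, close)

    at_c = (d6 >= 0) & (d5 <= d6)
    close = np.where(at_c[..., None], np.broadcast_to(c, close.shape), close)
    at_b = (d3 >= 0) & (d4 <= d3)
    close = np.where(at_b[..., None], np.broadcast_to(b, close.shape), close)
    at_a = (d1 <= 0) & (d2 <= 0)
    close = np.where(at_a[..., None], np.broadcast_to(a, close.shape), close)

    return np.sqrt(((pp - close) ** 2).sum(-1)).min(axis=1)


class PairwiseEvaluator:
    """Evaluates many ordered pairs of contours of one image on a single
    shared voxel grid, caching masks, centroids, KD-trees and distance
    fields per contour.

    Parameters
    ----------
    contours : mapping label -> SurfaceContour
    spacing : grid spacing, mm
    coverage : UM coverage fraction (default 0.95)
    """

    def __init__(self, contours: dict, spacing: float = DEFAULT_SPACING,
                 coverage: float = 0.95, pad: float = DEFAULT_PAD,
                 image_id: str = ""):
        if not contours:
            raise ValueError("no contours")
        self.contours = dict(contours)
        self.spacing = float(spacing)
        self.coverage = float(coverage)
        self.image_id = image_id or next(iter(contours.values())).image_id
        self.origin, self.shape = shared_grid(
            list(contours.values()), spacing, pad
        )
        self._masks: dict = {}
        self._cent: dict = {}
        self._tree: dict = {}
        self._dist: dict = {}

    def mask(self, label) -> VoxelMask:
        if label not in self._masks:
            self._masks[label] = voxelize(
                self.contours[label], self.spacing,
                origin=self.origin, shape=self.shape,
            )
        return self._masks[label]

    def centroid(self, label):
        if label not in self._cent:
            self._cent[label] = volume_centroid(self.contours[label])
        return self._cent[label]

    def tree(self, label):
        if label not in self._tree:
            self._tree[label] = cKDTree(self.contours[label].vertices)
        return self._tree[label]

    def dist(self, label):
        if label not in self._dist:
            self._dist[label] = distance_field(self.mask(label))
        return self._dist[label]

    def record(self, source: str, target: str, kind: str) -> AgreementRecord:
        a, b = self.contours[source], self.contours[target]
        dcv = float(np.linalg.norm(self.centroid(source) - self.centroid(target)))
        dscv = mask_dsc(self.mask(source), self.mask(target))
        d, _ = self.tree(target).query(a.vertices)
        mssdv = float(np.mean(d))
        umv = mask_um(self.mask(source), self.mask(target), self.coverage,
                      dist_a=self.dist(source))
        return AgreementRecord(
            image_id=self.image_id,
            source_label=source,
            target_label=target,
            comparison_kind=kind,
            dc_mm=dcv,
            dsc=dscv,
            mssd_mm=mssdv,
            um95_mm=umv,
            spacing_mm=self.spacing,
        )
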