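"""Mesh and voxel primitives: volume, centroid, voxelization, distance
fields and uniform margin expansion.

All coordinates are millimetres in a patient frame with +x Left,
+y Anterior, +z Superior.  Meshes must be closed, consistently oriented
2-manifolds (watertight); grids are isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateResolutionError,
    GridMismatchError,
    MeshStructureError,
)

__all__ = [
    "SurfaceContour",
    "VoxelMask",
    "enclosed_volume",
    "volume_centroid",
    "surface_area",
    "voxelize",
    "shared_grid",
    "distance_field",
    "distance_to_region",
    "expand_uniform",
]

# Deterministic sub-voxel offsets of the grid origin.  They push voxel
# centres off axis-aligned mesh planes/edges so the parity ray cast never
# hits a degenerate configuration on synthetic axis-aligned fixtures.
_JITTER = np.array([1.0, 2.0, 3.0]) * (np.sqrt(2.0) - 1.0) * 1e-4

DEFAULT_SPACING = 1.0
DEFAULT_PAD = 5.0


@dataclass
class SurfaceContour:
    """A closed triangle-mesh delineation of one organ.

    Parameters
    ----------
    vertices : (n, 3) float array, mm.
    faces : (m, 3) int array of vertex indices, outward oriented.
    image_id, delineator : identifying labels.
    method : ``"manual"`` or ``"ags"``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    image_id: str = ""
    delineator: str = ""
    method: str = "manual"
    _checked: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)

    @property
    def label(self) -> str:
        return f"{self.delineator}:{self.method}"

    def validate(self) -> "SurfaceContour":
        """Check the watertightness invariants, raising MeshStructureError.

        Requires: finite coordinates, >= 4 vertices and faces, every
        undirected edge shared by exactly two faces, consistent outward
        orientation (each directed edge used exactly once), and positive
        signed enclosed volume.
        """
        if self._checked:
            return self
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3 or f.ndim != 2 or f.shape[1] != 3:
            raise MeshStructureError("vertices must be (n,3), faces (m,3)")
        if len(v) < 4 or len(f) < 4:
            raise MeshStructureError("mesh needs >= 4 vertices and >= 4 faces")
        if not np.all(np.isfinite(v)):
            raise MeshStructureError("non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise MeshStructureError("face index out of range")

        directed = f[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        und = np.sort(directed, axis=1)
        _, counts = np.unique(und, axis=0, return_counts=True)
        if np.any(counts != 2):
            uniq, c = np.unique(und, axis=0, return_counts=True)
            bad = uniq[c != 2]
            raise MeshStructureError(
                f"mesh is not watertight: {len(bad)} edge(s) not shared by "
                f"exactly 2 faces, e.g. {bad[:10].tolist()}",
                open_edges=bad.tolist(),
            )
        _, dcounts = np.unique(directed, axis=0, return_counts=True)
        if np.any(dcounts != 1):
            raise MeshStructureError(
                "inconsistent face orientation (repeated directed edge)"
            )
        if _signed_volume(v, f) <= 0:
            raise MeshStructureError(
                "faces oriented inward (signed enclosed volume <= 0)"
            )
        self._checked = True
        return self

    def translated(self, t) -> "SurfaceContour":
        c = SurfaceContour(
            self.vertices + np.asarray(t, dtype=float),
            self.faces,
            self.image_id,
            self.delineator,
            self.method,
        )
        c._checked = self._checked
        return c

    def transformed(self, rotation=None, translation=None) -> "SurfaceContour":
        """Apply a rigid transform ``v -> v @ R.T + t``."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        c = SurfaceContour(v, self.faces, self.image_id, self.delineator, self.method)
        c._checked = self._checked
        return c

    def bounds(self):
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


@dataclass
class VoxelMask:
    """Binary occupancy on an isotropic grid.

    ``origin`` is the corner of voxel (0,0,0); the centre of voxel
    (i,j,k) is ``origin + (ijk + 0.5) * spacing``.
    """

    origin: np.ndarray
    spacing: float
    occupancy: np.ndarray
    pad_mm: float = 0.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def shape(self):
        return self.occupancy.shape

    @property
    def volume_mm3(self) -> float:
        return float(self.occupancy.sum()) * self.spacing**3

    def same_grid(self, other: "VoxelMask") -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) < 1e-12
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )

    def centers(self):
        """Voxel-centre coordinate arrays (broadcastable)."""
        idx = [np.arange(n) for n in self.shape]
        return [
            self.origin[d] + (idx[d] + 0.5) * self.spacing for d in range(3)
        ]


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    # shift to bbox centre for numerical stability; the signed sum is
    # origin-independent for a closed surface
    v = vertices - vertices.mean(axis=0)
    tv = v[faces]
    return float(np.einsum("ij,ij->", tv[:, 0], np.cross(tv[:, 1], tv[:, 2])) / 6.0)


def enclosed_volume(contour: SurfaceContour) -> float:
    """Volume enclosed by a watertight contour (divergence theorem), mm^3."""
    contour.validate()
    return _signed_volume(contour.vertices, contour.faces)


def volume_centroid(contour: SurfaceContour) -> np.ndarray:
    """Centroid of the enclosed volume (not of the vertex cloud), mm.

    Computed as the volume-weighted mean of the signed tetrahedra spanned
    by each face and a reference point; exactly translation-equivariant.
    """
    contour.validate()
    ref = contour.vertices.mean(axis=0)
    v = contour.vertices - ref
    tv = v[contour.faces]
    w = np.einsum("ij,ij->i", tv[:, 0], np.cross(tv[:, 1], tv[:, 2])) / 6.0
    # centroid of tetra (0, a, b, c) is (a + b + c) / 4
    cent = tv.sum(axis=1) / 4.0
    vol = w.sum()
    return ref + (w[:, None] * cent).sum(axis=0) / vol


def surface_area(contour: SurfaceContour) -> float:
    tv = contour.vertices[contour.faces]
    n = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])
    return float(np.linalg.norm(n, axis=1).sum() / 2.0)


def shared_grid(contours, spacing: float, pad: float = DEFAULT_PAD):
    """Grid (origin, shape, pad) covering every contour plus ``pad`` mm.

    The origin carries a deterministic sub-voxel jitter so voxel centres
    avoid axis-aligned mesh planes.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    los, his = zip(*(c.bounds() for c in contours))
    lo = np.min(los, axis=0) - pad
    hi = np.max(his, axis=0) + pad
    origin = lo - _JITTER * spacing
    shape = tuple(int(np.ceil((hi - origin[d]) / spacing)) + 1 for d, hi in enumerate(hi))
    return origin, shape


def voxelize(
    contour: SurfaceContour,
    spacing: float = DEFAULT_SPACING,
    pad: float = DEFAULT_PAD,
    origin=None,
    shape=None,
) -> VoxelMask:
    """Rasterize a watertight contour: a voxel is occupied iff its centre
    lies inside the mesh (parity of z-ray crossings).

    ``origin``/``shape`` may be supplied to place several contours on one
    common grid; otherwise the padded bounding box is used.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    contour.validate()
    if origin is None or shape is None:
        origin, shape = shared_grid([contour], spacing, pad)
    origin = np.asarray(origin, dtype=float)
    occ = _raycast_parity(contour.vertices, contour.faces, origin, spacing, shape)
    if not occ.any():
        raise DegenerateResolutionError(
            f"voxelization at spacing {spacing} mm produced an empty mask"
        )
    return VoxelMask(origin, spacing, occ, pad_mm=pad)


def _raycast_parity(verts, faces, origin, spacing, shape):
    """Parity fill along +z rays through voxel-column centres."""
    nx, ny, nz = shape
    ox, oy, oz = origin
    tv = verts[faces]  # (T, 3, 3)
    a, b, c = tv[:, 0], tv[:, 1], tv[:, 2]
    denom = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    scale = float(np.abs(verts).max()) + 1.0
    keep = np.abs(denom) > 1e-14 * scale * scale  # drop z-parallel triangles
    a, b, c, denom = a[keep], b[keep], c[keep], denom[keep]
    if len(a) == 0:
        return np.zeros(shape, dtype=bool)

    xs = np.stack([a[:, 0], b[:, 0], c[:, 0]], axis=1)
    ys = np.stack([a[:, 1], b[:, 1], c[:, 1]], axis=1)
    i0 = np.maximum(np.ceil((xs.min(1) - ox) / spacing - 0.5), 0).astype(np.int64)
    i1 = np.minimum(np.floor((xs.max(1) - ox) / spacing - 0.5), nx - 1).astype(np.int64)
    j0 = np.maximum(np.ceil((ys.min(1) - oy) / spacing - 0.5), 0).astype(np.int64)
    j1 = np.minimum(np.floor((ys.max(1) - oy) / spacing - 0.5), ny - 1).astype(np.int64)
    ki = np.maximum(i1 - i0 + 1, 0)
    kj = np.maximum(j1 - j0 + 1, 0)
    reps = ki * kj
    keep2 = reps > 0
    a, b, c, denom = a[keep2], b[keep2], c[keep2], denom[keep2]
    i0, j0, ki, kj, reps = i0[keep2], j0[keep2], ki[keep2], kj[keep2], reps[keep2]
    if len(a) == 0:
        return np.zeros(shape, dtype=bool)

    total = int(reps.sum())
    tri = np.repeat(np.arange(len(a)), reps)
    starts = np.concatenate([[0], np.cumsum(reps)[:-1]])
    off = np.arange(total) - np.repeat(starts, reps)
    I = i0[tri] + off // kj[tri]
    J = j0[tri] + off % kj[tri]

    px = ox + (I + 0.5) * spacing
    py = oy + (J + 0.5) * spacing
    at, bt, ct, d = a[tri], b[tri], c[tri], denom[tri]
    # barycentric coordinates of the (px, py) ray in the xy-projection
    w0 = ((bt[:, 0] - px) * (ct[:, 1] - py) - (bt[:, 1] - py) * (ct[:, 0] - px)) / d
    w1 = ((ct[:, 0] - px) * (at[:, 1] - py) - (ct[:, 1] - py) * (at[:, 0] - px)) / d
    w2 = 1.0 - w0 - w1
    inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
    if not inside.any():
        return np.zeros(shape, dtype=bool)
    I, J = I[inside], J[inside]
    z = (
        w0[inside] * at[inside, 2]
        + w1[inside] * bt[inside, 2]
        + w2[inside] * ct[inside, 2]
    )
    # first voxel index whose centre lies above the crossing
    k0 = np.ceil((z - oz) / spacing - 0.5).astype(np.int64)
    ok = k0 < nz
    I, J, k0 = I[ok], J[ok], np.maximum(k0[ok], 0)

    delta = np.zeros(shape, dtype=np.int32)
    np.add.at(delta, (I, J, k0), 1)
    return (np.cumsum(delta, axis=2) % 2).astype(bool)


def distance_field(mask: VoxelMask) -> np.ndarray:
    """Euclidean distance (mm) from every voxel centre to the nearest
    occupied voxel centre of ``mask``; zero inside the mask."""
    if not mask.occupancy.any():
        raise DegenerateResolutionError("distance field of an empty mask")
    return ndimage.distance_transform_edt(
        ~mask.occupancy, sampling=mask.spacing
    )


def distance_to_region(mask: VoxelMask, point_set: VoxelMask) -> np.ndarray:
    """Distance field of ``mask`` evaluated on the grid shared with
    ``point_set`` (grids must match exactly)."""
    if not mask.same_grid(point_set):
        raise GridMismatchError("masks are not on the same grid")
    return distance_field(mask)


def expand_uniform(mask: VoxelMask, margin: float) -> VoxelMask:
    """Uniform (Euclidean) expansion of a mask by ``margin`` mm.

    A voxel is occupied in the output iff its distance to the input mask
    is <= margin; margin 0 is the identity.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0:
        return VoxelMask(mask.origin.copy(), mask.spacing, mask.occupancy.copy(),
                         pad_mm=mask.pad_mm)
    occ = distance_field(mask) <= margin + 1e-9
    return VoxelMask(mask.origin.copy(), mask.spacing, occ, pad_mm=mask.pad_mm)
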