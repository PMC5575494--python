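"""Closed reference meshes used by tests, examples and the synthetic
shape generator."""

from __future__ import annotations

import numpy as np

from .geometry import SurfaceContour

__all__ = ["cube", "icosphere", "ellipsoid"]


def cube(size: float = 1.0, origin=(0.0, 0.0, 0.0), **labels) -> SurfaceContour:
    """Axis-aligned cube of edge ``size`` with corner at ``origin``
    (12 outward-oriented triangles)."""
    o = np.asarray(origin, dtype=float)
    v = (
        np.array(
            [
                [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
            ],
            dtype=float,
        )
        * size
        + o
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (z = 0), outward -z
            [4, 5, 6], [4, 6, 7],  # top
            [0, 1, 5], [0, 5, 4],  # y = 0
            [3, 7, 6], [3, 6, 2],  # y = 1
            [0, 4, 7], [0, 7, 3],  # x = 0
            [1, 2, 6], [1, 6, 5],  # x = 1
        ],
        dtype=np.int64,
    )
    return SurfaceContour(v, f, **labels).validate()


def _icosahedron():
    t = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1)[:, None]
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return v, f


def icosphere(radius: float = 1.0, subdivisions: int = 3, center=(0.0, 0.0, 0.0),
              **labels) -> SurfaceContour:
    """Subdivided icosahedron projected onto a sphere.

    Subdivision s has 20 * 4**s faces (s=3: 1280 faces / 642 vertices).
    """
    v, f = _icosahedron()
    for _ in range(subdivisions):
        v, f = _subdivide(v, f)
        v /= np.linalg.norm(v, axis=1)[:, None]
    v = v * radius + np.asarray(center, dtype=float)
    return SurfaceContour(v, f, **labels).validate()


def _subdivide(v, f):
    edges = np.sort(f[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid = (v[uniq[:, 0]] + v[uniq[:, 1]]) / 2.0
    mid_idx = len(v) + np.arange(len(uniq))
    newv = np.vstack([v, mid])
    e = mid_idx[inv].reshape(-1, 3)  # midpoints of edges (01, 12, 20) per face
    a, b, c = f[:, 0], f[:, 1], f[:, 2]
    m01, m12, m20 = e[:, 0], e[:, 1], e[:, 2]
    newf = np.concatenate(
        [
            np.stack([a, m01, m20], axis=1),
            np.stack([b, m12, m01], axis=1),
            np.stack([c, m20, m12], axis=1),
            np.stack([m01, m12, m20], axis=1),
        ]
    )
    return newv, newf


def ellipsoid(semi_axes=(1.0, 1.0, 1.0), subdivisions: int = 3,
              center=(0.0, 0.0, 0.0), **labels) -> SurfaceContour:
    s = icosphere(1.0, subdivisions)
    v = s.vertices * np.asarray(semi_axes, dtype=float) + np.asarray(center, float)
    return SurfaceContour(v, s.faces, **labels).validate()
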