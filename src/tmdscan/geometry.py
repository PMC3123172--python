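"""Low-level 3-D geometry: internal-coordinate atom placement, dihedrals,
rigid superposition and deterministic sphere point sets.

All routines are vectorized over a leading batch axis where noted; coordinates
are in Angstrom, angles in degrees unless stated otherwise.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "dihedral",
    "bond_angle",
    "kabsch_rotation",
    "superpose",
    "rmsd_after_superposition",
    "rotation_matrix",
    "random_rotations",
    "icosphere_points",
]


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def place_atom(a, b, c, bond_length, angle_deg, dihedral_deg):
    """Place atom D given positions of A, B, C (NeRF construction).

    D is at ``bond_length`` from C, with angle B-C-D = ``angle_deg`` and
    dihedral A-B-C-D = ``dihedral_deg``.  Inputs may carry a leading batch
    axis ``(..., 3)``; scalars broadcast.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)

    bc = _normalize(c - b)
    n = _normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)

    d_local = np.stack(
        [
            -bond_length * np.cos(theta) * np.ones_like(chi),
            bond_length * np.sin(theta) * np.cos(chi),
            bond_length * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    return (
        c
        + d_local[..., 0:1] * bc
        + d_local[..., 1:2] * m
        + d_local[..., 2:3] * n
    )


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = _normalize(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> 180 to keep the (-180, 180] convention
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def bond_angle(p0, p1, p2) -> np.ndarray:
    """Angle p0-p1-p2 in degrees."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    u = _normalize(p0 - p1)
    v = _normalize(p2 - p1)
    return np.degrees(np.arccos(np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)))


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centered ``mobile`` onto centered
    ``target`` (least-squares, proper rotation)."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, 1.0, d])
    return (u @ s @ vt).T


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Superpose ``mobile`` onto ``target``; returns transformed coordinates."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot = kabsch_rotation(mobile - mc, target - tc)
    return (mobile - mc) @ rot.T + tc


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    moved = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=-1))))


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    axis = _normalize(np.asarray(axis, dtype=float))
    t = np.deg2rad(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(t) * k + (1.0 - np.cos(t)) * (k @ k)


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` uniform random rotation matrices via unit quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], axis=-1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], axis=-1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], axis=-1),
        ],
        axis=1,
    )


def icosphere_points(subdivisions: int = 4) -> np.ndarray:
    """Deterministic unit-sphere point set from a geodesic icosahedron.

    Subdivision frequency ``f`` yields ``10 f^2 + 2`` vertices; the default
    ``f = 4`` gives the classic 162-point set used for accessible-surface
    sampling.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    f = subdivisions
    pts = [verts]
    for (i, j, k) in faces:
        a, b, c = verts[i], verts[j], verts[k]
        for u in range(f + 1):
            for v in range(f + 1 - u):
                w = f - u - v
                if (u % f == 0 and v % f == 0):
                    continue  # corner vertices already present
                pts.append(((u * a + v * b + w * c) / f)[None, :])
    allpts = np.concatenate(pts, axis=0)
    allpts = allpts / np.linalg.norm(allpts, axis=1, keepdims=True)
    # deduplicate shared edge points
    rounded = np.round(allpts, 9)
    _, idx = np.unique(rounded, axis=0, return_index=True)
    return allpts[np.sort(idx)]
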