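"""Structure descriptors: accessible surface area, hydrophobic/hydrophilic
surface ratio, dihedral+H-bond secondary-structure assignment, and all-atom
superposition RMSD.

ASA uses the classic Shrake-Rupley construction with a deterministic
162-point geodesic sphere per atom (probe radius 1.4 A).  The secondary
structure rule is a two-criterion helix test: the (phi, psi) couple must fall
inside an 80 deg circle around the canonical alpha center (-57, -47) *and*
the backbone amide H...carbonyl O hydrogen bond (i -> i+4 for alpha,
i -> i+3 for 3-10) must be shorter than 3 A.  Strand assignment uses a
90 deg circle around (-129, 123).  Everything else is coil, as are terminal
residues lacking a defined phi or psi.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry as geom
from .builder import Conformation

__all__ = [
    "AsaResult",
    "shrake_rupley_asa",
    "residue_asar",
    "pex_assign",
    "helicity_fraction",
    "superposed_rmsd",
    "HELIX_CENTER",
    "BETA_CENTER",
]

HELIX_CENTER = (-57.0, -47.0)
BETA_CENTER = (-129.0, 123.0)
HELIX_RADIUS = 80.0
BETA_RADIUS = 90.0
HBOND_MAX = 3.0  # A
ASAR_CAP = 99.9
ASAR_EPS_AREA = 0.1  # A^2

LABELS = ("alpha_helix", "three_ten_helix", "beta", "coil")


class DescriptorError(ValueError):
    pass


@dataclass
class AsaResult:
    """Per-atom and per-residue accessible surface areas (A^2)."""

    atom_asa: np.ndarray  # (n_atoms,)
    residue_hydrophobic: np.ndarray  # (L,)
    residue_hydrophilic: np.ndarray  # (L,)
    asar: np.ndarray  # (L,) hydrophobic / hydrophilic, capped
    capped: np.ndarray  # (L,) bool, True where the denominator was degenerate


_SPHERE = None


def _sphere_points() -> np.ndarray:
    global _SPHERE
    if _SPHERE is None:
        _SPHERE = geom.icosphere_points(4)  # 162 points
    return _SPHERE


def shrake_rupley_asa(conformation: Conformation, n_points: int = 162,
                      probe_radius: float = 1.4) -> AsaResult:
    """Accessible surface area by deterministic sphere-point sampling."""
    if n_points == 162:
        pts = _sphere_points()
    else:
        # nearest geodesic frequency with at least n_points vertices
        f = max(1, int(np.ceil(np.sqrt((n_points - 2) / 10))))
        pts = geom.icosphere_points(f)
    topo = conformation.topology
    coords = conformation.coords
    radii = topo.radius + probe_radius
    n = topo.n_atoms
    area_per_point = 4.0 * np.pi / len(pts)

    # A surface point u of atom a (at coords[a] + R_a * u) is buried by atom b
    # iff |R_a u - v|^2 < R_b^2 with v = coords[b] - coords[a]; expanding gives
    # a single matmul over all occluding (a, b) pairs at once.
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    close = d2 < (radii[:, None] + radii[None, :]) ** 2
    np.fill_diagonal(close, False)
    a_idx, b_idx = np.nonzero(close)  # ordered pairs, sorted by a
    exposed_count = np.full(n, len(pts), dtype=int)
    if len(a_idx):
        v = coords[b_idx] - coords[a_idx]
        m = pts @ v.T  # (n_points, n_pairs)
        lhs = (radii[a_idx] ** 2 - radii[b_idx] ** 2 + d2[a_idx, b_idx])[None, :] \
            - 2.0 * radii[a_idx][None, :] * m
        buried = lhs < 0.0
        starts = np.searchsorted(a_idx, np.arange(n))
        has = np.diff(np.append(starts, len(a_idx))) > 0
        seg_or = np.bitwise_or.reduceat(buried, starts[has], axis=1)
        exposed_count[has] = np.sum(~seg_or, axis=0)
    asa = area_per_point * radii ** 2 * exposed_count
    L = len(topo.sequence)
    phob = np.zeros(L)
    phil = np.zeros(L)
    for i in range(n):
        r = topo.residue_index[i]
        if topo.hydrophobic[i]:
            phob[r] += asa[i]
        else:
            phil[r] += asa[i]
    capped = phil < ASAR_EPS_AREA
    with np.errstate(divide="ignore", invalid="ignore"):
        asar = np.where(capped, ASAR_CAP, phob / np.where(capped, 1.0, phil))
    return AsaResult(asa, phob, phil, asar, capped)


def residue_asar(asa_result: AsaResult) -> np.ndarray:
    """Per-residue hydrophobic/hydrophilic surface ratio (capped where the
    hydrophilic surface is degenerate)."""
    return asa_result.asar


def _angle_distance(phi, psi, center) -> np.ndarray:
    d = np.stack([phi - center[0], psi - center[1]], axis=-1)
    d = (d + 180.0) % 360.0 - 180.0
    return np.sqrt(np.sum(d * d, axis=-1))


def pex_assign(conformation: Conformation) -> list[str]:
    """Per-residue secondary-structure label from dihedrals plus H-bonds."""
    topo = conformation.topology
    if conformation.topology.hydrogen_policy != "polar":
        raise DescriptorError(
            "secondary-structure assignment requires backbone amide hydrogens; "
            "build the conformation with hydrogen_policy='polar'")
    L = len(topo.sequence)
    dih = conformation.dihedrals
    coords = conformation.coords
    labels = []

    def hbond(i: int, offset: int) -> bool:
        # donor H of residue i+offset to carbonyl O of residue i, and the
        # mirrored test for residues near the C terminus
        ok = False
        if i + offset < L and topo.i_h[i + offset] >= 0:
            ok = np.linalg.norm(
                coords[topo.i_o[i]] - coords[topo.i_h[i + offset]]) < HBOND_MAX
        if not ok and i - offset >= 0 and topo.i_h[i] >= 0:
            ok = np.linalg.norm(
                coords[topo.i_h[i]] - coords[topo.i_o[i - offset]]) < HBOND_MAX
        return bool(ok)

    for i in range(L):
        phi, psi = dih[i]
        if np.isnan(phi) or np.isnan(psi):
            labels.append("coil")
            continue
        if _angle_distance(phi, psi, HELIX_CENTER) <= HELIX_RADIUS:
            if hbond(i, 4):
                labels.append("alpha_helix")
                continue
            if hbond(i, 3):
                labels.append("three_ten_helix")
                continue
        if _angle_distance(phi, psi, BETA_CENTER) <= BETA_RADIUS:
            labels.append("beta")
            continue
        labels.append("coil")
    return labels


def helicity_fraction(labels: list[str]) -> float:
    """Fraction of residues labeled helical (alpha or 3-10)."""
    if not labels:
        return 0.0
    n = sum(1 for l in labels if l in ("alpha_helix", "three_ten_helix"))
    return n / len(labels)


def superposed_rmsd(conformation_a: Conformation, conformation_b: Conformation) -> float:
    """All-atom RMSD after optimal rigid superposition (Kabsch)."""
    if conformation_a.sequence != conformation_b.sequence:
        raise DescriptorError("conformations must share the same sequence")
    a, b = conformation_a.coords, conformation_b.coords
    if a.shape != b.shape:
        raise DescriptorError("atom count mismatch")
    return geom.rmsd_after_superposition(a, b)
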