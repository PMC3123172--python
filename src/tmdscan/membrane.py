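"""Implicit DPPC-bilayer insertion scoring.

The bilayer is a smooth interface function C(z) along the membrane normal
(z = 0 at the bilayer center): C = 0 inside the acyl core (|z| < 1.35 nm),
C = 1 in water (|z| > 1.8 nm), with a logistic transition fitted to those
plateaus.  A rigid structure placed in the bilayer is scored by

* membranous hydrophobicity  E_pho_mem = - sum_i Etr_i * S_i * (1 - C(z_i)),
  stabilizing when hydrophobic surface (Etr > 0) sits in the core and
  penalizing buried hydrophilic surface, and
* lipid perturbation         E_lip = alip * sum_i S_i * (1 - C(z_i)),
  a uniform cost per unit of surface inserted into the bilayer
  (alip = 0.018 kJ/mol/A^2).

The insertion scan translates the structure along z on a fixed grid and, at
each z, samples rigid orientations, keeping the placement with the lowest
E_pot_mem = E_pho_mem + E_lip.  Because both terms depend on atom z
coordinates only, an orientation is fully described by the direction of the
membrane normal in the molecular frame, so orientations are sampled as unit
vectors (uniformly at random, or on a deterministic geodesic grid).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geom
from .builder import Conformation

__all__ = [
    "MembraneModel",
    "InsertionResult",
    "interface_function",
    "membrane_hydrophobicity_energy",
    "lipid_perturbation_energy",
    "membrane_potential_energy",
    "insertion_scan",
]


class MembraneError(ValueError):
    pass


@dataclass
class MembraneModel:
    """Interface geometry and scan settings.

    ``z0_nm``/``alpha_per_nm`` define the logistic interface; the defaults
    are fitted so C(1.35 nm) = 1e-3 and C(1.8 nm) = 1 - 1e-3.
    """

    z0_nm: float = 1.575
    alpha_per_nm: float = float(np.log(999.0) / 0.225)
    alip: float = 0.018  # kJ/mol/A^2
    z_scan_range: float = 10.0  # A, scan is symmetric about the center
    z_step: float = 0.1  # A
    orientation_trials: int = 10000

    @classmethod
    def default(cls) -> "MembraneModel":
        return cls()

    @classmethod
    def from_plateaus(cls, z_core_nm: float = 1.35, z_water_nm: float = 1.8,
                      tol: float = 1e-3, **kwargs) -> "MembraneModel":
        z0 = 0.5 * (z_core_nm + z_water_nm)
        alpha = np.log((1.0 - tol) / tol) / (z_water_nm - z0)
        return cls(z0_nm=z0, alpha_per_nm=float(alpha), **kwargs)


@dataclass
class InsertionResult:
    """Best rigid placement of a structure in the implicit bilayer."""

    best_z: float  # A, of the structure centroid
    tilt_deg: float  # angle between helix axis and membrane normal
    e_pot_mem: float  # kJ/mol at the best placement
    z_grid: np.ndarray  # A
    profile: np.ndarray  # min energy per z over sampled orientations
    normal_in_molecule_frame: np.ndarray  # best orientation (unit vector)


def interface_function(z_nm, membrane_model: MembraneModel | None = None):
    """C(z): 0 in the bilayer core, 1 in water, logistic in |z|."""
    m = membrane_model if membrane_model is not None else MembraneModel.default()
    z = np.abs(np.asarray(z_nm, dtype=float))
    c = 1.0 / (1.0 + np.exp(np.clip(m.alpha_per_nm * (m.z0_nm - z), -500, 500)))
    return c if c.ndim else float(c)


def _check_asa(asa, n):
    asa = np.asarray(asa, dtype=float)
    if asa.shape != (n,):
        raise MembraneError(f"ASA vector length {asa.shape} != atom count {n}")
    return asa


def membrane_hydrophobicity_energy(conformation_placed: Conformation,
                                   membrane_model: MembraneModel,
                                   asa_per_atom) -> float:
    """E_pho_mem of a structure with absolute z coordinates (A)."""
    topo = conformation_placed.topology
    asa = _check_asa(asa_per_atom, topo.n_atoms)
    c = interface_function(conformation_placed.coords[:, 2] / 10.0, membrane_model)
    return float(-np.sum(topo.etr * asa * (1.0 - c)))


def lipid_perturbation_energy(conformation_placed: Conformation,
                              membrane_model: MembraneModel,
                              asa_per_atom) -> float:
    """E_lip >= 0; zero for a fully aqueous structure."""
    topo = conformation_placed.topology
    asa = _check_asa(asa_per_atom, topo.n_atoms)
    c = interface_function(conformation_placed.coords[:, 2] / 10.0, membrane_model)
    return float(membrane_model.alip * np.sum(asa * (1.0 - c)))


def membrane_potential_energy(z_coords_A, etr, asa_per_atom,
                              membrane_model: MembraneModel) -> float:
    """E_pho_mem + E_lip from atom z coordinates and annotations."""
    z = np.asarray(z_coords_A, dtype=float)
    etr = np.asarray(etr, dtype=float)
    asa = np.asarray(asa_per_atom, dtype=float)
    c = interface_function(z / 10.0, membrane_model)
    g = asa * (membrane_model.alip - etr)
    return float(np.sum((1.0 - c) * g))


def _orientation_grid(n: int) -> np.ndarray:
    """Deterministic near-uniform directions (geodesic sphere vertices)."""
    f = 1
    while 10 * f * f + 2 < n:
        f += 1
    return geom.icosphere_points(f)


def helix_axis(conformation: Conformation) -> np.ndarray:
    """Principal axis of the CA trace (unit vector, molecular frame)."""
    ca = conformation.coords[conformation.topology.i_ca]
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    # canonical direction: from first to last CA
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def insertion_scan(conformation: Conformation,
                   membrane_model: MembraneModel | None = None,
                   rng_seed: int = 0,
                   asa_per_atom=None,
                   orientation_mode: str = "random",
                   orientation_trials: int | None = None,
                   chunk: int = 128) -> InsertionResult:
    """Exhaustive z-translation scan with per-z orientation sampling.

    ``orientation_mode='random'`` draws uniform directions (seeded,
    reproducible); ``'grid'`` uses a deterministic geodesic direction set of
    at least ``orientation_trials`` points, useful as a brute-force oracle.
    ASA is computed once on the isolated structure (the rigid scan does not
    change intramolecular burial).
    """
    m = membrane_model if membrane_model is not None else MembraneModel.default()
    topo = conformation.topology
    if topo.n_atoms == 0:
        raise MembraneError("empty conformation")
    if asa_per_atom is None:
        from .descriptors import shrake_rupley_asa
        asa_per_atom = shrake_rupley_asa(conformation).atom_asa
    asa = _check_asa(asa_per_atom, topo.n_atoms)
    n_trials = orientation_trials if orientation_trials is not None else m.orientation_trials

    centered = conformation.coords - conformation.coords.mean(axis=0)
    g = asa * (m.alip - topo.etr)  # per-atom weight of (1 - C)

    if orientation_mode == "random":
        rng = np.random.default_rng(rng_seed)
        v = rng.normal(size=(n_trials, 3))
        dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
    elif orientation_mode == "grid":
        dirs = _orientation_grid(n_trials)
    else:
        raise MembraneError(f"unknown orientation_mode {orientation_mode!r}")

    z_grid = np.arange(-m.z_scan_range, m.z_scan_range + 0.5 * m.z_step, m.z_step)
    profile = np.full(len(z_grid), np.inf)
    best_dir_per_z = np.zeros((len(z_grid), 3))
    for s in range(0, len(dirs), chunk):
        u = dirs[s:s + chunk]  # (K, 3)
        z_at = (centered @ u.T).T  # (K, n_atoms) atom z offsets per orientation
        zz = z_at[:, None, :] + z_grid[None, :, None]  # (K, n_z, n_atoms)
        c = interface_function(zz / 10.0, m)
        e = np.einsum("kza,a->kz", 1.0 - c, g)  # (K, n_z)
        k_best = np.argmin(e, axis=0)
        e_best = e[k_best, np.arange(len(z_grid))]
        better = e_best < profile
        profile[better] = e_best[better]
        best_dir_per_z[better] = u[k_best[better]]
    kz = int(np.argmin(profile))
    axis = helix_axis(conformation)
    u_best = best_dir_per_z[kz]
    tilt = float(np.degrees(np.arccos(np.clip(abs(np.dot(axis, u_best)), 0.0, 1.0))))
    return InsertionResult(
        best_z=float(z_grid[kz]),
        tilt_deg=tilt,
        e_pot_mem=float(profile[kz]),
        z_grid=z_grid,
        profile=profile,
        normal_in_molecule_frame=u_best,
    )
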