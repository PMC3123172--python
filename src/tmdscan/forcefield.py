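"""Non-bonded peptide energy terms.

Four contributions, all over non-bonded atom pairs (1-2 and 1-3 bonded pairs
excluded, 1-4 and beyond at full weight):

* 6-12 Lennard-Jones:  sum A/d^12 - B/d^6 with pairwise A, B from the
  per-type well depths and radii.
* Coulomb with a distance-dependent sigmoidal dielectric rising from 1 to 80
  between 0.2 and 1 nm (screening of charge-charge interactions by the
  increasingly water-like medium at larger separations).
* Intramolecular hydrophobicity: a contact term coupling transfer energies of
  atom pairs, attractive for like pairs (hydrophobic-hydrophobic or
  hydrophilic-hydrophilic) and repulsive for mixed pairs, weighted by the
  mutual surface-coverage ratio of the solvent-augmented spheres and decaying
  exponentially with separation (characteristic length 2 * rsol).
* Implicit solvation (hydrophilic environment only): sum Etr_i * S_i over
  atomic accessible surface areas.

In a uniform hydrophobic environment the solvation term is dropped; in a
membrane environment it is replaced by the implicit-bilayer potential of
:mod:`tmdscan.membrane`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import Conformation, PeptideTopology
from .params import ForceFieldParameters, PairParameters

__all__ = [
    "EnergyBreakdown",
    "NonbondedModel",
    "sigmoid_dielectric",
    "lennard_jones_energy",
    "coulomb_energy",
    "intramolecular_hydrophobicity_energy",
    "solvation_energy",
    "total_energy",
]

ENVIRONMENTS = ("hydrophilic", "hydrophobic", "membrane")


class EnergyError(ValueError):
    pass


@dataclass
class EnergyBreakdown:
    """Energy components in kJ/mol; ``e_total`` is the sum of the components
    active in the given environment."""

    environment: str
    e_vdw: float
    e_coulomb: float
    e_pho_intra: float
    e_solvation: float = 0.0
    e_membrane: float = 0.0

    @property
    def e_total(self) -> float:
        total = self.e_vdw + self.e_coulomb + self.e_pho_intra
        if self.environment == "hydrophilic":
            total += self.e_solvation
        elif self.environment == "membrane":
            total += self.e_membrane
        return total


def sigmoid_dielectric(distance_nm, pair_parameters: PairParameters | None = None):
    """Distance-dependent dielectric: 1 below 0.2 nm, 80 above 1 nm, smooth,
    monotone and symmetric about the interval midpoint (eps(0.6 nm) = 40.5).
    """
    d = np.asarray(distance_nm, dtype=float)
    if np.any(d < 0):
        raise EnergyError("distance must be non-negative")
    lo, hi = (0.2, 1.0) if pair_parameters is None else (
        pair_parameters.d_low_nm, pair_parameters.d_high_nm)
    e0, e1 = (1.0, 80.0) if pair_parameters is None else (
        pair_parameters.eps_low, pair_parameters.eps_high)
    t = np.clip((d - lo) / (hi - lo), 0.0, 1.0)
    eps = e0 + (e1 - e0) * 0.5 * (1.0 - np.cos(np.pi * t))
    return eps if eps.ndim else float(eps)


def _two_sphere_coverage(d, ri, rj):
    """Fraction of sphere i's area lying inside sphere j (spherical cap);
    vectorized, 0 where the spheres are disjoint."""
    d = np.maximum(d, 1e-9)
    f = np.zeros_like(d)
    overlap = (d < ri + rj) & (d > np.abs(ri - rj))
    with np.errstate(invalid="ignore"):
        h = ri - (d * d + ri * ri - rj * rj) / (2.0 * d)
        f = np.where(overlap, np.clip(h / (2.0 * ri), 0.0, 1.0), f)
    f = np.where(d <= rj - ri, 1.0, f)  # sphere i engulfed by j
    return f


class NonbondedModel:
    """Precomputed per-pair parameter arrays for one topology; evaluates all
    non-bonded terms over batches of coordinates (the sampler's hot path)."""

    def __init__(self, topology: PeptideTopology,
                 forcefield: ForceFieldParameters | None = None):
        self.topology = topology
        ff = forcefield if forcefield is not None else topology.forcefield
        self.forcefield = ff
        pp = ff.pair_parameters()
        self.pair_parameters = pp
        i, j = topology.pair_i, topology.pair_j
        ti, tj = topology.atype[i], topology.atype[j]
        self.A = pp.A[ti, tj]
        self.B = pp.B[ti, tj]
        self.kqq = ff.coulomb_constant * topology.charge[i] * topology.charge[j]
        self.q_mask = self.kqq != 0.0
        ei, ej = topology.etr[i], topology.etr[j]
        hp_i, hp_j = topology.hydrophobic[i], topology.hydrophobic[j]
        self.delta = np.where(hp_i == hp_j, -1.0, 1.0)
        self.etr_geom = np.sqrt(np.abs(ei * ej))
        self.r0i = topology.radius[i]
        self.r0j = topology.radius[j]
        self.rsum = self.r0i + self.r0j
        self.rsol = pp.rsol
        self.Ri = self.r0i + self.rsol
        self.Rj = self.r0j + self.rsol
        self._heavy_pairs = topology.heavy[i] & topology.heavy[j]
        # hot-path (float32) tables for batched evaluation
        n = topology.n_atoms
        self._flat = (i * n + j).astype(np.intp)
        self._A32 = self.A.astype(np.float32)
        self._B32 = self.B.astype(np.float32)
        self._rsum2 = ((self.Ri + self.Rj) ** 2).astype(np.float32)
        self._kqq32 = self.kqq[self.q_mask].astype(np.float32)
        self._qflat = self._flat[self.q_mask]

    def _distances(self, coords: np.ndarray) -> np.ndarray:
        diff = coords[..., self.topology.pair_i, :] - coords[..., self.topology.pair_j, :]
        return np.sqrt(np.sum(diff * diff, axis=-1))

    def _lj_from_d(self, d: np.ndarray) -> np.ndarray:
        inv6 = 1.0 / np.maximum(d, 1e-6) ** 6
        return np.sum(self.A * inv6 * inv6 - self.B * inv6, axis=-1)

    def _coulomb_from_d(self, d: np.ndarray) -> np.ndarray:
        if not np.any(self.q_mask):
            return np.zeros(d.shape[:-1])
        dq = d[..., self.q_mask]
        if np.any(dq <= 1e-9):
            bad = np.argwhere(dq <= 1e-9)
            raise EnergyError(f"zero interatomic distance for charged pair(s) {bad[:3]}")
        eps = sigmoid_dielectric(dq / 10.0, self.pair_parameters)
        return np.sum(self.kqq[self.q_mask] / (eps * dq), axis=-1)

    def _pho_from_d(self, d: np.ndarray) -> np.ndarray:
        fij = _two_sphere_coverage(d, self.Ri, self.Rj)
        fji = _two_sphere_coverage(d, self.Rj, self.Ri)
        decay = np.exp(-np.clip(d - self.rsum, 0.0, None) / (2.0 * self.rsol))
        terms = self.delta * self.etr_geom * 0.5 * (fij + fji) * decay
        return np.sum(terms, axis=-1)

    def lennard_jones(self, coords: np.ndarray) -> np.ndarray:
        return self._lj_from_d(self._distances(coords))

    def coulomb(self, coords: np.ndarray) -> np.ndarray:
        return self._coulomb_from_d(self._distances(coords))

    def hydrophobicity(self, coords: np.ndarray) -> np.ndarray:
        return self._pho_from_d(self._distances(coords))

    def nonbonded_total(self, coords: np.ndarray, chunk: int = 64) -> np.ndarray:
        """vdw + coulomb + intramolecular hydrophobicity for a coordinate
        batch (B, n_atoms, 3); one shared distance pass, chunked for memory."""
        e, _ = self.evaluate_batch(coords, chunk=chunk)
        return e

    def evaluate_batch(self, coords: np.ndarray, chunk: int = 64,
                       with_min_heavy: bool = False):
        """Total non-bonded energy per structure and, optionally, the minimum
        non-bonded heavy-atom distance (for the sampler's clash floor).

        This is the sampler's hot path: squared pair distances come from a
        single-precision Gram-matrix product and the contact-limited
        hydrophobicity term is only evaluated on pairs inside its cutoff.
        """
        coords = np.asarray(coords)
        single = coords.ndim == 2
        if single:
            coords = coords[None]
        B = len(coords)
        out = np.empty(B)
        dmin = np.empty(B) if with_min_heavy else None
        hp = self._heavy_pairs
        for s in range(0, B, chunk):
            c = np.ascontiguousarray(coords[s:s + chunk], dtype=np.float32)
            k = len(c)
            g = c @ c.transpose(0, 2, 1)
            sq = np.einsum("bij,bij->bi", c, c)
            d2_full = sq[:, :, None] + sq[:, None, :] - 2.0 * g
            d2 = d2_full.reshape(k, -1)[:, self._flat]
            np.maximum(d2, np.float32(1e-8), out=d2)

            inv2 = 1.0 / d2
            inv6 = inv2 * inv2 * inv2
            e = np.sum((self._A32 * inv6 - self._B32) * inv6, axis=-1, dtype=np.float64)

            if len(self._qflat):
                dq = np.sqrt(d2_full.reshape(k, -1)[:, self._qflat])
                eps = sigmoid_dielectric(np.maximum(dq, 1e-4) / 10.0, self.pair_parameters)
                e += np.sum(self._kqq32 / (eps * dq), axis=-1, dtype=np.float64)

            near_b, near_p = np.nonzero(d2 < self._rsum2)
            if len(near_b):
                d = np.sqrt(d2[near_b, near_p]).astype(np.float64)
                ri, rj = self.Ri[near_p], self.Rj[near_p]
                fij = _two_sphere_coverage(d, ri, rj)
                fji = _two_sphere_coverage(d, rj, ri)
                decay = np.exp(-np.clip(d - self.rsum[near_p], 0.0, None) / (2.0 * self.rsol))
                terms = self.delta[near_p] * self.etr_geom[near_p] * 0.5 * (fij + fji) * decay
                e += np.bincount(near_b, weights=terms, minlength=k)
            out[s:s + chunk] = e
            if with_min_heavy:
                dmin[s:s + chunk] = (
                    np.sqrt(d2[:, hp].min(axis=-1)) if hp.any() else np.inf)
        if single:
            return out[0], (dmin[0] if with_min_heavy else None)
        return out, dmin


_MODEL_CACHE: dict[int, NonbondedModel] = {}


def _model_for(conformation: Conformation) -> NonbondedModel:
    key = id(conformation.topology)
    model = _MODEL_CACHE.get(key)
    if model is None or model.topology is not conformation.topology:
        model = NonbondedModel(conformation.topology)
        _MODEL_CACHE[key] = model
        if len(_MODEL_CACHE) > 256:
            _MODEL_CACHE.pop(next(iter(_MODEL_CACHE)))
    return model


def lennard_jones_energy(conformation: Conformation,
                         pair_parameters: PairParameters | None = None) -> float:
    return float(_model_for(conformation).lennard_jones(conformation.coords))


def coulomb_energy(conformation: Conformation, dielectric_model=None) -> float:
    return float(_model_for(conformation).coulomb(conformation.coords))


def intramolecular_hydrophobicity_energy(
        conformation: Conformation,
        pair_parameters: PairParameters | None = None) -> float:
    return float(_model_for(conformation).hydrophobicity(conformation.coords))


def solvation_energy(conformation: Conformation, asa_per_atom: np.ndarray) -> float:
    """Implicit hydrophilic solvation: sum over atoms of Etr_i * S_i."""
    asa = np.asarray(asa_per_atom, dtype=float)
    if asa.shape != (conformation.topology.n_atoms,):
        raise EnergyError(
            f"ASA vector length {asa.shape} != atom count {conformation.topology.n_atoms}")
    return float(np.sum(conformation.topology.etr * asa))


def total_energy(conformation: Conformation, environment: str,
                 membrane_model=None, asa_per_atom=None) -> EnergyBreakdown:
    """Full energy breakdown in the requested environment.

    For ``hydrophilic``, atomic ASA is computed on demand when not supplied;
    for ``membrane`` the conformation coordinates are taken as already placed
    (z axis = membrane normal, bilayer center at z = 0).
    """
    if environment not in ENVIRONMENTS:
        raise EnergyError(
            f"unknown environment {environment!r}; expected one of {ENVIRONMENTS}")
    model = _model_for(conformation)
    c = conformation.coords
    bd = EnergyBreakdown(
        environment=environment,
        e_vdw=float(model.lennard_jones(c)),
        e_coulomb=float(model.coulomb(c)),
        e_pho_intra=float(model.hydrophobicity(c)),
    )
    if environment == "hydrophilic":
        if asa_per_atom is None:
            from .descriptors import shrake_rupley_asa
            asa_per_atom = shrake_rupley_asa(conformation).atom_asa
        bd.e_solvation = solvation_energy(conformation, asa_per_atom)
    elif environment == "membrane":
        from .membrane import MembraneModel, membrane_potential_energy
        if membrane_model is None:
            membrane_model = MembraneModel.default()
        if asa_per_atom is None:
            from .descriptors import shrake_rupley_asa
            asa_per_atom = shrake_rupley_asa(conformation).atom_asa
        bd.e_membrane = membrane_potential_energy(
            conformation.coords[:, 2], conformation.topology.etr,
            asa_per_atom, membrane_model)
    return bd
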