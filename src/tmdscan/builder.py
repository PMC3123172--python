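"""All-atom peptide construction from sequence plus backbone-state assignments.

The backbone (N, CA, C, O and the amide H) is chained residue by residue with
ideal bond lengths and angles (N-CA 1.458 A, CA-C 1.525 A, C-N 1.329 A), a
fixed trans peptide bond (omega = 180 deg) and the phi/psi couple assigned to
each residue from the structural alphabet.  Side chains are rigid: heavy-atom
ideal-geometry templates (one default rotamer per residue type) are placed in
the local N/CA/C frame of each residue.  Only the polar backbone amide
hydrogen is built explicitly; apolar hydrogens are implicit in the heavy-atom
hydrophobicity types.

Construction is vectorized over a batch of state assignments, which is what
makes the stochastic search affordable in pure numpy.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import geometry as geom
from .alphabet import StructuralAlphabet
from .params import ForceFieldParameters, load_forcefield

__all__ = [
    "AtomRecord",
    "Conformation",
    "PeptideTopology",
    "build_conformation",
    "get_topology",
    "AA_1TO3",
    "CLASH_FLOOR",
]


class BuilderError(ValueError):
    pass


AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}

#: hard lower bound on non-bonded heavy-atom distances (A); closer pairs make
#: a structure rejectable by the sampler (the energy already penalizes them,
#: the floor guards numerics).
CLASH_FLOOR = 1.5

# ideal backbone internal coordinates (lengths in A, angles in deg)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
A_C_N_CA, A_N_CA_C, A_CA_C_N, A_CA_C_O = 121.7, 111.2, 116.2, 120.8
OMEGA = 180.0


@dataclass
class AtomRecord:
    """One atom with its physicochemical annotation."""

    name: str
    element: str
    residue_index: int  # 0-based
    coordinates: np.ndarray  # (3,) Angstrom
    atomic_type: int  # 1..7
    transfer_energy: float  # kJ/mol per A^2 of accessible surface
    partial_charge: float  # fraction of unit charge
    vdw_radius: float  # A
    hydrophobic_flag: bool


def _residue_template(res3: str):
    """Heavy-atom ideal geometry of one residue type, from the bundled
    chemical-component dictionary, expressed in the local N/CA/C frame."""
    import biotite.structure.info as info

    arr = info.residue(res3)
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    names = list(arr.atom_name[keep])
    elements = list(arr.element[keep])
    coords = arr.coord[keep].astype(float)
    bonds = []
    index_map = {old: new for new, old in enumerate(np.where(keep)[0])}
    for a, b, _ in arr.bonds.as_array():
        if a in index_map and b in index_map:
            bonds.append((index_map[a], index_map[b]))
    i_n, i_ca, i_c = names.index("N"), names.index("CA"), names.index("C")
    coords = _set_default_chi1(res3, names, coords)
    frame = _frame_single(coords[i_n], coords[i_ca], coords[i_c])
    local = (coords - coords[i_ca]) @ frame.T  # rows of frame are e1,e2,e3
    side = [i for i, nm in enumerate(names) if nm not in ("N", "CA", "C", "O")]
    return {
        "names": [names[i] for i in side],
        "elements": [elements[i] for i in side],
        "local": local[side],
        "bonds": bonds,
        "all_names": names,
        "side_index": side,
    }


@lru_cache(maxsize=32)
def _template_cached(res3: str):
    return _residue_template(res3)


#: gamma-atom reference for the chi1 torsion, per residue type
_CHI1_REF = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "SER": "OG", "THR": "OG1", "TRP": "CG",
    "TYR": "CG", "VAL": "CG1",
}

#: default chi1 per residue type: chosen (once, by a torsion grid search on
#: ideal helix and strand hosts) as the rotamer with the largest non-bonded
#: clearance, so that every type is clash-free in regular secondary structure
_DEFAULT_CHI1 = {
    "ARG": 180.0, "ASN": -90.0, "ASP": -150.0, "CYS": 180.0, "GLN": -120.0,
    "GLU": -150.0, "HIS": 180.0, "ILE": -60.0, "LEU": -150.0, "LYS": 180.0,
    "MET": 180.0, "PHE": 180.0, "SER": 180.0, "THR": -60.0, "TRP": -120.0,
    "TYR": -90.0, "VAL": 180.0,
}

#: default chi2 for the ring-bearing types (same clearance criterion);
#: CD1 is the chi2 reference atom in all four
_DEFAULT_CHI2 = {"PHE": -90.0, "TYR": -30.0, "TRP": 0.0, "HIS": -150.0}


def _set_default_chi1(res3: str, names: list[str], coords: np.ndarray) -> np.ndarray:
    """Rotate the template side chain to the default chi1 (and chi2 for the
    aromatics).

    The component dictionary's ideal coordinates carry arbitrary torsions
    that can drive gamma/ring atoms into the preceding helix turn; the
    most-populated rotamers keep every type except proline clash-free on an
    ideal helix.  Proline's ring is left untouched.
    """
    from . import geometry as geom

    ref = _CHI1_REF.get(res3)
    if ref is None or ref not in names or "CB" not in names:
        return coords
    out = coords.copy()
    i_n, i_ca, i_cb = names.index("N"), names.index("CA"), names.index("CB")
    current = float(geom.dihedral(out[i_n], out[i_ca], out[i_cb],
                                  out[names.index(ref)]))
    rot = geom.rotation_matrix(out[i_cb] - out[i_ca], _DEFAULT_CHI1[res3] - current)
    distal = [i for i, nm in enumerate(names)
              if nm not in ("N", "CA", "C", "O", "CB")]
    out[distal] = (out[distal] - out[i_cb]) @ rot.T + out[i_cb]

    if res3 in _DEFAULT_CHI2 and "CG" in names and "CD1" in names:
        i_cg, i_cd1 = names.index("CG"), names.index("CD1")
        current2 = float(geom.dihedral(out[i_ca], out[i_cb], out[i_cg], out[i_cd1]))
        rot2 = geom.rotation_matrix(out[i_cg] - out[i_cb],
                                    _DEFAULT_CHI2[res3] - current2)
        ring = [i for i in distal if names[i] not in ("CG",)]
        out[ring] = (out[ring] - out[i_cg]) @ rot2.T + out[i_cg]
    return out


def _frame_single(n, ca, c):
    e1 = n - ca
    e1 = e1 / np.linalg.norm(e1)
    u = c - ca
    e3 = np.cross(e1, u)
    e3 = e3 / np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3])  # rows


def _frames_batch(n, ca, c):
    """Orthonormal residue frames for batched coordinates; shape (B, 3, 3)
    with basis vectors as rows."""
    e1 = n - ca
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    u = c - ca
    e3 = np.cross(e1, u)
    e3 /= np.linalg.norm(e3, axis=-1, keepdims=True)
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=1)


class PeptideTopology:
    """Per-sequence atom metadata, connectivity and batched coordinates.

    The atom order is per residue: N, CA, C, O, [H], side-chain heavy atoms
    in template order.
    """

    def __init__(self, sequence: str, forcefield: ForceFieldParameters | None = None,
                 hydrogen_policy: str = "polar"):
        if hydrogen_policy not in ("polar", "none"):
            raise BuilderError(f"unknown hydrogen_policy {hydrogen_policy!r}")
        bad = [c for c in sequence if c not in AA_1TO3]
        if bad:
            raise BuilderError(f"unknown residue letter(s) {bad} in sequence {sequence!r}")
        if not sequence:
            raise BuilderError("empty sequence")
        self.sequence = sequence
        self.hydrogen_policy = hydrogen_policy
        self.forcefield = forcefield if forcefield is not None else load_forcefield()
        ff = self.forcefield

        names, elements, res_index = [], [], []
        self.i_n = np.zeros(len(sequence), dtype=int)
        self.i_ca = np.zeros(len(sequence), dtype=int)
        self.i_c = np.zeros(len(sequence), dtype=int)
        self.i_o = np.zeros(len(sequence), dtype=int)
        self.i_h = np.full(len(sequence), -1, dtype=int)
        self._side = []  # (start, local_coords) per residue
        bonds = []

        for ri, aa in enumerate(sequence):
            res3 = AA_1TO3[aa]
            tpl = _template_cached(res3)
            base = len(names)
            self.i_n[ri], self.i_ca[ri], self.i_c[ri], self.i_o[ri] = (
                base, base + 1, base + 2, base + 3)
            names += ["N", "CA", "C", "O"]
            elements += ["N", "C", "C", "O"]
            res_index += [ri] * 4
            bonds += [(base, base + 1), (base + 1, base + 2), (base + 2, base + 3)]
            if ri > 0:
                bonds.append((self.i_c[ri - 1], base))  # peptide bond
            has_h = hydrogen_policy == "polar" and res3 != "PRO"
            if has_h:
                self.i_h[ri] = len(names)
                names.append("H")
                elements.append("H")
                res_index.append(ri)
                bonds.append((base, self.i_h[ri]))
            sc_start = len(names)
            names += tpl["names"]
            elements += tpl["elements"]
            res_index += [ri] * len(tpl["names"])
            self._side.append((sc_start, tpl["local"]))
            # side-chain internal bonds, remapped to global indices
            backbone_map = {"N": base, "CA": base + 1, "C": base + 2, "O": base + 3}
            side_map = {}
            for local_i, nm in zip(tpl["side_index"], tpl["names"]):
                side_map[local_i] = sc_start + tpl["names"].index(nm)
            all_names = tpl["all_names"]
            for a, b in tpl["bonds"]:
                ga = backbone_map.get(all_names[a], side_map.get(a))
                gb = backbone_map.get(all_names[b], side_map.get(b))
                if ga is None or gb is None:
                    continue
                if ga >= base or gb >= base:
                    pair = (min(ga, gb), max(ga, gb))
                    if pair not in bonds and ga != gb:
                        bonds.append(pair)

        self.atom_names = names
        self.elements = elements
        self.residue_index = np.array(res_index, dtype=int)
        self.n_atoms = len(names)
        self.bonds = sorted(set((min(a, b), max(a, b)) for a, b in bonds))

        # physicochemical annotation
        self.atype = np.zeros(self.n_atoms, dtype=int)
        self.charge = np.zeros(self.n_atoms)
        self.etr = np.zeros(self.n_atoms)
        self.radius = np.zeros(self.n_atoms)
        self.hydrophobic = np.zeros(self.n_atoms, dtype=bool)
        for i in range(self.n_atoms):
            res3 = AA_1TO3[sequence[self.residue_index[i]]]
            t = ff.atom_type(res3, names[i], elements[i])
            self.atype[i] = t
            self.charge[i] = ff.atom_charge(res3, names[i])
            self.etr[i] = ff.atom_etr(res3, names[i], t)
            self.radius[i] = ff.r0[t]
            self.hydrophobic[i] = ff.hydrophobic[t]
        self.heavy = np.array([e != "H" for e in elements])

        # 1-2 / 1-3 exclusions
        adj = [set() for _ in range(self.n_atoms)]
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        excl = set((a, b) for a, b in self.bonds)
        for m in range(self.n_atoms):
            nb = sorted(adj[m])
            for x in nb:
                for y in nb:
                    if x < y:
                        excl.add((x, y))
        # proline ring closure: CD is covalently tied into the backbone via
        # N, and with rigid ring templates its 1-4 contacts across the
        # preceding peptide bond sit at a fixed, spuriously short distance
        # whatever the backbone state; they are excluded like backbone 1-3s
        for ri, aa in enumerate(sequence):
            if aa == "P" and ri > 0:
                cd = [i for i in range(self.n_atoms)
                      if self.residue_index[i] == ri and names[i] == "CD"]
                if cd:
                    for prev in (self.i_o[ri - 1], self.i_ca[ri - 1]):
                        pair = (min(cd[0], prev), max(cd[0], prev))
                        excl.add(pair)
        self.excluded_pairs = excl

        ii, jj = np.triu_indices(self.n_atoms, k=1)
        mask = np.array([(a, b) not in excl for a, b in zip(ii, jj)])
        self.pair_i = ii[mask]
        self.pair_j = jj[mask]

    # ------------------------------------------------------------------

    def build_batch(self, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
        """Build coordinates for a batch of dihedral assignments.

        ``phi``, ``psi``: arrays (B, L) in degrees.  phi of the first and psi
        of the last residue are geometrically inert for the backbone chain
        (psi of the last residue only orients its carbonyl O).
        Returns coordinates (B, n_atoms, 3).
        """
        phi = np.atleast_2d(np.asarray(phi, dtype=float))
        psi = np.atleast_2d(np.asarray(psi, dtype=float))
        B, L = phi.shape
        if L != len(self.sequence):
            raise BuilderError("dihedral assignment length != sequence length")
        coords = np.zeros((B, self.n_atoms, 3))

        # residue 0 backbone, identical across the batch
        n0 = np.zeros(3)
        ca0 = np.array([B_N_CA, 0.0, 0.0])
        t = np.deg2rad(180.0 - A_N_CA_C)
        c0 = ca0 + B_CA_C * np.array([np.cos(np.pi - np.deg2rad(A_N_CA_C)), np.sin(np.pi - np.deg2rad(A_N_CA_C)), 0.0])
        coords[:, self.i_n[0]] = n0
        coords[:, self.i_ca[0]] = ca0
        coords[:, self.i_c[0]] = c0

        prev_n = np.broadcast_to(n0, (B, 3)).copy()
        prev_ca = np.broadcast_to(ca0, (B, 3)).copy()
        prev_c = np.broadcast_to(c0, (B, 3)).copy()
        for ri in range(1, L):
            n_i = geom.place_atom(prev_n, prev_ca, prev_c, B_C_N, A_CA_C_N, psi[:, ri - 1])
            ca_i = geom.place_atom(prev_ca, prev_c, n_i, B_N_CA, A_C_N_CA, np.full(B, OMEGA))
            c_i = geom.place_atom(prev_c, n_i, ca_i, B_CA_C, A_N_CA_C, phi[:, ri])
            coords[:, self.i_n[ri]] = n_i
            coords[:, self.i_ca[ri]] = ca_i
            coords[:, self.i_c[ri]] = c_i
            prev_n, prev_ca, prev_c = n_i, ca_i, c_i

        # carbonyl O (anti to the next N, i.e. dihedral psi + 180) and amide H
        for ri in range(L):
            n_i = coords[:, self.i_n[ri]]
            ca_i = coords[:, self.i_ca[ri]]
            c_i = coords[:, self.i_c[ri]]
            coords[:, self.i_o[ri]] = geom.place_atom(
                n_i, ca_i, c_i, B_C_O, A_CA_C_O, psi[:, ri] + 180.0)
            if self.i_h[ri] >= 0:
                if ri == 0:
                    coords[:, self.i_h[0]] = geom.place_atom(
                        c_i, ca_i, n_i, B_N_H, 118.2, np.full(B, 180.0))
                else:
                    c_prev = coords[:, self.i_c[ri - 1]]
                    u = n_i - c_prev
                    u /= np.linalg.norm(u, axis=-1, keepdims=True)
                    v = n_i - ca_i
                    v /= np.linalg.norm(v, axis=-1, keepdims=True)
                    h_dir = u + v
                    h_dir /= np.linalg.norm(h_dir, axis=-1, keepdims=True)
                    coords[:, self.i_h[ri]] = n_i + B_N_H * h_dir

        # rigid side chains in the local backbone frame
        for ri in range(L):
            start, local = self._side[ri]
            if len(local) == 0:
                continue
            frames = _frames_batch(coords[:, self.i_n[ri]],
                                   coords[:, self.i_ca[ri]],
                                   coords[:, self.i_c[ri]])
            sc = coords[:, self.i_ca[ri]][:, None, :] + np.einsum(
                "kj,bjd->bkd", local, frames)
            coords[:, start:start + len(local)] = sc
        return coords

    def measure_dihedrals(self, coords: np.ndarray) -> np.ndarray:
        """Measured (phi, psi) per residue, NaN where undefined."""
        L = len(self.sequence)
        out = np.full((L, 2), np.nan)
        for ri in range(L):
            if ri > 0:
                out[ri, 0] = geom.dihedral(
                    coords[self.i_c[ri - 1]], coords[self.i_n[ri]],
                    coords[self.i_ca[ri]], coords[self.i_c[ri]])
            if ri < L - 1:
                out[ri, 1] = geom.dihedral(
                    coords[self.i_n[ri]], coords[self.i_ca[ri]],
                    coords[self.i_c[ri]], coords[self.i_n[ri + 1]])
        return out

    def min_nonbonded_heavy_distance(self, coords: np.ndarray) -> float:
        hi = self.heavy[self.pair_i] & self.heavy[self.pair_j]
        d = np.linalg.norm(coords[self.pair_i[hi]] - coords[self.pair_j[hi]], axis=-1)
        return float(d.min()) if len(d) else np.inf

    def batch_clash_free(self, coords: np.ndarray, floor: float = CLASH_FLOOR) -> np.ndarray:
        """Boolean per batch entry: no non-bonded heavy pair below ``floor``."""
        hi = self.heavy[self.pair_i] & self.heavy[self.pair_j]
        d2 = np.sum((coords[:, self.pair_i[hi]] - coords[:, self.pair_j[hi]]) ** 2, axis=-1)
        return ~np.any(d2 < floor * floor, axis=-1)


@dataclass
class Conformation:
    """An all-atom peptide structure tied to its sequence topology."""

    topology: PeptideTopology
    coords: np.ndarray  # (n_atoms, 3)
    state_indices: np.ndarray | None = None  # per-residue alphabet index

    @property
    def sequence(self) -> str:
        return self.topology.sequence

    @property
    def dihedrals(self) -> np.ndarray:
        return self.topology.measure_dihedrals(self.coords)

    @property
    def atoms(self) -> list[AtomRecord]:
        t = self.topology
        return [
            AtomRecord(
                name=t.atom_names[i], element=t.elements[i],
                residue_index=int(t.residue_index[i]),
                coordinates=self.coords[i],
                atomic_type=int(t.atype[i]),
                transfer_energy=float(t.etr[i]),
                partial_charge=float(t.charge[i]),
                vdw_radius=float(t.radius[i]),
                hydrophobic_flag=bool(t.hydrophobic[i]),
            )
            for i in range(t.n_atoms)
        ]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Conformation":
        c = self.coords
        if rotation is not None:
            center = c.mean(axis=0)
            c = (c - center) @ np.asarray(rotation).T + center
        if translation is not None:
            c = c + np.asarray(translation)
        return Conformation(self.topology, c, self.state_indices)


_TOPO_CACHE: dict[tuple, PeptideTopology] = {}


def get_topology(sequence: str, forcefield: ForceFieldParameters | None = None,
                 hydrogen_policy: str = "polar") -> PeptideTopology:
    key = (sequence, hydrogen_policy, id(forcefield))
    if key not in _TOPO_CACHE:
        _TOPO_CACHE[key] = PeptideTopology(sequence, forcefield, hydrogen_policy)
        if len(_TOPO_CACHE) > 256:
            _TOPO_CACHE.pop(next(iter(_TOPO_CACHE)))
    return _TOPO_CACHE[key]


def build_conformation(sequence: str, state_indices, alphabet: StructuralAlphabet,
                       hydrogen_policy: str = "polar",
                       forcefield: ForceFieldParameters | None = None) -> Conformation:
    """Build one all-atom conformation from a per-residue state assignment."""
    state_indices = np.asarray(state_indices, dtype=int)
    if len(state_indices) != len(sequence):
        raise BuilderError(
            f"{len(state_indices)} states for {len(sequence)} residues")
    if np.any(state_indices < 0) or np.any(state_indices >= alphabet.n_states):
        raise BuilderError("state index out of alphabet range")
    topo = get_topology(sequence, forcefield, hydrogen_policy)
    angles = alphabet.states[state_indices]
    coords = topo.build_batch(angles[None, :, 0], angles[None, :, 1])[0]
    return Conformation(topo, coords, state_indices)
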