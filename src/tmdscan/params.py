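"""Force-field parameter loading and atom typing.

Atoms are classified into seven atomic types (aliphatic C, aromatic C,
polar/carbonyl C, N, O, S, polar H); each type carries a van der Waals radius,
a Lennard-Jones well depth and a transfer energy per unit accessible surface
(positive for hydrophobic types).  Pairwise Lennard-Jones A/B coefficients are
built from the per-type parameters by Lorentz-Berthelot combination.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ForceFieldParameters", "load_forcefield", "PairParameters"]


class ParameterError(ValueError):
    pass


# aromatic ring carbons per residue (type 2)
_AROMATIC = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD1", "CE1", "NE2", "CD2"},
}

# sp2 carbons of polar/charged groups (type 3)
_POLAR_C = {
    "ASP": {"CG"}, "GLU": {"CD"}, "ASN": {"CG"}, "GLN": {"CD"}, "ARG": {"CZ"},
}


@dataclass
class PairParameters:
    """Pairwise Lennard-Jones coefficients and shared model constants."""

    A: np.ndarray          # (7+1, 7+1) indexed by atomic type (1-based)
    B: np.ndarray
    rsol: float            # water radius, Angstrom
    eps_low: float = 1.0
    eps_high: float = 80.0
    d_low_nm: float = 0.2
    d_high_nm: float = 1.0

    def __post_init__(self):
        if np.any(self.A[1:, 1:] <= 0) or np.any(self.B[1:, 1:] <= 0):
            raise ParameterError("Lennard-Jones A and B must be positive for all pairs")
        if not np.allclose(self.A, self.A.T) or not np.allclose(self.B, self.B.T):
            raise ParameterError("pair coefficient tables must be symmetric")


@dataclass
class ForceFieldParameters:
    """Complete parameter set loaded from the packaged (or a user) YAML file."""

    version: int
    type_names: dict[int, str]
    type_element: dict[int, str]
    r0: dict[int, float]
    eps: dict[int, float]
    etr: dict[int, float]
    hydrophobic: dict[int, bool]
    backbone_charges: dict[str, float]
    sidechain_charges: dict[str, dict[str, float]]
    backbone_charge_overrides: dict[str, dict[str, float]]
    etr_overrides: dict[str, dict[str, float]]
    rsol: float
    alip: float
    coulomb_constant: float
    dielectric: dict
    membrane: dict

    # -- atom classification -------------------------------------------------

    def atom_type(self, res3: str, atom_name: str, element: str) -> int:
        if element == "H":
            return 7
        if element == "S":
            return 6
        if element == "N":
            return 4
        if element == "O":
            return 5
        if element == "C":
            if atom_name == "C":
                return 3  # backbone carbonyl
            if atom_name in _AROMATIC.get(res3, ()) and atom_name.startswith("C"):
                return 2
            if atom_name in _POLAR_C.get(res3, ()):
                return 3
            return 1
        raise ParameterError(f"no atomic type for element {element!r} ({res3}/{atom_name})")

    def atom_charge(self, res3: str, atom_name: str) -> float:
        bb = dict(self.backbone_charges)
        bb.update(self.backbone_charge_overrides.get(res3, {}))
        if atom_name in bb:
            return bb[atom_name]
        return self.sidechain_charges.get(res3, {}).get(atom_name, 0.0)

    def atom_etr(self, res3: str, atom_name: str, atype: int) -> float:
        return self.etr_overrides.get(res3, {}).get(atom_name, self.etr[atype])

    # -- derived tables ------------------------------------------------------

    def pair_parameters(self) -> PairParameters:
        """Lennard-Jones A/B per atomic-type pair (Lorentz-Berthelot)."""
        n = 8  # 1-based typing
        A = np.ones((n, n))
        B = np.ones((n, n))
        for i in range(1, 8):
            for j in range(1, 8):
                rmin = self.r0[i] + self.r0[j]
                sigma = rmin / 2.0 ** (1.0 / 6.0)
                e = np.sqrt(self.eps[i] * self.eps[j])
                A[i, j] = 4.0 * e * sigma ** 12
                B[i, j] = 4.0 * e * sigma ** 6
        d = self.dielectric
        return PairParameters(
            A=A, B=B, rsol=self.rsol,
            eps_low=d["eps_low"], eps_high=d["eps_high"],
            d_low_nm=d["d_low_nm"], d_high_nm=d["d_high_nm"],
        )


def _default_path() -> Path:
    return Path(str(importlib.resources.files("tmdscan") / "data" / "forcefield.yaml"))


def load_forcefield(path: str | Path | None = None) -> ForceFieldParameters:
    """Load force-field parameters from ``path`` or the packaged default."""
    p = Path(path) if path is not None else _default_path()
    with open(p) as fh:
        cfg = yaml.safe_load(fh)
    types = cfg["atom_types"]
    missing = [t for t in range(1, 8) if t not in types]
    if missing:
        raise ParameterError(f"atom_types must define types 1..7; missing {missing}")
    ff = ForceFieldParameters(
        version=cfg["version"],
        type_names={t: v["name"] for t, v in types.items()},
        type_element={t: v["element"] for t, v in types.items()},
        r0={t: float(v["r0"]) for t, v in types.items()},
        eps={t: float(v["eps"]) for t, v in types.items()},
        etr={t: float(v["etr"]) for t, v in types.items()},
        hydrophobic={t: bool(v["hydrophobic"]) for t, v in types.items()},
        backbone_charges=cfg["backbone_charges"],
        sidechain_charges=cfg.get("sidechain_charges", {}),
        backbone_charge_overrides=cfg.get("backbone_charge_overrides", {}),
        etr_overrides=cfg.get("etr_overrides", {}),
        rsol=float(cfg["rsol"]),
        alip=float(cfg["alip"]),
        coulomb_constant=float(cfg["coulomb_constant"]),
        dielectric=cfg["dielectric"],
        membrane=cfg["membrane"],
    )
    for t in range(1, 8):
        if ff.r0[t] <= 0:
            raise ParameterError(f"vdw radius of type {t} must be positive")
        if ff.hydrophobic[t] != (ff.etr[t] > 0):
            raise ParameterError(
                f"type {t}: hydrophobic flag inconsistent with transfer-energy sign"
            )
    return ff
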