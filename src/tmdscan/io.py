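"""File formats and run manifests.

FASTA input goes through Biopython; model ensembles are written as
multi-MODEL PDB 3.3 files with energies in REMARK records; per-residue
profiles and per-z insertion profiles are tab-separated tables with a header
line and "." for missing values.  Every command-line run also writes a
manifest (JSON) capturing the configuration, per-window seeds and input
checksums needed to reproduce the outputs bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .builder import AA_1TO3, AA_3TO1, Conformation, get_topology

__all__ = ["read_fasta", "write_models_pdb", "read_models_pdb",
           "write_profile_tsv", "write_insertion_tsv", "RunManifest"]


class IoError(ValueError):
    pass


def read_fasta(path: str | Path, allow_gaps: bool = False) -> dict[str, str]:
    """Named sequences from a FASTA file.

    Sequences are upper-cased; letters outside the 20 standard residues are
    rejected with their position.  Alignment gaps ("-") are only permitted
    with ``allow_gaps`` (consensus mode).
    """
    from Bio import SeqIO

    path = Path(path)
    out: dict[str, str] = {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise IoError(f"{path}: no FASTA records found")
    for rec in records:
        if rec.id in out:
            raise IoError(f"{path}: duplicate identifier {rec.id!r}")
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch == "-":
                if not allow_gaps:
                    raise IoError(
                        f"{path}: record {rec.id!r} has an alignment gap at "
                        f"position {pos}; gapped input is only valid in "
                        "consensus mode")
                continue
            if ch not in AA_1TO3:
                raise IoError(
                    f"{path}: record {rec.id!r} has illegal residue {ch!r} "
                    f"at position {pos}")
        out[rec.id] = seq
    return out


def _pdb_atom_line(serial: int, name: str, res3: str, res_id: int,
                   xyz: np.ndarray, element: str) -> str:
    atom_name = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {atom_name:<4s}{'':1s}{res3:>3s} A"
            f"{res_id:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


def write_models_pdb(model_set, path: str | Path) -> None:
    """Write a model ensemble as a multi-MODEL PDB file (chain A, 1-based
    residue numbering), with per-model energies in REMARK 250 records."""
    path = Path(path)
    lines = []
    for m_idx, conf in enumerate(model_set.models, start=1):
        lines.append(f"MODEL     {m_idx:4d}")
        if model_set.energies is not None and m_idx <= len(model_set.energies):
            lines.append(
                f"REMARK 250 TOTAL ENERGY {model_set.energies[m_idx - 1]:.4f} KJ/MOL")
        topo = conf.topology
        serial = 0
        for i in range(topo.n_atoms):
            serial += 1
            res3 = AA_1TO3[conf.sequence[topo.residue_index[i]]]
            lines.append(_pdb_atom_line(
                serial, topo.atom_names[i], res3,
                int(topo.residue_index[i]) + 1, conf.coords[i],
                topo.elements[i]))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_models_pdb(path: str | Path) -> list[Conformation]:
    """Read a (multi-)MODEL PDB written by this package back into
    conformations; atoms are matched to the sequence topology by residue
    index and atom name."""
    path = Path(path)
    models_raw: list[list[tuple]] = []
    current: list[tuple] | None = None
    saw_model_record = False
    for line in path.read_text().splitlines():
        if line.startswith("MODEL"):
            saw_model_record = True
            current = []
        elif line.startswith("ENDMDL"):
            if current:
                models_raw.append(current)
            current = None
        elif line.startswith(("ATOM  ", "HETATM")):
            if current is None:
                if saw_model_record:
                    continue
                current = []
            name = line[12:16].strip()
            res3 = line[17:20].strip()
            res_id = int(line[22:26])
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            current.append((name, res3, res_id, xyz))
    if current:
        models_raw.append(current)
    if not models_raw:
        raise IoError(f"{path}: no ATOM records found")

    out = []
    for atoms in models_raw:
        res_ids = sorted({a[2] for a in atoms})
        seq = []
        for rid in res_ids:
            res3 = next(a[1] for a in atoms if a[2] == rid)
            if res3 not in AA_3TO1:
                raise IoError(f"{path}: non-standard residue {res3!r}")
            seq.append(AA_3TO1[res3])
        sequence = "".join(seq)
        policy = "polar" if any(a[0] == "H" for a in atoms) else "none"
        topo = get_topology(sequence, hydrogen_policy=policy)
        coords = np.full((topo.n_atoms, 3), np.nan)
        lookup = {(topo.residue_index[i], topo.atom_names[i]): i
                  for i in range(topo.n_atoms)}
        for name, _res3, rid, xyz in atoms:
            key = (res_ids.index(rid), name)
            if key in lookup:
                coords[lookup[key]] = xyz
        if np.isnan(coords).any():
            missing = [topo.atom_names[i] for i in range(topo.n_atoms)
                       if np.isnan(coords[i]).any()]
            raise IoError(f"{path}: missing atoms {missing[:5]}...")
        out.append(Conformation(topo, coords, None))
    return out


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "."
    if isinstance(x, float):
        return f"{x:.4f}"
    return str(x)


def write_profile_tsv(profile, path: str | Path) -> None:
    """Per-residue profile table (see ResidueProfile.to_dataframe for the
    column meaning)."""
    df = profile.to_dataframe()
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row.to_list()) + "\n")


def write_insertion_tsv(result, path: str | Path) -> None:
    """Per-z insertion energy profile of one structure."""
    with open(path, "w") as fh:
        fh.write("z_A\tbest_energy_kJmol\n")
        for z, e in zip(result.z_grid, result.profile):
            fh.write(f"{z:.2f}\t{_fmt(float(e))}\n")


@dataclass
class RunManifest:
    """Everything needed to re-run a command bit-identically."""

    command: str
    config: dict
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    package_version: str = ""
    started: str = ""
    elapsed_seconds: float = 0.0

    @classmethod
    def start(cls, command: str, config: dict, input_paths=()) -> "RunManifest":
        from . import __version__

        checksums = {}
        for p in input_paths:
            h = hashlib.sha256(Path(p).read_bytes()).hexdigest()
            checksums[str(p)] = h
        m = cls(command=command, config=config, inputs=checksums,
                package_version=__version__,
                started=time.strftime("%Y-%m-%dT%H:%M:%S"))
        m._t0 = time.time()
        return m

    def finish(self, path: str | Path, seeds: dict | None = None) -> None:
        if seeds:
            self.seeds = {str(k): int(v) for k, v in seeds.items()}
        self.elapsed_seconds = round(time.time() - getattr(self, "_t0", time.time()), 3)
        payload = {k: v for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
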