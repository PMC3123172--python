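"""Deterministic synthetic fixtures for building, testing and examples.

The flagship fixture is ``synthetic_tmd``: a single-spanning membrane-protein
fragment with a 19-residue hydrophobic core (Leu/Ile/Val/Phe/Ala) flanked by
charged/polar juxta-membrane tails — acidic residues on the extracellular
(N-terminal) side, Lys/Arg on the cytosolic (C-terminal) side, following the
sidedness statistics of natural transmembrane domains.  Coordinate fixtures
are built through the regular conformation builder so they share the
package's geometry conventions.
"""
from __future__ import annotations

import numpy as np

from .alphabet import load_alphabet
from .builder import Conformation, build_conformation

__all__ = ["generate_fixture", "mfp_reference_set", "CORE_LENGTH"]

CORE_LENGTH = 19

KINDS = ("synthetic_tmd", "poly_leu_helix", "poly_lys_helix",
         "ideal_alpha_coords", "extended_coords", "two_bundle_modelset")


class FixtureError(ValueError):
    pass


def _helix_conformation(sequence: str) -> Conformation:
    alpha = load_alphabet()
    s = alpha.nearest_state(-57.0, -47.0)
    return build_conformation(sequence, [s] * len(sequence), alpha)


def _extended_conformation(sequence: str) -> Conformation:
    alpha = load_alphabet()
    s = alpha.nearest_state(-129.0, 123.0)
    return build_conformation(sequence, [s] * len(sequence), alpha)


def synthetic_tmd_sequence(length: int = 29, seed: int = 0) -> str:
    """Hydrophobic-core test sequence with charged flanks.

    ``length`` = core (19) + two flanks; flanks carry at least two charged
    residues each (Asp/Glu extracellular, Lys/Arg cytosolic).
    """
    if length < CORE_LENGTH + 4:
        raise FixtureError(
            f"length must be >= {CORE_LENGTH + 4} (19-residue core + 2-residue flanks)")
    n_flank = (length - CORE_LENGTH) // 2
    c_flank = length - CORE_LENGTH - n_flank
    rng = np.random.default_rng(seed)
    # The core reproduces the canonical mid-membrane hydrophobicity maximum
    # of single-span TMDs: bulky hydrophobics (Phe/Leu) central, beta-branched
    # (Ile/Val) next, small residues (Ala) at the core edges.  The multiset is
    # fixed; the seed decides which mirror position of each center-distance
    # shell receives which letter.  This grading makes the constructed core
    # midpoint the maximum of the residue-hydrophobicity profile, which is
    # what the parameter-recovery contract of the fixture requires.
    core_letters = list("FFFLLLLLLIIIIVVVVAA")  # sorted center-first
    slots = sorted(range(CORE_LENGTH), key=lambda p: (abs(p - CORE_LENGTH // 2),
                                                      rng.random()))
    core_arr = [""] * CORE_LENGTH
    for letter, pos in zip(core_letters, slots):
        core_arr[pos] = letter
    core = "".join(core_arr)
    n_tail = ["D", "E"] + list(rng.choice(list("DESN"), size=n_flank - 2))
    c_tail = list(rng.choice(list("KRST"), size=c_flank - 2)) + ["K", "R"]
    rng.shuffle(n_tail)
    rng.shuffle(c_tail)
    return "".join(n_tail) + core + "".join(c_tail)


def synthetic_tmd_core_midpoint(length: int = 29) -> int:
    """0-based index of the hydrophobic-core midpoint of the fixture."""
    n_flank = (length - CORE_LENGTH) // 2
    return n_flank + CORE_LENGTH // 2


def mfp_reference_set() -> list[Conformation]:
    """Host-guest reference structures: every residue type as the guest at
    the center of a poly-alanine 9-mer, in helical and extended backbones.

    Proline contributes only the extended variant: its ring is sterically
    incompatible with an interior helix position, and a clashing reference
    would poison the calibration means.
    """
    out = []
    for aa in "ACDEFGHIKLMNPQRSTVWY":
        seq = "AAAA" + aa + "AAAA"
        if aa != "P":
            out.append(_helix_conformation(seq))
        out.append(_extended_conformation(seq))
    return out


def generate_fixture(kind: str, length: int = 29, seed: int = 0):
    """Dispatch for the named fixtures.

    Returns a sequence string for ``synthetic_tmd``, a :class:`Conformation`
    for the coordinate fixtures, and a :class:`tmdscan.sampler.ModelSet` for
    ``two_bundle_modelset``.
    """
    if kind == "synthetic_tmd":
        return synthetic_tmd_sequence(length, seed)
    if kind == "poly_leu_helix":
        return _helix_conformation("L" * length)
    if kind == "poly_lys_helix":
        return _helix_conformation("K" * length)
    if kind == "ideal_alpha_coords":
        return _helix_conformation("A" * length)
    if kind == "extended_coords":
        return _extended_conformation("A" * length)
    if kind == "two_bundle_modelset":
        return _two_bundle_modelset(length, seed)
    raise FixtureError(f"unknown fixture kind {kind!r}; expected one of {KINDS}")


def _two_bundle_modelset(length: int, seed: int, n_per_bundle: int = 10):
    """Two tight coordinate bundles (jittered helix and extended backbones)
    far apart in RMSD — a clustering fixture."""
    from .sampler import ModelSet

    seq = "A" * max(length, 5)
    rng = np.random.default_rng(seed)
    models = []
    for base in (_helix_conformation(seq), _extended_conformation(seq)):
        for _ in range(n_per_bundle):
            jitter = rng.normal(0.0, 0.02, size=base.coords.shape)
            models.append(Conformation(base.topology, base.coords + jitter,
                                       base.state_indices))
    return ModelSet(sequence=seq, environment="hydrophobic", models=models,
                    energies=np.arange(len(models), dtype=float))
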