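"""The 64-state backbone structural alphabet.

Each state is a (phi, psi) couple in degrees; a peptide conformation is a
string of state indices, one per residue.  The sampler carries one probability
vector over the 64 states per sequence position, initialized uniform and
modulated during the stochastic search.

The packaged state table is derived by k-means clustering of backbone
dihedrals drawn from a synthetic Ramachandran basin mixture (alpha, beta,
polyproline-II, 3-10 and left-handed alpha basins plus a diffuse background),
with the canonical basin centers included as anchor states.  It is a
documented, user-replaceable stand-in for a table clustered from a
nonredundant structure set; :func:`derive_alphabet` reproduces it.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StructuralAlphabet",
    "load_alphabet",
    "derive_alphabet",
    "ramachandran_samples",
    "ALPHA_CENTER",
    "BETA_CENTER",
]

N_STATES = 64
ALPHA_CENTER = (-57.0, -47.0)
BETA_CENTER = (-129.0, 123.0)

#: canonical basin centers always present as states (phi, psi)
_ANCHORS = np.array(
    [
        [-57.0, -47.0],   # alpha helix
        [-49.0, -26.0],   # 3-10 helix
        [-129.0, 123.0],  # beta strand
        [-75.0, 145.0],   # polyproline II
        [57.0, 47.0],     # left-handed alpha
        [-180.0, 180.0],  # fully extended
    ]
)


class AlphabetError(ValueError):
    """Raised for malformed state tables or invalid probability vectors."""


@dataclass
class StructuralAlphabet:
    """64 (phi, psi) states plus per-position sampling probabilities.

    ``probabilities`` has shape ``(n_positions, n_states)``; every row sums
    to 1 and no entry is exactly zero (a floor is enforced by the sampler's
    update rule to preserve ergodicity).
    """

    states: np.ndarray  # (n_states, 2) degrees
    probabilities: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[1] != 2:
            raise AlphabetError("state table must be an (n, 2) array of (phi, psi)")
        if not (np.all(self.states > -180.0 - 1e-9) and np.all(self.states <= 180.0 + 1e-9)):
            raise AlphabetError("all angles must lie in (-180, 180]")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def with_uniform_probabilities(self, n_positions: int) -> "StructuralAlphabet":
        p = np.full((n_positions, self.n_states), 1.0 / self.n_states)
        return StructuralAlphabet(self.states.copy(), p)

    def validate_probabilities(self, atol: float = 1e-9) -> None:
        p = self.probabilities
        if p is None:
            raise AlphabetError("no probabilities attached")
        if p.shape[1] != self.n_states:
            raise AlphabetError("probability vector length != number of states")
        if np.any(p <= 0.0):
            raise AlphabetError("probabilities must be strictly positive")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > atol):
            raise AlphabetError("per-position probabilities must sum to 1")

    def nearest_state(self, phi: float, psi: float) -> int:
        """Index of the state closest to (phi, psi) in wrapped angle space."""
        d = self.states - np.array([phi, psi])
        d = (d + 180.0) % 360.0 - 180.0
        return int(np.argmin(np.sum(d * d, axis=1)))


def _default_table_path() -> Path:
    return Path(str(importlib.resources.files("tmdscan") / "data" / "alphabet64.tsv"))


def load_alphabet(parameter_source: str | Path | None = None,
                  n_expected: int = N_STATES) -> StructuralAlphabet:
    """Load the state table (TSV: index, phi, psi) from ``parameter_source``
    or from the packaged default; initial probabilities are uniform per state.

    Raises :class:`AlphabetError` naming missing entries when the table does
    not provide exactly ``n_expected`` states.
    """
    path = Path(parameter_source) if parameter_source is not None else _default_table_path()
    rows = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise AlphabetError(f"malformed state line: {line!r}")
            idx, phi, psi = int(parts[0]), float(parts[1]), float(parts[2])
            rows[idx] = (phi, psi)
    missing = [i for i in range(n_expected) if i not in rows]
    if missing:
        raise AlphabetError(
            f"state table {path} must define {n_expected} states; missing indices {missing}"
        )
    states = np.array([rows[i] for i in range(n_expected)])
    return StructuralAlphabet(states)


def ramachandran_samples(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw (phi, psi) pairs from a synthetic Ramachandran basin mixture.

    Basin weights approximate the secondary-structure composition of globular
    proteins (~35% alpha, ~25% beta, ~15% PPII, ~8% 3-10/bridge, ~5%
    left-alpha, ~12% diffuse coil).  A synthetic stand-in for dihedrals
    harvested from a nonredundant structure set.
    """
    basins = [
        # (weight, center_phi, center_psi, sd_phi, sd_psi)
        (0.35, -63.0, -43.0, 12.0, 12.0),
        (0.25, -120.0, 130.0, 25.0, 25.0),
        (0.15, -75.0, 150.0, 15.0, 15.0),
        (0.08, -60.0, -25.0, 12.0, 12.0),
        (0.05, 57.0, 47.0, 12.0, 12.0),
    ]
    w = np.array([b[0] for b in basins])
    w_bg = 1.0 - w.sum()
    choice = rng.choice(len(basins) + 1, size=n, p=np.append(w, w_bg))
    out = np.empty((n, 2))
    for k, (_, cp, cs, sp, ss) in enumerate(basins):
        m = choice == k
        out[m, 0] = rng.normal(cp, sp, m.sum())
        out[m, 1] = rng.normal(cs, ss, m.sum())
    m = choice == len(basins)
    out[m] = rng.uniform(-180.0, 180.0, size=(m.sum(), 2))
    out = (out + 180.0) % 360.0 - 180.0
    out[out == -180.0] = 180.0
    return out


def derive_alphabet(samples: np.ndarray | None = None,
                    k: int = N_STATES,
                    seed: int = 0) -> StructuralAlphabet:
    """Re-derive the alphabet by k-means on (phi, psi) samples.

    The canonical basin anchors replace their nearest centroids so that ideal
    helix and strand geometry is exactly representable.
    """
    from sklearn.cluster import KMeans

    if samples is None:
        samples = ramachandran_samples(20000, np.random.default_rng(seed))
    km = KMeans(n_clusters=k - len(_ANCHORS), n_init=4, random_state=seed)
    km.fit(samples)
    centers = km.cluster_centers_
    states = np.vstack([_ANCHORS, centers])
    states = (states + 180.0) % 360.0 - 180.0
    states[states == -180.0] = 180.0
    # stable ordering: by phi then psi
    order = np.lexsort((states[:, 1], states[:, 0]))
    return StructuralAlphabet(states[order])
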