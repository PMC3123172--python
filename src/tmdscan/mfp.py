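"""Mean-force-potential percentage: per-residue environment quality.

A residue's environment score sums the package's non-bonded pair terms
(Lennard-Jones + intramolecular hydrophobicity) between the residue's atoms
and all atoms of other residues within a cutoff; the more negative the score,
the more completely the residue is enveloped by stabilizing contacts.  Scores
are normalized per residue type against a calibration of mean scores over a
reference structure set and reported as a percentage: residues near 100%
sit in an environment as complete as the calibration average; low
percentages (< 40% by the usual reading) mark residues whose stabilization
must come from elsewhere — secondary-structure partners, lipids or another
chain.

The packaged default calibration uses synthetic host-guest helix and
extended fixtures built by this package (one guest per residue type inside
poly-alanine hosts).  It preserves the semantics of a
reference-set-calibrated potential but is not derived from any published
structure collection; calibrate on your own structures via
:func:`calibrate_mfp` for production use.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import Conformation, AA_1TO3
from .forcefield import NonbondedModel

__all__ = ["MfpCalibration", "residue_environment_score", "calibrate_mfp",
           "mfp_percentage", "default_calibration", "ENVIRONMENT_CUTOFF"]

ENVIRONMENT_CUTOFF = 10.0  # A

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


class MfpError(ValueError):
    pass


@dataclass
class MfpCalibration:
    """Per-residue-type mean environment score with provenance."""

    mean_score: dict[str, float]
    dispersion: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [a for a in AA_ORDER if a not in self.mean_score]
        if missing:
            raise MfpError(f"calibration lacks residue types {missing}")
        bad = [a for a, m in self.mean_score.items()
               if not np.isfinite(m) or m == 0.0]
        if bad:
            raise MfpError(f"calibration means must be finite and nonzero; bad: {bad}")


def _environment_scores(conformation: Conformation,
                        cutoff: float = ENVIRONMENT_CUTOFF) -> np.ndarray:
    """Environment score of every residue in one pass."""
    from .forcefield import _model_for

    topo = conformation.topology
    model = _model_for(conformation)
    d = model._distances(conformation.coords)
    lj = np.maximum(d, 1e-6)
    inv6 = 1.0 / lj ** 6
    e_pair = model.A * inv6 * inv6 - model.B * inv6
    from .forcefield import _two_sphere_coverage
    fij = _two_sphere_coverage(d, model.Ri, model.Rj)
    fji = _two_sphere_coverage(d, model.Rj, model.Ri)
    decay = np.exp(-np.clip(d - model.rsum, 0.0, None) / (2.0 * model.rsol))
    e_pair = e_pair + model.delta * model.etr_geom * 0.5 * (fij + fji) * decay
    ri = topo.residue_index[topo.pair_i]
    rj = topo.residue_index[topo.pair_j]
    keep = (ri != rj) & (d < cutoff)
    L = len(topo.sequence)
    scores = np.zeros(L)
    np.add.at(scores, ri[keep], e_pair[keep])
    np.add.at(scores, rj[keep], e_pair[keep])
    return scores


def residue_environment_score(conformation: Conformation, residue_index: int,
                              cutoff: float = ENVIRONMENT_CUTOFF) -> float:
    """Non-bonded interaction of one residue with the rest of the structure.

    ``residue_index`` is 0-based.  More negative = more enveloped.
    """
    L = len(conformation.sequence)
    if not (0 <= residue_index < L):
        raise MfpError(f"residue index {residue_index} out of range 0..{L - 1}")
    return float(_environment_scores(conformation, cutoff)[residue_index])


def calibrate_mfp(reference_structures: list[Conformation],
                  cutoff: float = ENVIRONMENT_CUTOFF,
                  provenance: dict | None = None) -> MfpCalibration:
    """Per-residue-type mean environment score over a reference set."""
    per_type: dict[str, list[float]] = {a: [] for a in AA_ORDER}
    for conf in reference_structures:
        scores = _environment_scores(conf, cutoff)
        for aa, s in zip(conf.sequence, scores):
            per_type[aa].append(float(s))
    missing = [a for a in AA_ORDER if not per_type[a]]
    if missing:
        raise MfpError(
            f"reference set lacks occurrences of residue type(s) {missing}")
    means = {a: float(np.mean(v)) for a, v in per_type.items()}
    disp = {a: float(np.std(v)) for a, v in per_type.items()}
    return MfpCalibration(
        mean_score=means, dispersion=disp,
        provenance=provenance or {"source": "user-supplied reference structures",
                                  "n_structures": len(reference_structures),
                                  "cutoff_A": cutoff},
    )


def mfp_percentage(conformation: Conformation, calibration: MfpCalibration,
                   cutoff: float = ENVIRONMENT_CUTOFF,
                   clip: tuple | None = None) -> np.ndarray:
    """Per-residue score as a percentage of the type's calibrated mean.

    Raw percentages are returned by default, which keeps the calibration
    self-consistency exact (scoring the calibration set averages to 100% per
    type).  Reporting layers may pass ``clip=(0, 200)`` to bound outliers in
    displayed profiles.
    """
    scores = _environment_scores(conformation, cutoff)
    means = np.array([calibration.mean_score[a] for a in conformation.sequence])
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * scores / means
    if clip is not None:
        pct = np.clip(pct, clip[0], clip[1])
    return pct


_DEFAULT_CALIBRATION: MfpCalibration | None = None


def default_calibration() -> MfpCalibration:
    """Calibration on the packaged synthetic host-guest fixture set
    (computed once per process)."""
    global _DEFAULT_CALIBRATION
    if _DEFAULT_CALIBRATION is None:
        from .fixtures import mfp_reference_set
        _DEFAULT_CALIBRATION = calibrate_mfp(
            mfp_reference_set(),
            provenance={"source": "packaged synthetic host-guest helix/extended fixtures",
                        "note": "not a published reference set",
                        "cutoff_A": ENVIRONMENT_CUTOFF},
        )
    return _DEFAULT_CALIBRATION
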