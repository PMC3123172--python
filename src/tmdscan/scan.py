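"""Sliding-window TMD delimitation.

The target sequence is scanned with a 19-residue window at shift 1.  Each
window peptide is modelled independently by the stochastic search (99 best
models, hydrophobic environment), each model is described (secondary
structure, hydrophobic/hydrophilic surface ratio ASAr, mean-force-potential
percentage) and inserted rigidly into the implicit bilayer.  Per-residue
statistics are then pooled over all models of all windows covering the
residue, excluding the 4 positions at each window extremity (their geometry
is dominated by chain-end artifacts), so an interior residue of a long
target is supported by 11 windows x 99 models = 1089 structures.

The TMD center is called at the maximum of the smoothed ASAr profile, the
declared primary criterion; the insertion-depth minimum corroborates it and
arbitrates double maxima, and the helicity of the 18-residue span around the
center must reach 75% for an unflagged call.  TMD limits are the maximal
contiguous helical run (>= 75%) around the center, capped at a 26-residue
span for geometric consistency with a <= 30 degree tilt.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import StructuralAlphabet, load_alphabet
from .builder import Conformation
from .descriptors import pex_assign, shrake_rupley_asa
from .membrane import InsertionResult, MembraneModel, insertion_scan
from .mfp import MfpCalibration, default_calibration, mfp_percentage
from .sampler import PRESETS, ModelSet, SamplerConfig, run_peplook

__all__ = [
    "ScanConfig", "ResidueProfile", "TmdCall", "WindowStats", "ScanResult",
    "generate_windows", "compute_window_stats", "aggregate_profiles",
    "call_tmd_center", "call_tmd_limits", "multispecies_consensus", "run_scan",
]


class ScanError(ValueError):
    pass


@dataclass
class ScanConfig:
    """Scan geometry, statistics and per-window search settings."""

    window_length: int = 19
    shift: int = 1
    end_exclusion: int = 4
    asar_smoothing_window: int = 5
    insertion_smoothing_window: int = 7
    helicity_threshold: float = 75.0  # percent
    span_cap: int = 26  # residues, limit-call cap
    min_span: int = 15
    environment: str = "hydrophobic"
    sampler_preset: str = "desk"
    master_seed: int = 0
    # membrane-insertion scan settings (desk defaults; the full preset uses
    # 10000 random orientations and a 0.1 A z step)
    orientation_mode: str = "grid"
    orientation_trials: int = 42
    z_step: float = 0.5
    z_scan_range: float = 10.0

    def __post_init__(self):
        if self.window_length % 2 == 0 or self.window_length < 2 * self.end_exclusion + 1:
            raise ScanError("window_length must be odd and >= 2*end_exclusion + 1")
        for w in (self.asar_smoothing_window, self.insertion_smoothing_window):
            if w % 2 == 0:
                raise ScanError("smoothing windows must be odd")

    def window_seed(self, window_index: int) -> int:
        ss = np.random.SeedSequence([self.master_seed, window_index])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def sampler_config(self, seed: int) -> SamplerConfig:
        return SamplerConfig(rng_seed=seed, environment=self.environment,
                             **PRESETS[self.sampler_preset])

    def membrane_model(self) -> MembraneModel:
        return MembraneModel(z_scan_range=self.z_scan_range, z_step=self.z_step,
                             orientation_trials=self.orientation_trials)


@dataclass
class WindowStats:
    """Per-model descriptor statistics of one scanned window."""

    offset: int  # 0-based start in the target sequence
    sequence: str
    helical: np.ndarray  # (n_models, L) bool
    asar: np.ndarray  # (n_models, L)
    mfp_pct: np.ndarray  # (n_models, L)
    best_z: np.ndarray  # (n_models,) per-model best insertion depth (A)
    mean_best_z: float = field(init=False)

    def __post_init__(self):
        self.mean_best_z = float(np.mean(self.best_z)) if len(self.best_z) else np.nan

    @property
    def n_models(self) -> int:
        return len(self.asar)


@dataclass
class ResidueProfile:
    """Per-residue aggregated statistics over all covering windows."""

    sequence: str
    n_covering_structures: np.ndarray  # (L,) int
    helicity_pct: np.ndarray  # (L,)
    asar_raw: np.ndarray
    asar_smooth: np.ndarray
    z_raw: np.ndarray  # window-center insertion depth (NaN off-center)
    z_smooth: np.ndarray
    mfp_pct: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "pos": np.arange(1, len(self.sequence) + 1),
            "aa": list(self.sequence),
            "n_structs": self.n_covering_structures,
            "helicity_pct": self.helicity_pct,
            "asar_raw": self.asar_raw,
            "asar_smooth5": self.asar_smooth,
            "z_mean": self.z_raw,
            "z_smooth": self.z_smooth,
            "mfp_pct": self.mfp_pct,
        })


@dataclass
class TmdCall:
    """Called TMD center and limits with the criteria trace (1-based)."""

    center_residues: tuple  # one or two adjacent 1-based indices
    limits: tuple | None  # (first, last) 1-based inclusive
    asar_argmax: int | None
    insertion_argmin: int | None
    helicity_ok: bool
    flags: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_call(self) -> bool:
        return bool(self.center_residues)


def generate_windows(sequence: str, scan_config: ScanConfig | None = None):
    """All contiguous windows at the configured shift: (offset, subsequence)."""
    cfg = scan_config if scan_config is not None else ScanConfig()
    L = cfg.window_length
    if len(sequence) < L:
        raise ScanError(
            f"sequence of {len(sequence)} residues is shorter than the "
            f"{L}-residue window; model it directly as a single peptide")
    return [(o, sequence[o:o + L]) for o in range(0, len(sequence) - L + 1, cfg.shift)]


def compute_window_stats(offset: int, model_set: ModelSet,
                         insertions: list[InsertionResult] | np.ndarray,
                         calibration: MfpCalibration | None = None) -> WindowStats:
    """Descriptor statistics for every archived model of one window."""
    calib = calibration if calibration is not None else default_calibration()
    L = len(model_set.sequence)
    n = len(model_set.models)
    helical = np.zeros((n, L), dtype=bool)
    asar = np.zeros((n, L))
    mfp = np.zeros((n, L))
    for k, conf in enumerate(model_set.models):
        labels = pex_assign(conf)
        helical[k] = [l in ("alpha_helix", "three_ten_helix") for l in labels]
        asar[k] = shrake_rupley_asa(conf).asar
        mfp[k] = mfp_percentage(conf, calib, clip=(0.0, 200.0))
    if len(insertions) and isinstance(insertions[0], InsertionResult):
        best_z = np.array([r.best_z for r in insertions])
    else:
        best_z = np.asarray(insertions, dtype=float)
    if len(best_z) != n:
        raise ScanError(f"{len(best_z)} insertion results for {n} models")
    return WindowStats(offset=offset, sequence=model_set.sequence,
                       helical=helical, asar=asar, mfp_pct=mfp, best_z=best_z)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware centered moving average with shrinking edges."""
    half = window // 2
    out = np.full_like(x, np.nan, dtype=float)
    for i in range(len(x)):
        seg = x[max(0, i - half): i + half + 1]
        if np.any(np.isfinite(seg)):
            out[i] = np.nanmean(seg)
    return out


def aggregate_profiles(window_stats: list[WindowStats],
                       scan_config: ScanConfig | None = None,
                       sequence: str | None = None) -> ResidueProfile:
    """Pool per-model statistics over covering windows into a per-residue
    profile of the full target sequence."""
    cfg = scan_config if scan_config is not None else ScanConfig()
    if not window_stats:
        raise ScanError("no window statistics to aggregate")
    stats = sorted(window_stats, key=lambda w: w.offset)
    L_win = len(stats[0].sequence)
    n_res = (sequence and len(sequence)) or stats[-1].offset + L_win
    if sequence is None:
        seq_chars = [None] * n_res
        for w in stats:
            for p, aa in enumerate(w.sequence):
                seq_chars[w.offset + p] = aa
        sequence = "".join(c or "X" for c in seq_chars)

    expected = {o for o in range(0, n_res - L_win + 1, cfg.shift)}
    got = {w.offset for w in stats}
    missing = sorted(expected - got)
    if missing:
        raise ScanError(f"missing windows at offsets {missing}")

    excl = cfg.end_exclusion
    counts = np.zeros(n_res, dtype=int)
    helix_sum = np.zeros(n_res)
    asar_sum = np.zeros(n_res)
    mfp_sum = np.zeros(n_res)
    z_center = np.full(n_res, np.nan)
    for w in stats:
        pos = np.arange(excl, L_win - excl)
        absolute = w.offset + pos
        counts[absolute] += w.n_models
        helix_sum[absolute] += w.helical[:, pos].sum(axis=0)
        asar_sum[absolute] += w.asar[:, pos].sum(axis=0)
        mfp_sum[absolute] += w.mfp_pct[:, pos].sum(axis=0)
        z_center[w.offset + L_win // 2] = w.mean_best_z

    with np.errstate(invalid="ignore", divide="ignore"):
        helicity = np.where(counts > 0, 100.0 * helix_sum / counts, np.nan)
        asar_raw = np.where(counts > 0, asar_sum / counts, np.nan)
        mfp_pct = np.where(counts > 0, mfp_sum / counts, np.nan)
    return ResidueProfile(
        sequence=sequence,
        n_covering_structures=counts,
        helicity_pct=helicity,
        asar_raw=asar_raw,
        asar_smooth=_moving_average(asar_raw, cfg.asar_smoothing_window),
        z_raw=z_center,
        z_smooth=_moving_average(z_center, cfg.insertion_smoothing_window),
        mfp_pct=mfp_pct,
    )


def _local_maxima(x: np.ndarray) -> list[int]:
    idx = []
    for i in range(len(x)):
        if not np.isfinite(x[i]):
            continue
        left = x[i - 1] if i > 0 and np.isfinite(x[i - 1]) else -np.inf
        right = x[i + 1] if i < len(x) - 1 and np.isfinite(x[i + 1]) else -np.inf
        if x[i] >= left and x[i] >= right:
            idx.append(i)
    return idx


def call_tmd_center(profile: ResidueProfile,
                    scan_config: ScanConfig | None = None) -> TmdCall:
    """Call the TMD central residue(s) from an aggregated profile."""
    cfg = scan_config if scan_config is not None else ScanConfig()
    asar = profile.asar_smooth
    finite = np.isfinite(asar)
    if not finite.any() or np.nanmax(asar) - np.nanmin(asar) < 1e-9:
        return TmdCall((), None, None, None, False, flags=["no_call_flat_profile"],
                       diagnostics={"reason": "ASAr profile absent or flat"})

    flags: list[str] = []
    center = int(np.nanargmax(asar))
    # deepest mean insertion = smallest |z| (window whose best placement sits
    # closest to the bilayer center)
    z = np.abs(profile.z_smooth)
    z_argmin = int(np.nanargmin(z)) if np.isfinite(z).any() else None

    # double maximum: a second local maximum within 5% of the best
    maxima = sorted(_local_maxima(asar), key=lambda i: -asar[i])
    if len(maxima) >= 2:
        best, second = maxima[0], maxima[1]
        if abs(second - best) > 1 and asar[second] >= 0.95 * asar[best]:
            flags.append("double_maximum")
            if z_argmin is not None:
                # the insertion criterion arbitrates
                center = min((best, second), key=lambda i: abs(i - z_argmin))

    centers = (center + 1,)
    if z_argmin is not None:
        if abs(z_argmin - center) == 1:
            centers = tuple(sorted((center + 1, z_argmin + 1)))
        elif abs(z_argmin - center) > 1:
            flags.append("insertion_discordant")

    # helicity of the 18-residue span centered on the call
    lo = max(0, center - 9)
    hi = min(len(asar), center + 9)
    span_hel = profile.helicity_pct[lo:hi]
    hel_ok = bool(np.isfinite(span_hel).any()
                  and np.nanmean(span_hel) >= cfg.helicity_threshold)
    if not hel_ok:
        flags.append("helicity_below_threshold")

    return TmdCall(
        center_residues=centers,
        limits=None,
        asar_argmax=center + 1,
        insertion_argmin=None if z_argmin is None else z_argmin + 1,
        helicity_ok=hel_ok,
        flags=flags,
        diagnostics={
            "asar_max": float(asar[center]),
            "span_helicity_pct": float(np.nanmean(span_hel)) if np.isfinite(span_hel).any() else np.nan,
        },
    )


def call_tmd_limits(profile: ResidueProfile, call: TmdCall,
                    scan_config: ScanConfig | None = None) -> tuple:
    """Delimit the TMD as the maximal helical run around the called center,
    capped to the configured span."""
    cfg = scan_config if scan_config is not None else ScanConfig()
    if not call.is_call:
        raise ScanError("cannot delimit without a called center")
    center0 = call.center_residues[0] - 1
    hel = profile.helicity_pct
    n = len(hel)
    ok = np.isfinite(hel) & (hel >= cfg.helicity_threshold)

    lo = hi = center0
    if ok[center0]:
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        while hi < n - 1 and ok[hi + 1]:
            hi += 1
    span = hi - lo + 1
    if span > cfg.span_cap:
        # trim symmetrically around the center
        over = span - cfg.span_cap
        cut_lo = min(over // 2 + over % 2, center0 - lo)
        lo += cut_lo
        hi -= (over - cut_lo)
        call.flags.append("span_capped")
    if span < cfg.min_span:
        call.flags.append("short_tmd")
    if lo == 0 or hi == n - 1:
        call.flags.append("clipped_to_sequence_bounds")
    call.limits = (lo + 1, hi + 1)
    return call.limits


def multispecies_consensus(profiles: dict[str, ResidueProfile],
                           aligned_sequences: dict[str, str],
                           scan_config: ScanConfig | None = None):
    """Column-wise unweighted mean of per-species profiles over an alignment.

    ``aligned_sequences`` maps species name to its gapped row; gaps carry no
    values.  Returns ``(consensus_profile, consensus_call, anomalies)`` where
    anomalies lists species whose own ASAr maximum deviates from the
    consensus by more than one aligned column (the isolated double-maximum
    situation the inter-species mean is meant to absorb).
    """
    cfg = scan_config if scan_config is not None else ScanConfig()
    if len(profiles) < 2:
        raise ScanError("consensus needs at least two species profiles")
    names = sorted(profiles)
    if set(names) - set(aligned_sequences):
        raise ScanError("every profile needs an aligned sequence row")
    ncol = {len(aligned_sequences[n]) for n in names}
    if len(ncol) != 1:
        raise ScanError("aligned rows must share one length")
    ncol = ncol.pop()

    # per-species map: alignment column -> residue index
    col_maps = {}
    for n in names:
        row = aligned_sequences[n]
        degapped = row.replace("-", "")
        if degapped != profiles[n].sequence:
            raise ScanError(
                f"aligned row of {n!r} does not match its profile sequence")
        m = np.full(ncol, -1, dtype=int)
        r = 0
        for c, ch in enumerate(row):
            if ch != "-":
                m[c] = r
                r += 1
        col_maps[n] = m

    def col_stack(attr):
        out = np.full((len(names), ncol), np.nan)
        for k, n in enumerate(names):
            vals = getattr(profiles[n], attr)
            m = col_maps[n]
            has = m >= 0
            out[k, has] = vals[m[has]]
        return out

    cons_seq = []
    for c in range(ncol):
        letters = {aligned_sequences[n][c] for n in names if aligned_sequences[n][c] != "-"}
        cons_seq.append(letters.pop() if len(letters) == 1 else "X")

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        counts = np.nansum(col_stack("n_covering_structures"), axis=0).astype(int)
        consensus = ResidueProfile(
            sequence="".join(cons_seq),
            n_covering_structures=counts,
            helicity_pct=np.nanmean(col_stack("helicity_pct"), axis=0),
            asar_raw=np.nanmean(col_stack("asar_raw"), axis=0),
            asar_smooth=np.nanmean(col_stack("asar_smooth"), axis=0),
            z_raw=np.nanmean(col_stack("z_raw"), axis=0),
            z_smooth=np.nanmean(col_stack("z_smooth"), axis=0),
            mfp_pct=np.nanmean(col_stack("mfp_pct"), axis=0),
        )
    call = call_tmd_center(consensus, cfg)
    if call.is_call:
        call_tmd_limits(consensus, call, cfg)

    anomalies = []
    if call.is_call:
        cons_argmax = call.asar_argmax - 1
        for n in names:
            p = profiles[n]
            if not np.isfinite(p.asar_smooth).any():
                continue
            own = int(np.nanargmax(p.asar_smooth))
            own_col = int(np.where(col_maps[n] == own)[0][0])
            if abs(own_col - cons_argmax) > 1:
                anomalies.append(n)
    return consensus, call, anomalies


@dataclass
class ScanResult:
    sequence: str
    profile: ResidueProfile
    call: TmdCall
    window_stats: list[WindowStats]
    window_seeds: dict[int, int]
    config: ScanConfig


def run_scan(sequence: str, scan_config: ScanConfig | None = None,
             alphabet: StructuralAlphabet | None = None,
             calibration: MfpCalibration | None = None,
             progress: bool = False) -> ScanResult:
    """Run the complete scan on one sequence and call the TMD."""
    cfg = scan_config if scan_config is not None else ScanConfig()
    alpha = alphabet if alphabet is not None else load_alphabet()
    calib = calibration if calibration is not None else default_calibration()
    mm = cfg.membrane_model()
    windows = generate_windows(sequence, cfg)
    stats = []
    seeds = {}
    for wi, (offset, subseq) in enumerate(windows):
        seed = cfg.window_seed(wi)
        seeds[offset] = seed
        ms = run_peplook(subseq, cfg.environment, cfg.sampler_config(seed),
                         alphabet=alpha)
        # one descriptor pass per model; ASA is shared between the surface
        # ratio and the membrane terms
        n, Lw = len(ms.models), len(subseq)
        helical = np.zeros((n, Lw), dtype=bool)
        asar = np.zeros((n, Lw))
        mfp = np.zeros((n, Lw))
        best_z = np.zeros(n)
        for k, conf in enumerate(ms.models):
            asa = shrake_rupley_asa(conf)
            asar[k] = asa.asar
            labels = pex_assign(conf)
            helical[k] = [l in ("alpha_helix", "three_ten_helix") for l in labels]
            mfp[k] = mfp_percentage(conf, calib, clip=(0.0, 200.0))
            best_z[k] = insertion_scan(
                conf, mm, rng_seed=seed, asa_per_atom=asa.atom_asa,
                orientation_mode=cfg.orientation_mode,
                orientation_trials=cfg.orientation_trials).best_z
        stats.append(WindowStats(offset=offset, sequence=subseq, helical=helical,
                                 asar=asar, mfp_pct=mfp, best_z=best_z))
        if progress:
            print(f"window {wi + 1}/{len(windows)} (offset {offset}) done", flush=True)
    profile = aggregate_profiles(stats, cfg, sequence)
    call = call_tmd_center(profile, cfg)
    if call.is_call:
        call_tmd_limits(profile, call, cfg)
    return ScanResult(sequence=sequence, profile=profile, call=call,
                      window_stats=stats, window_seeds=seeds, config=cfg)
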