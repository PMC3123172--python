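import numpy as np
import pytest

from tmdscan.scan import (ResidueProfile, ScanConfig, ScanError, TmdCall,
                          WindowStats, aggregate_profiles, call_tmd_center,
                          call_tmd_limits, generate_windows,
                          multispecies_consensus)


def make_stats(sequence, n_models=99, asar_value=1.0, helical=True, z=0.0,
               cfg=None):
    """Constant per-model stubs for every window of ``sequence``."""
    cfg = cfg or ScanConfig()
    out = []
    for offset, sub in generate_windows(sequence, cfg):
        L = len(sub)
        out.append(WindowStats(
            offset=offset, sequence=sub,
            helical=np.full((n_models, L), helical, dtype=bool),
            asar=np.full((n_models, L), asar_value, dtype=float),
            mfp_pct=np.full((n_models, L), 80.0),
            best_z=np.full(n_models, z),
        ))
    return out


def test_window_stats_from_model_set_and_insertions():
    from tmdscan.fixtures import generate_fixture
    from tmdscan.scan import compute_window_stats

    ms = generate_fixture("two_bundle_modelset", 19, seed=1)
    stats = compute_window_stats(0, ms, np.zeros(len(ms.models)))
    assert stats.n_models == len(ms.models)
    assert stats.helical.shape == (len(ms.models), 19)
    # half the bundle is an ideal helix, half extended
    helix_rows = stats.helical[:, 1:-1].all(axis=1)
    assert helix_rows.sum() == len(ms.models) // 2
    assert stats.mean_best_z == 0.0
    with pytest.raises(ScanError, match="insertion"):
        compute_window_stats(0, ms, np.zeros(3))


def test_window_generation_counts_and_offsets():
    cfg = ScanConfig()
    w30 = generate_windows("A" * 30, cfg)
    assert len(w30) == 12
    w19 = generate_windows("A" * 19, cfg)
    assert len(w19) == 1
    # window k covers absolute residues k .. k+18 (0-based offsets)
    offsets = [o for o, _ in w30]
    assert offsets == list(range(12))
    assert all(len(s) == 19 for _, s in w30)
    with pytest.raises(ScanError, match="single"):
        generate_windows("A" * 10, cfg)


def test_interior_residues_collect_1089_structures():
    seq = "A" * 30
    profile = aggregate_profiles(make_stats(seq), ScanConfig(), seq)
    # interior residues: covered by 11 windows x 99 models
    interior = profile.n_covering_structures[14:16]
    assert np.all(interior == 11 * 99)


def test_boundary_coverage_matches_enumeration_oracle():
    seq = "A" * 30
    cfg = ScanConfig()
    profile = aggregate_profiles(make_stats(seq, cfg=cfg), cfg, seq)
    # oracle: enumerate windows and their end-exclusion hits per residue
    expected = np.zeros(len(seq), dtype=int)
    for o, sub in generate_windows(seq, cfg):
        for p in range(cfg.end_exclusion, len(sub) - cfg.end_exclusion):
            expected[o + p] += 99
    assert np.array_equal(profile.n_covering_structures, expected)
    assert profile.n_covering_structures.sum() == expected.sum()


def test_constant_inputs_give_constant_columns():
    seq = "A" * 30
    profile = aggregate_profiles(make_stats(seq, asar_value=2.5, z=-1.0),
                                 ScanConfig(), seq)
    covered = profile.n_covering_structures > 0
    assert np.allclose(profile.asar_raw[covered], 2.5)
    assert np.allclose(profile.asar_smooth[covered], 2.5)
    assert np.allclose(profile.helicity_pct[covered], 100.0)
    centers = np.isfinite(profile.z_raw)
    assert np.allclose(profile.z_raw[centers], -1.0)
    assert np.allclose(profile.z_smooth[np.isfinite(profile.z_smooth)], -1.0)


def test_missing_window_is_reported():
    seq = "A" * 30
    stats = make_stats(seq)
    del stats[5]
    with pytest.raises(ScanError, match="5"):
        aggregate_profiles(stats, ScanConfig(), seq)


def _profile(asar, helicity=None, z=None):
    n = len(asar)
    helicity = np.full(n, 90.0) if helicity is None else np.asarray(helicity, float)
    z = np.full(n, np.nan) if z is None else np.asarray(z, float)
    asar = np.asarray(asar, float)
    return ResidueProfile(
        sequence="A" * n,
        n_covering_structures=np.full(n, 1089),
        helicity_pct=helicity,
        asar_raw=asar,
        asar_smooth=asar,
        z_raw=z,
        z_smooth=z,
        mfp_pct=np.full(n, 80.0),
    )


def test_unimodal_peak_with_agreeing_insertion_is_called():
    asar = np.concatenate([np.linspace(1, 5, 12), np.linspace(4.6, 1, 12)])
    z = np.abs(np.arange(24.0) - 11.0) + 0.5
    call = call_tmd_center(_profile(asar, z=z))
    assert call.is_call
    assert call.center_residues == (12,)
    assert call.helicity_ok
    assert "insertion_discordant" not in call.flags


def test_adjacent_insertion_minimum_widens_the_center():
    asar = np.concatenate([np.linspace(1, 5, 12), np.linspace(4.6, 1, 12)])
    z = np.abs(np.arange(24.0) - 12.0) + 0.5  # minimum one to the right
    call = call_tmd_center(_profile(asar, z=z))
    assert call.center_residues == (12, 13)


def test_discordant_insertion_keeps_asar_priority_and_flags():
    asar = np.concatenate([np.linspace(1, 5, 12), np.linspace(4.6, 1, 12)])
    z = np.abs(np.arange(24.0) - 14.0) + 0.5  # minimum three residues away
    call = call_tmd_center(_profile(asar, z=z))
    assert call.center_residues == (12,)
    assert "insertion_discordant" in call.flags


def test_flat_profile_is_a_no_call():
    call = call_tmd_center(_profile(np.full(24, 3.0)))
    assert not call.is_call
    assert "no_call_flat_profile" in call.flags


def test_double_maximum_is_arbitrated_by_insertion():
    asar = np.concatenate([np.linspace(1, 5, 8), np.linspace(4.8, 2, 6),
                           np.linspace(2.2, 4.9, 6), np.linspace(4.5, 1, 8)])
    z = np.abs(np.arange(28.0) - 19.0) + 0.5  # deepest near the second peak
    call = call_tmd_center(_profile(asar, z=z))
    assert "double_maximum" in call.flags
    assert call.center_residues[0] >= 19  # insertion chose the second peak


def test_limits_follow_the_helical_run():
    n = 40
    asar = np.concatenate([np.linspace(1, 5, 20), np.linspace(4.8, 1, 20)])
    hel = np.full(n, 90.0)
    hel[:14] = 50.0  # helicity dips below threshold on the N side
    profile = _profile(asar, helicity=hel)
    call = call_tmd_center(profile)
    limits = call_tmd_limits(profile, call)
    assert limits[0] == 15
    assert limits[1] - limits[0] + 1 <= 26


def test_long_helical_run_is_capped_symmetrically():
    n = 40
    asar = np.concatenate([np.linspace(1, 5, 20), np.linspace(4.8, 1, 20)])
    profile = _profile(asar)  # helical everywhere
    call = call_tmd_center(profile)
    limits = call_tmd_limits(profile, call)
    assert limits[1] - limits[0] + 1 == 26
    assert "span_capped" in call.flags
    assert "clipped_to_sequence_bounds" not in call.flags or limits[0] == 1


def test_short_helical_run_is_flagged():
    n = 24
    asar = np.concatenate([np.linspace(1, 5, 12), np.linspace(4.6, 1, 12)])
    hel = np.full(n, 50.0)
    hel[10:14] = 90.0
    profile = _profile(asar, helicity=hel)
    call = call_tmd_center(profile)
    call_tmd_limits(profile, call)
    assert "short_tmd" in call.flags


def test_consensus_of_identical_profiles_is_identity():
    asar = np.concatenate([np.linspace(1, 5, 12), np.linspace(4.6, 1, 12)])
    p = _profile(asar, z=np.abs(np.arange(24.0) - 11.0) + 0.5)
    profiles = {"human": p, "mouse": p}
    aligned = {"human": p.sequence, "mouse": p.sequence}
    cons, call, anomalies = multispecies_consensus(profiles, aligned)
    assert np.allclose(cons.asar_smooth, p.asar_smooth)
    assert call.center_residues == (12,)
    assert anomalies == []


def test_consensus_flags_the_anomalous_species():
    base = np.concatenate([np.linspace(1, 5, 12), np.linspace(4.6, 1, 12)])
    spurious = base.copy()
    spurious[20] = 7.0  # lone second maximum far from the consensus
    profiles = {"a": _profile(base), "b": _profile(base),
                "c": _profile(base), "weird": _profile(spurious)}
    aligned = {k: profiles[k].sequence for k in profiles}
    cons, call, anomalies = multispecies_consensus(profiles, aligned)
    assert call.is_call
    assert anomalies == ["weird"]


def test_consensus_mean_matches_hand_average_with_gaps():
    a = _profile(np.linspace(1, 3, 6))
    b = _profile(np.linspace(2, 4, 5))
    profiles = {"a": a, "b": b}
    aligned = {"a": "AAAAAA", "b": "AA-AAA"}
    cons, _, _ = multispecies_consensus(profiles, aligned)
    # column 2 holds only species a; others average both species
    assert cons.asar_raw[2] == pytest.approx(a.asar_raw[2])
    assert cons.asar_raw[0] == pytest.approx((a.asar_raw[0] + b.asar_raw[0]) / 2)
    assert cons.asar_raw[3] == pytest.approx((a.asar_raw[3] + b.asar_raw[2]) / 2)


def test_consensus_input_validation():
    p = _profile(np.linspace(1, 2, 5))
    with pytest.raises(ScanError):
        multispecies_consensus({"only": p}, {"only": p.sequence})
    with pytest.raises(ScanError, match="length"):
        multispecies_consensus({"a": p, "b": p},
                               {"a": p.sequence, "b": p.sequence + "A"})


def test_scan_config_validation_and_seed_determinism():
    with pytest.raises(ScanError):
        ScanConfig(window_length=18)
    with pytest.raises(ScanError):
        ScanConfig(asar_smoothing_window=4)
    cfg = ScanConfig(master_seed=11)
    assert cfg.window_seed(3) == cfg.window_seed(3)
    assert cfg.window_seed(3) != cfg.window_seed(4)
    assert 0 <= cfg.window_seed(3) < 2 ** 31
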