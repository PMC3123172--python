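import itertools

import numpy as np
import pytest

from tmdscan.builder import get_topology
from tmdscan.forcefield import NonbondedModel
from tmdscan.sampler import (ModelSet, SamplerConfig, SamplerError,
                             cluster_models, run_peplook, sample_structure,
                             update_probabilities, _draw_states)


def test_uniform_sampling_law():
    probs = np.full((1, 64), 1.0 / 64.0)
    draws = _draw_states(probs, 100_000, np.random.default_rng(0))
    counts = np.bincount(draws[:, 0], minlength=64)
    p = 1.0 / 64.0
    sigma = np.sqrt(100_000 * p * (1 - p))
    assert np.all(np.abs(counts - 100_000 * p) < 3.5 * sigma)


def test_concentrated_probability_dominates_draws():
    eps = 0.005
    probs = np.full((1, 64), eps / 63.0)
    probs[0, 17] = 1.0 - eps
    draws = _draw_states(probs, 10_000, np.random.default_rng(1))
    assert np.mean(draws[:, 0] == 17) >= 0.99


def test_sampling_is_deterministic_per_seed(alphabet):
    a = alphabet.with_uniform_probabilities(6)
    s1 = sample_structure("AGLKAV", a, np.random.default_rng(42))
    s2 = sample_structure("AGLKAV", a, np.random.default_rng(42))
    assert np.array_equal(s1.state_indices, s2.state_indices)
    assert np.array_equal(s1.coords, s2.coords)


def _toy_update_inputs():
    # 10 ranked structures, 4 positions, 8 states
    rng = np.random.default_rng(3)
    states = rng.integers(0, 8, size=(10, 4))
    energies = np.sort(rng.normal(size=10))
    probs = np.full((4, 8), 1.0 / 8.0)
    return states, energies, probs


def test_update_ignores_states_present_in_both_tiers():
    states, energies, probs = _toy_update_inputs()
    cfg = SamplerConfig(structures_per_step=10, favorable_fraction=0.2,
                        unfavorable_fraction=0.2)
    states[0, 2] = 5  # favorable tier
    states[9, 2] = 5  # unfavorable tier: shared pair must stay untouched
    out = update_probabilities(states, energies, probs, cfg)
    assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
    # the shared pair is not boosted above its neighbors by the update
    boosted = out[2, 5] / probs[2, 5]
    others = np.delete(out[2] / probs[2], 5)
    assert boosted <= others.max() + 1e-12


def test_update_without_tier_exclusive_states_is_identity():
    cfg = SamplerConfig(structures_per_step=4, favorable_fraction=0.25,
                        unfavorable_fraction=0.25)
    # identical state rows: every pair is in both tiers
    states = np.tile(np.array([[1, 2, 3, 4]]), (4, 1))
    energies = np.arange(4.0)
    probs = np.full((4, 8), 1.0 / 8.0)
    out = update_probabilities(states, energies, probs, cfg)
    assert np.allclose(out, probs, atol=1e-12)


def test_single_exclusive_favorable_state_is_boosted():
    cfg = SamplerConfig(structures_per_step=10, favorable_fraction=0.1,
                        unfavorable_fraction=0.1)
    states = np.ones((10, 5), dtype=int)
    states[0, 3] = 7  # appears only in the single favorable structure
    energies = np.arange(10.0)
    probs = np.full((5, 16), 1.0 / 16.0)
    out = update_probabilities(states, energies, probs, cfg)
    assert out[3, 7] > probs[3, 7]
    assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(out >= cfg.probability_floor - 1e-15)


def _enumerate_toy_minimum(toy_alphabet, sequence="AGLKA"):
    topo = get_topology(sequence)
    model = NonbondedModel(topo)
    assign = np.array(list(itertools.product(range(4), repeat=len(sequence))))
    ang = toy_alphabet.states[assign]
    coords = topo.build_batch(ang[:, :, 0], ang[:, :, 1])
    energies = model.nonbonded_total(coords)
    k = int(np.argmin(energies))
    return tuple(assign[k]), float(energies[k])


def test_toy_search_finds_the_enumerated_global_minimum(toy_alphabet):
    best_states, best_e = _enumerate_toy_minimum(toy_alphabet)
    for seed in (0, 1, 2):
        cfg = SamplerConfig(structures_per_step=128, total_steps=50,
                            rng_seed=seed)
        ms = run_peplook("AGLKA", "hydrophobic", cfg, alphabet=toy_alphabet)
        assert tuple(ms.prime.state_indices) == best_states
        assert ms.prime_energy == pytest.approx(best_e, abs=1e-9)


def test_archive_contract(toy_alphabet):
    cfg = SamplerConfig(structures_per_step=64, total_steps=20, rng_seed=5)
    ms = run_peplook("AGLKA", "hydrophobic", cfg, alphabet=toy_alphabet)
    assert len(ms.models) <= 99
    assert np.all(np.diff(ms.energies) >= 0.0)
    assert ms.prime is ms.models[0]
    keys = ms.state_strings()
    assert len(keys) == len(set(keys))  # no duplicate state strings


def test_identical_seed_reproduces_the_prime(toy_alphabet):
    cfg = SamplerConfig(structures_per_step=64, total_steps=15, rng_seed=9)
    a = run_peplook("AGLKA", "hydrophobic", cfg, alphabet=toy_alphabet)
    b = run_peplook("AGLKA", "hydrophobic", cfg, alphabet=toy_alphabet)
    assert tuple(a.prime.state_indices) == tuple(b.prime.state_indices)
    assert np.array_equal(a.energies, b.energies)


def test_invalid_inputs_are_rejected():
    with pytest.raises(SamplerError):
        run_peplook("A" * 35, "hydrophobic")
    with pytest.raises(SamplerError):
        run_peplook("AAAAA", "membrane")
    with pytest.raises(SamplerError):
        SamplerConfig(archive_size=50)
    with pytest.raises(SamplerError):
        SamplerConfig(favorable_fraction=0.7)


def test_clustering_trivial_and_two_bundle_cases():
    from tmdscan.fixtures import generate_fixture

    ms = generate_fixture("two_bundle_modelset", 6, seed=0)
    labels, sizes, prime_label = cluster_models(ms, rmsd_threshold=1.0)
    assert len(set(labels)) == 2
    assert sorted(sizes.values()) == [10, 10]
    assert prime_label == labels[0]

    # 10 identical copies collapse to one cluster
    from tmdscan.builder import Conformation
    base = ms.models[0]
    same = ModelSet(sequence=base.sequence, environment="hydrophobic",
                    models=[Conformation(base.topology, base.coords.copy())
                            for _ in range(10)],
                    energies=np.zeros(10))
    labels, sizes, _ = cluster_models(same)
    assert len(set(labels)) == 1 and sizes[labels[0]] == 10


def test_clustering_matches_naive_single_linkage_oracle(alphabet):
    from tmdscan.builder import build_conformation
    from tmdscan.descriptors import superposed_rmsd

    rng = np.random.default_rng(8)
    models = [build_conformation("AGLK", rng.integers(0, alphabet.n_states, 4),
                                 alphabet) for _ in range(12)]
    ms = ModelSet(sequence="AGLK", environment="hydrophobic", models=models,
                  energies=np.arange(12.0))
    labels, _, _ = cluster_models(ms, rmsd_threshold=1.0)

    # oracle: connected components of the graph with edges rmsd <= 1
    n = len(models)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if superposed_rmsd(models[i], models[j]) <= 1.0:
                adj[i].add(j)
                adj[j].add(i)
    seen, comp = {}, 0
    for s in range(n):
        if s in seen:
            continue
        comp += 1
        stack = [s]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen[u] = comp
            stack.extend(adj[u] - seen.keys())
    oracle = np.array([seen[i] for i in range(n)])
    # same partition (label values may differ)
    for i in range(n):
        for j in range(n):
            assert (labels[i] == labels[j]) == (oracle[i] == oracle[j])
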