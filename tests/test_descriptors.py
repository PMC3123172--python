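import numpy as np
import pytest

from tmdscan.builder import Conformation, build_conformation, get_topology
from tmdscan.descriptors import (DescriptorError, helicity_fraction,
                                 pex_assign, residue_asar, shrake_rupley_asa,
                                 superposed_rmsd)
from tmdscan.geometry import icosphere_points

from conftest import random_rotation


def spread_atoms(sequence="GG", spacing=100.0):
    """A conformation whose atoms are mutually isolated spheres."""
    topo = get_topology(sequence, hydrogen_policy="none")
    coords = np.zeros((topo.n_atoms, 3))
    coords[:, 0] = np.arange(topo.n_atoms) * spacing
    return Conformation(topo, coords)


def test_isolated_spheres_recover_the_analytic_area():
    conf = spread_atoms()
    res = shrake_rupley_asa(conf)
    expected = 4.0 * np.pi * (conf.topology.radius + 1.4) ** 2
    assert res.atom_asa == pytest.approx(expected, rel=0.02)


def test_fully_caged_atom_has_zero_area():
    topo = get_topology("GGGGGGGGGGGGG", hydrogen_policy="none")
    coords = np.zeros((topo.n_atoms, 3))
    coords[12:, 0] = 999.0  # park the unused atoms far away
    cage = icosphere_points(1)[:12] * 2.0
    coords[0] = 0.0
    coords[1:12] = cage[:11]
    # add the 12th cage vertex in place of a parked atom
    coords[12] = cage[11]
    res = shrake_rupley_asa(Conformation(topo, coords))
    assert res.atom_asa[0] == 0.0


def test_two_overlapping_spheres_match_the_cap_formula():
    conf = spread_atoms("GG")
    coords = conf.coords.copy()
    # bring exactly two atoms (same radius R) to distance d, keep others far
    i, j = 0, 1
    coords[j] = coords[i] + np.array([3.0, 0.0, 0.0])
    coords[2:, 0] += 5000.0
    r = shrake_rupley_asa(Conformation(conf.topology, coords))
    R_i = conf.topology.radius[i] + 1.4
    R_j = conf.topology.radius[j] + 1.4
    d = 3.0
    h_i = R_i - (d * d + R_i * R_i - R_j * R_j) / (2 * d)
    h_j = R_j - (d * d + R_j * R_j - R_i * R_i) / (2 * d)
    expect_i = 4 * np.pi * R_i ** 2 - 2 * np.pi * R_i * h_i
    expect_j = 4 * np.pi * R_j ** 2 - 2 * np.pi * R_j * h_j
    assert r.atom_asa[i] == pytest.approx(expect_i, rel=0.03)
    assert r.atom_asa[j] == pytest.approx(expect_j, rel=0.03)


def test_asa_agrees_with_independent_implementation(helix19):
    """Cross-check against biotite's Shrake-Rupley on identical radii."""
    import biotite.structure as struc

    topo = helix19.topology
    arr = struc.AtomArray(topo.n_atoms)
    arr.coord = helix19.coords
    arr.atom_name = np.array(topo.atom_names)
    arr.element = np.array(topo.elements)
    arr.res_id = topo.residue_index + 1
    arr.res_name = np.array(["LEU"] * topo.n_atoms)
    ours = shrake_rupley_asa(helix19).atom_asa.sum()
    theirs = np.nansum(struc.sasa(arr, vdw_radii=topo.radius,
                                  point_number=500, probe_radius=1.4))
    assert ours == pytest.approx(theirs, rel=0.03)


def test_asa_is_rigid_transform_invariant(helix19):
    moved = helix19.transformed(rotation=random_rotation(21),
                                translation=np.array([7.0, -4.0, 11.0]))
    a = shrake_rupley_asa(helix19).atom_asa
    b = shrake_rupley_asa(moved).atom_asa
    # the deterministic sphere points do not rotate with the molecule, so
    # per-atom exposure counts re-quantize by a few grid points
    assert np.allclose(a, b, atol=8.0)
    assert abs(a.sum() - b.sum()) / a.sum() < 0.015


def test_compact_structure_exposes_less_than_pulled_apart(helix19):
    compact = shrake_rupley_asa(helix19).atom_asa.sum()
    stretched_coords = helix19.coords * 3.0
    stretched = shrake_rupley_asa(
        Conformation(helix19.topology, stretched_coords)).atom_asa.sum()
    assert compact < stretched


def test_asar_ranks_leucine_above_aspartate(alphabet, helix_state):
    conf = build_conformation("ALDLA", [helix_state] * 5, alphabet)
    res = shrake_rupley_asa(conf)
    asar = residue_asar(res)
    assert asar[1] > asar[2]  # Leu > Asp
    assert np.all(res.atom_asa >= 0.0)
    # residue sums decompose the atom areas
    for r in range(5):
        mask = conf.topology.residue_index == r
        total = res.residue_hydrophobic[r] + res.residue_hydrophilic[r]
        assert total == pytest.approx(res.atom_asa[mask].sum(), abs=1e-6)


def test_pex_labels_ideal_helix_and_strand(alphabet, helix_state, extended_state):
    helix = build_conformation("A" * 12, [helix_state] * 12, alphabet)
    labels = pex_assign(helix)
    assert labels[0] == "coil" and labels[-1] == "coil"  # undefined phi/psi
    assert all(l == "alpha_helix" for l in labels[1:-1])
    strand = build_conformation("A" * 8, [extended_state] * 8, alphabet)
    labels = pex_assign(strand)
    assert all(l == "beta" for l in labels[1:-1])


def test_helix_dihedrals_alone_are_not_sufficient(alphabet, helix_state, extended_state):
    # a 4-mer with perfect helical dihedrals is too short to form any
    # i,i+4 or i,i+3 hydrogen bond: the conjunction rule labels it coil
    short = build_conformation("AAAA", [helix_state] * 4, alphabet)
    assert all(l == "coil" for l in pex_assign(short))
    # at 5 residues the first i,i+3 contact appears and is recognized as
    # 3-10 helix, still not alpha
    five = build_conformation("AAAAA", [helix_state] * 5, alphabet)
    assert "alpha_helix" not in pex_assign(five)
    # a kink in the middle of a longer helix demotes the flipped residue
    states = [helix_state] * 12
    states[6] = extended_state
    conf = build_conformation("A" * 12, states, alphabet)
    labels = pex_assign(conf)
    assert labels[6] != "alpha_helix"


def test_pex_requires_amide_hydrogens(alphabet, helix_state):
    topo = get_topology("AAAA", hydrogen_policy="none")
    angles = alphabet.states[[helix_state] * 4]
    coords = topo.build_batch(angles[None, :, 0], angles[None, :, 1])[0]
    with pytest.raises(DescriptorError, match="hydrogen_policy"):
        pex_assign(Conformation(topo, coords))


def test_pex_is_rigid_transform_invariant(helix19):
    moved = helix19.transformed(rotation=random_rotation(4),
                                translation=np.array([1.0, 2.0, 3.0]))
    assert pex_assign(moved) == pex_assign(helix19)


def test_poly_ala_helix_meets_the_helicity_threshold(alphabet, helix_state):
    conf = build_conformation("A" * 19, [helix_state] * 19, alphabet)
    assert helicity_fraction(pex_assign(conf)) >= 0.75


def test_rmsd_of_rigidly_moved_copy_is_zero(helix19):
    moved = helix19.transformed(rotation=random_rotation(9),
                                translation=np.array([-4.0, 8.0, 2.0]))
    assert superposed_rmsd(helix19, moved) < 1e-6
    assert superposed_rmsd(helix19, helix19) < 1e-9


def test_rmsd_matches_scipy_alignment_oracle(alphabet):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(12)
    a = build_conformation("AGLW", rng.integers(0, alphabet.n_states, 4), alphabet)
    b = build_conformation("AGLW", rng.integers(0, alphabet.n_states, 4), alphabet)
    ours = superposed_rmsd(a, b)
    pa = a.coords - a.coords.mean(axis=0)
    pb = b.coords - b.coords.mean(axis=0)
    _, rssd = Rotation.align_vectors(pb, pa)
    assert ours == pytest.approx(rssd / np.sqrt(len(pa)), rel=1e-6)


def test_rmsd_rejects_mismatched_structures(alphabet, helix_state):
    a = build_conformation("AA", [helix_state] * 2, alphabet)
    b = build_conformation("AAA", [helix_state] * 3, alphabet)
    with pytest.raises(DescriptorError):
        superposed_rmsd(a, b)
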