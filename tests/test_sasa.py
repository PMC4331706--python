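import numpy as np
import pytest

from ifacewcn import sasa
from ifacewcn.structure_io import ComplexStructure
from ifacewcn.synthetic_data import make_lattice_subunit
from tests._helpers import random_rotation, residues_from_coords, single_atom_residue


def cluster(rng, n, box=8.0, chain="A"):
    return residues_from_coords(rng.uniform(0, box, size=(n, 3)), chain=chain)


def test_isolated_atom_matches_analytic_sphere():
    res = [single_atom_residue([0.0, 0.0, 0.0])]
    out = sasa.shrake_rupley(res, probe=1.4, n_points=960, vdw_radii={"C": 1.6})
    analytic = 4.0 * np.pi * 3.0**2
    assert out.per_atom[0] == pytest.approx(analytic, rel=0.01)
    assert out.per_residue[0] == pytest.approx(out.per_atom[0])


def test_fully_caged_atom_has_zero_area():
    sub = make_lattice_subunit(3, spacing=3.4)
    out = sasa.shrake_rupley(sub.residues)
    center = 1 * 9 + 1 * 3 + 1  # lattice index (1,1,1)
    assert out.per_residue[center] == 0.0
    hull = np.delete(out.per_residue, center)
    assert np.all(hull > 0.0)


def test_cage_burial_threshold_in_spacing():
    # a cubic cage of carbons buries its center against a 1.4 Å probe only
    # below spacing 2*(1.7+1.4)/sqrt(3) ≈ 3.58 Å
    center = 13
    tight = sasa.shrake_rupley(make_lattice_subunit(3, spacing=3.5).residues)
    loose = sasa.shrake_rupley(make_lattice_subunit(3, spacing=3.7).residues)
    assert tight.per_residue[center] == 0.0
    assert loose.per_residue[center] > 0.0


def test_well_separated_atoms_are_independent():
    res = residues_from_coords([[0, 0, 0], [50, 0, 0]])
    out = sasa.shrake_rupley(res)
    alone = sasa.shrake_rupley(res[:1])
    assert out.per_atom == pytest.approx([alone.per_atom[0]] * 2)


def test_self_convergence_of_point_density(rng):
    res = cluster(rng, 30)
    coarse = sasa.shrake_rupley(res, n_points=960)
    fine = sasa.shrake_rupley(res, n_points=10000)
    scale = 4.0 * np.pi * (1.7 + 1.4) ** 2
    # per-atom agreement within 2% of the inflated-sphere area
    assert np.all(np.abs(coarse.per_atom - fine.per_atom) < 0.02 * scale)


def test_rigid_motion_invariance(rng):
    res = cluster(rng, 25)
    base = sasa.shrake_rupley(res, n_points=2000).per_residue
    rot = random_rotation(rng)
    shift = rng.uniform(-20, 20, size=3)
    moved = residues_from_coords([rot @ r.atoms[0].coord + shift for r in res])
    out = sasa.shrake_rupley(moved, n_points=2000).per_residue
    # point-set tolerance: the test-point lattice has a fixed orientation
    assert np.all(np.abs(out - base) <= 0.005 * (4 * np.pi * 3.1**2))


def test_adding_atoms_never_increases_area(rng):
    res = cluster(rng, 20)
    before = sasa.shrake_rupley(res).per_atom
    extended = res + cluster(rng, 10, chain="B")
    after = sasa.shrake_rupley(extended).per_atom[:20]
    assert np.all(after <= before + 1e-12)


def test_agreement_with_reference_implementation(rng):
    biotite_struc = pytest.importorskip("biotite.structure")
    res = cluster(rng, 50, box=12.0)
    ours = sasa.shrake_rupley(res, n_points=10000).per_atom

    arr = biotite_struc.AtomArray(len(res))
    arr.coord = np.vstack([r.atoms[0].coord for r in res]).astype(np.float32)
    arr.element = np.array(["C"] * len(res))
    arr.res_id = np.arange(1, len(res) + 1)
    arr.atom_name = np.array(["CA"] * len(res))
    arr.res_name = np.array(["GLY"] * len(res))
    arr.chain_id = np.array(["A"] * len(res))
    ref = biotite_struc.sasa(
        arr, probe_radius=1.4, point_number=5000, vdw_radii=np.full(len(res), 1.7)
    )
    np.testing.assert_allclose(ours, ref, rtol=0.03, atol=0.5)


def test_small_point_count_and_unknown_element_error():
    res = [single_atom_residue([0, 0, 0])]
    with pytest.raises(ValueError, match="n_points"):
        sasa.shrake_rupley(res, n_points=16)
    weird = [single_atom_residue([0, 0, 0], element="XX")]
    with pytest.raises(KeyError, match="XX"):
        sasa.shrake_rupley(weird)


def test_relative_sasa_contract():
    assert sasa.relative_sasa(0.0, "ALA") == 0.0
    max_ala = sasa.MAX_ASA_ROST_SANDER["ALA"]
    assert sasa.relative_sasa(max_ala, "ALA") == pytest.approx(1.0)
    assert sasa.relative_sasa(max_ala / 2, "ALA") == pytest.approx(0.5)
    # over-exposure is not clamped
    assert sasa.relative_sasa(2 * max_ala, "ALA") == pytest.approx(2.0)
    with pytest.raises(KeyError):
        sasa.relative_sasa(10.0, "UNK")


def test_max_asa_tables_cover_standard_residues():
    for table in sasa.MAX_ASA_TABLES.values():
        assert len(table) == 20
        assert all(v > 0 for v in table.values())


def test_bound_equals_unbound_for_distant_chains(rng):
    a = cluster(rng, 10, chain="A")
    b = residues_from_coords(rng.uniform(0, 8, size=(10, 3)) + 100.0, chain="B")
    st = ComplexStructure("FAR0", 0, {"A": a, "B": b})
    (ua, ba), (ub, bb) = sasa.bound_and_unbound_sasa(
        st, [frozenset("A"), frozenset("B")]
    )
    np.testing.assert_allclose(ua, ba)
    np.testing.assert_allclose(ub, bb)


def test_bound_never_exceeds_unbound(rng):
    a = cluster(rng, 15, chain="A")
    b = residues_from_coords(rng.uniform(0, 8, size=(15, 3)) + 4.0, chain="B")
    st = ComplexStructure("MIX0", 0, {"A": a, "B": b})
    for unbound, bound in sasa.bound_and_unbound_sasa(st, [frozenset("A"), frozenset("B")]):
        assert np.all(bound <= unbound + 1e-12)
        assert bound.sum() <= unbound.sum() + 1e-9


def test_slab_core_buried_only_in_complex(slab_dimer):
    structure, labels = slab_dimer
    groups = [frozenset("A"), frozenset("B")]
    (unbound, bound), _ = sasa.bound_and_unbound_sasa(structure, groups)
    n = len(structure.chains["A"])
    core = [i for i in range(n) if labels[i].value == "central"]
    assert core
    assert np.all(unbound[core] > 0.0)
    # near-total burial: well under the 5% centrality threshold (4.2 Å² for GLY)
    assert np.all(bound[core] < 1.0)
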