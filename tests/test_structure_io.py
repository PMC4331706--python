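import numpy as np
import pytest

from ifacewcn.structure_io import (
    ManifestError,
    PDBParseError,
    extract_subunit,
    load_manifest,
    parse_pdb,
    parse_pdb_models,
    select_first_model,
    write_pdb,
)


def _atom_line(serial, name, res, chain, resnum, x, y, z, occ=1.0, altloc=" ",
               element=None, record="ATOM  "):
    element = element or name[0]
    return (
        f"{record}{serial:5d}  {name:<3s}{altloc}{res:<3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )


TWO_CHAIN = "\n".join(
    [
        _atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
        _atom_line(2, "CA", "ALA", "B", 1, 10.0, 0.0, 0.0),
        "END",
    ]
)


def test_minimal_two_chain_file():
    s = parse_pdb(TWO_CHAIN)
    assert s.chain_ids == ["A", "B"]
    assert [len(c) for c in s.chains.values()] == [1, 1]
    assert s.chains["B"][0].res_name == "ALA"


def test_altloc_keeps_highest_occupancy_conformer():
    text = "\n".join(
        [
            _atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, occ=0.6, altloc="A"),
            _atom_line(2, "CA", "GLY", "A", 1, 5.0, 0.0, 0.0, occ=0.4, altloc="B"),
            "END",
        ]
    )
    s = parse_pdb(text)
    (res,) = s.chains["A"]
    assert len(res.atoms) == 1
    assert res.atoms[0].occupancy == pytest.approx(0.6)
    assert res.atoms[0].coord[0] == pytest.approx(0.0)


def test_altloc_occupancy_tie_keeps_first_conformer():
    text = "\n".join(
        [
            _atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, occ=0.5, altloc="A"),
            _atom_line(2, "CA", "GLY", "A", 1, 5.0, 0.0, 0.0, occ=0.5, altloc="B"),
            "END",
        ]
    )
    (res,) = parse_pdb(text).chains["A"]
    assert res.atoms[0].coord[0] == pytest.approx(0.0)


def test_waters_ligands_and_hydrogens_excluded():
    text = "\n".join(
        [
            _atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
            f"ATOM      2  H   GLY A   1       1.000   0.000   0.000  1.00  0.00           H",
            _atom_line(3, "O", "HOH", "A", 2, 3.0, 0.0, 0.0, record="HETATM"),
            _atom_line(4, "FE", "HEM", "A", 3, 6.0, 0.0, 0.0, record="HETATM", element="FE"),
            "END",
        ]
    )
    s = parse_pdb(text)
    residues = s.residues()
    assert len(residues) == 1
    assert [a.name for a in residues[0].atoms] == ["CA"]


def test_nonstandard_residue_dropped_with_warning(caplog):
    text = "\n".join(
        [
            _atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
            _atom_line(2, "CA", "MSE", "A", 2, 4.0, 0.0, 0.0),
            "END",
        ]
    )
    with caplog.at_level("WARNING", logger="ifacewcn.structure_io"):
        s = parse_pdb(text)
    assert s.n_residues() == 1
    assert any("MSE" in rec.message for rec in caplog.records)


def test_first_model_selected_from_nmr_ensemble():
    text = "\n".join(
        [
            "MODEL        1",
            _atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
            "ENDMDL",
            "MODEL        2",
            _atom_line(1, "CA", "GLY", "A", 1, 9.0, 9.0, 9.0),
            "ENDMDL",
            "MODEL        3",
            _atom_line(1, "CA", "GLY", "A", 1, 5.0, 5.0, 5.0),
            "ENDMDL",
            "END",
        ]
    )
    models = parse_pdb_models(text)
    assert len(models) == 3
    first = select_first_model(models)
    assert first.chains["A"][0].atoms[0].coord[0] == pytest.approx(0.0)
    assert parse_pdb(text).chains["A"][0].atoms[0].coord[0] == pytest.approx(0.0)


def test_single_model_file_passes_through():
    s = parse_pdb(TWO_CHAIN)
    assert select_first_model(s) is s


def test_empty_model_list_is_an_error():
    with pytest.raises(PDBParseError):
        select_first_model([])


def test_no_atom_records_is_a_parse_error():
    with pytest.raises(PDBParseError, match="no ATOM"):
        parse_pdb("HEADER    NOTHING\nEND\n")


def test_malformed_coordinate_names_the_line():
    bad = TWO_CHAIN.replace("  10.000", "  1x.000")
    with pytest.raises(PDBParseError, match="line 2"):
        parse_pdb(bad)


def test_extract_subunit_single_and_all_chains():
    s = parse_pdb(TWO_CHAIN)
    sub_a = extract_subunit(s, {"A"})
    assert [r.chain_id for r in sub_a.residues] == ["A"]
    sub_ab = extract_subunit(s, {"A", "B"})
    assert len(sub_ab.residues) == s.n_residues()


def test_extract_unknown_chain_lists_available():
    s = parse_pdb(TWO_CHAIN)
    with pytest.raises(KeyError, match=r"'A', 'B'"):
        extract_subunit(s, {"C"})


def test_manifest_basic_row():
    (entry,) = load_manifest("2TSC\tA\tB\thomodimer\n")
    assert entry.pdb_id == "2TSC"
    assert entry.subunit_chain_groups == [frozenset("A"), frozenset("B")]
    assert entry.category == "homodimer"


def test_manifest_multichain_group_and_comments():
    text = "# immunoglobulin complex\n1ABC\tH:L\tX\ttransient\n"
    (entry,) = load_manifest(text)
    assert entry.subunit_chain_groups[0] == frozenset({"H", "L"})


def test_manifest_obsolete_substitution(caplog):
    with caplog.at_level("INFO", logger="ifacewcn.structure_io"):
        entries = load_manifest(
            "2SDH\tA\tB\thomodimer\n2SSI\tA\tB\ttransient\n3GAP\tA\tB\thomodimer\n"
        )
    assert [e.pdb_id for e in entries] == ["3SDH", "3SSI", "1G6N"]
    assert any("2SDH" in rec.message for rec in caplog.records)


@pytest.mark.parametrize(
    "row, match",
    [
        ("XXXX\tA\thomodimer", "chain groups"),
        ("XXXX\tA\tB\ttrimer", "category"),
        ("XXXX\tA\tA:B\thomodimer", "overlap"),
    ],
)
def test_manifest_rejects_bad_rows(row, match):
    with pytest.raises(ManifestError, match=match):
        load_manifest(row + "\n")


def test_write_parse_round_trip(rng):
    from tests._helpers import residues_from_coords
    from ifacewcn.structure_io import ComplexStructure

    coords = rng.uniform(-30, 30, size=(40, 3))
    st = ComplexStructure(
        pdb_id="TEST",
        model_index=0,
        chains={"A": residues_from_coords(coords[:20], "A"),
                "B": residues_from_coords(coords[20:], "B")},
    )
    text = write_pdb(st)
    again = parse_pdb(text, pdb_id="TEST")
    assert again.n_residues() == st.n_residues()
    got = np.vstack([r.coords() for r in again.residues()])
    np.testing.assert_allclose(got, coords, atol=5e-4)  # PDB fixed 3-decimal fields
    # a second round trip is exact: filtering and formatting are idempotent
    assert write_pdb(again) == text


def test_write_pdb_field_width_errors():
    from ifacewcn.structure_io import ComplexStructure
    from tests._helpers import single_atom_residue

    st = ComplexStructure("X", 0, {"AB": [single_atom_residue([0, 0, 0], chain="AB")]})
    with pytest.raises(ValueError, match="chain id"):
        write_pdb(st)
    big = single_atom_residue([0, 0, 0])
    big.seq_id = "10000"
    st2 = ComplexStructure("X", 0, {"A": [big]})
    with pytest.raises(ValueError, match="9999|field width"):
        write_pdb(st2)
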