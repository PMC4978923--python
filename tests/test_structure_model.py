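"""PDB reading/writing and the chain-sequence index map."""

import pytest

from pinmap.structure_model import (
    StructureError,
    chain_sequence,
    read_structure,
    write_structure,
)


def _atom_line(serial, name, alt, res, chain, seq, icode, x, y, z, occ, elem, record="ATOM  "):
    return (
        f"{record}{serial:5d} {name:<4s}{alt:1s}{res:3s} {chain:1s}{seq:4d}{icode:1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{20.0:6.2f}          {elem:>2s}"
    )


def _write_pdb(path, lines):
    path.write_text("\n".join(lines + ["END"]) + "\n")
    return path


@pytest.fixture()
def toy_pdb(tmp_path):
    """Three-residue single chain: Ala, Gly, Trp."""
    lines = [
        _atom_line(1, "CA", " ", "ALA", "A", 1, " ", 0.0, 0.0, 0.0, 1.0, "C"),
        _atom_line(2, "CA", " ", "GLY", "A", 2, " ", 3.8, 0.0, 0.0, 1.0, "C"),
        _atom_line(3, "CA", " ", "TRP", "A", 3, " ", 7.6, 0.0, 0.0, 1.0, "C"),
    ]
    return _write_pdb(tmp_path / "toy.pdb", lines)


@pytest.fixture()
def synthetic_realistic_pdb(tmp_path):
    """Synthetic PDB exercising realistic records: altlocs, insertion codes,
    hydrogens, waters, HETATM ligand, a numbering gap, and a second chain."""
    lines = [
        "HEADER    SYNTHETIC TEST STRUCTURE",
        "REMARK 465 MISSING RESIDUES",
        _atom_line(1, "N", " ", "MET", "A", 1, " ", 0.0, 0.0, 0.0, 1.0, "N"),
        _atom_line(2, "CA", " ", "MET", "A", 1, " ", 1.5, 0.0, 0.0, 1.0, "C"),
        _atom_line(3, "H", " ", "MET", "A", 1, " ", 1.5, 1.0, 0.0, 1.0, "H"),
        _atom_line(4, "CA", "A", "SER", "A", 2, " ", 5.0, 0.0, 0.0, 0.6, "C"),
        _atom_line(5, "CA", "B", "SER", "A", 2, " ", 5.2, 0.0, 0.0, 0.4, "C"),
        _atom_line(6, "CA", " ", "GLY", "A", 2, "A", 8.0, 0.0, 0.0, 1.0, "C"),
        # numbering gap 3..5 -> missing segment
        _atom_line(7, "CA", " ", "LYS", "A", 6, " ", 12.0, 0.0, 0.0, 1.0, "C"),
        "TER       8      LYS A   6",
        _atom_line(9, "CA", " ", "MSE", "B", 1, " ", 0.0, 8.0, 0.0, 1.0, "C"),
        _atom_line(10, "O", " ", "HOH", "B", 101, " ", 0.0, 12.0, 0.0, 1.0, "O", "HETATM"),
        _atom_line(11, "ZN", " ", "ZN", "B", 201, " ", 0.0, 16.0, 0.0, 1.0, "ZN", "HETATM"),
    ]
    return _write_pdb(tmp_path / "synthetic_realistic.pdb", lines)


def test_toy_roundtrip(toy_pdb, tmp_path):
    model = read_structure(toy_pdb)
    assert list(model.chains) == ["A"]
    assert model.n_residues == 3
    assert model.missing_segments["A"] == []
    seq, index_map = chain_sequence(model, "A")
    assert seq == "AGW"
    assert len(index_map) == 3

    out = tmp_path / "rt.pdb"
    write_structure(model, out)
    model2 = read_structure(out)
    assert model2.n_residues == model.n_residues
    for r1, r2 in zip(model.residues(), model2.residues()):
        assert (r1.chain_id, r1.seq_num, r1.icode, r1.aa) == (
            r2.chain_id, r2.seq_num, r2.icode, r2.aa)
        for a1, a2 in zip(r1.atoms, r2.atoms):
            assert a1.element == a2.element
            assert max(abs(x - y) for x, y in zip(a1.coord, a2.coord)) <= 1e-3


def test_realistic_filters_and_altloc(synthetic_realistic_pdb):
    model = read_structure(synthetic_realistic_pdb)
    # hydrogens and waters dropped, HETATM dropped by default
    a_res = model.chains["A"]
    assert [r.aa for r in a_res] == ["M", "S", "G", "K"]
    # altloc: the occupancy-0.6 A conformer is kept, exactly one CA for residue 2
    ser = next(r for r in a_res if r.seq_num == 2 and r.icode == "")
    assert len([a for a in ser.atoms if a.name == "CA"]) == 1
    assert ser.atoms[0].coord[0] == pytest.approx(5.0)
    # insertion code residue ordered after its base number
    assert [(r.seq_num, r.icode) for r in a_res] == [(1, ""), (2, ""), (2, "A"), (6, "")]
    # MET lost its hydrogen but kept N + CA
    met = a_res[0]
    assert sorted(a.name for a in met.atoms) == ["CA", "N"]
    # numbering gap becomes a missing segment
    assert model.missing_segments["A"] == [(3, 5)]
    # nonstandard MSE residue reads as X
    assert model.chains["B"][0].aa == "X"
    assert all(not r.aa == "O" for r in model.chains["B"])  # no water residues


def test_keep_het_retains_ligand(synthetic_realistic_pdb):
    model = read_structure(synthetic_realistic_pdb, keep_het=True)
    names = [a.name for r in model.chains["B"] for a in r.atoms]
    assert "ZN" in names
    assert not any(r.aa == "X" and r.seq_num == 101 for r in model.chains["B"])  # water still out


def test_altloc_tie_breaks_lexicographically(tmp_path):
    lines = [
        _atom_line(1, "CA", "B", "ALA", "A", 1, " ", 1.0, 0.0, 0.0, 0.5, "C"),
        _atom_line(2, "CA", "A", "ALA", "A", 1, " ", 2.0, 0.0, 0.0, 0.5, "C"),
    ]
    model = read_structure(_write_pdb(tmp_path / "tie.pdb", lines))
    assert model.chains["A"][0].atoms[0].coord[0] == pytest.approx(2.0)


def test_gap_arithmetic(tmp_path):
    lines = [
        _atom_line(i, "CA", " ", "ALA", "A", n, " ", n * 3.8, 0.0, 0.0, 1.0, "C")
        for i, n in enumerate(list(range(1, 11)) + list(range(15, 21)), start=1)
    ]
    model = read_structure(_write_pdb(tmp_path / "gap.pdb", lines))
    assert model.missing_segments["A"] == [(11, 14)]


def test_empty_and_unparseable_errors(tmp_path):
    no_atoms = tmp_path / "empty.pdb"
    no_atoms.write_text("HEADER    NOTHING\nEND\n")
    with pytest.raises(StructureError, match="empty structure"):
        read_structure(no_atoms)

    bad = tmp_path / "bad.pdb"
    good = _atom_line(1, "CA", " ", "ALA", "A", 1, " ", 0.0, 0.0, 0.0, 1.0, "C")
    bad.write_text(good + "\nATOM      2  CA  ALA A   2      xx.xxx   0.000   0.000\nEND\n")
    with pytest.raises(StructureError, match="line 2"):
        read_structure(bad)


def test_chain_sequence_errors_and_bijectivity(toy_pdb):
    model = read_structure(toy_pdb)
    with pytest.raises(KeyError, match="available"):
        chain_sequence(model, "Z")
    seq, index_map = chain_sequence(model, "A")
    positions = [p for p, _, _ in index_map]
    assert positions == list(range(1, len(seq) + 1))
    assert len({(n, i) for _, n, i in index_map}) == len(seq)


def test_fixture_index_maps_are_bijective(all_fixture_models):
    for model, _ in all_fixture_models.values():
        total = 0
        for cid in model.chains:
            seq, index_map = chain_sequence(model, cid)
            assert len(seq) == len(index_map) == len(model.chains[cid])
            assert len({(n, i) for _, n, i in index_map}) == len(seq)
            total += len(seq)
        assert total == model.n_residues
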