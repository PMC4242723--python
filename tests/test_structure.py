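"""Structure model: torsion <-> Cartesian round trips, PDB I/O fidelity,
polar-hydrogen topology building and its invariants."""

import numpy as np
import pytest

from loopcsa import topology as topo
from loopcsa.geom import dihedral
from loopcsa.structure import (LoopDefinition, StructureError,
                               build_chain_from_torsions,
                               build_polar_hydrogen_topology, closure_error,
                               coords_from_torsions, read_pdb,
                               torsions_from_coords, write_pdb)

# expected atom counts in the polar-hydrogen model (N, CA, C, O, amide H,
# side chain incl. polar H), assembled independently from the chemistry
POLAR_H_ATOM_COUNTS = {
    "GLY": 5, "ALA": 6, "SER": 8, "CYS": 8, "THR": 9, "VAL": 8,
    "LEU": 9, "ILE": 9, "MET": 9, "PRO": 7, "PHE": 12, "TYR": 14,
    "TRP": 16, "HIS": 12, "ASP": 9, "GLU": 10, "ASN": 11, "GLN": 12,
    "LYS": 13, "ARG": 17,
}


def test_build_measures_round_trip(chain20, loop8, native_torsions):
    rebuilt = coords_from_torsions(chain20, loop8, native_torsions)
    ts2 = torsions_from_coords(rebuilt, loop8)
    assert np.max(np.abs(ts2.phi - native_torsions.phi)) < 1e-6
    assert np.max(np.abs(ts2.psi - native_torsions.psi)) < 1e-6
    # built at ideal geometry, the rebuild reproduces coordinates exactly
    for i in loop8.indices:
        for nm in ("N", "CA", "C", "O"):
            d = np.linalg.norm(rebuilt.atom("A", i, nm).pos
                               - chain20.atom("A", i, nm).pos)
            assert d < 1e-9


def test_native_state_is_closed(chain20, loop8, native_torsions):
    assert closure_error(chain20, loop8, native_torsions) < 1e-9


def test_extended_chain_end_to_end_span():
    # all-trans backbone: CA-CA span grows by ~3.5 A per residue
    for n in (5, 8, 12):
        st = build_chain_from_torsions("A" * n, np.full(n, 180.0),
                                       np.full(n, 180.0))
        ca = [st.atom("A", i, "CA").pos for i in range(1, n + 1)]
        span = np.linalg.norm(ca[-1] - ca[0])
        assert abs(span / (n - 1) - 3.6) < 0.3


def test_pdb_round_trip(tmp_path, chain20):
    path = tmp_path / "chain.pdb"
    write_pdb(chain20, path)
    back = read_pdb(path)
    for cid, r in back.iter_residues():
        for a in r.atoms:
            ref = chain20.atom(cid, r.index, a.name).pos
            assert np.max(np.abs(a.pos - ref)) <= 1e-3 + 1e-9


def test_write_ter_between_chains(tmp_path, chain20):
    two = chain20.copy()
    second = [r.copy() for r in chain20.residues("A")[:4]]
    for r in second:
        for a in r.atoms:
            a.pos = a.pos + np.array([40.0, 0.0, 0.0])
    two.chains["B"] = second
    path = tmp_path / "two.pdb"
    write_pdb(two, path)
    text = path.read_text()
    assert text.count("TER") >= 2
    assert len(read_pdb(path).chains) == 2


def test_empty_structure_write_rejected(tmp_path):
    from loopcsa.structure import ProteinStructure
    with pytest.raises(StructureError):
        write_pdb(ProteinStructure(), tmp_path / "empty.pdb")


def test_altloc_highest_occupancy(tmp_path):
    lines = [
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
        "ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C",
        "ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O",
        "ATOM      5  CB AALA A   1       2.000  -1.000   1.000  0.60  0.00           C",
        "ATOM      6  CB BALA A   1       2.000  -1.000  -1.000  0.40  0.00           C",
        "END",
    ]
    path = tmp_path / "alt.pdb"
    path.write_text("\n".join(lines) + "\n")
    st = read_pdb(path)
    cb = st.atom("A", 1, "CB")
    assert cb.pos[2] == pytest.approx(1.0)  # the 0.60-occupancy conformer


def test_missing_backbone_atom_names_residue(tmp_path):
    lines = [
        "ATOM      1  N   ALA A   7       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  C   ALA A   7       2.009   1.420   0.000  1.00  0.00           C",
        "ATOM      3  O   ALA A   7       1.251   2.390   0.000  1.00  0.00           O",
        "END",
    ]
    path = tmp_path / "bad.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(StructureError, match="ALA A:7"):
        read_pdb(path)


def test_topology_idempotent_and_atom_counts(chain20):
    once = build_polar_hydrogen_topology(chain20)
    twice = build_polar_hydrogen_topology(once)
    assert once.n_atoms == twice.n_atoms
    for cid, r in once.iter_residues():
        expected = POLAR_H_ATOM_COUNTS[r.name]
        if r.index == 1 and r.name != "PRO":
            pass  # N-terminal residue still carries a single amide H here
        assert len(r.atoms) == expected, r


def test_proline_has_no_amide_h(chain20):
    pro = [r for _, r in chain20.iter_residues() if r.name == "PRO"]
    assert pro and all(not r.has_atom("H") for r in pro)


def test_serine_hydroxyl_geometry(chain20):
    ser = next(r for _, r in chain20.iter_residues() if r.name == "SER")
    d = np.linalg.norm(ser.atom("HG").pos - ser.atom("OG").pos)
    assert d == pytest.approx(0.96, abs=1e-6)


def test_sidechain_rebuild_from_missing_atoms(chain20):
    st = chain20.copy()
    lys = next(r for _, r in st.iter_residues() if r.name == "LYS")
    lys.remove_atom("NZ")
    lys.remove_atom("CE")
    rebuilt = build_polar_hydrogen_topology(st)
    r2 = rebuilt.residue("A", lys.index)
    assert r2.has_atom("NZ") and r2.has_atom("CE")


def test_cis_proline_flag():
    n = 6
    seq = "AAPAAA"
    omega = np.full(n, 180.0)
    omega[1] = 0.0  # bond preceding the proline (residue 3)
    st = build_chain_from_torsions(seq, np.full(n, -70.0), np.full(n, 150.0),
                                   omega)
    assert st.residue("A", 3).is_cis_proline


def test_glycine_has_no_chi(chain20):
    gly = next(r for _, r in chain20.iter_residues() if r.name == "GLY")
    assert gly.chi_definitions == []


def test_loop_definition_validation(chain20):
    with pytest.raises(StructureError):
        LoopDefinition("A", 1, 2).validate(chain20)   # too short + no anchor
    with pytest.raises(StructureError):
        LoopDefinition("A", 19, 22).validate(chain20)  # anchor 23 missing
    LoopDefinition("A", 6, 13).validate(chain20)
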