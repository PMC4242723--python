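"""Residue topology templates for the polar-hydrogen (united-atom) model.

Each standard amino acid is described by:

* ``sidechain``: internal-coordinate entries ``(name, cls, (a, b, c), bond,
  angle, dih)`` placing side-chain atoms (and side-chain polar hydrogens)
  from three previously placed reference atoms.  ``dih`` is either a fixed
  dihedral in degrees or ``("chi", k, offset)`` meaning rotatable torsion
  ``chi_k + offset``.
* ``chi``: the 4-atom-name tuples defining each rotatable chi torsion.
* ``bonds``: covalent bonds beyond the backbone N-CA, CA-C, C-O set.
* ``rotamer``: chi values (deg) of the most common rotamer, used when side
  chains must be rebuilt from scratch.

Aliphatic and aromatic carbons are united atoms (their hydrogens are
implicit and the carbon radii correspondingly enlarged); only hydrogens on
N, O and S are explicit.  Atom classes index into the packaged parameter
table (charge, vdW rmin/2, well depth, surface tension).
"""

from __future__ import annotations

# --- ideal backbone geometry (lengths in Angstrom, angles in degrees) ----
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 0.997
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_CA_N_H = 118.2
# CB placement relative to the backbone (L-chirality)
CB_BOND = 1.530
CB_ANGLE = 110.4          # N-CA-CB
CB_DIH = -122.69          # dihedral C-N-CA-CB (L-chirality)

BACKBONE_CLASSES = {"N": "NH1", "CA": "CT1", "C": "C", "O": "O", "H": "H"}

STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


def _chi(k: int, off: float = 0.0):
    return ("chi", k, off)


# (name, class, (a, b, c), bond, angle, dihedral-spec); CB entries use the
# shared backbone reference and are inserted automatically.
_CB = ("CB", None, ("C", "N", "CA"), CB_BOND, CB_ANGLE, CB_DIH)


def _cb(cls):
    return ("CB", cls) + _CB[2:]


RESIDUE_TEMPLATES = {
    "GLY": {"sidechain": [], "chi": [], "bonds": [], "rotamer": []},
    "ALA": {"sidechain": [_cb("CT3")], "chi": [], "bonds": [("CA", "CB")], "rotamer": []},
    "SER": {
        "sidechain": [
            _cb("CT2P"),
            ("OG", "OH1", ("N", "CA", "CB"), 1.417, 110.8, _chi(1)),
            ("HG", "HO", ("CA", "CB", "OG"), 0.96, 108.5, 180.0),
        ],
        "chi": [("N", "CA", "CB", "OG")],
        "bonds": [("CA", "CB"), ("CB", "OG"), ("OG", "HG")],
        "rotamer": [-65.0],
    },
    "CYS": {
        "sidechain": [
            _cb("CT2P"),
            ("SG", "S1", ("N", "CA", "CB"), 1.808, 113.8, _chi(1)),
            ("HG", "HS", ("CA", "CB", "SG"), 1.33, 96.0, 180.0),
        ],
        "chi": [("N", "CA", "CB", "SG")],
        "bonds": [("CA", "CB"), ("CB", "SG"), ("SG", "HG")],
        "rotamer": [-65.0],
    },
    "THR": {
        "sidechain": [
            _cb("CT1P"),
            ("OG1", "OH1", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
            ("CG2", "CT3", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0)),
            ("HG1", "HO", ("CA", "CB", "OG1"), 0.96, 108.5, 180.0),
        ],
        "chi": [("N", "CA", "CB", "OG1")],
        "bonds": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2"), ("OG1", "HG1")],
        "rotamer": [-60.0],
    },
    "VAL": {
        "sidechain": [
            _cb("CT1S"),
            ("CG1", "CT3", ("N", "CA", "CB"), 1.521, 110.5, _chi(1)),
            ("CG2", "CT3", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, 122.0)),
        ],
        "chi": [("N", "CA", "CB", "CG1")],
        "bonds": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
        "rotamer": [175.0],
    },
    "LEU": {
        "sidechain": [
            _cb("CT2"),
            ("CG", "CT1S", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
            ("CD1", "CT3", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
            ("CD2", "CT3", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 122.0)),
        ],
        "chi": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
        "bonds": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
        "rotamer": [-65.0, 175.0],
    },
    "ILE": {
        "sidechain": [
            _cb("CT1S"),
            ("CG1", "CT2", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
            ("CG2", "CT3", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
            ("CD1", "CT3", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2)),
        ],
        "chi": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
        "bonds": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
        "rotamer": [-65.0, 170.0],
    },
    "MET": {
        "sidechain": [
            _cb("CT2"),
            ("CG", "CT2P", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
            ("CE", "CT3", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3)),
        ],
        "chi": [
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE"),
        ],
        "bonds": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
        "rotamer": [-65.0, 180.0, 75.0],
    },
    "PRO": {
        # ring fixed at a common up-pucker; chi not treated as rotatable
        "sidechain": [
            _cb("CT2"),
            ("CG", "CT2", ("N", "CA", "CB"), 1.492, 104.5, 25.0),
            ("CD", "CT2", ("CA", "CB", "CG"), 1.503, 106.1, -38.0),
        ],
        "chi": [],
        "bonds": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
        "rotamer": [],
    },
    "PHE": {
        "sidechain": [
            _cb("CT2"),
            ("CG", "CAN", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
            ("CD1", "CAH", ("CA", "CB", "CG"), 1.384, 120.3, _chi(2)),
            ("CD2", "CAH", ("CA", "CB", "CG"), 1.384, 120.3, _chi(2, 180.0)),
            ("CE1", "CAH", ("CB", "CG", "CD1"), 1.384, 120.6, 180.0),
            ("CE2", "CAH", ("CB", "CG", "CD2"), 1.384, 120.6, 180.0),
            ("CZ", "CAH", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
        ],
        "chi": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
        "bonds": [
            ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
        ],
        "rotamer": [-65.0, 90.0],
    },
    "TYR": {
        "sidechain": [
            _cb("CT2"),
            ("CG", "CAN", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
            ("CD1", "CAH", ("CA", "CB", "CG"), 1.384, 120.3, _chi(2)),
            ("CD2", "CAH", ("CA", "CB", "CG"), 1.384, 120.3, _chi(2, 180.0)),
            ("CE1", "CAH", ("CB", "CG", "CD1"), 1.384, 120.6, 180.0),
            ("CE2", "CAH", ("CB", "CG", "CD2"), 1.384, 120.6, 180.0),
            ("CZ", "CAP", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
            ("OH", "OH1", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
            ("HH", "HO", ("CE1", "CZ", "OH"), 0.96, 109.0, 180.0),
        ],
        "chi": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
        "bonds": [
            ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH"), ("OH", "HH"),
        ],
        "rotamer": [-65.0, 90.0],
    },
    "TRP": {
        "sidechain": [
            _cb("CT2"),
            ("CG", "CAN", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
            ("CD1", "CAH", ("CA", "CB", "CG"), 1.365, 126.9, _chi(2)),
            ("CD2", "CAN", ("CA", "CB", "CG"), 1.433, 126.7, _chi(2, 180.0)),
            ("NE1", "NH1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
            ("CE2", "CAN", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
            ("CE3", "CAH", ("CD1", "CG", "CD2"), 1.398, 133.9, 180.0),
            ("CZ2", "CAH", ("CG", "CD2", "CE2"), 1.398, 122.4, 180.0),
            ("CZ3", "CAH", ("CE2", "CD2", "CE3"), 1.382, 118.8, 0.0),
            ("CH2", "CAH", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0),
            ("HE1", "H", ("CG", "CD1", "NE1"), 1.01, 125.0, 180.0),
        ],
        "chi": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
        "bonds": [
            ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2"),
            ("NE1", "HE1"),
        ],
        "rotamer": [-65.0, 95.0],
    },
    "HIS": {
        # neutral N-delta-H tautomer; NE2 is the ring acceptor
        "sidechain": [
            _cb("CT2"),
            ("CG", "CAN", ("N", "CA", "CB"), 1.497, 113.8, _chi(1)),
            ("ND1", "NH1", ("CA", "CB", "CG"), 1.371, 122.7, _chi(2)),
            ("CD2", "CAH", ("CA", "CB", "CG"), 1.356, 131.0, _chi(2, 180.0)),
            ("CE1", "CRP", ("CB", "CG", "ND1"), 1.319, 109.0, 180.0),
            ("NE2", "NR", ("CB", "CG", "CD2"), 1.374, 107.0, 180.0),
            ("HD1", "H", ("CB", "CG", "ND1"), 1.01, 126.0, 0.0),
        ],
        "chi": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
        "bonds": [
            ("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CE1", "NE2"), ("CD2", "NE2"), ("ND1", "HD1"),
        ],
        "rotamer": [-65.0, 90.0],
    },
    "ASP": {
        "sidechain": [
            _cb("CT2"),
            ("CG", "CCARB", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", "OC", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
            ("OD2", "OC", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0)),
        ],
        "chi": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
        "bonds": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
        "rotamer": [-70.0, -15.0],
    },
    "GLU": {
        "sidechain": [
            _cb("CT2"),
            ("CG", "CT2", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", "CCARB", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", "OC", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
            ("OE2", "OC", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0)),
        ],
        "chi": [
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1"),
        ],
        "bonds": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
        "rotamer": [-65.0, 180.0, -10.0],
    },
    "ASN": {
        "sidechain": [
            _cb("CT2"),
            ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
            ("ND2", "NH2", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0)),
            ("HD21", "H", ("OD1", "CG", "ND2"), 1.00, 119.0, 180.0),
            ("HD22", "H", ("OD1", "CG", "ND2"), 1.00, 119.0, 0.0),
        ],
        "chi": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
        "bonds": [
            ("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2"),
            ("ND2", "HD21"), ("ND2", "HD22"),
        ],
        "rotamer": [-65.0, -20.0],
    },
    "GLN": {
        "sidechain": [
            _cb("CT2"),
            ("CG", "CT2", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
            ("NE2", "NH2", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0)),
            ("HE21", "H", ("OE1", "CD", "NE2"), 1.00, 119.0, 180.0),
            ("HE22", "H", ("OE1", "CD", "NE2"), 1.00, 119.0, 0.0),
        ],
        "chi": [
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1"),
        ],
        "bonds": [
            ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2"), ("NE2", "HE21"), ("NE2", "HE22"),
        ],
        "rotamer": [-65.0, 180.0, 0.0],
    },
    "LYS": {
        "sidechain": [
            _cb("CT2"),
            ("CG", "CT2", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", "CT2", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("CE", "CT2P", ("CB", "CG", "CD"), 1.520, 111.3, _chi(3)),
            ("NZ", "NH3", ("CG", "CD", "CE"), 1.489, 112.0, _chi(4)),
            ("HZ1", "HC", ("CD", "CE", "NZ"), 1.04, 109.5, 180.0),
            ("HZ2", "HC", ("CD", "CE", "NZ"), 1.04, 109.5, 60.0),
            ("HZ3", "HC", ("CD", "CE", "NZ"), 1.04, 109.5, -60.0),
        ],
        "chi": [
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"),
            ("CG", "CD", "CE", "NZ"),
        ],
        "bonds": [
            ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ"), ("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3"),
        ],
        "rotamer": [-65.0, 180.0, 180.0, 180.0],
    },
    "ARG": {
        "sidechain": [
            _cb("CT2"),
            ("CG", "CT2", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", "CT2P", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("NE", "NC2", ("CB", "CG", "CD"), 1.461, 112.0, _chi(3)),
            ("CZ", "CR", ("CG", "CD", "NE"), 1.329, 124.2, _chi(4)),
            ("NH1", "NC2", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", "NC2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
            ("HE", "HC", ("CG", "CD", "NE"), 1.00, 118.0, _chi(4, 180.0)),
            ("HH11", "HC", ("NE", "CZ", "NH1"), 1.00, 120.0, 0.0),
            ("HH12", "HC", ("NE", "CZ", "NH1"), 1.00, 120.0, 180.0),
            ("HH21", "HC", ("NE", "CZ", "NH2"), 1.00, 120.0, 0.0),
            ("HH22", "HC", ("NE", "CZ", "NH2"), 1.00, 120.0, 180.0),
        ],
        "chi": [
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"),
            ("CG", "CD", "NE", "CZ"),
        ],
        "bonds": [
            ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2"), ("NE", "HE"),
            ("NH1", "HH11"), ("NH1", "HH12"), ("NH2", "HH21"), ("NH2", "HH22"),
        ],
        "rotamer": [-65.0, 180.0, 180.0, 180.0],
    },
}

# residue-specific atom-class overrides for backbone atoms
BACKBONE_CLASS_OVERRIDES = {"PRO": {"N": "NP"}}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def element_of(atom_name: str) -> str:
    """Chemical element inferred from a PDB atom name."""
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[0].upper()


def heavy_sidechain_atoms(resname: str):
    """Ordered heavy side-chain atom names for a standard residue."""
    tpl = RESIDUE_TEMPLATES[resname]
    return [e[0] for e in tpl["sidechain"] if element_of(e[0]) != "H"]


def polar_hydrogens(resname: str):
    """Side-chain polar-hydrogen names (backbone amide H excluded)."""
    tpl = RESIDUE_TEMPLATES[resname]
    return [e[0] for e in tpl["sidechain"] if element_of(e[0]) == "H"]


def expected_atom_names(resname: str, has_amide_h: bool = True):
    """Full polar-hydrogen-model atom list for one residue."""
    names = ["N", "CA", "C", "O"]
    if has_amide_h and resname != "PRO":
        names.append("H")
    names += [e[0] for e in RESIDUE_TEMPLATES[resname]["sidechain"]]
    return names
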