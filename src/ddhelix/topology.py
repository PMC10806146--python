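"""Amino-acid heavy-atom topology: ideal internal coordinates, bonds, chi
torsions, van der Waals radii and the reduced charge model.

Side chains are described as z-matrix rows ``(atom, (a, b, c), bond, angle,
torsion)``: the atom is bonded to ``c`` and placed by
:func:`ddhelix.geometry.place_atom`.  Torsions are either numbers (degrees,
fixed ring geometry) or the strings ``"chi1"``..``"chi4"`` optionally with a
``+120``/``-120``/``+180`` branch offset; chi torsions default to the
extended value of 180 degrees.  Values are generic ideal-geometry numbers
(bond lengths to ~0.01 A, angles to ~1 degree), adequate for rigid-body
modelling; no claim of force-field fidelity is made.
"""
from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# CB placement from the backbone, L-chirality: torsion dihedral(C, N, CA, CB).
CB_INTERNAL = {"refs": ("C", "N", "CA"), "bond": 1.53, "angle": 110.6, "torsion": -122.7}

# fmt: off
SIDECHAIN_ZMATRIX = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG",  ("N", "CA", "CB"), 1.41, 110.8, "chi1")],
    "CYS": [("SG",  ("N", "CA", "CB"), 1.81, 114.4, "chi1")],
    "THR": [("OG1", ("N", "CA", "CB"), 1.43, 109.6, "chi1"),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, "chi1-120")],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.52, 110.5, "chi1"),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, "chi1+120")],
    "LEU": [("CG",  ("N", "CA", "CB"), 1.53, 116.3, "chi1"),
            ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, "chi2"),
            ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, "chi2+120")],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.53, 110.4, "chi1"),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, "chi1-120"),
            ("CD1", ("CA", "CB", "CG1"), 1.52, 113.9, "chi2")],
    "MET": [("CG",  ("N", "CA", "CB"), 1.52, 114.1, "chi1"),
            ("SD",  ("CA", "CB", "CG"), 1.80, 112.7, "chi2"),
            ("CE",  ("CB", "CG", "SD"), 1.79, 100.8, "chi3")],
    # proline ring torsions are fixed near closure; the ring is not rotatable
    "PRO": [("CG",  ("N", "CA", "CB"), 1.50, 104.5, 12.0),
            ("CD",  ("CA", "CB", "CG"), 1.51, 106.1, -17.0)],
    "PHE": [("CG",  ("N", "CA", "CB"), 1.51, 113.8, "chi1"),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, "chi2"),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, "chi2+180"),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
            ("CZ",  ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0)],
    "TYR": [("CG",  ("N", "CA", "CB"), 1.51, 113.8, "chi1"),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, "chi2"),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, "chi2+180"),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
            ("CZ",  ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
            ("OH",  ("CD1", "CE1", "CZ"), 1.38, 119.9, 180.0)],
    "TRP": [("CG",  ("N", "CA", "CB"), 1.50, 113.6, "chi1"),
            ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, "chi2"),
            ("CD2", ("CA", "CB", "CG"), 1.43, 126.5, "chi2+180"),
            ("NE1", ("CB", "CG", "CD1"), 1.38, 110.1, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.41, 107.3, 180.0),
            ("CE3", ("CB", "CG", "CD2"), 1.40, 133.8, 0.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.6, 180.0),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0)],
    "HIS": [("CG",  ("N", "CA", "CB"), 1.50, 113.8, "chi1"),
            ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, "chi2"),
            ("CD2", ("CA", "CB", "CG"), 1.36, 131.1, "chi2+180"),
            ("CE1", ("CB", "CG", "ND1"), 1.32, 109.2, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, 180.0)],
    "ASP": [("CG",  ("N", "CA", "CB"), 1.52, 113.0, "chi1"),
            ("OD1", ("CA", "CB", "CG"), 1.25, 118.2, "chi2"),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.2, "chi2+180")],
    "ASN": [("CG",  ("N", "CA", "CB"), 1.52, 112.7, "chi1"),
            ("OD1", ("CA", "CB", "CG"), 1.23, 120.9, "chi2"),
            ("ND2", ("CA", "CB", "CG"), 1.33, 116.5, "chi2+180")],
    "GLU": [("CG",  ("N", "CA", "CB"), 1.52, 114.1, "chi1"),
            ("CD",  ("CA", "CB", "CG"), 1.52, 112.6, "chi2"),
            ("OE1", ("CB", "CG", "CD"), 1.25, 118.2, "chi3"),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.2, "chi3+180")],
    "GLN": [("CG",  ("N", "CA", "CB"), 1.52, 114.1, "chi1"),
            ("CD",  ("CA", "CB", "CG"), 1.52, 112.6, "chi2"),
            ("OE1", ("CB", "CG", "CD"), 1.23, 120.9, "chi3"),
            ("NE2", ("CB", "CG", "CD"), 1.33, 116.5, "chi3+180")],
    "LYS": [("CG",  ("N", "CA", "CB"), 1.52, 114.1, "chi1"),
            ("CD",  ("CA", "CB", "CG"), 1.52, 111.3, "chi2"),
            ("CE",  ("CB", "CG", "CD"), 1.52, 111.3, "chi3"),
            ("NZ",  ("CG", "CD", "CE"), 1.49, 111.9, "chi4")],
    "ARG": [("CG",  ("N", "CA", "CB"), 1.52, 114.1, "chi1"),
            ("CD",  ("CA", "CB", "CG"), 1.52, 111.3, "chi2"),
            ("NE",  ("CB", "CG", "CD"), 1.46, 112.0, "chi3"),
            ("CZ",  ("CG", "CD", "NE"), 1.33, 124.2, "chi4"),
            ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0)],
}
# fmt: on

# ring-closure bonds not implied by the z-matrix parent relation
RING_CLOSURE_BONDS = {
    "PHE": [("CE2", "CZ")],
    "TYR": [("CE2", "CZ")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
    "HIS": [("CE1", "NE2")],
    "PRO": [("CD", "N")],
}

# chi torsion atom quadruples, in rotation order
CHI_ATOMS = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}


def element_of(atom_name: str) -> str:
    """Element symbol from a standard PDB protein atom name."""
    name = atom_name.strip()
    if name.startswith(("1", "2", "3")):
        name = name[1:]
    return name[0]


def residue_bonds(resname: str) -> list[tuple[str, str]]:
    """Covalent heavy-atom bonds within one residue (backbone + side chain)."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    if resname != "GLY":
        bonds.append(("CA", "CB"))
    for atom, refs, _, _, _ in SIDECHAIN_ZMATRIX.get(resname, []):
        bonds.append((refs[2], atom))
    bonds.extend(RING_CLOSURE_BONDS.get(resname, []))
    return bonds


# Bondi-style heavy-atom van der Waals radii, Angstrom
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

# generic per-element well depths, kcal/mol; pair r_min = r_i + r_j
LJ_EPSILON = {"C": 0.11, "N": 0.17, "O": 0.21, "S": 0.25}

# reduced charge model: one unit charge on the side-chain tip of the four
# ionizable residues, backbone and everything else neutral
PARTIAL_CHARGES = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "CZ"): 1.0,
    ("ASP", "CG"): -1.0,
    ("GLU", "CD"): -1.0,
}
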