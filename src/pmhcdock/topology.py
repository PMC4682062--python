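"""Amino-acid heavy-atom topology and ideal side-chain internal coordinates.

The tables here drive three things:

* the canonical atom ordering used by :func:`pmhcdock.structure_io.select_atoms`
  so that two structures with the same sequence yield positionally
  corresponding atom lists;
* the heavy-atom completeness audit applied to threaded peptides;
* side-chain construction during threading, as internal coordinates
  (bond length r in Angstrom, bond angle theta in degrees, torsion tau in
  degrees) resolved by the NeRF placement rule.

Side chains are built in a single, most-common rotamer (chi1 = -60 deg
gauche-, aliphatic chi2+ = trans, ring torsions planar); the docking stage,
not the builder, is responsible for exploring side-chain conformations.
"""

from __future__ import annotations

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")
TERMINAL_OXYGEN = "OXT"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

#: Non-standard residues mapped to their standard parent during sanitization.
NONSTANDARD_PARENT = {
    "MSE": "MET",  # selenomethionine
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "CSO": "CYS",
    "CME": "CYS",
    "KCX": "LYS",
}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# chi1 reference torsion (N-CA-CB-X) and common geometric constants
_CHI1 = -60.0

# Each entry: (atom_name, (a, b, c), r, theta, tau) placing the atom D with
# |D-c| = r, angle(b,c,D) = theta and dihedral(a,b,c,D) = tau. CB is listed
# first for every non-Gly residue; remaining atoms follow PDB canonical order.
_CB = ("CB", ("C", "N", "CA"), 1.530, 110.5, -122.6)

SIDE_CHAIN_ICS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.417, 110.8, _CHI1)],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.808, 113.8, _CHI1)],
    "THR": [_CB,
            ("OG1", ("N", "CA", "CB"), 1.433, 109.6, 60.0),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, -60.0)],
    "VAL": [_CB,
            ("CG1", ("N", "CA", "CB"), 1.527, 110.5, _CHI1),
            ("CG2", ("N", "CA", "CB"), 1.527, 110.5, _CHI1 + 122.0)],
    "LEU": [_CB,
            ("CG", ("N", "CA", "CB"), 1.530, 116.3, _CHI1),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 175.0),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, 175.0 + 120.0)],
    "ILE": [_CB,
            ("CG1", ("N", "CA", "CB"), 1.530, 110.4, _CHI1),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _CHI1 + 122.0),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, 170.0)],
    "MET": [_CB,
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, _CHI1),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.9, 180.0)],
    "PRO": [_CB,
            ("CG", ("N", "CA", "CB"), 1.492, 104.5, 30.0),
            ("CD", ("CA", "CB", "CG"), 1.503, 106.1, -35.0)],
    "PHE": [_CB,
            ("CG", ("N", "CA", "CB"), 1.502, 113.8, _CHI1),
            ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, 90.0 + 180.0),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0)],
    "TYR": [_CB,
            ("CG", ("N", "CA", "CB"), 1.512, 113.9, _CHI1),
            ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, 90.0 + 180.0),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "TRP": [_CB,
            ("CG", ("N", "CA", "CB"), 1.498, 113.6, _CHI1),
            ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, 90.0 + 180.0),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
            ("CE3", ("CD1", "CG", "CD2"), 1.398, 133.9, 180.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
            ("CZ3", ("CE2", "CD2", "CE3"), 1.382, 118.7, 0.0),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0)],
    "ASP": [_CB,
            ("CG", ("N", "CA", "CB"), 1.516, 113.0, _CHI1),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, -20.0),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, -20.0 + 180.0)],
    "ASN": [_CB,
            ("CG", ("N", "CA", "CB"), 1.516, 112.7, _CHI1),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.9, -60.0),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.5, -60.0 + 180.0)],
    "GLU": [_CB,
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, _CHI1),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, -20.0),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, -20.0 + 180.0)],
    "GLN": [_CB,
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, _CHI1),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.9, -60.0),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.5, -60.0 + 180.0)],
    "HIS": [_CB,
            ("CG", ("N", "CA", "CB"), 1.497, 113.8, _CHI1),
            ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.354, 131.0, 90.0 + 180.0),
            ("CE1", ("CB", "CG", "ND1"), 1.321, 109.2, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0)],
    "LYS": [_CB,
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, _CHI1),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, 180.0)],
    "ARG": [_CB,
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, _CHI1),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
            ("NE", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
            ("CZ", ("CG", "CD", "NE"), 1.329, 124.5, 180.0),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
}

#: Heavy atoms expected for a complete residue, in canonical PDB order.
HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    res: BACKBONE_ATOMS + tuple(entry[0] for entry in ics)
    for res, ics in SIDE_CHAIN_ICS.items()
}

#: Canonical ordering index per residue; OXT sorts after every named atom.
_ORDER_INDEX = {
    res: {name: i for i, name in enumerate(names)}
    for res, names in HEAVY_ATOMS.items()
}


def atom_sort_key(residue_name: str, atom_name: str) -> tuple[int, str]:
    """Sort key giving the canonical heavy-atom order within a residue."""
    idx = _ORDER_INDEX.get(residue_name, {})
    if atom_name in idx:
        return (idx[atom_name], atom_name)
    if atom_name == TERMINAL_OXYGEN:
        return (len(idx), atom_name)
    return (len(idx) + 1, atom_name)  # unknown names last, alphabetical


def heavy_atom_count(residue_name: str) -> int:
    return len(HEAVY_ATOMS[residue_name])


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               r: float, theta_deg: float, tau_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms a-b-c (NeRF).

    |D - c| = r, angle(b, c, D) = theta, dihedral(a, b, c, D) = tau.
    """
    theta = np.deg2rad(theta_deg)
    tau = np.deg2rad(tau_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        # a-b-c collinear: pick an arbitrary perpendicular, deterministic
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, bc)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        n = np.cross(ref, bc)
        n_norm = np.linalg.norm(n)
    n /= n_norm
    m = np.cross(n, bc)
    d_local = np.array([
        -r * np.cos(theta),
        r * np.sin(theta) * np.cos(tau),
        -r * np.sin(theta) * np.sin(tau),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
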