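"""Amino-acid chemistry tables: ideal geometry, rotamers, radii, charges.

Ideal residue geometry (coordinates and bond graphs) comes from the Chemical
Component Dictionary templates bundled with biotite.  Side chains are built by
superposing the template on the actual backbone triad (N, CA, C) and applying
chi rotations about the standard rotatable bonds.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import biotite.structure.info as struc_info

from . import geometry

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# van der Waals radii by element (Å)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}
DEFAULT_RADIUS = 1.70

# Standard chi dihedrals (four atom names each).
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# Small backbone-independent rotamer set: most frequent chi combinations per
# residue type, first entry most common (used for tie breaking and for
# rebuilding atoms whose chi cannot be inferred).  PRO keeps the template
# pucker.
ROTAMERS = {
    "ALA": [()], "GLY": [()], "PRO": [()],
    "SER": [(-65.0,), (180.0,), (65.0,)],
    "CYS": [(-65.0,), (180.0,), (65.0,)],
    "THR": [(-60.0,), (60.0,), (180.0,)],
    "VAL": [(175.0,), (-60.0,), (65.0,)],
    "ILE": [(-65.0, 170.0), (-60.0, -60.0), (180.0, 165.0), (65.0, 170.0)],
    "LEU": [(-65.0, 175.0), (180.0, 65.0), (-85.0, 65.0), (180.0, 180.0)],
    "ASP": [(-70.0, -15.0), (180.0, 10.0), (65.0, -10.0)],
    "ASN": [(-65.0, -40.0), (180.0, -60.0), (65.0, -75.0), (180.0, 30.0)],
    "HIS": [(-65.0, -70.0), (180.0, 60.0), (65.0, -70.0), (-65.0, 165.0)],
    "PHE": [(-65.0, 95.0), (180.0, 80.0), (65.0, 90.0), (-65.0, -85.0)],
    "TYR": [(-65.0, 95.0), (180.0, 80.0), (65.0, 90.0), (-65.0, -85.0)],
    "TRP": [(-65.0, 95.0), (180.0, 80.0), (65.0, 90.0), (-65.0, -85.0)],
    "GLU": [(-65.0, 180.0, -10.0), (180.0, 180.0, 0.0),
            (-65.0, -65.0, -40.0), (180.0, 65.0, 10.0)],
    "GLN": [(-65.0, 180.0, -25.0), (180.0, 180.0, 0.0),
            (-65.0, -65.0, -40.0), (180.0, 65.0, 20.0)],
    "MET": [(-65.0, 180.0, 75.0), (-65.0, 180.0, -75.0),
            (180.0, 180.0, 75.0), (-65.0, -65.0, -70.0), (180.0, 65.0, 75.0)],
    "LYS": [(-65.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
            (-65.0, -65.0, 180.0, 180.0), (180.0, 180.0, 65.0, 180.0),
            (-65.0, 180.0, 180.0, 65.0)],
    "ARG": [(-65.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, -85.0),
            (-65.0, -65.0, 180.0, 180.0), (180.0, 180.0, 65.0, 85.0),
            (-65.0, 180.0, 65.0, 85.0)],
}

# Coarse partial charges for the screened-Coulomb terms: a neutral backbone
# dipole per residue, neutral polar-group dipoles, and formal charges of ±1
# smeared over the terminal heavy atoms of ionizable side chains.
_BACKBONE_CHARGE = {"N": -0.30, "CA": 0.10, "C": 0.50, "O": -0.30}
_SIDECHAIN_CHARGE = {
    ("ASP", "OD1"): -0.65, ("ASP", "OD2"): -0.65, ("ASP", "CG"): 0.30,
    ("GLU", "OE1"): -0.65, ("GLU", "OE2"): -0.65, ("GLU", "CD"): 0.30,
    ("LYS", "NZ"): 0.85, ("LYS", "CE"): 0.15,
    ("ARG", "NH1"): 0.45, ("ARG", "NH2"): 0.45, ("ARG", "NE"): 0.10,
    ("ASN", "CG"): 0.55, ("ASN", "OD1"): -0.45, ("ASN", "ND2"): -0.10,
    ("GLN", "CD"): 0.55, ("GLN", "OE1"): -0.45, ("GLN", "NE2"): -0.10,
    ("SER", "OG"): -0.35, ("SER", "CB"): 0.35,
    ("THR", "OG1"): -0.35, ("THR", "CB"): 0.35,
    ("TYR", "OH"): -0.35, ("TYR", "CZ"): 0.35,
    ("HIS", "ND1"): -0.25, ("HIS", "NE2"): -0.25, ("HIS", "CE1"): 0.50,
    ("TRP", "NE1"): -0.25, ("TRP", "CE2"): 0.25,
    ("CYS", "SG"): -0.10, ("CYS", "CB"): 0.10,
    ("MET", "SD"): -0.10, ("MET", "CE"): 0.10,
}


def charge_of(res_name: str, atom_name: str) -> float:
    """Coarse partial charge of a heavy atom (e units)."""
    if atom_name in _BACKBONE_CHARGE:
        return _BACKBONE_CHARGE[atom_name]
    return _SIDECHAIN_CHARGE.get((res_name, atom_name), 0.0)


def radius_of(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_RADIUS)


# Hydrogen-bond donor / acceptor heavy atoms (polar hydrogens are implicit).
_DONOR_ATOMS = {
    ("*", "N"),  # backbone amide (PRO excluded at call time)
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("TRP", "NE1"), ("CYS", "SG"),
}
_ACCEPTOR_ATOMS = {
    ("*", "O"),  # backbone carbonyl
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}


def is_donor(res_name: str, atom_name: str) -> bool:
    if atom_name == "N":
        return res_name != "PRO"
    return (res_name, atom_name) in _DONOR_ATOMS


def is_acceptor(res_name: str, atom_name: str) -> bool:
    return atom_name == "O" or (res_name, atom_name) in _ACCEPTOR_ATOMS


@lru_cache(maxsize=None)
def template(res_name: str):
    """Heavy-atom ideal template for a residue.

    Returns (names, coords, bonds) with OXT dropped; bonds is a list of
    (i, j) index pairs into the heavy-atom arrays.
    """
    res = struc_info.residue(res_name)
    if res is None:
        raise ValueError(f"unknown residue type: {res_name}")
    keep = (res.element != "H") & (res.atom_name != "OXT")
    idx_map = {}
    names, coords = [], []
    for i in np.where(keep)[0]:
        idx_map[i] = len(names)
        names.append(res.atom_name[i])
        coords.append(res.coord[i])
    bonds = []
    for i, j, _order in res.bonds.as_array():
        if i in idx_map and j in idx_map:
            bonds.append((idx_map[i], idx_map[j]))
    return tuple(names), np.asarray(coords, dtype=float), tuple(bonds)


def heavy_atom_names(res_name: str) -> tuple:
    return template(res_name)[0]


def side_chain_names(res_name: str) -> tuple:
    return tuple(n for n in heavy_atom_names(res_name)
                 if n not in BACKBONE_ATOMS)


@lru_cache(maxsize=None)
def _chi_machinery(res_name: str):
    """Per-chi (atom index quadruple, moving index tuple) for a residue."""
    names, _coords, bonds = template(res_name)
    index = {n: i for i, n in enumerate(names)}
    adj = {i: set() for i in range(len(names))}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    out = []
    for quad in CHI_ATOMS.get(res_name, []):
        ia, ib, ic, id_ = (index[q] for q in quad)
        # atoms that move when rotating about ib-ic: component of ic with the
        # ib-ic edge removed, minus ic itself (on the axis)
        seen = {ib, ic}
        stack = [x for x in adj[ic] if x != ib]
        moving = set()
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            moving.add(x)
            stack.extend(adj[x] - seen)
        out.append(((ia, ib, ic, id_), tuple(sorted(moving))))
    return tuple(out)


def n_chi(res_name: str) -> int:
    return len(CHI_ATOMS.get(res_name, []))


def build_side_chain(res_name: str, n_pos, ca_pos, c_pos, chis=None) -> dict:
    """Place side-chain heavy atoms (including CB) on a given backbone.

    The CCD template is rigidly fitted on (N, CA, C); the requested chi
    dihedrals (degrees) are then applied.  Returns {atom_name: xyz}.
    """
    names, coords, _bonds = template(res_name)
    index = {n: i for i, n in enumerate(names)}
    ref = np.array([n_pos, ca_pos, c_pos], dtype=float)
    mob = coords[[index["N"], index["CA"], index["C"]]]
    rot, trans, _rmsd = geometry.kabsch(mob, ref)
    placed = coords @ rot.T + trans
    # anchor the backbone reference atoms at their true positions so chi
    # values are exact with respect to the actual chain
    actual = {"N": np.asarray(n_pos, float), "CA": np.asarray(ca_pos, float),
              "C": np.asarray(c_pos, float)}
    for bb, pos in actual.items():
        placed[index[bb]] = pos

    def pos_of(i):
        return placed[i]

    if chis is None:
        chis = ROTAMERS[res_name][0]
    for chi_val, (quad, moving) in zip(chis, _chi_machinery(res_name)):
        ia, ib, ic, _id = quad
        current = geometry.dihedral(pos_of(ia), pos_of(ib),
                                    pos_of(ic), pos_of(_id))
        delta = np.deg2rad(chi_val) - current
        placed = geometry.rotate_about_axis(
            placed, placed[ib], placed[ic], delta, np.array(moving, dtype=int))
    return {names[i]: placed[i] for i in range(len(names))
            if names[i] not in BACKBONE_ATOMS}


@lru_cache(maxsize=None)
def ideal_internal(res_name: str):
    """Ideal bond lengths and bond angles measured on the CCD template.

    Returns (bonds, angles): bonds = ((name_a, name_b, length), ...);
    angles = ((name_a, name_b, name_c, degrees), ...) with b the vertex.
    """
    names, coords, bond_idx = template(res_name)
    adj = {i: set() for i in range(len(names))}
    for i, j in bond_idx:
        adj[i].add(j)
        adj[j].add(i)
    bonds = tuple(
        (names[i], names[j], float(np.linalg.norm(coords[i] - coords[j])))
        for i, j in bond_idx)
    angles = []
    for j in range(len(names)):
        neigh = sorted(adj[j])
        for a_i in range(len(neigh)):
            for c_i in range(a_i + 1, len(neigh)):
                i, k = neigh[a_i], neigh[c_i]
                ang = geometry.angle(coords[i], coords[j], coords[k])
                angles.append((names[i], names[j], names[k],
                               float(np.rad2deg(ang))))
    return bonds, tuple(angles)
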