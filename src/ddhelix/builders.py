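"""Construction of backbones and side chains from ideal internal coordinates.

The backbone builder produces N/CA/C/O traces from a (phi, psi) list; side
chains are grown beyond CB with the z-matrix tables in
:mod:`ddhelix.topology`, chi torsions defaulting to the extended 180-degree
rotamer.  These primitives back the threading stand-in, the synthetic
fixtures and the mutation operator.
"""
from __future__ import annotations

import numpy as np

from .geometry import dihedral_deg, place_atom, rotation_about_axis
from .structure import Residue, make_residue
from .topology import (CB_INTERNAL, CHI_ATOMS, SIDECHAIN_ZMATRIX,
                       residue_bonds)

__all__ = [
    "backbone_from_dihedrals", "build_cb", "sidechain_coords",
    "build_residue", "rebuild_sidechain", "get_chi", "set_chi",
    "chi_movable_atoms", "n_chi",
]

# ideal peptide internal coordinates
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_OMEGA = 180.0


def backbone_from_dihedrals(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone atom coordinates (N, CA, C, O per residue) for a dihedral list.

    The first residue's phi and the last residue's psi still orient O
    placement; omega is fixed trans.
    """
    out: list[dict[str, np.ndarray]] = []
    n_res = len(phi_psi)
    if n_res == 0:
        return out
    # seed residue 0 in a canonical frame
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    # torsion reference for the seed residue is arbitrary (fixes global frame)
    C = place_atom(np.array([0.0, 1.0, 0.0]), N, CA, _B_CA_C, _A_N_CA_C, 37.0)
    out.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n_res):
        prev = out[i - 1]
        psi_prev = phi_psi[i - 1][1]
        Nn = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        CAn = place_atom(prev["CA"], prev["C"], Nn, _B_N_CA, _A_C_N_CA, _OMEGA)
        Cn = place_atom(prev["C"], Nn, CAn, _B_CA_C, _A_N_CA_C, phi_psi[i][0])
        out.append({"N": Nn, "CA": CAn, "C": Cn})
    # carbonyl oxygens: anti to the next residue's N (psi + 180)
    for i, res in enumerate(out):
        psi = phi_psi[i][1]
        res["O"] = place_atom(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O,
                              psi + 180.0)
    return out


def build_cb(backbone: dict[str, np.ndarray]) -> np.ndarray:
    """CB position from N/CA/C with L-amino-acid chirality."""
    refs = CB_INTERNAL["refs"]
    return place_atom(backbone[refs[0]], backbone[refs[1]], backbone[refs[2]],
                      CB_INTERNAL["bond"], CB_INTERNAL["angle"],
                      CB_INTERNAL["torsion"])


def _resolve_torsion(spec, chi_values: dict[str, float]) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    name = spec[:4]
    base = chi_values.get(name, 180.0)
    offset = float(spec[4:]) if len(spec) > 4 else 0.0
    return base + offset


def sidechain_coords(resname: str, backbone: dict[str, np.ndarray],
                     chi: dict[str, float] | None = None) -> dict[str, np.ndarray]:
    """All side-chain heavy atoms (CB onward) for ``resname`` on a backbone.

    ``chi`` overrides individual torsions, e.g. ``{"chi1": -60.0}``; anything
    unspecified uses the extended default.
    """
    chi = chi or {}
    if resname == "GLY":
        return {}
    coords = dict(backbone)
    coords["CB"] = coords.get("CB", build_cb(backbone))
    out = {"CB": coords["CB"]}
    for atom, refs, bond, angle, torsion in SIDECHAIN_ZMATRIX.get(resname, []):
        pos = place_atom(coords[refs[0]], coords[refs[1]], coords[refs[2]],
                         bond, angle, _resolve_torsion(torsion, chi))
        coords[atom] = pos
        out[atom] = pos
    return out


def build_residue(seq_id: int, resname: str, backbone: dict[str, np.ndarray],
                  chi: dict[str, float] | None = None) -> Residue:
    """Full residue (backbone + ideal side chain) from backbone coordinates."""
    atoms = {k: backbone[k] for k in ("N", "CA", "C") if k in backbone}
    if "O" in backbone:
        atoms["O"] = backbone["O"]
    atoms.update(sidechain_coords(resname, backbone, chi))
    return make_residue(seq_id, resname, atoms)


def rebuild_sidechain(residue: Residue, new_name: str,
                      chi: dict[str, float] | None = None) -> Residue:
    """Replace a residue's side chain (beyond the backbone) with an ideal one.

    The backbone (N, CA, C, O) is copied bit-identically; CB is kept when
    both residue types have one, rebuilt otherwise.
    """
    backbone = {n: residue.atom(n).coord.copy()
                for n in ("N", "CA", "C", "O") if residue.has_atom(n)}
    keep_cb = residue.has_atom("CB") and new_name != "GLY"
    if keep_cb:
        backbone["CB"] = residue.atom("CB").coord.copy()
    atoms = dict(backbone)
    if new_name != "GLY":
        atoms.update(sidechain_coords(new_name, backbone, chi))
        if keep_cb:
            atoms["CB"] = backbone["CB"]
    return make_residue(residue.seq_id, new_name, atoms, residue.insertion_code)


def n_chi(resname: str) -> int:
    return len(CHI_ATOMS.get(resname, []))


def get_chi(residue: Residue, k: int) -> float:
    """Current chi_k torsion (1-based) in degrees."""
    quad = CHI_ATOMS[residue.name][k - 1]
    p = [residue.atom(n).coord for n in quad]
    return dihedral_deg(*p)


def chi_movable_atoms(resname: str, k: int) -> set[str]:
    """Atom names distal to the chi_k bond (the set a chi rotation moves)."""
    a2, a3 = CHI_ATOMS[resname][k - 1][1:3]
    adj: dict[str, set[str]] = {}
    for x, y in residue_bonds(resname):
        adj.setdefault(x, set()).add(y)
        adj.setdefault(y, set()).add(x)
    seen = {a2, a3}
    stack = [a3]
    while stack:
        cur = stack.pop()
        for nb in adj.get(cur, ()):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    seen -= {a2, a3}
    return seen


def set_chi(residue: Residue, k: int, angle: float) -> None:
    """Rotate the distal side chain so chi_k equals ``angle`` (in place)."""
    quad = CHI_ATOMS[residue.name][k - 1]
    current = get_chi(residue, k)
    delta = angle - current
    b = residue.atom(quad[1]).coord
    c = residue.atom(quad[2]).coord
    R = rotation_about_axis(c - b, delta)
    movable = chi_movable_atoms(residue.name, k) | {quad[3]}
    for atom in residue.atoms:
        if atom.name in movable:
            atom.coord = R @ (atom.coord - c) + c
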