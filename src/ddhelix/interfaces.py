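"""Inter-subunit contact maps, face/offset statistics and the simplified
per-residue interface-energy decomposition.

Death-domain assemblies use three interface classes: type I pairs subunits
one helix step apart, type II pairs subunits three or four steps apart; the
``a`` face of a class looks up-helix (toward smaller helix index), the
``b`` face down-helix.  Offsets are reported as ``dn = n_partner - n_pivot``.

The energy model is a deliberately simple single-conformation pairwise
potential — screened Coulomb with a distance-dependent dielectric
(eps(r) = 4r) on unit side-chain-tip charges, plus a 12-6 Lennard-Jones
term on heavy atoms — standing in for ensemble-averaged MM/GBSA residue
decomposition, which is out of scope.  Values are on a kcal/mol-like scale
but are meaningful at rank/sign level only.  Per residue, the copy energies
across the eight query subunits are aggregated as the mean of the four
lowest (most favourable) values.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .assembly import Assembly
from .topology import LJ_EPSILON, PARTIAL_CHARGES, VDW_RADII

__all__ = [
    "FaceDefinition", "ContactRecord", "ResidueEnergy", "PotentialParams",
    "contact_map", "face_offsets", "classify_interface",
    "per_residue_energy", "total_intersubunit_energy", "rank_residues",
    "IRAK_M_FACES", "SYNTHETIC_FACES",
]

DEFAULT_CONTACT_CUTOFF = 4.5  # Angstrom, heavy-atom minimum distance
DEFAULT_ENERGY_CUTOFF = 10.0  # Angstrom, pairwise potential cutoff
COULOMB_CONSTANT = 332.0637  # kcal mol^-1 A e^-2


@dataclass
class FaceDefinition:
    """One interaction face: its pivot residues and auxiliary partners."""

    face: str  # "Ia" | "Ib" | "IIa" | "IIb" | "IIIa" | "IIIb"
    pivots: list[int]
    auxiliary: list[int] = field(default_factory=list)


#: the query-numbering face definitions used throughout: type Ia pivoted by
#: Lys60 (partner Asp33), IIa by Trp74 (with Phe18/Asp19/Leu20/Pro21/Gln78
#: around it), IIb by Arg97 with Tyr105, reaching Asp19 of the n+4 subunit
IRAK_M_FACES = {
    "Ia": FaceDefinition("Ia", pivots=[60], auxiliary=[33]),
    "IIa": FaceDefinition("IIa", pivots=[74], auxiliary=[18, 19, 20, 21, 78]),
    "IIb": FaceDefinition("IIb", pivots=[97, 105], auxiliary=[19]),
}

#: additional residues reported as strongly interactive in the assembly
ADDITIONAL_INTERACTIVE = [52, 56, 64]

#: same faces in the synthetic marker-domain numbering
SYNTHETIC_FACES = {
    "Ia": FaceDefinition("Ia", pivots=[2], auxiliary=[12]),
    "IIa": FaceDefinition("IIa", pivots=[42], auxiliary=[35]),
    "IIb": FaceDefinition("IIb", pivots=[16], auxiliary=[35]),
}


@dataclass
class ContactRecord:
    subunit_i: int
    residue_i: int
    subunit_j: int
    residue_j: int
    distance: float
    offset: int  # n_j - n_i, with subunit_i < subunit_j canonical

    def __post_init__(self) -> None:
        if self.subunit_i == self.subunit_j:
            raise ValueError("contacts are inter-subunit")
        if self.offset != self.subunit_j - self.subunit_i:
            raise ValueError("offset must equal n_j - n_i")


@dataclass
class ResidueEnergy:
    residue: int  # query numbering
    resname: str
    per_copy: dict[int, float]  # local copy index -> energy
    aggregated: float
    flagged: bool = False  # fewer than four copies available


@dataclass
class PotentialParams:
    coulomb_constant: float = COULOMB_CONSTANT
    dielectric_factor: float = 4.0  # eps(r) = factor * r
    lj_epsilon: dict = field(default_factory=lambda: dict(LJ_EPSILON))
    vdw_radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    charges: dict = field(default_factory=lambda: dict(PARTIAL_CHARGES))
    cutoff: float = DEFAULT_ENERGY_CUTOFF

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if any(e <= 0 for e in self.lj_epsilon.values()):
            raise ValueError("LJ well depths must be positive")


def _flat_atoms(a: Assembly):
    """Heavy atoms of the assembly as flat arrays + metadata rows."""
    coords, rows = [], []
    for sub in a.subunits:
        for chain in sub.structure.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    if atom.is_heavy:
                        coords.append(atom.coord)
                        rows.append((sub.helix_index, sub.layer,
                                     sub.local_index, res.seq_id, res.name,
                                     atom.name, atom.element))
    return np.array(coords), rows


def contact_map(a: Assembly,
                cutoff: float = DEFAULT_CONTACT_CUTOFF) -> list[ContactRecord]:
    """All inter-subunit residue pairs with min heavy-atom distance <= cutoff.

    Stored canonically with ``subunit_i < subunit_j``; the distance is the
    minimum over the residues' heavy-atom pairs.
    """
    coords, rows = _flat_atoms(a)
    if len(coords) == 0:
        return []
    tree = cKDTree(coords)
    best: dict[tuple, float] = {}
    for i, j in tree.query_pairs(r=cutoff, output_type="ndarray"):
        si, sj = rows[i][0], rows[j][0]
        if si == sj:
            continue
        if si > sj:
            i, j = j, i
            si, sj = sj, si
        key = (si, rows[i][3], sj, rows[j][3])
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < best.get(key, np.inf):
            best[key] = d
    return [ContactRecord(si, ri, sj, rj, d, sj - si)
            for (si, ri, sj, rj), d in sorted(best.items())]


def classify_interface(delta_n: int) -> str:
    """Interface-type label for a subunit-offset: |1| -> type I,
    |3| or |4| -> type II, otherwise unclassified.  The ``a`` face looks
    up-helix (negative offset from the pivot), ``b`` down-helix."""
    mag = abs(int(delta_n))
    if mag == 1:
        body = "I"
    elif mag in (3, 4):
        body = "II"
    else:
        return "unclassified"
    return body + ("a" if delta_n < 0 else "b")


def face_offsets(a: Assembly, contacts: list[ContactRecord],
                 face: FaceDefinition,
                 subunit_scope: list[int] | None = None) -> dict:
    """Partner-offset statistics for each pivot residue of a face.

    For every in-scope query subunit the offsets ``dn`` of partner subunits
    the pivot residue contacts (within the contact cutoff), plus — reported
    separately — the offset of the nearest partner subunit by minimum
    heavy-atom distance even when no contact is under the cutoff.
    """
    queries = a.query_subunits()
    if not queries:
        raise ValueError("assembly has no query subunits")
    scope = set(subunit_scope) if subunit_scope is not None \
        else {s.helix_index for s in queries}
    present = {r.seq_id for s in queries for r in s.chain.residues}
    out: dict[int, dict] = {}
    coords, rows = _flat_atoms(a)
    sub_idx = np.array([r[0] for r in rows])
    for pivot in face.pivots:
        if pivot not in present:
            raise KeyError(
                f"pivot residue {pivot} absent from the query model; "
                f"model positions are {sorted(present)}")
        offsets: dict[int, list[int]] = {}
        nearest: dict[int, int] = {}
        hist: Counter = Counter()
        for sub in queries:
            n = sub.helix_index
            if n not in scope:
                continue
            found = []
            for c in contacts:
                if c.subunit_i == n and c.residue_i == pivot:
                    found.append(c.offset)
                elif c.subunit_j == n and c.residue_j == pivot:
                    found.append(-c.offset)
            offsets[n] = sorted(found)
            hist.update(found)
            try:
                res = sub.chain.residue(pivot)
            except KeyError:
                continue
            X = np.array([at.coord for at in res.atoms if at.is_heavy])
            other = np.flatnonzero(sub_idx != n)
            if len(other) and len(X):
                d, idx = cKDTree(coords[other]).query(X)
                k = int(np.argmin(d))
                nearest[n] = int(sub_idx[other[idx[k]]] - n)
        out[pivot] = {"offsets": offsets, "nearest": nearest,
                      "histogram": dict(sorted(hist.items()))}
    return out


def _charge_radius_eps(rows, params: PotentialParams):
    q = np.zeros(len(rows))
    r = np.zeros(len(rows))
    e = np.zeros(len(rows))
    for k, row in enumerate(rows):
        resname, atom, elem = row[4], row[5], row[6].upper()
        q[k] = params.charges.get((resname, atom), 0.0)
        if elem not in params.vdw_radii or elem not in params.lj_epsilon:
            raise KeyError(f"no potential parameters for atom type {elem!r} "
                           f"({resname} {atom})")
        r[k] = params.vdw_radii[elem]
        e[k] = params.lj_epsilon[elem]
    return q, r, e


def _pair_energies(a: Assembly, params: PotentialParams):
    """Energies of all inter-subunit atom pairs within the cutoff.

    Yields (row_i, row_j, energy) with rows the metadata tuples of
    :func:`_flat_atoms`.
    """
    coords, rows = _flat_atoms(a)
    if len(coords) == 0:
        return [], []
    q, rad, eps = _charge_radius_eps(rows, params)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=params.cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return [], rows
    i, j = pairs[:, 0], pairs[:, 1]
    inter = np.array([rows[x][0] != rows[y][0] for x, y in pairs])
    i, j = i[inter], j[inter]
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    d = np.maximum(d, 1e-6)
    elec = params.coulomb_constant * q[i] * q[j] / (params.dielectric_factor * d * d)
    rm = rad[i] + rad[j]
    e_ij = np.sqrt(eps[i] * eps[j])
    x6 = (rm / d) ** 6
    lj = e_ij * (x6 * x6 - 2.0 * x6)
    return list(zip(i.tolist(), j.tolist(), (elec + lj).tolist())), rows


def total_intersubunit_energy(a: Assembly,
                              params: PotentialParams | None = None) -> float:
    """Sum of all inter-subunit pair energies (each pair counted once)."""
    params = params or PotentialParams()
    pairs, _ = _pair_energies(a, params)
    return float(sum(e for _, _, e in pairs))


def per_residue_energy(a: Assembly,
                       params: PotentialParams | None = None) -> list[ResidueEnergy]:
    """Interface-energy decomposition over the query copies.

    Each residue of each query copy receives the full energy of every
    inter-subunit atom pair it participates in (so summing residue terms
    over an all-query assembly double-counts the total pair energy — the
    conservation identity used in tests).  Per residue label the aggregate
    is the mean of the four most favourable copy energies; with fewer than
    four copies all are averaged and the record flagged.
    """
    params = params or PotentialParams()
    if len(a.query_subunits()) < 2:
        raise ValueError("need at least two query subunits")
    pairs, rows = _pair_energies(a, params)
    acc: dict[tuple[int, int], float] = {}
    resnames: dict[int, str] = {}
    for sub in a.query_subunits():
        for res in sub.chain.residues:
            acc[(sub.local_index, res.seq_id)] = 0.0
            resnames[res.seq_id] = res.name
    for i, j, e in pairs:
        for k in (i, j):
            row = rows[k]
            if row[1] == "QUERY":
                acc[(row[2], row[3])] += e
    by_res: dict[int, dict[int, float]] = {}
    for (copy, seq), e in acc.items():
        by_res.setdefault(seq, {})[copy] = e
    out = []
    for seq in sorted(by_res):
        copies = by_res[seq]
        vals = sorted(copies.values())
        if len(vals) >= 4:
            agg = float(np.mean(vals[:4]))
            flagged = False
        else:
            agg = float(np.mean(vals))
            flagged = True
        out.append(ResidueEnergy(seq, resnames[seq], copies, agg, flagged))
    return out


def rank_residues(energies: list[ResidueEnergy]) -> list[ResidueEnergy]:
    """Most favourable (lowest aggregated energy) first; ties by residue."""
    return sorted(energies, key=lambda e: (e.aggregated, e.residue))
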