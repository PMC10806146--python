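"""Steric clash detection and greedy side-chain relief ("debumping").

A clash is a pair of non-bonded heavy atoms whose distance is below the sum
of their van der Waals radii minus a tolerance (default 0.4 A).  Pairs
within three covalent bonds of each other (1-2, 1-3, 1-4, including the
peptide link between consecutive residues) are never counted.  Relief is a
greedy grid search over side-chain chi torsions (30-degree steps, worst
residue first) that only accepts strictly overlap-reducing moves; the
backbone never moves.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .assembly import Assembly
from .builders import n_chi, set_chi
from .structure import Residue
from .topology import VDW_RADII, residue_bonds

__all__ = ["ClashRecord", "AtomTable", "detect_clashes", "relieve"]

DEFAULT_OVERLAP_THRESHOLD = 0.4
_CHI_GRID = np.arange(-180.0, 180.0, 30.0)


@dataclass(frozen=True)
class AtomRef:
    subunit: int  # helix index
    chain: str
    residue: tuple[int, str]  # (seq_id, insertion code)
    resname: str
    atom: str


@dataclass
class ClashRecord:
    a: AtomRef
    b: AtomRef
    distance: float
    overlap: float

    def __post_init__(self) -> None:
        if self.overlap <= 0:
            raise ValueError("a clash must have positive overlap")
        if (self.a.subunit, self.a.chain, self.a.residue) == \
                (self.b.subunit, self.b.chain, self.b.residue):
            raise ValueError("clash atoms must come from different residues")


class AtomTable:
    """Flat heavy-atom view of an assembly with a covalent-bond graph."""

    def __init__(self, a: Assembly):
        self.assembly = a
        self.refs: list[AtomRef] = []
        self.atoms = []  # Atom objects, shared with the assembly
        self.radii: list[float] = []
        index_of: dict[tuple, int] = {}
        for sub in a.subunits:
            for chain in sub.structure.chains:
                for res in chain.residues:
                    for atom in res.atoms:
                        if not atom.is_heavy:
                            continue
                        key = (sub.helix_index, chain.id, res.key, atom.name)
                        index_of[key] = len(self.refs)
                        self.refs.append(AtomRef(sub.helix_index, chain.id,
                                                 res.key, res.name, atom.name))
                        self.atoms.append(atom)
                        self.radii.append(VDW_RADII.get(atom.element.upper(), 1.7))
        self.radii = np.array(self.radii)
        self._adj: dict[int, set[int]] = {i: set() for i in range(len(self.refs))}

        def link(k1, k2):
            i, j = index_of.get(k1), index_of.get(k2)
            if i is not None and j is not None:
                self._adj[i].add(j)
                self._adj[j].add(i)

        for sub in a.subunits:
            for chain in sub.structure.chains:
                for ri, res in enumerate(chain.residues):
                    base = (sub.helix_index, chain.id, res.key)
                    for n1, n2 in residue_bonds(res.name):
                        link(base + (n1,), base + (n2,))
                    if ri + 1 < len(chain.residues):
                        nxt = chain.residues[ri + 1]
                        link(base + ("C",),
                             (sub.helix_index, chain.id, nxt.key, "N"))

    def coords(self) -> np.ndarray:
        return np.array([at.coord for at in self.atoms])

    def within_three_bonds(self, i: int, j: int) -> bool:
        if j in self._adj[i]:
            return True
        frontier = {i}
        for _ in range(3):
            frontier = set().union(*(self._adj[k] for k in frontier)) if frontier else set()
            if j in frontier:
                return True
        return False

    def residue_of(self, i: int):
        ref = self.refs[i]
        for sub in self.assembly.subunits:
            if sub.helix_index == ref.subunit:
                for chain in sub.structure.chains:
                    if chain.id == ref.chain:
                        return chain.residue(*ref.residue)
        raise KeyError(ref)


def _clashes_from_table(table: AtomTable,
                        threshold: float) -> list[ClashRecord]:
    coords = table.coords()
    if len(coords) == 0:
        return []
    rmax = float(table.radii.max())
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2 * rmax - threshold, output_type="ndarray")
    records: list[ClashRecord] = []
    for i, j in pairs:
        ri, rj = table.refs[i], table.refs[j]
        if (ri.subunit, ri.chain, ri.residue) == (rj.subunit, rj.chain, rj.residue):
            continue  # intra-residue geometry is fixed by construction
        d = float(np.linalg.norm(coords[i] - coords[j]))
        overlap = float(table.radii[i] + table.radii[j] - threshold - d)
        if overlap <= 0:
            continue
        if table.within_three_bonds(int(i), int(j)):
            continue
        records.append(ClashRecord(ri, rj, d,
                                   float(table.radii[i] + table.radii[j] - d)))
    records.sort(key=lambda r: -r.overlap)
    return records


def detect_clashes(a: Assembly,
                   overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD) -> list[ClashRecord]:
    """All heavy-atom pairs with vdW overlap exceeding ``overlap_threshold``.

    The reported ``overlap`` is the raw ``r_i + r_j - d``; only pairs whose
    overlap exceeds the threshold are returned.  Spatial binning (k-d tree)
    keeps this far from all-pairs cost.
    """
    return _clashes_from_table(AtomTable(a), overlap_threshold)


def _residue_overlaps(clashes: list[ClashRecord], threshold: float) -> dict:
    per_res: dict[tuple, float] = {}
    for c in clashes:
        for ref in (c.a, c.b):
            key = (ref.subunit, ref.chain, ref.residue, ref.resname)
            per_res[key] = per_res.get(key, 0.0) + (c.overlap - threshold)
    return per_res


def _sidechain_overlap(table: AtomTable, residue: Residue, res_key,
                       tree: cKDTree, coords: np.ndarray,
                       own_idx: list[int], threshold: float) -> float:
    """Sum of above-threshold overlaps between this residue's movable atoms
    and all atoms outside the residue."""
    movable_names = set(a.name for a in residue.atoms) - {"N", "CA", "C", "O", "CB"}
    total = 0.0
    rmax = float(table.radii.max())
    own = set(own_idx)
    for idx in own_idx:
        if table.refs[idx].atom not in movable_names:
            continue
        x = table.atoms[idx].coord
        for j in tree.query_ball_point(x, 2 * rmax - threshold):
            if j in own:
                continue
            if table.within_three_bonds(idx, j):
                continue
            d = float(np.linalg.norm(x - coords[j]))
            overlap = table.radii[idx] + table.radii[j] - d
            if overlap > threshold:
                total += overlap - threshold
    return total


def relieve(a: Assembly, max_iters: int = 200, seed: int = 0,
            overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
            residue_scope: set | None = None) -> tuple[Assembly, dict]:
    """Greedy chi-grid debumping of an assembly (in place on a copy).

    One iteration adjusts the currently worst-clashing rotatable residue by
    a sequential 30-degree grid search over its chi torsions, accepting the
    move only if the total overlap strictly decreases.  Terminates at zero
    clashes, ``max_iters``, or when no improving move exists
    (``report["converged"]`` is False in the latter case only if clashes
    remain).  ``residue_scope`` optionally restricts which residues may move
    (set of (chain_id, seq_id) pairs).

    Returns the relieved assembly and a report with the strictly decreasing
    per-iteration total-overlap sequence.
    """
    import copy as _copy

    out = _copy.deepcopy(a)
    rng = np.random.default_rng(seed)
    table = AtomTable(out)
    history: list[float] = []
    moved: list[dict] = []
    clashes = _clashes_from_table(table, overlap_threshold)
    initial_count = len(clashes)
    total = sum(c.overlap - overlap_threshold for c in clashes)
    history.append(total)
    tried_and_failed: set[tuple] = set()
    iters = 0
    while clashes and iters < max_iters:
        per_res = _residue_overlaps(clashes, overlap_threshold)
        candidates = []
        for key, ov in per_res.items():
            sub_idx, chain_id, res_key, resname = key
            if n_chi(resname) == 0:
                continue
            if residue_scope is not None and (chain_id, res_key[0]) not in residue_scope:
                continue
            if key in tried_and_failed:
                continue
            candidates.append((ov, key))
        if not candidates:
            break
        best_ov = max(ov for ov, _ in candidates)
        top = [key for ov, key in candidates if ov == best_ov]
        key = top[int(rng.integers(len(top)))] if len(top) > 1 else top[0]
        sub_idx, chain_id, res_key, resname = key
        residue = None
        own_idx = [i for i, r in enumerate(table.refs)
                   if (r.subunit, r.chain, r.residue) == (sub_idx, chain_id, res_key)]
        residue = table.residue_of(own_idx[0])
        coords = table.coords()
        tree = cKDTree(coords)
        before = _sidechain_overlap(table, residue, res_key, tree, coords,
                                    own_idx, overlap_threshold)
        saved = {at.name: at.coord.copy() for at in residue.atoms}
        best = (before, None)
        for k in range(1, n_chi(resname) + 1):
            current_best_angle = None
            base_score = best[0]
            for ang in _CHI_GRID:
                set_chi(residue, k, float(ang))
                score = _sidechain_overlap(table, residue, res_key, tree,
                                           coords, own_idx, overlap_threshold)
                if score < base_score - 1e-12:
                    base_score = score
                    current_best_angle = float(ang)
            if current_best_angle is None:
                # restore this chi to its pre-search value
                for at in residue.atoms:
                    at.coord = saved[at.name].copy()
                # re-apply accepted chis from earlier rounds
                for kk, aa in (best[1] or {}).items():
                    set_chi(residue, kk, aa)
            else:
                set_chi(residue, k, current_best_angle)
                accepted = dict(best[1] or {})
                accepted[k] = current_best_angle
                best = (base_score, accepted)
        after = best[0]
        if best[1] is None or after >= before - 1e-12:
            for at in residue.atoms:
                at.coord = saved[at.name].copy()
            tried_and_failed.add(key)
            continue
        iters += 1
        total = total - (before - after)
        history.append(total)
        moved.append({"chain": chain_id, "residue": res_key[0],
                      "resname": resname, "chi": best[1],
                      "overlap_before": before, "overlap_after": after})
        tried_and_failed.clear()
        clashes = _clashes_from_table(table, overlap_threshold)
    final = _clashes_from_table(table, overlap_threshold)
    report = {
        "initial_clashes": initial_count,
        "final_clashes": len(final),
        "iterations": iters,
        "overlap_history": history,
        "moves": moved,
        "converged": len(final) == 0,
        "seed": seed,
    }
    return out, report
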