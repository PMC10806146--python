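"""Hierarchical structure model (chain -> residue -> atom) and PDB I/O.

The in-memory model is deliberately small: author chain ids and author
residue numbering are authoritative, coordinates are numpy arrays in
Angstrom.  Reading goes through :mod:`gemmi`; writing emits fixed-column
ATOM/TER/END records directly so chain separation and atom numbering are
fully under our control.
"""
from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .topology import AA3_TO_1, element_of

__all__ = [
    "Atom", "Residue", "Chain", "Structure",
    "read_pdb", "write_pdb", "chain_sequence",
    "EmptyStructureError", "PdbOverflowError",
]


class EmptyStructureError(ValueError):
    """Raised when a PDB source yields no ATOM records."""


class PdbOverflowError(ValueError):
    """Raised when a structure does not fit the fixed-column PDB format."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError(f"residue {self.name}{self.seq_id}: duplicate atom names")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in {self.name}{self.seq_id}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"chain {self.id}: duplicate residue identifiers")

    def residue(self, seq_id: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.seq_id == seq_id and r.insertion_code == icode:
                return r
        raise KeyError(f"no residue {seq_id}{icode} in chain {self.id}")

    def ca_coords(self) -> np.ndarray:
        """CA coordinates in residue order (residues lacking CA are skipped)."""
        return np.array([r.atom("CA").coord for r in self.residues if r.has_atom("CA")])


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    title: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError("chain ids must be unique")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def iter_atoms(self):
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for _, _, a in self.iter_atoms() if a.is_heavy])

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A deep copy with ``x -> R x + t`` applied to every atom."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for _, _, a in out.iter_atoms():
            a.coord = R @ a.coord + t
        return out


_WATERS = {"HOH", "WAT", "DOD"}


def read_pdb(path: str | Path, *, keep_waters: bool = False,
             keep_hetero: bool = True) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    First model only; waters dropped unless ``keep_waters``; for altloc
    groups the highest-occupancy conformer is kept (ties: first in file).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate records")
    model = st[0]
    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if res.name in _WATERS and not keep_waters:
                continue
            if res.het_flag == "H" and res.name not in _WATERS and not keep_hetero:
                continue
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > prev.occ:
                    best[at.name] = at
            atoms = [Atom(name=n, element=best[n].element.name,
                          coord=np.array([best[n].pos.x, best[n].pos.y, best[n].pos.z]))
                     for n in order]
            if atoms:
                residues.append(Residue(seq_id=res.seqid.num, name=res.name,
                                        atoms=atoms,
                                        insertion_code=(res.seqid.icode or "").strip()))
        if residues:
            chains.append(Chain(id=ch.name, residues=residues))
    if not chains:
        raise EmptyStructureError(f"{path}: no ATOM records")
    return Structure(chains=chains, title=st.name or "", source=str(path))


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write fixed-column ATOM records, TER after each chain, END last."""
    if s.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    if s.n_atoms + len(s.chains) > 99999:
        raise PdbOverflowError(
            f"{s.n_atoms} atoms exceed the 99,999 serial limit of the PDB format")
    lines = []
    serial = 0
    for ch in s.chains:
        cid = ch.id[:1] if ch.id else "A"
        for r in ch.residues:
            for a in r.atoms:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {r.name:<3s} {cid}"
                    f"{r.seq_id:4d}{(r.insertion_code or ' '):1s}   "
                    f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
                )
        serial += 1
        last = ch.residues[-1]
        lines.append(f"TER   {serial:5d}      {last.name:<3s} {cid}{last.seq_id:4d}"
                     f"{(last.insertion_code or ' '):1s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def chain_sequence(c: Chain) -> str:
    """One-letter sequence of a chain; unknown residue names become 'X'."""
    return "".join(AA3_TO_1.get(r.name, "X") for r in c.residues)


def make_residue(seq_id: int, name: str, atom_coords: dict[str, np.ndarray],
                 icode: str = "") -> Residue:
    """Convenience constructor from an atom-name -> coordinate mapping."""
    atoms = [Atom(name=n, element=element_of(n), coord=xyz)
             for n, xyz in atom_coords.items()]
    return Residue(seq_id=seq_id, name=name, atoms=atoms, insertion_code=icode)
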