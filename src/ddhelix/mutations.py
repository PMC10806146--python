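"""In-silico point mutations of the query octamer and interface-score deltas.

A mutation is applied homotypically — to every query copy at once, since
the biological mutant oligomerizes with itself — by regrowing the side
chain at the target position with ideal geometry, followed by clash relief
restricted to the mutated residues.  Score deltas are rank/sign-level
quantities of the simplified pairwise potential, reported per subunit-offset
class; no free-energy calibration is claimed.

The classic probe is the charge flip at the type Ia pivot (lysine to
glutamate): with an acidic partner across the Ia interface the
electrostatic term switches from attraction to repulsion.
"""
from __future__ import annotations

from dataclasses import dataclass

import copy as _copy

from .assembly import Assembly
from .builders import rebuild_sidechain
from .clashes import relieve
from .interfaces import PotentialParams, _pair_energies, classify_interface
from .topology import AA1_TO_3, AA3_TO_1

__all__ = ["MutationSpec", "PAPER_PANEL", "synthetic_panel",
           "apply_mutation", "delta_score", "scan"]


@dataclass(frozen=True)
class MutationSpec:
    position: int  # query numbering
    from_aa: str  # one-letter
    to_aa: str

    @property
    def label(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"

    def __post_init__(self) -> None:
        if self.from_aa not in AA1_TO_3 or self.to_aa not in AA1_TO_3:
            raise ValueError(f"unknown amino acid in {self.from_aa}->{self.to_aa}")


#: the experimental mutation panel in query (IRAK-M DD) numbering; the
#: Gln78 substitution target is not pinned down by the experiments and is
#: kept configurable (alanine by default)
PAPER_PANEL = [
    MutationSpec(74, "W", "A"),
    MutationSpec(97, "R", "Q"),
    MutationSpec(60, "K", "E"),
    MutationSpec(105, "Y", "A"),
    MutationSpec(18, "F", "A"),
    MutationSpec(19, "D", "N"),
    MutationSpec(20, "L", "A"),
    MutationSpec(21, "P", "A"),
    MutationSpec(22, "P", "A"),
    MutationSpec(23, "A", "S"),
    MutationSpec(78, "Q", "A"),
]


def synthetic_panel() -> list[MutationSpec]:
    """The analogous panel on the synthetic marker domain: charge flip at
    the Ia pivot, truncations of the IIa/IIb pivots."""
    return [
        MutationSpec(2, "K", "E"),   # K60E analogue
        MutationSpec(42, "W", "A"),  # W74A analogue
        MutationSpec(16, "R", "Q"),  # R97Q analogue
    ]


def apply_mutation(a: Assembly, m: MutationSpec, *, relieve_clashes: bool = True,
                   seed: int = 0, max_iters: int = 24) -> Assembly:
    """Mutate every query copy at ``m.position``; backbone untouched.

    A self-mutation returns an unchanged deep copy.  Otherwise the side
    chain is regrown in the extended rotamer and the mutated residues (only)
    are debumped.
    """
    queries = a.query_subunits()
    if not queries:
        raise ValueError("assembly has no query subunits")
    for sub in queries:
        try:
            res = sub.chain.residue(m.position)
        except KeyError:
            raise KeyError(f"position {m.position} missing from query copy "
                           f"{sub.local_index}") from None
        found = AA3_TO_1.get(res.name, "X")
        if found != m.from_aa:
            raise ValueError(f"{m.label}: model has {res.name} ({found}) at "
                             f"position {m.position}")
    if m.from_aa == m.to_aa:
        return _copy.deepcopy(a)
    out = _copy.deepcopy(a)
    scope = set()
    for sub in out.query_subunits():
        chain = sub.structure.chains[0]
        for i, res in enumerate(chain.residues):
            if res.seq_id == m.position:
                chain.residues[i] = rebuild_sidechain(res, AA1_TO_3[m.to_aa])
                scope.add((chain.id, m.position))
    if relieve_clashes:
        out, _ = relieve(out, max_iters=max_iters, seed=seed,
                         residue_scope=scope)
    return out


def _position_energy_by_offset(a: Assembly, position: int,
                               params: PotentialParams) -> dict[int, float]:
    """Summed pair energy of the mutated position's atoms against other
    subunits, keyed by partner offset dn."""
    pairs, rows = _pair_energies(a, params)
    out: dict[int, float] = {}
    for i, j, e in pairs:
        ri, rj = rows[i], rows[j]
        for mine, other in ((ri, rj), (rj, ri)):
            if mine[1] == "QUERY" and mine[3] == position:
                dn = other[0] - mine[0]
                out[dn] = out.get(dn, 0.0) + e
    return out


def delta_score(wt: Assembly, mut: Assembly, m: MutationSpec,
                params: PotentialParams | None = None) -> dict:
    """Interface-score change of a mutation, per offset and offset class.

    ``delta = E_mut - E_wt`` restricted to inter-subunit pairs involving the
    mutated position; positive values mean the mutation worsened that
    interface.  Offsets are labelled with their interface class (a-face:
    partner up-helix).
    """
    params = params or PotentialParams()
    wt_e = _position_energy_by_offset(wt, m.position, params)
    mut_e = _position_energy_by_offset(mut, m.position, params)
    offsets = sorted(set(wt_e) | set(mut_e))
    by_offset = {dn: mut_e.get(dn, 0.0) - wt_e.get(dn, 0.0) for dn in offsets}
    by_class: dict[str, float] = {}
    for dn, de in by_offset.items():
        by_class[classify_interface(dn)] = \
            by_class.get(classify_interface(dn), 0.0) + de
    return {
        "mutation": m.label,
        "by_offset": by_offset,
        "by_class": by_class,
        "total": float(sum(by_offset.values())),
        "wt_by_offset": wt_e,
        "mut_by_offset": mut_e,
    }


def scan(a: Assembly, panel: list[MutationSpec] | None = None,
         params: PotentialParams | None = None, seed: int = 0) -> list[dict]:
    """Apply a panel of mutations and collect their delta scores."""
    panel = panel if panel is not None else synthetic_panel()
    out = []
    for m in panel:
        mut = apply_mutation(a, m, seed=seed)
        out.append(delta_score(a, mut, m, params))
    return out
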