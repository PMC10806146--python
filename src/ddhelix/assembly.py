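"""Template-guided construction of the extended death-domain assembly.

The two-stage procedure: (1) a copy of the query DD is rigid-body
superposed onto every subunit of the template's two IRAK layers, giving an
octamer of query copies riding on the template scaffold; (2) the first
tetramer of that octamer (the copies sitting on the kinase-adaptor layer)
is re-anchored onto the template's bottom layer with a single joint rigid
transform applied to the whole octamer, which slides it one layer down.
The template's own bottom-layer chains are dropped, leaving the scaffold
(6) + adaptor (4) layers plus 8 query subunits.

Because the original query homology model is not distributable, a threading
stand-in is provided: backbone and CB copied from a homologous template
chain at sequence-aligned positions, side chains regrown with ideal
geometry.  Its provenance records that it is a stand-in, not a homology
model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builders import rebuild_sidechain
from .lattice import ScrewTransform
from .structure import Atom, Chain, Residue, Structure
from .superpose import align_chains, kabsch, superpose_homolog
from .topology import AA1_TO_3

__all__ = ["Subunit", "Assembly", "LayerPlan", "thread_query",
           "build_extended_layer", "reanchor", "CoverageError"]

QUERY_LAYER = "QUERY"


class CoverageError(ValueError):
    """Alignment covers too little of the query sequence for threading."""


@dataclass
class Subunit:
    helix_index: int  # position along the single-start helix, 1-based
    layer: str  # template layer label or "QUERY"
    structure: Structure  # single-chain structure
    provenance: dict = field(default_factory=dict)
    local_index: int | None = None  # 1..8 within the query octamer

    @property
    def chain(self) -> Chain:
        return self.structure.chains[0]


@dataclass
class Assembly:
    subunits: list[Subunit] = field(default_factory=list)
    generator: ScrewTransform | None = None

    def __post_init__(self) -> None:
        for s in self.subunits:
            if not s.structure.chains:
                raise ValueError("every subunit needs at least one chain")
        by_layer: dict[str, list[int]] = {}
        for s in self.subunits:
            by_layer.setdefault(s.layer, []).append(s.helix_index)
        for layer, idx in by_layer.items():
            if len(set(idx)) != len(idx):
                raise ValueError(f"duplicate helix indices in layer {layer}")

    def is_contiguous(self) -> bool:
        """Whether each layer occupies an unbroken helix-index range (true
        for builder output; sub-assemblies used in analysis may have gaps)."""
        by_layer: dict[str, list[int]] = {}
        for s in self.subunits:
            by_layer.setdefault(s.layer, []).append(s.helix_index)
        return all(sorted(idx) == list(range(min(idx), min(idx) + len(idx)))
                   for idx in by_layer.values())

    def query_subunits(self) -> list["Subunit"]:
        return [s for s in self.subunits if s.layer == QUERY_LAYER]

    def layer_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.subunits:
            out[s.layer] = out.get(s.layer, 0) + 1
        return out

    def to_structure(self, title: str = "assembly") -> Structure:
        """Merge all subunits into one multi-chain structure (A, B, C...)."""
        ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
        chains = []
        for i, s in enumerate(sorted(self.subunits, key=lambda x: (x.helix_index,
                                                                   x.layer))):
            st = s.structure.copy()
            st.chains[0].id = ids[i]
            chains.append(st.chains[0])
        return Structure(chains=chains, title=title)

    def manifest(self) -> dict:
        return {
            "n_subunits": len(self.subunits),
            "layer_counts": self.layer_counts(),
            "subunits": [{
                "helix_index": s.helix_index,
                "layer": s.layer,
                "local_index": s.local_index,
                "chain_id": s.chain.id,
                "provenance": {k: v for k, v in s.provenance.items()},
            } for s in self.subunits],
        }


@dataclass
class LayerPlan:
    """Chain ids of the template layers and the query placement targets."""

    layer_chain_ids: dict[str, list[str]]
    targets: list[str]

    def validate(self, template: Structure) -> None:
        known = {c.id for c in template.chains}
        for layer, ids in self.layer_chain_ids.items():
            missing = set(ids) - known
            if missing:
                raise ValueError(f"layer {layer}: chains {sorted(missing)} "
                                 "not in template")
        missing = set(self.targets) - known
        if missing:
            raise ValueError(f"targets {sorted(missing)} not in template")

    @classmethod
    def from_manifest(cls, manifest: dict) -> "LayerPlan":
        """Standard plan from a synthetic-lattice manifest: place the query
        on both IRAK layers, in helix order."""
        layers: dict[str, list[str]] = {}
        for row in manifest["layers"]:
            layers.setdefault(row["layer"], []).append(row["chain_id"])
        targets = layers.get("IRAK4", []) + layers.get("IRAK2", [])
        return cls(layer_chain_ids=layers, targets=targets)


def thread_query(template_chain: Chain, query_sequence: str,
                 correspondence: list[tuple[int, int]] | None = None,
                 min_coverage: float = 0.8, chain_id: str = "Q") -> Structure:
    """Threading stand-in for an unavailable query homology model.

    Backbone (N, CA, C, O) and CB are copied from the template chain at
    sequence-aligned positions; side chains beyond CB are regrown with ideal
    geometry in the extended rotamer; residues are renamed and renumbered to
    the query sequence (1-based).  Unaligned query positions are omitted and
    listed in the returned structure's ``source``.
    """
    query_sequence = query_sequence.strip().upper()
    if correspondence is None:
        pseudo = Chain(id="q", residues=[
            Residue(seq_id=i + 1, name=AA1_TO_3.get(aa, "ALA"))
            for i, aa in enumerate(query_sequence)])
        # sequence-only alignment: the pseudo chain has no atoms
        correspondence = align_chains(pseudo, template_chain)
    coverage = len(correspondence) / max(len(query_sequence), 1)
    if coverage < min_coverage:
        raise CoverageError(
            f"alignment covers {coverage:.0%} of the query "
            f"(minimum {min_coverage:.0%})")
    residues: list[Residue] = []
    for qi, ti in correspondence:
        tres = template_chain.residues[ti]
        resname = AA1_TO_3.get(query_sequence[qi], None)
        if resname is None:
            raise ValueError(f"unknown query residue {query_sequence[qi]!r}"
                             f" at position {qi + 1}")
        if not all(tres.has_atom(n) for n in ("N", "CA", "C")):
            continue
        if tres.name == resname:
            # identical residue type: carry the template side chain as is
            residues.append(Residue(seq_id=qi + 1, name=resname, atoms=[
                Atom(name=a.name, element=a.element, coord=a.coord.copy())
                for a in tres.atoms if a.is_heavy]))
            continue
        backbone = Residue(seq_id=qi + 1, name=tres.name, atoms=[
            a for a in tres.atoms if a.name in ("N", "CA", "C", "O", "CB")])
        residues.append(rebuild_sidechain(backbone, resname))
    omitted = sorted(set(range(1, len(query_sequence) + 1))
                     - {r.seq_id for r in residues})
    return Structure(
        chains=[Chain(id=chain_id, residues=residues)],
        title="threaded query stand-in (NOT a homology model)",
        source=f"thread_query(template={template_chain.id}, "
               f"coverage={coverage:.2f}, omitted={omitted})")


def build_extended_layer(query: Structure, template: Structure,
                         plan: LayerPlan) -> Assembly:
    """Stage 1: one placed query copy per target chain, template layers kept.

    Helix indices follow template layer order; the template's bottom layer
    (any layer not named in the carried set) provides placement targets only
    and its own chains are not carried into the assembly.
    """
    plan.validate(template)
    carried = [l for l in ("MYD88", "IRAK4") if l in plan.layer_chain_ids]
    index_of: dict[str, int] = {}
    n = 0
    for layer in plan.layer_chain_ids:
        for cid in plan.layer_chain_ids[layer]:
            n += 1
            index_of[cid] = n
    subunits: list[Subunit] = []
    for layer in carried:
        for cid in plan.layer_chain_ids[layer]:
            sub = Structure(chains=[template.chain(cid)]).copy()
            subunits.append(Subunit(helix_index=index_of[cid], layer=layer,
                                    structure=sub,
                                    provenance={"origin": "template",
                                                "template_chain": cid}))
    for local, cid in enumerate(plan.targets, start=1):
        try:
            placed, res = superpose_homolog(query, template.chain(cid))
        except Exception as exc:
            raise RuntimeError(f"placement on chain {cid} failed: {exc}") from exc
        placed.chains[0].id = f"Q{local}"
        subunits.append(Subunit(
            helix_index=index_of[cid], layer=QUERY_LAYER, structure=placed,
            local_index=local,
            provenance={"origin": "query", "target_chain": cid,
                        "rmsd": res.rmsd, "n_pairs": res.n_pairs}))
    return Assembly(subunits=subunits)


def reanchor(a: Assembly, template: Structure,
             anchor_chain_ids: list[str]) -> Assembly:
    """Stage 2: slide the query octamer one layer down the helix.

    A single rigid transform — the joint CA Kabsch optimum mapping the first
    ``len(anchor_chain_ids)`` query copies onto the anchor chains
    (order-respecting) — is applied to every query subunit; template layers
    are untouched.  Helix indices of the query copies shift accordingly.
    """
    queries = sorted(a.query_subunits(), key=lambda s: s.local_index)
    k = len(anchor_chain_ids)
    if len(queries) < k:
        raise ValueError(f"assembly has {len(queries)} query subunits, "
                         f"need at least {k} to anchor")
    mobile, fixed = [], []
    for sub, cid in zip(queries[:k], anchor_chain_ids):
        anchor_chain = template.chain(cid)
        pairs = align_chains(sub.chain, anchor_chain)
        for qi, ti in pairs:
            qres = sub.chain.residues[qi]
            tres = anchor_chain.residues[ti]
            if qres.has_atom("CA") and tres.has_atom("CA"):
                mobile.append(qres.atom("CA").coord)
                fixed.append(tres.atom("CA").coord)
    if len(mobile) < 3 * k:
        raise ValueError("anchor mismatch: too few CA pairs across the tetramer")
    res = kabsch(np.array(mobile), np.array(fixed))
    t = res.transform
    # index shift: local copy 1 moves onto the first anchor chain's position
    anchor_positions = _positions_in_template_order(a, template, anchor_chain_ids)
    shift = anchor_positions[0] - queries[0].helix_index if anchor_positions else 0
    new_subs: list[Subunit] = []
    for s in a.subunits:
        if s.layer != QUERY_LAYER:
            new_subs.append(s)
            continue
        moved = s.structure.transformed(t.rotation, t.translation)
        prov = dict(s.provenance)
        prov["reanchor_rmsd"] = res.rmsd
        new_subs.append(Subunit(helix_index=s.helix_index + shift,
                                layer=QUERY_LAYER, structure=moved,
                                provenance=prov, local_index=s.local_index))
    return Assembly(subunits=new_subs, generator=a.generator)


def _positions_in_template_order(a: Assembly, template: Structure,
                                 chain_ids: list[str]) -> list[int]:
    order = [c.id for c in template.chains]
    return [order.index(cid) + 1 for cid in chain_ids if cid in order]
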