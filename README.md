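# ddhelix

Modelling of death-domain (DD) helical assemblies: template-guided
extension of a DD oligomer under a myddosome-style scaffold, steric
debumping, interface contact/offset analysis, a simplified per-residue
interface-energy decomposition, and an in-silico mutation scan.

## The problem

Death domains are ~90-residue six-helix bundles that assemble into
layered, left-handed, single-start helical oligomers (the myddosome being
the canonical example: layers of MyD88, IRAK-4 and IRAK family DDs).  Each
subunit `n` in such a helix touches its neighbours at characteristic
helix-index offsets — `n±1` within a turn (type I interfaces) and `n±3`,
`n±4` between turns (type II interfaces) — and each interface pairs the
`a` face of one subunit (looking up-helix) with the `b` face of another.

`ddhelix` reconstructs, as a tested pipeline, the structural argument that
an inhibitory IRAK-family DD can extend such a scaffold into a
homo-octamer: a query DD is rigid-body superposed (CA Kabsch over a
sequence-guided correspondence) onto every subunit of the template's two
IRAK layers, and the resulting octamer is re-anchored one layer down by a
single joint rigid transform of its first tetramer onto the template's
bottom layer.  The final model carries the 6-subunit scaffold layer, the
4-subunit adaptor layer and 8 query copies.  The package then asks the
structural questions the model exists to answer:

* which subunit offsets does each interaction face engage
  (type Ia pivot → `n−1`; type IIb pivot → acidic partner on `n+4`;
  type IIa pivot → `n−3`/`n−4`),
* which residues carry the most favourable interface energy (per-residue
  decomposition, aggregated per residue as the **mean of the four lowest
  copy energies** across the eight query copies), and
* what a point mutation does to each interface class — e.g. the
  lysine→glutamate charge flip at the Ia pivot, which turns a salt bridge
  into electrostatic repulsion.

Everything runs against a packaged synthetic fixture with known ground
truth: a layered 6:4:4 left-handed helical lattice (twist −98° ≈ 3.7
subunits/turn) of a compact marker domain whose charged/aromatic residues
sit on the face-equivalent positions.  Any real multi-chain template PDB
can be substituted through the same interfaces.

## Worked example

```python
from ddhelix.synthetic import LatticeSpec, make_lattice
from ddhelix.assembly import LayerPlan, build_extended_layer, reanchor, thread_query
from ddhelix.structure import chain_sequence
from ddhelix.interfaces import (contact_map, face_offsets, SYNTHETIC_FACES,
                                per_residue_energy, rank_residues)

template, manifest = make_lattice(LatticeSpec())
plan = LayerPlan.from_manifest(manifest)
query = thread_query(template.chain("G"), chain_sequence(template.chain("G")))
octamer = reanchor(build_extended_layer(query, template, plan),
                   template, plan.layer_chain_ids["IRAK2"])
print("layer counts:", octamer.manifest()["layer_counts"])

contacts = contact_map(octamer)
print("contact offsets:", sorted({c.offset for c in contacts}))
ia = face_offsets(octamer, contacts, SYNTHETIC_FACES["Ia"])
print("Ia pivot nearest partners:", ia[2]["nearest"])
for rec in rank_residues(per_residue_energy(octamer))[:5]:
    print(f"{rec.resname}{rec.residue}: {rec.aggregated:.2f}")
```

prints

```
layer counts: {'MYD88': 6, 'IRAK4': 4, 'QUERY': 8}
contact offsets: [1, 3, 4]
Ia pivot nearest partners: {11: -1, 12: -1, 13: -1, 14: -1, 15: -1, 16: -1, 17: -1, 18: -1}
ASP12: -8.92
LYS2: -6.95
ASP35: -6.61
ARG16: -6.16
TRP42: -2.08
```

The two-stage build yields exactly 8 query subunits under the 6:4
template layers; touching subunits sit only at offsets ±1, ±3, ±4; every
copy's Ia-pivot lysine has its `n−1` neighbour as nearest partner; and the
five face markers (the Lys/Asp salt-bridge pair of the type I interface,
the Arg/Asp pair of the IIb interface, and the IIa tryptophan) carry the
most favourable aggregated interface energies.  Energies are on a
kcal/mol-like scale but are meaningful at rank/sign level only (see
`docs/methods.md`).

The same chain is available from the shell:

```sh
ddhelix run --outdir out --seed 7       # simulate + build + debump + analyze + scan
ddhelix simulate --out fixture.pdb --manifest fixture.json
ddhelix lattice --in fixture.pdb --chains A,B,C,D,E,F
```

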