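"""Shared fixtures: synthetic template, built octamer, toy constructs."""
from __future__ import annotations

import numpy as np
import pytest

from ddhelix.assembly import (Assembly, LayerPlan, Subunit,
                              build_extended_layer, reanchor, thread_query)
from ddhelix.builders import backbone_from_dihedrals, build_residue
from ddhelix.structure import Chain, Structure, chain_sequence
from ddhelix.synthetic import LatticeSpec, make_lattice

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.123  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.773  -1.210  1.00  0.00           C
ATOM      6  N   GLY A   2       3.332   1.536  -0.130  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.984   2.841  -0.150  1.00  0.00           C
ATOM      8  C   GLY A   2       5.482   2.686  -0.370  1.00  0.00           C
ATOM      9  O   GLY A   2       6.010   1.577  -0.480  1.00  0.00           O
ATOM     10  N   TRP A   3       6.200   3.804  -0.440  1.00  0.00           N
ATOM     11  CA  TRP A   3       7.650   3.780  -0.650  1.00  0.00           C
ATOM     12  C   TRP A   3       8.350   5.100  -0.350  1.00  0.00           C
ATOM     13  O   TRP A   3       7.700   6.140  -0.230  1.00  0.00           O
ATOM     14  CB  TRP A   3       8.280   2.650   0.180  1.00  0.00           C
TER      15      TRP A   3
END
"""

TOY_SEQUENCE = "AGW"


@pytest.fixture()
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture(scope="session")
def lattice_spec():
    return LatticeSpec()


@pytest.fixture(scope="session")
def template_and_manifest(lattice_spec):
    return make_lattice(lattice_spec)


@pytest.fixture(scope="session")
def octamer(template_and_manifest):
    """The two-stage extended assembly built on the synthetic template."""
    template, manifest = template_and_manifest
    plan = LayerPlan.from_manifest(manifest)
    query = thread_query(template.chain("G"), chain_sequence(template.chain("G")))
    asm = build_extended_layer(query, template, plan)
    return reanchor(asm, template, plan.layer_chain_ids["IRAK2"])


def single_residue_chain(chain_id: str, resname: str, seq_id: int = 1,
                         offset=(0.0, 0.0, 0.0), chi=None) -> Chain:
    """One ideally-built residue on a minimal backbone, rigidly shifted."""
    bb = backbone_from_dihedrals([(-57.0, -47.0)])[0]
    res = build_residue(seq_id, resname, bb, chi=chi)
    for a in res.atoms:
        a.coord = a.coord + np.asarray(offset, dtype=float)
    return Chain(id=chain_id, residues=[res])


def two_subunit_assembly(chain_a: Chain, chain_b: Chain,
                         layers=("QUERY", "QUERY")) -> Assembly:
    return Assembly(subunits=[
        Subunit(helix_index=1, layer=layers[0], local_index=1,
                structure=Structure(chains=[chain_a])),
        Subunit(helix_index=2, layer=layers[1], local_index=2,
                structure=Structure(chains=[chain_b])),
    ])


@pytest.fixture()
def salt_bridge_pair():
    """Two single-residue subunits: a Lys whose ammonium sits ~3 A from the
    carboxylate carbon of an Asp on the other subunit."""
    from scipy.spatial.transform import Rotation

    lys_chain = single_residue_chain("A", "LYS")
    nz = lys_chain.residues[0].atom("NZ").coord
    ce = lys_chain.residues[0].atom("CE").coord
    direction = (nz - ce) / np.linalg.norm(nz - ce)
    asp_chain = single_residue_chain("B", "ASP")
    asp = asp_chain.residues[0]
    cg, cb = asp.atom("CG").coord, asp.atom("CB").coord
    tip = (cg - cb) / np.linalg.norm(cg - cb)
    # point the Asp side chain back at the ammonium, body on the far side
    R, _ = Rotation.align_vectors([-direction], [tip])
    target = nz + 3.0 * direction
    for a in asp.atoms:
        a.coord = R.as_matrix() @ (a.coord - cg) + target
    asm = two_subunit_assembly(lys_chain, asp_chain,
                               layers=("QUERY", "IRAK4"))
    # sanity: nothing interpenetrates in the constructed geometry
    from scipy.spatial import cKDTree
    xa = np.array([a.coord for a in lys_chain.residues[0].atoms])
    xb = np.array([a.coord for a in asp.atoms])
    assert cKDTree(xa).query(xb)[0].min() > 2.5
    return asm
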