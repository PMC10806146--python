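"""Threading stand-in and the two-stage assembly construction."""
import numpy as np
import pytest

from ddhelix.assembly import (CoverageError, LayerPlan, build_extended_layer,
                              reanchor, thread_query)
from ddhelix.lattice import estimate_generator
from ddhelix.structure import Structure, chain_sequence
from ddhelix.superpose import kabsch
from ddhelix.topology import SIDECHAIN_ZMATRIX


def test_thread_identical_sequence_preserves_coordinates(template_and_manifest):
    template, _ = template_and_manifest
    chain = template.chain("G")
    threaded = thread_query(chain, chain_sequence(chain))
    assert len(threaded.chains[0].residues) == len(chain.residues)
    for r1, r2 in zip(threaded.chains[0].residues, chain.residues):
        assert r1.name == r2.name
        for a in r2.atoms:
            assert np.allclose(r1.atom(a.name).coord, a.coord)


def test_thread_substitution_changes_atom_count_only(template_and_manifest):
    template, _ = template_and_manifest
    chain = template.chain("G")
    seq = chain_sequence(chain)
    mutated = seq[:5] + "W" + seq[6:]  # ALA6 -> TRP6
    threaded = thread_query(chain, mutated)
    res = threaded.chains[0].residue(6)
    assert res.name == "TRP"
    # atom-count arithmetic from the topology table: TRP has 9 more
    # side-chain atoms beyond CB than ALA
    diff = len(SIDECHAIN_ZMATRIX["TRP"]) - len(SIDECHAIN_ZMATRIX["ALA"])
    orig = template.chain("G").residue(6)
    assert len(res.atoms) - len(orig.atoms) == diff
    for n in ("N", "CA", "C", "O", "CB"):
        assert np.allclose(res.atom(n).coord, orig.atom(n).coord)


def test_thread_to_glycine_drops_cb(template_and_manifest):
    template, _ = template_and_manifest
    chain = template.chain("G")
    seq = chain_sequence(chain)
    threaded = thread_query(chain, seq[:5] + "G" + seq[6:])
    res = threaded.chains[0].residue(6)
    assert res.name == "GLY"
    assert not res.has_atom("CB")


def test_thread_coverage_error(template_and_manifest):
    template, _ = template_and_manifest
    chain = template.chain("G")
    with pytest.raises(CoverageError):
        # a sequence twice the template length cannot be 80% covered
        thread_query(chain, chain_sequence(chain) * 2)


def test_build_zero_targets_keeps_template_only(template_and_manifest):
    template, manifest = template_and_manifest
    plan = LayerPlan.from_manifest(manifest)
    plan.targets = []
    query = Structure(chains=[template.chain("G")]).copy()
    asm = build_extended_layer(query, template, plan)
    counts = asm.layer_counts()
    assert counts == {"MYD88": 6, "IRAK4": 4}


def test_build_places_one_copy_per_target(octamer):
    counts = octamer.layer_counts()
    assert counts["QUERY"] == 8
    assert counts["MYD88"] == 6 and counts["IRAK4"] == 4
    assert [s.provenance["rmsd"] for s in octamer.query_subunits()] == \
        pytest.approx([0.0] * 8, abs=1e-9)


def test_helix_indices_after_reanchor(octamer):
    assert sorted(s.helix_index for s in octamer.query_subunits()) == \
        list(range(11, 19))
    assert sorted(s.local_index for s in octamer.query_subunits()) == \
        list(range(1, 9))


def test_reanchored_tetramer_matches_joint_kabsch(template_and_manifest,
                                                  octamer):
    """CA rmsd of query copies 1-4 to the anchor layer equals the direct
    four-subunit joint Kabsch optimum (0 for the identical-sequence query)."""
    template, manifest = template_and_manifest
    anchors = [r["chain_id"] for r in manifest["layers"]
               if r["layer"] == "IRAK2"]
    queries = sorted(octamer.query_subunits(), key=lambda s: s.local_index)
    mobile, fixed = [], []
    for sub, cid in zip(queries[:4], anchors):
        mobile.append(sub.chain.ca_coords())
        fixed.append(template.chain(cid).ca_coords())
    mobile, fixed = np.vstack(mobile), np.vstack(fixed)
    joint = kabsch(mobile, fixed)
    direct = float(np.sqrt(np.mean(np.sum((mobile - fixed) ** 2, axis=1))))
    assert direct == pytest.approx(joint.rmsd, abs=1e-9)
    assert direct == pytest.approx(0.0, abs=1e-9)


def test_reanchor_moves_all_copies_rigidly(template_and_manifest):
    template, manifest = template_and_manifest
    plan = LayerPlan.from_manifest(manifest)
    query = thread_query(template.chain("G"),
                         chain_sequence(template.chain("G")))
    asm = build_extended_layer(query, template, plan)
    before = {s.local_index: s.chain.ca_coords()
              for s in asm.query_subunits()}
    asm2 = reanchor(asm, template, plan.layer_chain_ids["IRAK2"])
    after = {s.local_index: s.chain.ca_coords()
             for s in asm2.query_subunits()}
    # internal pairwise distances between copies 5-8 are preserved exactly
    for a, b in [(5, 6), (5, 8), (7, 8)]:
        d_before = np.linalg.norm(before[a] - before[b], axis=1)
        d_after = np.linalg.norm(after[a] - after[b], axis=1)
        assert np.allclose(d_before, d_after, atol=1e-9)
    # template layers untouched
    for s in asm2.subunits:
        if s.layer != "QUERY":
            orig = template.chain(s.chain.id)
            assert np.allclose(s.chain.ca_coords(), orig.ca_coords())


def test_reanchor_of_already_anchored_layer_is_identity(template_and_manifest):
    template, manifest = template_and_manifest
    plan = LayerPlan.from_manifest(manifest)
    anchors = plan.layer_chain_ids["IRAK2"]
    query = thread_query(template.chain("K"),
                         chain_sequence(template.chain("K")))
    # place copies directly on the anchor layer only
    plan.targets = anchors
    asm = build_extended_layer(query, template, plan)
    asm2 = reanchor(asm, template, anchors)
    for s1, s2 in zip(asm.query_subunits(), asm2.query_subunits()):
        assert np.allclose(s1.chain.ca_coords(), s2.chain.ca_coords(),
                           atol=1e-9)


def test_construction_determinism(template_and_manifest):
    template, manifest = template_and_manifest
    plan = LayerPlan.from_manifest(manifest)
    query = thread_query(template.chain("G"),
                         chain_sequence(template.chain("G")))

    def run():
        asm = build_extended_layer(query, template, plan)
        return reanchor(asm, template, plan.layer_chain_ids["IRAK2"])

    a1, a2 = run(), run()
    assert a1.manifest() == a2.manifest()
    for s1, s2 in zip(a1.subunits, a2.subunits):
        for r1, r2 in zip(s1.chain.residues, s2.chain.residues):
            for at1, at2 in zip(r1.atoms, r2.atoms):
                assert np.array_equal(at1.coord, at2.coord)


def test_placement_preserves_internal_geometry(octamer, template_and_manifest):
    template, _ = template_and_manifest
    ref = template.chain("G").ca_coords()
    ref_d = np.linalg.norm(ref[:, None] - ref[None], axis=-1)
    for s in octamer.query_subunits():
        ca = s.chain.ca_coords()
        d = np.linalg.norm(ca[:, None] - ca[None], axis=-1)
        assert np.allclose(d, ref_d, atol=1e-9)


def test_query_layer_obeys_template_screw(octamer, lattice_spec):
    subs = [s.structure for s in
            sorted(octamer.query_subunits(), key=lambda x: x.helix_index)]
    g = estimate_generator(subs)
    assert g.twist == pytest.approx(lattice_spec.twist, abs=1e-6)
    assert g.rise == pytest.approx(lattice_spec.rise, abs=1e-6)


def test_build_unknown_target_chain(template_and_manifest):
    template, manifest = template_and_manifest
    plan = LayerPlan.from_manifest(manifest)
    plan.targets = ["Z"]
    query = Structure(chains=[template.chain("G")]).copy()
    with pytest.raises(ValueError):
        build_extended_layer(query, template, plan)
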