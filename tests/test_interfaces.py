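"""Contact maps, face offsets, interface classification and the
simplified per-residue energy decomposition."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddhelix.assembly import Assembly, Subunit
from ddhelix.interfaces import (PotentialParams, SYNTHETIC_FACES,
                                classify_interface, contact_map, face_offsets,
                                per_residue_energy, rank_residues,
                                total_intersubunit_energy, ResidueEnergy)
from ddhelix.lattice import place_at_index
from ddhelix.synthetic import LatticeSpec, make_marker_domain
from conftest import single_residue_chain, two_subunit_assembly


def _subassembly(spec, indices):
    """All-query assembly of lattice subunits at the given helix indices."""
    dom = make_marker_domain(spec)
    screw = spec.screw()
    subs = []
    for k, n in enumerate(indices, start=1):
        placed = place_at_index(dom, screw, n - 1)
        placed.chains[0].id = f"Q{k}"
        subs.append(Subunit(helix_index=n, layer="QUERY", structure=placed,
                            local_index=k))
    return Assembly(subunits=subs)


def test_contact_map_empty_when_far_apart():
    a = single_residue_chain("A", "ALA")
    b = single_residue_chain("B", "ALA", offset=(80.0, 0.0, 0.0))
    assert contact_map(two_subunit_assembly(a, b)) == []


def test_contact_offset_spectrum_of_touching_lattice(octamer):
    contacts = contact_map(octamer)
    offsets = {abs(c.offset) for c in contacts}
    assert offsets == {1, 3, 4}


def test_contact_map_matches_brute_force(lattice_spec):
    asm = _subassembly(lattice_spec, [1, 2])
    contacts = contact_map(asm, cutoff=4.5)
    # exhaustive all-pairs oracle
    expected = {}
    c1, c2 = asm.subunits[0].chain, asm.subunits[1].chain
    for r1 in c1.residues:
        for r2 in c2.residues:
            d = min(np.linalg.norm(a1.coord - a2.coord)
                    for a1 in r1.atoms for a2 in r2.atoms)
            if d <= 4.5:
                expected[(1, r1.seq_id, 2, r2.seq_id)] = d
    got = {(c.subunit_i, c.residue_i, c.subunit_j, c.residue_j): c.distance
           for c in contacts}
    assert set(got) == set(expected)
    for key in got:
        assert got[key] == pytest.approx(expected[key], abs=1e-9)


def test_classification_rules():
    assert classify_interface(-1) == "Ia"
    assert classify_interface(1) == "Ib"
    assert classify_interface(-3) == "IIa"
    assert classify_interface(-4) == "IIa"
    assert classify_interface(4) == "IIb"
    assert classify_interface(2) == "unclassified"
    assert classify_interface(-2) == "unclassified"
    assert classify_interface(7) == "unclassified"


def test_face_offsets_on_single_subunit_assembly(lattice_spec):
    asm = _subassembly(lattice_spec, [1])
    out = face_offsets(asm, contact_map(asm), SYNTHETIC_FACES["Ia"])
    assert out[2]["offsets"] == {1: []}
    assert out[2]["nearest"] == {}
    assert out[2]["histogram"] == {}


def test_face_offsets_antisymmetric_bookkeeping(lattice_spec):
    asm = _subassembly(lattice_spec, [1, 2])
    contacts = contact_map(asm)
    ia = face_offsets(asm, contacts, SYNTHETIC_FACES["Ia"])
    partner = face_offsets(
        asm, contacts,
        type(SYNTHETIC_FACES["Ia"])("Ia", pivots=[12]))
    # if the Lys pivot of subunit 2 sees its partner at -1, the Asp partner
    # residue on subunit 1 reports +1
    assert set(ia[2]["offsets"][2]) == {-1}
    assert set(partner[12]["offsets"][1]) == {1}


def test_missing_pivot_raises_with_mapping(octamer):
    from ddhelix.interfaces import FaceDefinition
    with pytest.raises(KeyError, match="model positions"):
        face_offsets(octamer, [], FaceDefinition("Ia", pivots=[999]))


def test_octamer_pivot_offsets(octamer):
    """The built model reproduces the face-offset geometry: Ia pivot
    partners at n-1, IIb pivot at n+4, IIa pivot at n-3/n-4."""
    contacts = contact_map(octamer)
    ia = face_offsets(octamer, contacts, SYNTHETIC_FACES["Ia"])
    assert all(v == -1 for v in ia[2]["nearest"].values())
    iib = face_offsets(octamer, contacts, SYNTHETIC_FACES["IIb"])
    assert set(iib[16]["histogram"]) == {4}
    # copies 1-4 (with an n+4 partner below) have that partner nearest
    assert [iib[16]["nearest"][n] for n in (11, 12, 13, 14)] == [4, 4, 4, 4]
    iia = face_offsets(octamer, contacts, SYNTHETIC_FACES["IIa"])
    assert set(iia[42]["histogram"]) == {-3, -4}


def test_energy_zero_beyond_cutoff():
    a = single_residue_chain("A", "LYS")
    b = single_residue_chain("B", "ASP", offset=(50.0, 0.0, 0.0))
    energies = per_residue_energy(two_subunit_assembly(a, b))
    assert all(e.aggregated == 0.0 for e in energies)
    assert all(v == 0.0 for e in energies for v in e.per_copy.values())


def test_lowest_four_aggregation_rule():
    e = ResidueEnergy(residue=1, resname="ALA",
                      per_copy=dict(enumerate([-5, -4, -3, -2, -1, 0, 1, 2])),
                      aggregated=0.0)
    vals = sorted(e.per_copy.values())[:4]
    assert np.mean(vals) == pytest.approx(-3.5)
    # and the implementation applies exactly that rule
    spec = LatticeSpec()
    asm = _subassembly(spec, list(range(1, 9)))
    for rec in per_residue_energy(asm):
        assert rec.aggregated == pytest.approx(
            np.mean(sorted(rec.per_copy.values())[:4]))
        assert not rec.flagged
        assert rec.aggregated <= np.mean(list(rec.per_copy.values())) + 1e-12


def test_fewer_than_four_copies_flagged(lattice_spec):
    asm = _subassembly(lattice_spec, [1, 2])
    for rec in per_residue_energy(asm):
        assert rec.flagged
        assert rec.aggregated == pytest.approx(
            np.mean(list(rec.per_copy.values())))


def test_salt_bridge_energy_closed_form(salt_bridge_pair):
    """The Lys/Asp pair term matches the hand-computed screened Coulomb +
    Lennard-Jones value at the constructed geometry."""
    params = PotentialParams()
    nz = salt_bridge_pair.subunits[0].chain.residues[0].atom("NZ").coord
    cg = salt_bridge_pair.subunits[1].chain.residues[0].atom("CG").coord
    r = float(np.linalg.norm(nz - cg))
    expected_elec = params.coulomb_constant * (1.0) * (-1.0) / (4.0 * r * r)
    # the charged-pair electrostatic term dominates the total energy sign
    total = total_intersubunit_energy(salt_bridge_pair, params)
    assert expected_elec < 0
    assert total < 0
    # electrostatics isolated: switch LJ off by comparing charged vs
    # uncharged parameterization
    neutral = PotentialParams(charges={})
    lj_only = total_intersubunit_energy(salt_bridge_pair, neutral)
    assert total - lj_only == pytest.approx(expected_elec, rel=1e-9)


def test_energy_conservation_identity(lattice_spec):
    """Sum of per-copy residue terms equals exactly twice the total
    inter-subunit pair energy on an all-query assembly."""
    for indices in ([1, 2], [1, 2, 3], [1, 4, 5, 8]):
        asm = _subassembly(lattice_spec, indices)
        params = PotentialParams()
        total = total_intersubunit_energy(asm, params)
        residues = per_residue_energy(asm, params)
        acc = sum(v for e in residues for v in e.per_copy.values())
        assert acc == pytest.approx(2.0 * total, rel=1e-9, abs=1e-9)


def test_rank_residues_order_and_ties():
    recs = [ResidueEnergy(3, "ALA", {1: 0.0}, 0.0),
            ResidueEnergy(1, "ALA", {1: 0.0}, 0.0),
            ResidueEnergy(2, "TRP", {1: -2.0}, -2.0)]
    ranked = rank_residues(recs)
    assert [r.residue for r in ranked] == [2, 1, 3]


def test_markers_dominate_energy_ranking(octamer):
    """The charged/aromatic face markers carry the most favourable
    aggregated interface energies in the built octamer."""
    ranked = rank_residues(per_residue_energy(octamer))
    top5 = {r.residue for r in ranked[:5]}
    assert top5 == {2, 12, 16, 35, 42}


def test_missing_parameter_error(lattice_spec):
    asm = _subassembly(lattice_spec, [1, 2])
    bad = PotentialParams(vdw_radii={"C": 1.7})  # N, O missing
    with pytest.raises(KeyError, match="potential parameters"):
        per_residue_energy(asm, bad)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=-50, max_value=50,
                          allow_nan=False), min_size=4, max_size=12))
def test_lowest_four_mean_never_exceeds_full_mean(values):
    lowest4 = float(np.mean(sorted(values)[:4]))
    assert lowest4 <= float(np.mean(values)) + 1e-9
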