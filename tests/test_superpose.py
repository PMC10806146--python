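"""Kabsch superposition and sequence-guided correspondence."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ddhelix.structure import Chain, Structure
from ddhelix.superpose import (RigidTransform, TooFewPairsError,
                               UnderdeterminedError, align_chains, kabsch,
                               superpose_homolog)
from ddhelix.builders import backbone_from_dihedrals, build_residue


def _cloud(n=10, seed=0):
    return np.random.default_rng(seed).normal(size=(n, 3)) * 8.0


def test_kabsch_identity_on_equal_sets():
    P = _cloud()
    res = kabsch(P, P)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-10)
    assert np.allclose(res.transform.translation, 0.0, atol=1e-10)


def test_kabsch_recovers_known_transform():
    P = _cloud()
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    t = np.array([1.0, 2.0, 3.0])
    Q = P @ R.T + t
    res = kabsch(P, Q)
    assert res.rmsd <= 1e-10
    assert np.allclose(res.transform.rotation, R, atol=1e-10)
    assert np.allclose(res.transform.translation, t, atol=1e-10)


def test_kabsch_beats_random_rotation_sampling():
    """Closed-form optimum vs a 1,000-sample brute-force rotation oracle."""
    rng = np.random.default_rng(42)
    P = _cloud(10, seed=1)
    Q = _cloud(10, seed=2)
    best = kabsch(P, Q).rmsd
    cp, cq = P.mean(0), Q.mean(0)
    for R in Rotation.random(1000, random_state=7):
        moved = (P - cp) @ R.as_matrix().T + cq
        sampled = np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1)))
        assert best <= sampled + 1e-12


def test_kabsch_never_returns_reflection():
    # planar points invite a reflection; determinant must stay +1
    P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
    Q = P.copy()
    Q[:, 0] = -Q[:, 0]
    res = kabsch(P, Q)
    assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0)


def test_kabsch_underdetermined():
    with pytest.raises(UnderdeterminedError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


def test_kabsch_collinear_warns_but_proper():
    line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
    with pytest.warns(UserWarning):
        res = kabsch(line, line + np.array([0.0, 1.0, 0.0]))
    assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0)


def test_rmsd_invariant_under_joint_rigid_motion():
    P, Q = _cloud(12, seed=3), _cloud(12, seed=4)
    base = kabsch(P, Q).rmsd
    R = Rotation.random(random_state=11).as_matrix()
    t = np.array([5.0, -2.0, 0.5])
    moved = kabsch(P @ R.T + t, Q @ R.T + t).rmsd
    assert moved == pytest.approx(base, abs=1e-9)


def test_forward_backward_compose_to_identity():
    P, Q = _cloud(12, seed=5), _cloud(12, seed=6)
    fwd = kabsch(P, Q).transform
    back = kabsch(Q, P).transform
    comp = fwd.compose(back)
    assert np.allclose(comp.rotation, np.eye(3), atol=1e-8)
    assert np.allclose(comp.translation, 0.0, atol=1e-8)


def test_rigid_transform_rejects_improper():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


def _poly_chain(seq3, chain_id="A"):
    bbs = backbone_from_dihedrals([(-57.0, -47.0)] * len(seq3))
    return Chain(id=chain_id, residues=[
        build_residue(i + 1, name, bb) for i, (name, bb) in
        enumerate(zip(seq3, bbs))])


def test_align_identical_sequences_identity_pairing():
    c1 = _poly_chain(["ALA", "GLY", "TRP", "LYS", "ASP"] * 3)
    c2 = _poly_chain(["ALA", "GLY", "TRP", "LYS", "ASP"] * 3, "B")
    pairs = align_chains(c1, c2)
    assert pairs == [(i, i) for i in range(15)]


def test_align_with_internal_deletion():
    names = ["ALA", "GLY", "TRP", "LYS", "ASP", "PHE", "SER", "GLU",
             "ARG", "TYR", "LEU", "MET"]
    template = _poly_chain(names)
    query = _poly_chain(names[:5] + names[6:], "B")  # one internal deletion
    pairs = align_chains(query, template)
    assert len(pairs) == len(names) - 1


def test_unrelated_sequences_refuse_superposition():
    polya = _poly_chain(["ALA"] * 15)
    polyw = _poly_chain(["TRP"] * 15, "B")
    pairs = align_chains(polya, polyw)
    assert len(pairs) <= 15
    with pytest.raises(TooFewPairsError):
        superpose_homolog(Structure(chains=[polya]), polyw)


def test_superpose_homolog_restores_premoved_copy():
    chain = _poly_chain(["ALA", "GLY", "TRP", "LYS", "ASP"] * 5)
    template = Structure(chains=[chain])
    R = Rotation.from_euler("xyz", [10, 40, -30], degrees=True).as_matrix()
    t = np.array([4.0, -7.0, 2.0])
    moved = template.transformed(R, t)
    placed, res = superpose_homolog(moved, chain)
    assert res.rmsd <= 1e-6
    for (_, r1, a1), (_, r2, a2) in zip(placed.iter_atoms(),
                                        template.iter_atoms()):
        assert np.allclose(a1.coord, a2.coord, atol=1e-6)
    # the input was not modified
    assert not np.allclose(moved.chains[0].residues[0].atom("CA").coord,
                           template.chains[0].residues[0].atom("CA").coord)


def test_superpose_onto_every_template_subunit(template_and_manifest):
    """Placing one query onto all subunits of a symmetric template gives
    identical fit quality everywhere."""
    template, _ = template_and_manifest
    query = Structure(chains=[template.chain("A")]).copy()
    rmsds = []
    for c in "ABCDEFGH":
        _, res = superpose_homolog(query, template.chain(c))
        rmsds.append(res.rmsd)
    assert np.allclose(rmsds, rmsds[0], atol=1e-6)
    assert rmsds[0] == pytest.approx(0.0, abs=1e-9)
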