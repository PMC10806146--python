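"""Optimal rigid-body superposition and sequence-guided chain correspondence.

Superposition is CA-based Kabsch (closed-form SVD solution, proper rotations
only).  Correspondence between homologous death-domain chains comes from a
global Needleman-Wunsch alignment (BLOSUM62, affine gaps) of the one-letter
sequences; only aligned non-gap columns become coordinate pairs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure import Chain, Structure, chain_sequence

__all__ = [
    "RigidTransform", "SuperpositionResult",
    "kabsch", "align_chains", "superpose_homolog",
    "UnderdeterminedError", "TooFewPairsError",
]

#: alignment defaults, exposed so callers can override consistently
GAP_OPEN = -10.0
GAP_EXTEND = -1.0


class UnderdeterminedError(ValueError):
    """Fewer than three point pairs: the rigid transform is not determined."""


class TooFewPairsError(ValueError):
    """Chain correspondence too short for a reliable superposition."""


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation is improper (determinant != +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: ``(self o other)(x) = self(other(x))``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def is_identity(self, atol: float = 1e-8) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=atol)
                and np.allclose(self.translation, 0.0, atol=atol))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    correspondence: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be nonnegative")
        if self.correspondence and len(self.correspondence) != self.n_pairs:
            raise ValueError("n_pairs must equal the correspondence length")


def kabsch(mobile: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rigid transform taking ``mobile`` onto ``fixed``.

    Closed-form SVD (Kabsch) solution over paired point sets; a reflection is
    never returned, so for degenerate (e.g. planar/collinear) inputs the best
    proper rotation is used and a warning is emitted for collinear sets.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and fixed must be matching N x 3 arrays")
    n = P.shape[0]
    if n < 3:
        raise UnderdeterminedError(f"need at least 3 point pairs, got {n}")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        warnings.warn("near-collinear point set: rotation about the line is arbitrary",
                      stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(RigidTransform(R, t), rmsd, n)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def align_chains(query: Chain, template: Chain) -> list[tuple[int, int]]:
    """Residue-index correspondence (query_idx, template_idx) from a global
    BLOSUM62 alignment of the two chain sequences."""
    if not query.residues or not template.residues:
        raise ValueError("cannot align an empty chain")
    qseq = chain_sequence(query)
    tseq = chain_sequence(template)
    aln = _make_aligner().align(qseq, tseq)[0]
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        pairs.extend((qi, ti) for qi, ti in zip(range(qs, qe), range(ts, te)))
    return pairs


def superpose_homolog(query: Structure, template_chain: Chain,
                      min_pairs: int = 20) -> tuple[Structure, SuperpositionResult]:
    """Place a copy of ``query`` (single-chain) onto a homologous template chain.

    The rigid transform is the CA Kabsch optimum over the sequence-aligned
    residue pairs; the input ``query`` is left untouched.
    """
    if len(query.chains) != 1:
        raise ValueError("query must contain exactly one chain")
    qchain = query.chains[0]
    pairs = align_chains(qchain, template_chain)
    ca_pairs = [(qi, ti) for qi, ti in pairs
                if qchain.residues[qi].has_atom("CA")
                and template_chain.residues[ti].has_atom("CA")]
    if len(ca_pairs) < min_pairs:
        raise TooFewPairsError(
            f"only {len(ca_pairs)} aligned CA pairs (need >= {min_pairs})")
    mobile = np.array([qchain.residues[qi].atom("CA").coord for qi, _ in ca_pairs])
    fixed = np.array([template_chain.residues[ti].atom("CA").coord for _, ti in ca_pairs])
    res = kabsch(mobile, fixed)
    res.correspondence = ca_pairs
    placed = query.transformed(res.transform.rotation, res.transform.translation)
    return placed, res
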