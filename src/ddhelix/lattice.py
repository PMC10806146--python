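"""Screw-axis analysis of the helical death-domain lattice.

A single-start helical assembly is generated by one screw transform: a
rotation (twist) about an axis combined with a translation (rise) along it.
Sign convention: the axis direction is oriented so the rise is nonnegative,
and the twist is the right-handed rotation angle about that direction, so a
left-handed helix has negative twist with positive rise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Structure
from .superpose import RigidTransform, superpose_homolog

__all__ = [
    "ScrewTransform", "HelixParams",
    "screw_decompose", "screw_recompose", "place_at_index",
    "transform_between_subunits", "estimate_generator",
]

_ANGLE_EPS = 1e-9  # degrees below which a rotation counts as none


@dataclass
class ScrewTransform:
    axis_direction: np.ndarray
    axis_point: np.ndarray
    twist: float  # degrees, in (-180, 180]
    rise: float  # Angstrom along axis_direction
    is_identity: bool = False

    def __post_init__(self) -> None:
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        if not np.isclose(np.linalg.norm(self.axis_direction), 1.0, atol=1e-8):
            raise ValueError("axis_direction must be a unit vector")
        if not (-180.0 < self.twist <= 180.0):
            raise ValueError("twist must lie in (-180, 180]")


@dataclass
class HelixParams:
    subunits_per_turn: float
    handedness: str  # "left" | "right" | "none"

    @classmethod
    def from_screw(cls, s: ScrewTransform) -> "HelixParams":
        if abs(s.twist) < _ANGLE_EPS:
            return cls(subunits_per_turn=np.inf, handedness="none")
        hand = "left" if (s.twist < 0 and s.rise >= 0) or (s.twist > 0 and s.rise < 0) \
            else "right"
        return cls(subunits_per_turn=360.0 / abs(s.twist), handedness=hand)


def screw_decompose(t: RigidTransform) -> ScrewTransform:
    """Axis/twist/rise decomposition of a proper rigid motion.

    The axis point is the minimum-norm point on the screw axis.  A pure
    translation reports twist 0 with the axis along the translation; a true
    identity sets ``is_identity``.
    """
    rot = Rotation.from_matrix(t.rotation)
    rotvec = rot.as_rotvec()
    angle = np.degrees(np.linalg.norm(rotvec))
    trans = t.translation
    if angle < _ANGLE_EPS:
        norm = np.linalg.norm(trans)
        if norm < 1e-12:
            return ScrewTransform(np.array([0.0, 0.0, 1.0]), np.zeros(3),
                                  0.0, 0.0, is_identity=True)
        return ScrewTransform(trans / norm, np.zeros(3), 0.0, float(norm))
    axis = rotvec / np.linalg.norm(rotvec)
    twist = angle
    rise = float(np.dot(trans, axis))
    # orient the axis so rise >= 0; the twist flips sign with it
    if rise < 0:
        axis = -axis
        twist = -twist
        rise = -rise
    if twist > 180.0:  # keep within (-180, 180]
        twist -= 360.0
    t_perp = trans - np.dot(trans, axis) * axis
    # (I - R) c = t_perp has the min-norm solution via the pseudoinverse
    c = np.linalg.pinv(np.eye(3) - t.rotation) @ t_perp
    return ScrewTransform(axis, c, float(twist), rise)


def _screw_rigid(axis: np.ndarray, point: np.ndarray,
                 twist_deg: float, rise: float) -> RigidTransform:
    R = Rotation.from_rotvec(np.radians(twist_deg) * axis).as_matrix()
    t = rise * axis + (np.eye(3) - R) @ point
    return RigidTransform(R, t)


def screw_recompose(s: ScrewTransform) -> RigidTransform:
    """The rigid motion generated by a screw transform."""
    if s.is_identity:
        return RigidTransform.identity()
    return _screw_rigid(s.axis_direction, s.axis_point, s.twist, s.rise)


def screw_power(s: ScrewTransform, n: int) -> RigidTransform:
    """n-fold composition of a screw with itself (n may be negative)."""
    if s.is_identity or n == 0:
        return RigidTransform.identity()
    return _screw_rigid(s.axis_direction, s.axis_point, n * s.twist, n * s.rise)


def place_at_index(reference: Structure, s: ScrewTransform, n: int) -> Structure:
    """Copy of ``reference`` moved ``n`` screw steps along the helix.

    ``n = 0`` is the identity; negative ``n`` moves up-helix (against the
    axis direction).
    """
    t = screw_power(s, n)
    return reference.transformed(t.rotation, t.translation)


def transform_between_subunits(a: Structure, b: Structure,
                               min_pairs: int = 20) -> RigidTransform:
    """Kabsch transform mapping subunit ``a``'s CA set onto subunit ``b``'s.

    Subunits must be structurally equivalent (sequence-alignable single
    chains with at least ``min_pairs`` CA pairs).
    """
    _, res = superpose_homolog(a, b.chains[0], min_pairs=min_pairs)
    return res.transform


def estimate_generator(subunits: list[Structure],
                       min_pairs: int = 20) -> ScrewTransform:
    """Estimate the lattice-generating screw from an ordered subunit path.

    The Kabsch transform is computed for every consecutive pair and averaged
    (rotations by quaternion mean, translations arithmetically) before the
    screw decomposition — more robust than a single pair on noisy input.
    """
    if len(subunits) < 2:
        raise ValueError("need at least two subunits along the helix path")
    transforms = [transform_between_subunits(a, b, min_pairs=min_pairs)
                  for a, b in zip(subunits[:-1], subunits[1:])]
    if len(transforms) == 1:
        return screw_decompose(transforms[0])
    mean_rot = Rotation.mean(
        Rotation.from_matrix(np.array([t.rotation for t in transforms])))
    mean_trans = np.mean([t.translation for t in transforms], axis=0)
    return screw_decompose(RigidTransform(mean_rot.as_matrix(), mean_trans))
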