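"""Synthetic layered death-domain helix fixtures with known ground truth.

The generator emulates the myddosome template architecture the pipeline is
built for: a left-handed single-start helical lattice carrying three layers
of death-domain subunits (6 scaffold + 4 kinase-adaptor + 4 bottom-layer
chains by default) with ~3.7 subunits per turn, so that touching subunits
sit at helix-index offsets {+-1, +-3, +-4} and never at +-2 — the contact
regime of death-domain higher-order assemblies.

The subunit is a packaged toy fold: a compact 42-residue three-helix bundle
(poly-alanine) with charged/aromatic marker residues at the positions that
face each interaction surface, so contact-offset and charge-flip tests have
defined targets:

=======  ====  ================  =========================================
residue  type  faces offset      stands in for (IRAK-M numbering)
=======  ====  ================  =========================================
2        LYS   n-1               Lys60 (type Ia pivot)
12       ASP   n+1               Asp33 (Ia partner on the n-1 subunit)
16       ARG   n+4               Arg97 (type IIb pivot)
35       ASP   n-4               Asp19 (IIa-side partner of Arg97)
42       TRP   n-3 / n-4         Trp74 (type IIa pivot)
=======  ====  ================  =========================================

The fold, its orientation in the lattice and the default screw parameters
are frozen constants: they were chosen once so the sigma=0 fixture
reproduces the 1/3/4 offset pattern, and tests treat them as ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builders import backbone_from_dihedrals, build_residue
from .lattice import HelixParams, ScrewTransform, screw_power
from .structure import Chain, Residue, Structure

__all__ = ["LatticeSpec", "make_marker_domain", "make_lattice",
           "DEFAULT_MARKERS", "MARKER_LABELS", "LAYER_NAMES"]

# three-helix bundle: 12-residue helices joined by frozen 3-residue turns
_HELIX = (-57.0, -47.0)
_TURN = [(-90.0, 0.0), (60.0, 30.0), (-80.0, 80.0)]
_PHI_PSI = [_HELIX] * 12 + _TURN + [_HELIX] * 12 + _TURN + [_HELIX] * 12

#: marker residue types at face-equivalent positions (toy numbering)
DEFAULT_MARKERS = {2: "LYS", 12: "ASP", 16: "ARG", 35: "ASP", 42: "TRP"}

# frozen marker rotamers: the Lys ammonium points at the Asp(12) carboxylate
# of the n-1 neighbour and the Arg guanidinium at the Asp(35) carboxylate of
# the n+4 neighbour (~3 A salt bridges in the sigma=0 lattice)
_MARKER_CHI = {
    2: {"chi1": 0.0, "chi2": -60.0, "chi3": -120.0, "chi4": -180.0},
    16: {"chi1": -180.0, "chi2": 60.0, "chi3": 60.0, "chi4": 0.0},
}

#: what each marker stands in for, with its interface face
MARKER_LABELS = {
    2: ("K60-like", "Ia"),
    12: ("D33-like", "Ia-partner"),
    16: ("R97-like", "IIb"),
    35: ("D19-like", "IIa-partner"),
    42: ("W74-like", "IIa"),
}

LAYER_NAMES = ("MYD88", "IRAK4", "IRAK2")

# fixed orientation of the domain frame inside the lattice (chosen with the
# screw defaults; part of the packaged fixture definition)
_DOMAIN_ORIENTATION = np.array([
    [-0.43940025, 0.82998783, 0.34358060],
    [-0.77138558, -0.15263568, -0.61779175],
    [-0.46031697, -0.53649097, 0.70730879],
])

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class LatticeSpec:
    """Parameters of the synthetic layered helix fixture."""

    n_per_layer: tuple[int, ...] = (6, 4, 4)
    rise: float = 4.5  # Angstrom per subunit, positive down-helix
    twist: float = -98.0  # degrees per subunit; negative = left-handed
    radius: float = 18.0  # Angstrom, domain centroid to helix axis
    noise_sigma: float = 0.0  # Gaussian coordinate noise, Angstrom
    seed: int = 0
    markers: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_MARKERS))

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not (0.0 < abs(self.twist) < 180.0):
            raise ValueError("twist must have magnitude in (0, 180)")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if any(n < 0 for n in self.n_per_layer) or sum(self.n_per_layer) < 1:
            raise ValueError("layer sizes must be nonnegative with at least one subunit")

    @property
    def n_subunits(self) -> int:
        return sum(self.n_per_layer)

    def screw(self) -> ScrewTransform:
        """The ground-truth generator screw (axis = z through the origin)."""
        axis = np.array([0.0, 0.0, 1.0])
        return ScrewTransform(axis, np.zeros(3), self.twist, self.rise)


def make_marker_domain(spec: LatticeSpec | None = None,
                       chain_id: str = "Q") -> Structure:
    """The toy death-domain subunit, in its lattice reference position.

    Poly-alanine three-helix bundle with the marker residues of
    ``spec.markers`` grafted in extended rotamers.  The returned coordinates
    are those of helix index 1 (first subunit) of the lattice.
    """
    spec = spec or LatticeSpec()
    backbones = backbone_from_dihedrals(_PHI_PSI)
    residues: list[Residue] = []
    for i, bb in enumerate(backbones, start=1):
        residues.append(build_residue(i, spec.markers.get(i, "ALA"), bb,
                                      chi=_MARKER_CHI.get(i)))
    # center, orient, push out to the helix radius
    coords = np.array([a.coord for r in residues for a in r.atoms])
    center = coords.mean(axis=0)
    shift = np.array([spec.radius, 0.0, 0.0])
    for r in residues:
        for a in r.atoms:
            a.coord = _DOMAIN_ORIENTATION @ (a.coord - center) + shift
    return Structure(chains=[Chain(id=chain_id, residues=residues)],
                     title="synthetic DD-like marker domain",
                     source=f"make_marker_domain(radius={spec.radius})")


def make_lattice(spec: LatticeSpec | None = None) -> tuple[Structure, dict]:
    """Generate the layered helical template plus its ground-truth manifest.

    Subunit ``n`` (1-based) is the ``(n-1)``-fold screw image of the marker
    domain; chain ids run A, B, C, ... in helix order and encode the layer
    through the manifest.  With ``noise_sigma > 0`` seeded Gaussian noise is
    added to every coordinate after placement.
    """
    spec = spec or LatticeSpec()
    if spec.n_subunits > len(_CHAIN_IDS):
        raise ValueError(f"at most {len(_CHAIN_IDS)} subunits supported")
    reference = make_marker_domain(spec)
    screw = spec.screw()
    rng = np.random.default_rng(spec.seed)
    chains: list[Chain] = []
    layer_rows = []
    n = 0
    for layer_name, count in zip(LAYER_NAMES, spec.n_per_layer):
        for _ in range(count):
            t = screw_power(screw, n)
            sub = reference.transformed(t.rotation, t.translation)
            chain = sub.chains[0]
            chain.id = _CHAIN_IDS[n]
            chains.append(chain)
            layer_rows.append({"chain_id": chain.id, "layer": layer_name,
                               "helix_index": n + 1})
            n += 1
    structure = Structure(chains=chains, title="synthetic layered DD helix",
                          source=f"make_lattice(seed={spec.seed})")
    if spec.noise_sigma > 0:
        for _, _, a in structure.iter_atoms():
            a.coord = a.coord + rng.normal(0.0, spec.noise_sigma, size=3)
    params = HelixParams.from_screw(screw)
    manifest = {
        "twist": spec.twist,
        "rise": spec.rise,
        "radius": spec.radius,
        "subunits_per_turn": params.subunits_per_turn,
        "handedness": params.handedness,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "layers": layer_rows,
        "markers": {str(pos): {"residue": name,
                               "stands_for": MARKER_LABELS.get(pos, ("", ""))[0],
                               "face": MARKER_LABELS.get(pos, ("", ""))[1]}
                    for pos, name in spec.markers.items()},
    }
    return structure, manifest
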