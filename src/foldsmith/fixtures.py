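"""Deterministic synthetic backbone fixtures with known ground truth.

Every fixture is generated programmatically (no data files) and annotated
with the parameters it was built from, so tests can compare measured
geometry against construction.  Kinds: ideal-helix, kinked-helix,
ideal-strand, hairpin, three-helix-bundle, flat-sheet, scrambled-decoy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .folddef import FoldDefinition, SegmentSpec, SheetSpec, StrandPairingSpec
from .geometry import BackboneChain, chain_from_coords, torsions_to_coords

HELIX_TORSIONS = (-57.0, -47.0, 180.0)
STRAND_TORSIONS = (-135.0, 135.0, 180.0)

KINDS = (
    "ideal-helix",
    "kinked-helix",
    "ideal-strand",
    "hairpin",
    "three-helix-bundle",
    "flat-sheet",
    "scrambled-decoy",
)


@dataclass
class FixtureSpec:
    kind: str
    length: int = 12
    kink_angle: float = 20.0
    separation: float = 10.5
    n_strands: int = 4
    loop_abego: str = "GG"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


@dataclass
class Fixture:
    chain: BackboneChain
    ground_truth: dict = field(default_factory=dict)
    fold: FoldDefinition | None = None
    lengths: dict[str, int] = field(default_factory=dict)


def ideal_helix(length: int) -> BackboneChain:
    return torsions_to_coords([HELIX_TORSIONS] * length, ss="H" * length)


def ideal_strand(length: int) -> BackboneChain:
    return torsions_to_coords([STRAND_TORSIONS] * length, ss="E" * length)


def _orient_along_z(coords: np.ndarray) -> np.ndarray:
    """Rigidly move a chain's atoms so its CA principal axis runs along +z."""
    ca = coords[:, 1]
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
    return rot.apply((coords - centroid).reshape(-1, 3)).reshape(coords.shape)


def _kinked_helix(length: int, angle: float) -> BackboneChain:
    if not (0 <= angle <= 90):
        raise ValueError("kink angle must be in [0, 90] degrees")
    chain = ideal_helix(length)
    coords = chain.coords.copy()
    ca = coords[:, 1]
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    # rotate the C-terminal half rigidly about its first amide N, around an
    # axis perpendicular to the helix axis: bond lengths at the junction are
    # preserved and each half stays ideally helical
    j = length // 2
    pivot = coords[j, 0].copy()
    perp = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    rot = Rotation.from_rotvec(np.radians(angle) * perp)
    moved = rot.apply((coords[j:] - pivot).reshape(-1, 3)).reshape(
        coords[j:].shape
    ) + pivot
    coords[j:] = moved
    return chain_from_coords(coords, ss="H" * length)


def _hairpin(strand_len: int, loop_abego: str) -> Fixture:
    """Ideal antiparallel hairpin at register 0 by rigid strand placement."""
    s1 = ideal_strand(strand_len)
    coords1 = _orient_along_z(s1.coords)
    # rotate the second strand 180 degrees about x (so it runs along -z) and
    # offset it in y; shift along z so residue i pairs residue L-1-i
    s2 = ideal_strand(strand_len)
    coords2 = _orient_along_z(s2.coords)
    flip = Rotation.from_rotvec([math.pi, 0.0, 0.0])
    coords2 = flip.apply(coords2.reshape(-1, 3)).reshape(coords2.shape)
    # grid-search the lateral/axial offset so every partner CA-CA distance
    # sits mid-window: flipping the strand puts the pleat out of phase, so
    # the naive centroid shift leaves alternating long/short pairs
    ca1 = coords1[::-1, 1]
    base_shift = np.zeros(3)
    base_shift[2] = float(np.mean(coords1[::-1, 1, 2] - coords2[:, 1, 2]))
    best, best_cost = None, np.inf
    for dy in np.arange(4.2, 5.6, 0.05):
        for dz in np.arange(-2.0, 2.0, 0.05):
            cand = coords2[:, 1] + base_shift + [0.0, dy, dz]
            dists = np.linalg.norm(ca1 - cand, axis=1)
            cost = float(((dists - 4.9) ** 2).max())
            if cost < best_cost:
                best, best_cost = (dy, dz), cost
    shift = base_shift + [0.0, best[0], best[1]]
    coords2 = coords2 + shift
    loop_len = len(loop_abego)
    # loop placed by linear interpolation between the strand termini; the
    # pairing geometry, not the loop, is this fixture's ground truth
    start = coords1[-1, 2]
    end = coords2[0, 0]
    loop_coords = np.zeros((loop_len, 4, 3))
    for k in range(loop_len):
        t = (k + 1) / (loop_len + 1)
        center = (1 - t) * start + t * end
        loop_coords[k, 0] = center + [0.0, -0.6, 0.0]
        loop_coords[k, 1] = center
        loop_coords[k, 2] = center + [0.0, 0.6, 0.0]
        loop_coords[k, 3] = center + [0.6, 0.0, 0.6]
    coords = np.concatenate([coords1, loop_coords, coords2])
    ss = "E" * strand_len + "L" * loop_len + "E" * strand_len
    chain = chain_from_coords(coords, ss=ss)
    fold = FoldDefinition(
        segments=[
            SegmentSpec("E1", "strand", (strand_len, strand_len)),
            SegmentSpec("L1", "loop", (loop_len, loop_len), (loop_abego,)),
            SegmentSpec("E2", "strand", (strand_len, strand_len)),
        ],
        strand_pairings=[StrandPairingSpec("E1", "E2", "antiparallel", (0, 0))],
        sheets=[SheetSpec(("E1", "E2"))],
    )
    lengths = {"E1": strand_len, "L1": loop_len, "E2": strand_len}
    return Fixture(chain, {"register": 0, "orientation": "antiparallel"}, fold, lengths)


def _three_helix_bundle(helix_len: int, separation: float) -> Fixture:
    """Three ideal helices on a triangle, alternating direction (no loops)."""
    base = _orient_along_z(ideal_helix(helix_len).coords)
    flip = Rotation.from_rotvec([math.pi, 0.0, 0.0])
    flipped = flip.apply(base.reshape(-1, 3)).reshape(base.shape)
    h = separation * math.sqrt(3) / 2
    offsets = [
        np.array([0.0, 0.0, 0.0]),
        np.array([separation, 0.0, 0.0]),
        np.array([separation / 2, h, 0.0]),
    ]
    parts = [base + offsets[0], flipped[::-1] + offsets[1], base + offsets[2]]
    coords = np.concatenate(parts)
    chain = chain_from_coords(coords, ss="H" * (3 * helix_len))
    return Fixture(
        chain,
        {"helix_len": helix_len, "separation": separation,
         "central_range": (helix_len + 1, 2 * helix_len)},
    )


def _flat_sheet(n_strands: int, strand_len: int) -> Fixture:
    base = _orient_along_z(ideal_strand(strand_len).coords)
    parts = [base + np.array([0.0, 4.9 * k, 0.0]) for k in range(n_strands)]
    coords = np.concatenate(parts)
    chain = chain_from_coords(coords, ss="E" * (n_strands * strand_len))
    return Fixture(chain, {"n_strands": n_strands, "strand_len": strand_len})


def _scrambled_decoy(length: int, seed: int) -> BackboneChain:
    rng = np.random.default_rng(seed)
    tors = [
        tuple(float(a) for a in rng.uniform(-179.9, 180.0, size=3))
        for _ in range(length)
    ]
    return torsions_to_coords(tors, ss="L" * length)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the requested fixture with its ground-truth record."""
    if spec.kind == "ideal-helix":
        chain = ideal_helix(spec.length)
        fold = FoldDefinition(
            segments=[SegmentSpec("H1", "helix", (spec.length, spec.length))]
        )
        return Fixture(chain, {"torsions": HELIX_TORSIONS}, fold,
                       {"H1": spec.length})
    if spec.kind == "ideal-strand":
        chain = ideal_strand(spec.length)
        return Fixture(chain, {"torsions": STRAND_TORSIONS})
    if spec.kind == "kinked-helix":
        length = max(spec.length, 16)
        chain = _kinked_helix(length, spec.kink_angle)
        fold = FoldDefinition(
            segments=[SegmentSpec("H1", "helix", (length, length))]
        )
        return Fixture(chain, {"kink_angle": spec.kink_angle}, fold,
                       {"H1": length})
    if spec.kind == "hairpin":
        return _hairpin(spec.length, spec.loop_abego)
    if spec.kind == "three-helix-bundle":
        return _three_helix_bundle(spec.length, spec.separation)
    if spec.kind == "flat-sheet":
        return _flat_sheet(spec.n_strands, spec.length)
    chain = _scrambled_decoy(spec.length, spec.seed)
    return Fixture(chain, {"seed": spec.seed})
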