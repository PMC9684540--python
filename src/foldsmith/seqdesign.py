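"""Layer-based sequence design with optional pair-motif core seeding.

Residues are partitioned into core / boundary / surface layers by a burial
proxy (neighbor count inside a cone along the CA -> pseudo-CB direction),
then assigned amino acids from per-layer palettes.  The "motif" protocol
first seeds pairs of directly interacting core residues from a pair-motif
table (two residue types plus a CB-CB distance window, harvested in spirit
from crystal-structure side-chain pairings) before palette assignment.

This is the combinatorial layer of sequence design only: no rotamer
packing or all-atom energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import BackboneChain

HYDROPHOBIC = set("AVLIFMW")

PALETTES = {
    "core": "AVLIFMW",
    "boundary": "AVILTSNQEKR",
    "surface": "DEKRNQSTH",
}
NCAP_PALETTE = "DNST"  # helix N-terminal positions
LOOP_G_LETTERS = {"G", "E"}  # positive-phi loop bins prefer glycine

DEFAULT_CORE_MIN = 5
DEFAULT_SURFACE_MAX = 2
BURIAL_RADIUS = 10.5
CONE_HALF_ANGLE = 70.0  # degrees


@dataclass
class LayerAssignment:
    layers: list[str]  # per-residue: core | boundary | surface
    burial: list[int]


@dataclass(frozen=True)
class PairMotif:
    res_a: str
    res_b: str
    dmin: float
    dmax: float
    orientation: str = "any"

    def mirrored(self) -> "PairMotif":
        return PairMotif(self.res_b, self.res_a, self.dmin, self.dmax, self.orientation)


def pseudo_cb(chain: BackboneChain) -> np.ndarray:
    """Ideal tetrahedral CB position from N/CA/C, one point per residue.

    Standard linear-combination construction for an L-amino-acid beta
    carbon given the three backbone atoms.
    """
    n = chain.coords[:, 0]
    ca = chain.coords[:, 1]
    c = chain.coords[:, 2]
    b = ca - n
    c2 = c - ca
    a = np.cross(b, c2)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c2 + ca


def assign_layers(
    chain: BackboneChain,
    core_min: int = DEFAULT_CORE_MIN,
    surface_max: int = DEFAULT_SURFACE_MAX,
) -> LayerAssignment:
    """Burial-count layering.

    Burial of residue i counts CA atoms of other residues within
    ``BURIAL_RADIUS`` (10.5 A) of CA_i lying inside a cone (half-angle 70
    degrees) around the CA -> pseudo-CB direction, i.e. packed against the
    side-chain face.  Burial >= ``core_min`` -> core, <= ``surface_max`` -> surface,
    else boundary; higher burial never maps to a more exposed layer.
    """
    ca = chain.ca_coords()
    cb = pseudo_cb(chain)
    direction = cb - ca
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    d = cdist(ca, ca)
    cos_limit = math.cos(math.radians(CONE_HALF_ANGLE))
    burial = []
    n = len(ca)
    for i in range(n):
        count = 0
        for j in range(n):
            if abs(i - j) < 2 or d[i, j] > BURIAL_RADIUS:
                continue
            v = ca[j] - ca[i]
            v = v / np.linalg.norm(v)
            if float(np.dot(v, direction[i])) >= cos_limit:
                count += 1
        burial.append(count)
    layers = [
        "core" if b >= core_min else ("surface" if b <= surface_max else "boundary")
        for b in burial
    ]
    return LayerAssignment(layers=layers, burial=burial)


def load_motif_table(path=None) -> list[PairMotif]:
    """Delimited motif table: resA resB dmin dmax orientation-class."""
    if path is None:
        text = resources.files("foldsmith.data").joinpath("pair_motifs.tsv").read_text()
    else:
        text = open(path).read()
    motifs = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"motif table line {lineno}: expected >= 4 columns")
        motifs.append(
            PairMotif(parts[0], parts[1], float(parts[2]), float(parts[3]),
                      parts[4] if len(parts) > 4 else "any")
        )
    return motifs


def seed_pair_motifs(
    chain: BackboneChain,
    layers: LayerAssignment,
    motif_table: list[PairMotif],
    rng: np.random.Generator,
) -> dict[int, str]:
    """Greedily seed motif pairs onto unassigned core position pairs.

    Core position pairs (0-based) whose pseudo-CB distance falls inside a
    motif's window are assigned that motif's residue types; each position is
    used at most once.  Candidate pairs are visited nearest-first; the motif
    among the matching ones is drawn with the rng, so the assignment is
    deterministic under seed.
    """
    if not motif_table:
        return {}
    cb = pseudo_cb(chain)
    core = [i for i, l in enumerate(layers.layers) if l == "core"]
    pairs = []
    for ai in range(len(core)):
        for bi in range(ai + 1, len(core)):
            i, j = core[ai], core[bi]
            if abs(i - j) < 2:
                continue
            dist = float(np.linalg.norm(cb[i] - cb[j]))
            pairs.append((dist, i, j))
    pairs.sort()
    assigned: dict[int, str] = {}
    for dist, i, j in pairs:
        if i in assigned or j in assigned:
            continue
        matches = [m for m in motif_table if m.dmin <= dist <= m.dmax]
        if not matches:
            continue
        m = matches[int(rng.integers(len(matches)))]
        if rng.random() < 0.5:
            m = m.mirrored()
        assigned[i] = m.res_a
        assigned[j] = m.res_b
    return assigned


def design_sequence(
    chain: BackboneChain,
    protocol: str = "plain",
    rng: np.random.Generator | None = None,
    layers: LayerAssignment | None = None,
    motif_table: list[PairMotif] | None = None,
) -> str:
    """Assign one amino acid per residue from layer palettes.

    ``protocol="motif"`` first seeds core pairs from the motif table and
    fills the remaining positions from palettes; ``"plain"`` uses palettes
    only.  Loop residues in positive-phi bins become glycine; the first
    residue of each helix draws from the N-cap palette.  Every position
    ends up assigned.
    """
    if protocol not in ("plain", "motif"):
        raise ValueError(f"unknown protocol {protocol!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    layers = assign_layers(chain) if layers is None else layers
    n = len(chain)
    seq: list[str | None] = [None] * n
    if protocol == "motif":
        table = load_motif_table() if motif_table is None else motif_table
        for i, aa in seed_pair_motifs(chain, layers, table, rng).items():
            seq[i] = aa
    ss = chain.ss
    for i in range(n):
        if seq[i] is not None:
            continue
        if ss[i] == "L" and chain.abego[i] in LOOP_G_LETTERS:
            seq[i] = "G"
            continue
        if ss[i] == "H" and (i == 0 or ss[i - 1] != "H"):
            palette = NCAP_PALETTE
        else:
            palette = PALETTES[layers.layers[i]]
        seq[i] = palette[int(rng.integers(len(palette)))]
    return "".join(seq)
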