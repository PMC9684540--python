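"""Backbone geometry: internal/Cartesian conversion, dihedrals, superposition.

A backbone chain is represented by its N, CA, C and O atoms (angstroms) and
the phi/psi/omega torsions (degrees).  Chains are built residue-by-residue
with ideal bond lengths and angles (Engh–Huber-style values); the only
degrees of freedom are the torsions, which is exactly the parameterisation
used by the fragment-insertion folder.

Torsion conventions (1-based residue ``i``):

* ``phi_i``   = dihedral(C_{i-1}, N_i, CA_i, C_i) — undefined for residue 1
* ``psi_i``   = dihedral(N_i, CA_i, C_i, N_{i+1}) — undefined for the last
* ``omega_i`` = dihedral(CA_i, C_i, N_{i+1}, CA_{i+1}) — the peptide torsion
  between residues ``i`` and ``i+1``; undefined for the last residue.

Undefined torsions carry the sentinel ``UNDEFINED_TORSION`` (NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

UNDEFINED_TORSION = math.nan

# Ideal backbone covalent geometry (angstroms / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

#: consecutive C(i)–N(i+1) distances above this mark a chain break
CHAIN_BREAK_CUTOFF = 2.0

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def is_undefined(angle: float) -> bool:
    """True for the undefined-torsion sentinel."""
    return isinstance(angle, float) and math.isnan(angle)


@dataclass
class ResidueBackbone:
    """One residue's backbone atoms and torsions (view onto a chain)."""

    index: int  # 1-based
    N: np.ndarray
    CA: np.ndarray
    C: np.ndarray
    O: np.ndarray
    phi: float
    psi: float
    omega: float


@dataclass
class BackboneChain:
    """Ordered backbone residues with per-residue annotations.

    ``coords`` has shape (n, 4, 3) ordered N, CA, C, O.  ``ss`` holds one of
    'H'/'E'/'L' per residue, ``abego`` one letter of the torsion alphabet
    (or '-' where torsions are undefined).  ``breaks`` lists 1-based residue
    indices i where the C(i)–N(i+1) bond exceeds the chain-break cutoff.
    """

    coords: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    ss: list[str] = field(default_factory=list)
    abego: list[str] = field(default_factory=list)
    breaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise ValueError("coords must have shape (n, 4, 3)")
        n = len(self.coords)
        if not self.ss:
            self.ss = ["L"] * n
        if not self.abego:
            self.abego = ["-"] * n

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.coords)

    def atom(self, index: int, name: str) -> np.ndarray:
        """Coordinates of one backbone atom; ``index`` is 1-based."""
        return self.coords[index - 1, BACKBONE_ATOMS.index(name)]

    def ca_coords(self) -> np.ndarray:
        return self.coords[:, 1]

    def residue(self, index: int) -> ResidueBackbone:
        i = index - 1
        return ResidueBackbone(
            index,
            self.coords[i, 0],
            self.coords[i, 1],
            self.coords[i, 2],
            self.coords[i, 3],
            float(self.phi[i]),
            float(self.psi[i]),
            float(self.omega[i]),
        )

    @property
    def residues(self) -> list[ResidueBackbone]:
        return [self.residue(i + 1) for i in range(len(self))]

    def torsion_list(self) -> list[tuple[float, float, float]]:
        return [
            (float(self.phi[i]), float(self.psi[i]), float(self.omega[i]))
            for i in range(len(self))
        ]

    def copy(self) -> "BackboneChain":
        return BackboneChain(
            self.coords.copy(),
            self.phi.copy(),
            self.psi.copy(),
            self.omega.copy(),
            list(self.ss),
            list(self.abego),
            list(self.breaks),
        )


# ---------------------------------------------------------------------------
# dihedrals


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Returns the undefined sentinel when the central axis p2-p3 is degenerate
    or either flanking triple is collinear.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    p4 = np.asarray(p4, dtype=float)
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-10 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        return UNDEFINED_TORSION
    m1 = np.cross(n1, b2 / b2n)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = -math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _place_atom(a, b, c, bond: float, angle: float, torsion: float):
    """Place atom d given atoms a,b,c, |c-d|, angle(b,c,d) and dihedral(a,b,c,d).

    Pure-float NeRF step; ``a``..``c`` are (x, y, z) tuples.  Kept free of
    numpy so the Monte-Carlo rebuild loop stays cheap.
    """
    ang = math.radians(angle)
    tor = math.radians(torsion)
    # local displacement in the frame of bond c<-b
    d2 = (
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    )
    bcx = c[0] - b[0]
    bcy = c[1] - b[1]
    bcz = c[2] - b[2]
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx *= inv
    bcy *= inv
    bcz *= inv
    abx = b[0] - a[0]
    aby = b[1] - a[1]
    abz = b[2] - a[2]
    # n = ab x bc, normalised
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    nx *= inv
    ny *= inv
    nz *= inv
    # m = n x bc
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    return (
        c[0] + bcx * d2[0] + mx * d2[1] + nx * d2[2],
        c[1] + bcy * d2[0] + my * d2[1] + ny * d2[2],
        c[2] + bcz * d2[0] + mz * d2[1] + nz * d2[2],
    )


def _place_oxygens(coords: np.ndarray, n: int, psi_last: float) -> None:
    """Carbonyl O trans to the next amide N, in the C(i) plane.

    The terminal O uses a virtual next N built with the last psi (180 if
    undefined).
    """
    for i in range(n):
        ca = coords[i, 1]
        c = coords[i, 2]
        if i + 1 < n:
            n_next = coords[i + 1, 0]
        else:
            psi = 180.0 if math.isnan(psi_last) else psi_last
            n_next = np.array(
                _place_atom(
                    tuple(coords[i, 0]), tuple(ca), tuple(c),
                    BOND_C_N, ANGLE_CA_C_N, psi,
                )
            )
        u1 = ca - c
        u1 /= np.linalg.norm(u1)
        u2 = n_next - c
        u2 /= np.linalg.norm(u2)
        bis = u1 + u2
        coords[i, 3] = c - BOND_C_O * bis / np.linalg.norm(bis)


def torsions_to_coords(
    torsion_list: Sequence[tuple[float, float, float]],
    ss: Iterable[str] | None = None,
) -> BackboneChain:
    """Build Cartesian backbone coordinates from (phi, psi, omega) torsions.

    The first residue is placed in a canonical frame (N at the origin, CA on
    +x, C in the xy-plane).  Residue 1's phi and the last residue's
    psi/omega may be the undefined sentinel; all other angles must be finite
    and in (-180, 180].
    """
    tl = list(torsion_list)
    n = len(tl)
    if n < 2:
        raise ValueError("need at least 2 residues")
    for i, (phi, psi, omega) in enumerate(tl):
        used = []
        if i > 0:
            used.append(phi)
        if i < n - 1:
            used.extend([psi, omega])
        for a in used:
            if not math.isfinite(a):
                raise ValueError(f"non-finite torsion at residue {i + 1}")
            if not (-180.0 < a <= 180.0):
                raise ValueError(f"torsion out of (-180,180] at residue {i + 1}")

    coords = np.zeros((n, 4, 3))
    # canonical first-residue frame
    N0 = (0.0, 0.0, 0.0)
    CA0 = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(ANGLE_N_CA_C)
    C0 = (
        CA0[0] - BOND_CA_C * math.cos(ang),
        BOND_CA_C * math.sin(ang),
        0.0,
    )
    coords[0, 0] = N0
    coords[0, 1] = CA0
    coords[0, 2] = C0
    prev = (N0, CA0, C0)
    for i in range(n - 1):
        psi, omega = tl[i][1], tl[i][2]
        phi_next = tl[i + 1][0]
        pn, pca, pc = prev
        n_next = _place_atom(pn, pca, pc, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_next = _place_atom(pca, pc, n_next, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_next = _place_atom(pc, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi_next)
        coords[i + 1, 0] = n_next
        coords[i + 1, 1] = ca_next
        coords[i + 1, 2] = c_next
        prev = (n_next, ca_next, c_next)

    _place_oxygens(coords, n, tl[-1][1])

    phi = np.array([t[0] for t in tl])
    psi = np.array([t[1] for t in tl])
    omega = np.array([t[2] for t in tl])
    phi[0] = UNDEFINED_TORSION
    psi[-1] = UNDEFINED_TORSION
    omega[-1] = UNDEFINED_TORSION
    chain = BackboneChain(coords, phi, psi, omega)
    if ss is not None:
        chain.ss = list(ss)
    from .abego import abego_string  # deferred: abego depends on geometry

    chain.abego = list(abego_string(chain))
    return chain


def measure_torsions(chain: BackboneChain) -> list[tuple[float, float, float]]:
    """Measure (phi, psi, omega) per residue from coordinates.

    Residues flanking a chain break (C–N distance beyond the cutoff) get
    undefined sentinels for the torsions that span the break; the break is
    also recorded on ``chain.breaks`` rather than silently ignored.
    """
    n = len(chain)
    out: list[tuple[float, float, float]] = []
    breaks = []
    for i in range(n - 1):
        d = np.linalg.norm(chain.coords[i + 1, 0] - chain.coords[i, 2])
        if d > CHAIN_BREAK_CUTOFF:
            breaks.append(i + 1)
    chain.breaks = breaks
    broken = set(breaks)
    for i in range(n):
        c = chain.coords
        if i == 0 or i in broken:
            phi = UNDEFINED_TORSION
        else:
            phi = dihedral(c[i - 1, 2], c[i, 0], c[i, 1], c[i, 2])
        if i == n - 1 or (i + 1) in broken:
            psi = UNDEFINED_TORSION
            omega = UNDEFINED_TORSION
        else:
            psi = dihedral(c[i, 0], c[i, 1], c[i, 2], c[i + 1, 0])
            omega = dihedral(c[i, 1], c[i, 2], c[i + 1, 0], c[i + 1, 1])
        out.append((phi, psi, omega))
    return out


def chain_from_coords(coords: np.ndarray, ss: Iterable[str] | None = None) -> BackboneChain:
    """Wrap an (n,4,3) coordinate array into a chain, measuring torsions."""
    chain = BackboneChain(np.asarray(coords, dtype=float),
                          np.zeros(len(coords)), np.zeros(len(coords)),
                          np.zeros(len(coords)))
    torsions = measure_torsions(chain)
    chain.phi = np.array([t[0] for t in torsions])
    chain.psi = np.array([t[1] for t in torsions])
    chain.omega = np.array([t[2] for t in torsions])
    if ss is not None:
        chain.ss = list(ss)
    from .abego import abego_string

    chain.abego = list(abego_string(chain))
    return chain


# ---------------------------------------------------------------------------
# superposition


def superpose_rmsd(A: np.ndarray, B: np.ndarray):
    """Least-squares rigid superposition of point set A onto B (Kabsch).

    Returns ``(rmsd, R, t)`` with ``R`` a proper rotation (det +1) and ``t``
    a translation such that ``A @ R.T + t`` best fits ``B``; the RMSD is the
    global minimum over rigid transforms.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("point sets must have equal cardinality")
    if A.ndim != 2 or A.shape[0] < 3 or A.shape[1] != 3:
        raise ValueError("need at least 3 points of dimension 3")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = math.sqrt(float((diff * diff).sum()) / len(A))
    return rmsd, R, t


# ---------------------------------------------------------------------------
# helix axis / bend


def _fit_line(points: np.ndarray):
    """Least-squares line through points: (centroid, unit direction)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[0]


def helix_axis_points(ca: np.ndarray) -> np.ndarray:
    """Sliding 4-CA window centroids; these track the local helix axis."""
    n = len(ca)
    if n < 4:
        raise ValueError("need >= 4 CA atoms")
    return np.array([ca[k : k + 4].mean(axis=0) for k in range(n - 3)])


def local_axis_directions(ca: np.ndarray) -> np.ndarray:
    """Unit local-axis direction per sliding 4-CA window.

    Uses the cross product of consecutive second differences of the CA
    trace, which is exactly parallel to the helix axis for an ideal helix
    (one estimate per 4-CA window), so a straight helix measures 0 bend
    regardless of how the window phase sits on the helical period.
    """
    v = np.diff(ca, axis=0)
    a = v[1:] - v[:-1]
    axes = np.cross(a[:-1], a[1:])
    norms = np.linalg.norm(axes, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    return axes / norms


def helix_bend_ca(ca: np.ndarray, n_windows: int = 4) -> float:
    """Bend angle (degrees) between the first and last local-axis windows."""
    if len(ca) < 8:
        return UNDEFINED_TORSION
    axes = local_axis_directions(ca)
    if len(axes) < 2:
        return UNDEFINED_TORSION
    m = min(n_windows, max(1, len(axes) // 2))
    d1 = axes[:m].mean(axis=0)
    d2 = axes[-m:].mean(axis=0)
    n1 = np.linalg.norm(d1)
    n2 = np.linalg.norm(d2)
    if n1 < 1e-12 or n2 < 1e-12:
        return UNDEFINED_TORSION
    cosang = float(np.clip(np.dot(d1 / n1, d2 / n2), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def helix_bend(chain: BackboneChain, start: int, end: int) -> float:
    """Bend angle (degrees) of the helix spanning residues start..end (1-based).

    Local axes are averaged over the first and last four 4-residue windows
    of the CA trace; 0 means perfectly straight.  Helices shorter than 8
    residues return the undefined sentinel (not evaluable).  Invariant
    under rigid motion of the chain.
    """
    n = end - start + 1
    if n < 8:
        return UNDEFINED_TORSION
    return helix_bend_ca(chain.ca_coords()[start - 1 : end])


# ---------------------------------------------------------------------------
# clashes


def count_clashes(chain: BackboneChain, cutoff: float) -> int:
    """Backbone heavy-atom pairs closer than ``cutoff`` between residues
    separated by at least 2 in sequence."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if cutoff == 0:
        return 0
    n = len(chain)
    flat = chain.coords.reshape(n * 4, 3)
    res_idx = np.repeat(np.arange(n), 4)
    d = cdist(flat, flat)
    sep = np.abs(res_idx[:, None] - res_idx[None, :])
    mask = (sep >= 2) & (d < cutoff)
    return int(np.triu(mask, k=1).sum())


def count_ca_clashes(ca: np.ndarray, cutoff: float) -> int:
    """CA–CA pairs below cutoff with sequence separation >= 2 (MC surrogate)."""
    d = cdist(ca, ca)
    n = len(ca)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    return int(np.triu((sep >= 2) & (d < cutoff), k=1).sum())
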