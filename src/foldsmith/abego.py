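"""The five-letter torsion-bin alphabet (A, B, E, G, O).

Backbone torsion space partitions into five regions of the Ramachandran
plot plus the cis-omega slab: A (alpha-helical), B (beta/extended), G
(left-handed helical, positive phi), E (extended positive-phi), and O (cis
peptide bonds).  The alphabet compresses backbone conformation into one
letter per residue and drives fragment sampling during folding.

Region boundaries (degrees, half-open on psi):

* O: ``|omega| < 90`` (cis), regardless of phi/psi
* phi < 0:  A if psi in [-75, 50), else B
* phi >= 0: G if psi in [-100, 100), else E

psi is wrapped into (-180, 180] before the comparison, so the B and E
regions are contiguous across the +-180 seam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import BackboneChain, is_undefined

LETTERS = ("A", "B", "E", "G", "O")

# psi split points
_A_B_SPLIT = (-75.0, 50.0)
_G_E_SPLIT = (-100.0, 100.0)

# sampling centers and standard deviations per letter: (phi, psi, sd)
SAMPLING = {
    "A": ((-63.0, -42.0), 10.0),
    "B": ((-135.0, 135.0), 20.0),
    "E": ((75.0, 170.0), 20.0),
    "G": ((75.0, -10.0), 20.0),
    "O": ((-75.0, 160.0), 20.0),  # cis-proline-like region
}
OMEGA_TRANS = 180.0
OMEGA_CIS = 0.0
OMEGA_SD = 3.0


@dataclass(frozen=True)
class AbegoRegion:
    letter: str
    phi_range: tuple[float, float]
    psi_range: tuple[float, float]
    cis: bool


REGIONS = (
    AbegoRegion("A", (-180.0, 0.0), _A_B_SPLIT, False),
    AbegoRegion("B", (-180.0, 0.0), (_A_B_SPLIT[1], _A_B_SPLIT[0] + 360.0), False),
    AbegoRegion("G", (0.0, 180.0), _G_E_SPLIT, False),
    AbegoRegion("E", (0.0, 180.0), (_G_E_SPLIT[1], _G_E_SPLIT[0] + 360.0), False),
    AbegoRegion("O", (-180.0, 180.0), (-180.0, 180.0), True),
)


def wrap_angle(a: float) -> float:
    """Wrap into (-180, 180]."""
    a = math.fmod(a, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def classify_abego(phi: float, psi: float, omega: float) -> str:
    """Map one (phi, psi, omega) triple to its alphabet letter (total function)."""
    if not all(map(math.isfinite, (phi, psi, omega))):
        raise ValueError("angles must be finite")
    if abs(wrap_angle(omega)) < 90.0:
        return "O"
    psi = wrap_angle(psi)
    if wrap_angle(phi) < 0.0:
        return "A" if _A_B_SPLIT[0] <= psi < _A_B_SPLIT[1] else "B"
    return "G" if _G_E_SPLIT[0] <= psi < _G_E_SPLIT[1] else "E"


def abego_string(chain: BackboneChain) -> str:
    """One letter per residue; '-' where terminal torsions are undefined.

    A residue is classifiable when phi and psi are both defined; the last
    residue (undefined psi) and the first (undefined phi) emit '-'.
    """
    out = []
    for i in range(len(chain)):
        phi = float(chain.phi[i])
        psi = float(chain.psi[i])
        omega = float(chain.omega[i])
        if is_undefined(phi) or is_undefined(psi):
            out.append("-")
        else:
            out.append(classify_abego(phi, psi, 180.0 if is_undefined(omega) else omega))
    return "".join(out)


def sample_torsions_for_abego(
    letter: str, rng: np.random.Generator, sd: float | None = None
) -> tuple[float, float, float]:
    """Draw (phi, psi, omega) from a truncated Gaussian inside the region.

    The draw is Gaussian around the letter's canonical center and
    rejection-sampled so the returned angles always classify back to the
    requested letter.  ``sd`` overrides the region's default dispersion;
    the folder uses a tighter spread for helix/strand interiors, where
    independent wide draws would mimic neither real structured fragments
    nor their internal correlations.
    """
    if letter not in LETTERS:
        raise ValueError(f"unknown letter {letter!r}")
    (cphi, cpsi), default_sd = SAMPLING[letter]
    sd = default_sd if sd is None else sd
    omega_center = OMEGA_CIS if letter == "O" else OMEGA_TRANS
    for _ in range(1000):
        phi = wrap_angle(cphi + sd * rng.standard_normal())
        psi = wrap_angle(cpsi + sd * rng.standard_normal())
        omega = wrap_angle(omega_center + OMEGA_SD * rng.standard_normal())
        if phi == -180.0:
            phi = 180.0
        if classify_abego(phi, psi, omega) == letter:
            return phi, psi, omega
    raise RuntimeError("rejection sampling failed")  # pragma: no cover


def load_fragment_file(path) -> dict[str, list[list[tuple[float, float, float]]]]:
    """Parse a torsion-fragment file keyed by ABEGO string.

    Format: a header line ``#abego <string>`` opens each fragment, followed
    by one ``phi psi omega`` triple per residue.  Returns a mapping from
    ABEGO string to the list of fragments carrying it.
    """
    frags: dict[str, list[list[tuple[float, float, float]]]] = {}
    current_key = None
    current: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#abego"):
                if current_key is not None:
                    frags.setdefault(current_key, []).append(current)
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"line {lineno}: malformed #abego header")
                current_key = parts[1]
                current = []
            else:
                if current_key is None:
                    raise ValueError(f"line {lineno}: torsions before #abego header")
                vals = line.split()
                if len(vals) != 3:
                    raise ValueError(f"line {lineno}: expected 'phi psi omega'")
                current.append(tuple(float(v) for v in vals))
    if current_key is not None:
        frags.setdefault(current_key, []).append(current)
    for key, flist in frags.items():
        for frag in flist:
            if len(frag) != len(key):
                raise ValueError(f"fragment length != ABEGO length for {key!r}")
    return frags
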