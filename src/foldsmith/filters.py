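"""Accept/reject gates applied to folded subsegments and finished backbones.

Each filter is a pure function of the chain plus configuration and returns
a :class:`FilterReport`.  Thresholds: helix bend < 15 degrees, harmonic
constraint tolerance 2 x sd, strand partner CA-CA window 4.2-5.7 A, omega
within 20 degrees of trans, Ramachandran-region margin 5 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import abego as _abego
from .abego import classify_abego, wrap_angle
from .folddef import (
    ConstraintSpec,
    FoldDefinition,
    StrandPairingSpec,
    partner_pairs_local,
    resolve_segment,
    segment_bounds,
)
from .geometry import BackboneChain, count_clashes, helix_bend, is_undefined

MAX_HELIX_BEND = 15.0
PAIR_DIST_MIN = 4.2
PAIR_DIST_MAX = 5.7
OMEGA_TOLERANCE = 20.0
RAMA_MARGIN = 5.0
CLASH_CUTOFF = 2.5
#: minimum fraction of partner CA pairs inside the pleated-sheet window for
#: a strand pairing to pass (the primary pass criteria are register and
#: orientation; the floor rejects barely-zipped sheets)
MIN_PAIRED_FRACTION = 0.7


@dataclass
class FilterReport:
    name: str
    passed: bool
    diagnostic: float
    details: dict = field(default_factory=dict)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def _ss_from_abego(letter: str) -> str:
    if letter == "A":
        return "H"
    if letter in ("B", "E"):
        return "E"
    return "L"


def ss_identity_filter(
    chain: BackboneChain,
    fold: FoldDefinition,
    chosen_lengths: dict[str, int],
    only_segments: set[str] | None = None,
) -> FilterReport:
    """Helix/strand interiors must carry their intended secondary structure.

    The per-residue label is derived from the ABEGO letter (A -> H, B/E -> E,
    else L) and compared against the fold spec for every interior residue of
    each helix and strand (one residue at each terminus is exempt); loops are
    unconstrained.
    """
    bounds = segment_bounds(fold, chosen_lengths)
    total = 0
    bad: list[int] = []
    for seg in fold.segments:
        if seg.kind == "loop":
            continue
        if only_segments is not None and seg.name not in only_segments:
            continue
        start, end = bounds[seg.name]
        for idx in range(start + 1, end):  # interior: termini +-1 exempt
            total += 1
            letter = chain.abego[idx - 1]
            if letter == "-" or _ss_from_abego(letter) != seg.ss_letter:
                bad.append(idx)
    frac = 1.0 if total == 0 else 1.0 - len(bad) / total
    return FilterReport("ss_identity", not bad, frac, {"mismatches": bad})


def helix_kink_filter(
    chain: BackboneChain,
    fold: FoldDefinition,
    chosen_lengths: dict[str, int],
    max_bend: float = MAX_HELIX_BEND,
    only_segments: set[str] | None = None,
) -> FilterReport:
    """Every helix must bend less than ``max_bend`` degrees.

    Helices too short to fit an axis (fewer than 8 residues) pass with a
    not-evaluable note.
    """
    bounds = segment_bounds(fold, chosen_lengths)
    worst = 0.0
    per_helix: dict[str, float | None] = {}
    passed = True
    for seg in fold.segments:
        if seg.kind != "helix":
            continue
        if only_segments is not None and seg.name not in only_segments:
            continue
        start, end = bounds[seg.name]
        bend = helix_bend(chain, start, end)
        if is_undefined(bend):
            per_helix[seg.name] = None  # not evaluable
            continue
        per_helix[seg.name] = bend
        worst = max(worst, bend)
        if bend >= max_bend:
            passed = False
    return FilterReport("helix_kink", passed, worst, {"bends": per_helix})


def constraint_filter(
    chain: BackboneChain,
    fold: FoldDefinition,
    chosen_lengths: dict[str, int],
    constraints: list[ConstraintSpec] | None = None,
    tolerance_factor: float = 2.0,
) -> FilterReport:
    """Distance constraints must hold within ``tolerance_factor`` x sd.

    Harmonic: |d - target| <= tol.  Bounded: d within
    [target - width - tol, target + width + tol].  The diagnostic is the
    worst violation normalised by sd.
    """
    constraints = fold.constraints if constraints is None else constraints
    worst = 0.0
    failures = []
    for c in constraints:
        ia = resolve_segment(fold, chosen_lengths, *c.a)
        ib = resolve_segment(fold, chosen_lengths, *c.b)
        d = float(np.linalg.norm(chain.atom(ia, "CA") - chain.atom(ib, "CA")))
        tol = tolerance_factor * c.sd
        if c.function == "harmonic":
            excess = abs(d - c.target) - tol
        else:
            lo = c.target - c.bound_width - tol
            hi = c.target + c.bound_width + tol
            excess = max(lo - d, d - hi)
        norm = max(0.0, excess) / c.sd
        worst = max(worst, norm)
        if excess > 0:
            failures.append({"a": c.a, "b": c.b, "distance": d, "target": c.target})
    return FilterReport("constraint", not failures, worst, {"failures": failures})


def measure_register(
    chain: BackboneChain,
    fold: FoldDefinition,
    chosen_lengths: dict[str, int],
    pairing: StrandPairingSpec,
    search_window: int = 3,
    prefer: int = 0,
) -> tuple[int, float]:
    """(best register, paired fraction at that register) for one pairing.

    The measured register is the integer shift maximising the number of
    partner CA pairs inside the pleated-sheet window; ties break toward the
    shift nearest ``prefer`` (short strands make neighboring shifts
    genuinely ambiguous, so the declared register wins ties).
    """
    bounds = segment_bounds(fold, chosen_lengths)
    s1 = bounds[pairing.first]
    s2 = bounds[pairing.second]
    l1 = s1[1] - s1[0] + 1
    l2 = s2[1] - s2[0] + 1
    ca = chain.ca_coords()
    lo = pairing.register_range[0] - search_window
    hi = pairing.register_range[1] + search_window
    best_r, best_count, best_frac = 0, -1, 0.0
    for r in range(lo, hi + 1):
        pairs = partner_pairs_local(pairing, l1, l2, r)
        if not pairs:
            continue
        count = 0
        for i, j in pairs:
            d = float(np.linalg.norm(ca[s1[0] - 1 + i] - ca[s2[0] - 1 + j]))
            if PAIR_DIST_MIN <= d <= PAIR_DIST_MAX:
                count += 1
        frac = count / len(pairs)
        if count > best_count or (
            count == best_count and abs(r - prefer) < abs(best_r - prefer)
        ):
            best_r, best_count, best_frac = r, count, frac
    return best_r, best_frac


def strand_pairing_filter(
    chain: BackboneChain,
    fold: FoldDefinition,
    chosen_lengths: dict[str, int],
    chosen_registers: dict[tuple[str, str], int] | None = None,
    min_fraction: float = MIN_PAIRED_FRACTION,
    pairings: list[StrandPairingSpec] | None = None,
) -> FilterReport:
    """Measured register and orientation must match the declared pairing.

    For each declared strand pairing the register is measured by maximising
    in-window partner counts; the filter passes when it equals the chosen
    (or declared) register, the strand direction vectors agree with the
    declared orientation, and at least ``min_fraction`` of partner pairs sit
    in the 4.2-5.7 A window.
    """
    bounds = segment_bounds(fold, chosen_lengths)
    ca = chain.ca_coords()
    details = {}
    passed = True
    worst_frac = 1.0
    pairing_list = fold.strand_pairings if pairings is None else pairings
    for p in pairing_list:
        key = (p.first, p.second)
        want_r = (
            chosen_registers.get(key, p.register_range[0])
            if chosen_registers
            else p.register_range[0]
        )
        meas_r, frac_at_meas = measure_register(
            chain, fold, chosen_lengths, p, prefer=want_r
        )
        s1, s2 = bounds[p.first], bounds[p.second]
        d1 = ca[s1[1] - 1] - ca[s1[0] - 1]
        d2 = ca[s2[1] - 1] - ca[s2[0] - 1]
        dot = float(np.dot(d1, d2))
        orient_ok = dot > 0 if p.orientation == "parallel" else dot < 0
        # fraction evaluated at the declared register
        l1 = s1[1] - s1[0] + 1
        l2 = s2[1] - s2[0] + 1
        pairs = partner_pairs_local(p, l1, l2, want_r)
        count = 0
        for i, j in pairs:
            d = float(np.linalg.norm(ca[s1[0] - 1 + i] - ca[s2[0] - 1 + j]))
            if PAIR_DIST_MIN <= d <= PAIR_DIST_MAX:
                count += 1
        frac = count / len(pairs) if pairs else 0.0
        ok = (meas_r == want_r) and orient_ok and frac >= min_fraction
        passed = passed and ok
        worst_frac = min(worst_frac, frac)
        details[f"{p.first}-{p.second}"] = {
            "measured_register": meas_r,
            "expected_register": want_r,
            "orientation_ok": orient_ok,
            "paired_fraction": frac,
        }
    return FilterReport("strand_pairing", passed, worst_frac, details)


def rama_omega_filter(chain: BackboneChain) -> FilterReport:
    """No unintended cis peptide bonds; torsions stay inside their region.

    Every defined omega must lie within 20 degrees of trans (unless the
    residue is assigned the cis letter 'O'), and every (phi, psi) must fall
    inside its assigned ABEGO region with at most a 5-degree excursion past
    the region boundary.
    """
    bad: list[int] = []
    n = len(chain)
    for i in range(n):
        letter = chain.abego[i]
        if letter == "-":
            continue
        phi = float(chain.phi[i])
        psi = float(chain.psi[i])
        omega = float(chain.omega[i])
        if is_undefined(phi) or is_undefined(psi):
            continue  # terminal or chain-break residue: not classifiable
        if not is_undefined(omega) and letter != "O":
            if abs(wrap_angle(omega - 180.0)) > OMEGA_TOLERANCE:
                bad.append(i + 1)
                continue
        if not _in_region_with_margin(letter, phi, psi):
            bad.append(i + 1)
    frac = 1.0 if n == 0 else 1.0 - len(bad) / n
    return FilterReport("rama_omega", not bad, frac, {"outliers": bad})


def _in_region_with_margin(letter: str, phi: float, psi: float) -> bool:
    if letter == "O":
        return True
    phi = wrap_angle(phi)
    psi = wrap_angle(psi)
    m = RAMA_MARGIN
    if letter in ("A", "B"):
        if phi >= m:
            return False
        lo, hi = _abego._A_B_SPLIT
        inside_a = lo - m <= psi < hi + m
        return inside_a if letter == "A" else not (lo + m <= psi < hi - m)
    if phi < -m:
        return False
    lo, hi = _abego._G_E_SPLIT
    inside_g = lo - m <= psi < hi + m
    return inside_g if letter == "G" else not (lo + m <= psi < hi - m)


def clash_filter(chain: BackboneChain, cutoff: float = CLASH_CUTOFF) -> FilterReport:
    """No backbone heavy-atom pair below the steric cutoff."""
    n = count_clashes(chain, cutoff)
    return FilterReport("clash", n == 0, float(n))


def run_all_filters(
    chain: BackboneChain,
    fold: FoldDefinition,
    chosen_lengths: dict[str, int],
    chosen_registers: dict[tuple[str, str], int] | None = None,
    max_bend: float = MAX_HELIX_BEND,
) -> list[FilterReport]:
    """The full gate battery applied to a finished backbone."""
    return [
        rama_omega_filter(chain),
        ss_identity_filter(chain, fold, chosen_lengths),
        helix_kink_filter(chain, fold, chosen_lengths, max_bend=max_bend),
        constraint_filter(chain, fold, chosen_lengths),
        strand_pairing_filter(chain, fold, chosen_lengths, chosen_registers),
        clash_filter(chain),
    ]
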