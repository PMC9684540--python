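"""Shape-diversity descriptors and stability-score utilities.

Per-design geometric measurements used to compare designs of one fold:
inter-element distances, helix midpoint distance (Hm-d), helix dihedral
(H-dih), helix opening angles (H1a/H2a), the sheet dihedral through the
outer-strand ends, and measured strand registers.  Stability handling:
per-protease scores combine by the minimum (one negative protease score
means unfolded), and a fold's success rate is the fraction of designs with
combined score strictly above 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import measure_register
from .folddef import FoldDefinition, segment_bounds
from .geometry import BackboneChain, dihedral, helix_axis_points, _fit_line

SUCCESS_THRESHOLD = 0.5
NOT_APPLICABLE = math.nan


@dataclass
class DescriptorRecord:
    design_id: str
    total_length: int
    element_distances: dict[str, float] = field(default_factory=dict)
    helix_midpoint_distance: float = NOT_APPLICABLE  # Hm-d
    helix_dihedral: float = NOT_APPLICABLE  # H-dih
    helix1_opening_angle: float = NOT_APPLICABLE  # H1a
    helix2_opening_angle: float = NOT_APPLICABLE  # H2a
    sheet_dihedral: float = NOT_APPLICABLE
    registers: dict[str, int] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        data = {
            "total_length": self.total_length,
            "Hm-d": self.helix_midpoint_distance,
            "H-dih": self.helix_dihedral,
            "H1a": self.helix1_opening_angle,
            "H2a": self.helix2_opening_angle,
            "sheet_dihedral": self.sheet_dihedral,
        }
        data.update(self.element_distances)
        return pd.Series(data, name=self.design_id)


@dataclass
class StabilityRecord:
    design_id: str
    fold_label: str
    trypsin_score: float
    chymotrypsin_score: float

    @property
    def stability_score(self) -> float:
        return combine_stability(self.trypsin_score, self.chymotrypsin_score)


def _axis(ca: np.ndarray):
    """(point_start, midpoint, point_end, unit direction) of a helix axis."""
    cents = helix_axis_points(ca)
    centroid, direction = _fit_line(cents)
    if np.dot(direction, cents[-1] - cents[0]) < 0:
        direction = -direction
    proj = (cents - centroid) @ direction
    start = centroid + proj.min() * direction
    end = centroid + proj.max() * direction
    return start, (start + end) / 2.0, end, direction


def element_geometry(
    chain: BackboneChain,
    fold: FoldDefinition,
    chosen_lengths: dict[str, int],
    design_id: str = "design",
) -> DescriptorRecord:
    """Measure the per-design shape descriptors.

    Hm-d is the distance between the axis midpoints of the first two
    helices; H-dih the dihedral through (H1 axis start, H1 mid, H2 mid, H2
    axis end); Hk-a the angle between helix k's axis and the partner sheet
    (or, absent strands, the other helix's) CA plane; the sheet dihedral
    runs through the four end-CA pairs' midpoints of the two outer strands
    in sheet order.  Missing element classes leave NaN sentinels.  All
    descriptors are invariant under rigid motion; dihedral-valued ones flip
    sign under mirroring.
    """
    bounds = segment_bounds(fold, chosen_lengths)
    ca = chain.ca_coords()
    rec = DescriptorRecord(design_id, sum(chosen_lengths.values()))

    ss_elems = fold.ss_segments()
    mids = {}
    for seg in ss_elems:
        a, b = bounds[seg.name]
        mids[seg.name] = ca[a - 1 : b].mean(axis=0)
    for i, s1 in enumerate(ss_elems):
        for s2 in ss_elems[i + 1 :]:
            rec.element_distances[f"d_{s1.name}_{s2.name}"] = float(
                np.linalg.norm(mids[s1.name] - mids[s2.name])
            )

    helices = [s for s in ss_elems if s.kind == "helix"]
    strands = [s for s in ss_elems if s.kind == "strand"]
    axes = {}
    for h in helices:
        a, b = bounds[h.name]
        if b - a + 1 >= 4:
            axes[h.name] = _axis(ca[a - 1 : b])
    if len(helices) >= 2 and helices[0].name in axes and helices[1].name in axes:
        h1 = axes[helices[0].name]
        h2 = axes[helices[1].name]
        rec.helix_midpoint_distance = float(np.linalg.norm(h1[1] - h2[1]))
        # axis end points on the same flank, so two aligned parallel
        # helices measure ~0 and antiparallel ones ~180
        rec.helix_dihedral = dihedral(h1[2], h1[1], h2[1], h2[2])

    # opening angles: helix axis vs the reference plane of the partner set
    ref_points = None
    if strands:
        ref_points = np.concatenate(
            [ca[bounds[s.name][0] - 1 : bounds[s.name][1]] for s in strands]
        )
    elif len(helices) >= 2:
        ref_points = np.concatenate(
            [ca[bounds[h.name][0] - 1 : bounds[h.name][1]] for h in helices[:2]]
        )
    if ref_points is not None and len(ref_points) >= 3:
        centroid = ref_points.mean(axis=0)
        _, _, vt = np.linalg.svd(ref_points - centroid)
        normal = vt[2]
        for k, h in enumerate(helices[:2]):
            if h.name not in axes:
                continue
            direction = axes[h.name][3]
            sin_angle = abs(float(np.dot(direction, normal)))
            angle = math.degrees(math.asin(min(1.0, sin_angle)))
            if k == 0:
                rec.helix1_opening_angle = angle
            else:
                rec.helix2_opening_angle = angle

    # sheet dihedral: through the end midpoints of the two outer strands
    if fold.sheets:
        order = fold.sheets[0].strands
    else:
        order = tuple(s.name for s in strands)
    if len(order) >= 2:
        s_first, s_last = order[0], order[-1]
        a1, b1 = bounds[s_first]
        a2, b2 = bounds[s_last]
        # N-end, C-end of the first outer strand, then N-end, C-end of the
        # last: a perfectly flat sheet measures 180 (planarity convention)
        rec.sheet_dihedral = dihedral(
            ca[a1 - 1], ca[b1 - 1], ca[a2 - 1], ca[b2 - 1]
        )

    for p in fold.strand_pairings:
        reg, _ = measure_register(chain, fold, chosen_lengths, p)
        rec.registers[f"{p.first}-{p.second}"] = reg
    return rec


def ensemble_correlations(
    records: list[DescriptorRecord] | pd.DataFrame,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix over descriptor columns.

    Zero-variance features yield NaN entries rather than raising.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        if len(records) < 3:
            raise ValueError("need at least 3 records")
        df = pd.DataFrame([r.as_series() for r in records])
    if features is not None:
        df = df[features]
    df = df.select_dtypes(include=[np.number])
    return df.corr(method="pearson", min_periods=2)


def combine_stability(trypsin: float, chymotrypsin: float) -> float:
    """Combined stability score = min over the two proteases.

    A protein cleaved by either protease is unfolded, so a high score for
    one enzyme cannot rescue a negative score for the other.
    """
    if not (math.isfinite(trypsin) and math.isfinite(chymotrypsin)):
        raise ValueError("scores must be finite")
    return min(trypsin, chymotrypsin)


def success_rate(
    records: list[StabilityRecord],
    threshold: float = SUCCESS_THRESHOLD,
) -> dict[str, float]:
    """Per-fold fraction of designs with combined score strictly above
    ``threshold``; empty fold groups map to NaN."""
    by_fold: dict[str, list[float]] = {}
    for r in records:
        by_fold.setdefault(r.fold_label, []).append(r.stability_score)
    out = {}
    for fold_label, scores in by_fold.items():
        if not scores:
            out[fold_label] = NOT_APPLICABLE
        else:
            out[fold_label] = sum(s > threshold for s in scores) / len(scores)
    return out


def score_bin_counts(
    records: list[StabilityRecord],
    bin_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cumulative designs-at-or-above-score counts per fold per bin edge."""
    edges = np.arange(-1.0, 2.01, 0.25) if bin_edges is None else np.asarray(bin_edges)
    rows = {}
    by_fold: dict[str, list[float]] = {}
    for r in records:
        by_fold.setdefault(r.fold_label, []).append(r.stability_score)
    for fold_label, scores in sorted(by_fold.items()):
        arr = np.asarray(scores)
        rows[fold_label] = [(arr >= e).sum() for e in edges]
    return pd.DataFrame(rows, index=edges).T
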