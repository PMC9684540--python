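"""Shape descriptors, correlations, stability scores and success rates."""

import math

import numpy as np
import pandas as pd
import pytest

from foldsmith.descriptors import (
    DescriptorRecord,
    StabilityRecord,
    combine_stability,
    element_geometry,
    ensemble_correlations,
    score_bin_counts,
    success_rate,
)
from foldsmith.fixtures import FixtureSpec, ideal_helix, ideal_strand, make_fixture, _orient_along_z
from foldsmith.folddef import FoldDefinition, SegmentSpec, SheetSpec, StrandPairingSpec
from foldsmith.geometry import chain_from_coords

from conftest import apply_rigid, random_rotation_translation


def _two_helix_chain(separation=10.0, antiparallel=False):
    """Two ideal aligned helices joined by a 2-residue placeholder loop."""
    h = _orient_along_z(ideal_helix(12).coords)
    h2 = h.copy()
    if antiparallel:
        from scipy.spatial.transform import Rotation

        flip = Rotation.from_rotvec([math.pi, 0, 0])
        h2 = flip.apply(h2.reshape(-1, 3)).reshape(h2.shape)
    h2 = h2 + np.array([separation, 0.0, 0.0])
    loop = np.zeros((2, 4, 3))
    loop[0] = h[-1] + [2.0, 0, 2.0]
    loop[1] = h2[0] + [-2.0, 0, 2.0]
    coords = np.concatenate([h, loop, h2])
    fold = FoldDefinition(
        segments=[
            SegmentSpec("H1", "helix", (12, 12)),
            SegmentSpec("L1", "loop", (2, 2)),
            SegmentSpec("H2", "helix", (12, 12)),
        ]
    )
    lengths = {"H1": 12, "L1": 2, "H2": 12}
    chain = chain_from_coords(coords, ss="H" * 12 + "LL" + "H" * 12)
    return chain, fold, lengths


def _flat_sheet_chain(n_strands=4):
    base = _orient_along_z(ideal_strand(6).coords)
    parts = []
    segments = []
    ss = ""
    for k in range(n_strands):
        parts.append(base + np.array([0.0, 4.9 * k, 0.0]))
        segments.append(SegmentSpec(f"E{k + 1}", "strand", (6, 6)))
        ss += "E" * 6
        if k < n_strands - 1:
            mid = parts[-1][-1].mean(axis=0) + [0, 2.45, 0]
            loop = np.tile(mid, (1, 4, 1)).reshape(1, 4, 3)
            parts.append(loop)
            segments.append(SegmentSpec(f"L{k + 1}", "loop", (1, 1)))
            ss += "L"
    coords = np.concatenate(parts)
    pairings = [
        StrandPairingSpec(f"E{k + 1}", f"E{k + 2}", "parallel", (0, 0))
        for k in range(n_strands - 1)
    ]
    fold = FoldDefinition(
        segments=segments,
        strand_pairings=pairings,
        sheets=[SheetSpec(tuple(f"E{k + 1}" for k in range(n_strands)))],
    )
    lengths = {s.name: s.length_range[0] for s in segments}
    return chain_from_coords(coords, ss=ss), fold, lengths


class TestElementGeometry:
    def test_parallel_helices_midpoint_distance_and_dihedral(self):
        chain, fold, lengths = _two_helix_chain(separation=10.0)
        rec = element_geometry(chain, fold, lengths)
        assert abs(rec.helix_midpoint_distance - 10.0) < 0.5
        assert abs(rec.helix_dihedral) < 5.0

    def test_antiparallel_helices_dihedral_is_180(self):
        chain, fold, lengths = _two_helix_chain(separation=10.0, antiparallel=True)
        rec = element_geometry(chain, fold, lengths)
        assert abs(abs(rec.helix_dihedral) - 180.0) < 5.0

    def test_flat_sheet_dihedral_is_planar(self):
        chain, fold, lengths = _flat_sheet_chain()
        rec = element_geometry(chain, fold, lengths)
        assert abs(abs(rec.sheet_dihedral) - 180.0) < 5.0

    def test_rigid_motion_invariance(self, rng):
        chain, fold, lengths = _two_helix_chain()
        rec = element_geometry(chain, fold, lengths)
        R, t = random_rotation_translation(rng)
        moved = apply_rigid(chain, R, t)
        rec2 = element_geometry(moved, fold, lengths)
        assert abs(rec.helix_midpoint_distance - rec2.helix_midpoint_distance) < 1e-6
        assert abs(rec.helix_dihedral - rec2.helix_dihedral) < 1e-6
        for key in rec.element_distances:
            assert abs(rec.element_distances[key] - rec2.element_distances[key]) < 1e-6

    def test_mirror_flips_dihedral_sign(self):
        chain, fold, lengths = _flat_sheet_chain()
        # twist one end of the last strand out of plane so the dihedral is
        # signed and informative
        coords = chain.coords.copy()
        coords[-3:] += np.array([3.0, 0.0, 0.0])
        bent = chain_from_coords(coords, ss=chain.ss)
        rec = element_geometry(bent, fold, lengths)
        mirrored = bent.copy()
        mirrored.coords = bent.coords * np.array([1.0, 1.0, -1.0])
        rec_m = element_geometry(
            chain_from_coords(mirrored.coords, ss=chain.ss), fold, lengths
        )
        assert abs(rec.sheet_dihedral + rec_m.sheet_dihedral) < 1e-6

    def test_missing_helices_leave_sentinels(self):
        chain, fold, lengths = _flat_sheet_chain()
        rec = element_geometry(chain, fold, lengths)
        assert math.isnan(rec.helix_midpoint_distance)


class TestEnsembleCorrelations:
    def _records(self, n, rng, linear=False):
        records = []
        for k in range(n):
            r = DescriptorRecord(f"d{k}", total_length=50)
            x = float(rng.normal())
            r.helix_midpoint_distance = 10.0 + x
            r.helix_dihedral = 2.0 * (10.0 + x) if linear else float(rng.normal())
            r.sheet_dihedral = float(rng.normal())
            records.append(r)
        return records

    def test_linear_dependence_is_perfectly_correlated(self, rng):
        corr = ensemble_correlations(self._records(20, rng, linear=True))
        assert abs(corr.loc["H-dih", "Hm-d"] - 1.0) < 1e-9

    def test_independent_features_near_zero(self, rng):
        corr = ensemble_correlations(self._records(1000, rng))
        assert abs(corr.loc["H-dih", "Hm-d"]) < 0.1

    def test_matches_bruteforce_pearson(self, rng):
        records = self._records(50, rng)
        corr = ensemble_correlations(records)
        a = np.array([r.helix_midpoint_distance for r in records])
        b = np.array([r.sheet_dihedral for r in records])
        manual = float(
            ((a - a.mean()) * (b - b.mean())).sum()
            / math.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        )
        assert abs(corr.loc["Hm-d", "sheet_dihedral"] - manual) < 1e-12

    def test_zero_variance_gives_nan(self, rng):
        records = self._records(10, rng)
        for r in records:
            r.sheet_dihedral = 1.0
        corr = ensemble_correlations(records)
        assert math.isnan(corr.loc["sheet_dihedral", "Hm-d"])

    def test_too_few_records_rejected(self, rng):
        with pytest.raises(ValueError):
            ensemble_correlations(self._records(2, rng))


class TestStability:
    def test_one_negative_protease_means_unfolded(self):
        assert combine_stability(1.2, -0.3) == -0.3

    def test_identity_and_commutativity(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=2)
            assert combine_stability(a, a) == a
            assert combine_stability(a, b) == combine_stability(b, a)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            combine_stability(float("nan"), 1.0)


def _recs(scores, fold="f1"):
    return [
        StabilityRecord(f"d{i}", fold, s, s) for i, s in enumerate(scores)
    ]


class TestSuccessRate:
    def test_strictly_above_threshold(self):
        rates = success_rate(_recs([0.6, 0.4, 0.51, -1.0]))
        assert rates["f1"] == 0.5

    def test_boundary_scores_do_not_count(self):
        assert success_rate(_recs([0.5, 0.5, 0.5]))["f1"] == 0.0

    def test_all_stable(self):
        assert success_rate(_recs([1.0, 1.0]))["f1"] == 1.0

    def test_monotone_in_threshold(self, rng):
        records = _recs(list(rng.normal(0.5, 0.5, size=50)))
        prev = 1.1
        for thr in np.linspace(-1, 2, 13):
            rate = success_rate(records, threshold=thr)["f1"]
            assert rate <= prev + 1e-12
            prev = rate

    def test_bin_counts_are_cumulative(self):
        records = _recs([0.0, 0.5, 1.0, 1.5])
        table = score_bin_counts(records, bin_edges=np.array([0.0, 1.0]))
        assert table.loc["f1", 0.0] == 4
        assert table.loc["f1", 1.0] == 2
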