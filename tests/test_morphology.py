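"""Morphometrics: skeletons, Sholl profiles, lengths, volumes, compartments."""

import math

import numpy as np
import pytest

from microdyn.morphology import (
    cell_volume,
    compartment_ratio,
    count_branch_segments,
    sholl,
    skeleton_from_polylines,
    skeletonize_cell,
    total_process_length,
    write_swc,
)
from microdyn.simulate import AcquisitionConfig, build_cell_model, render_cell


def _star_graph(k, arm_length=30.0, n_nodes=11):
    lines = []
    for i in range(k):
        phi = 2 * math.pi * i / k
        d = np.array([0.0, math.sin(phi), math.cos(phi)])
        ts = np.linspace(0, arm_length, n_nodes)
        lines.append(np.array([t * d for t in ts]))
    return skeleton_from_polylines(lines, root_pos=np.zeros(3), soma_radius_um=2.0)


class TestSholl:
    @pytest.mark.parametrize("k", range(1, 9))
    def test_star_has_k_intersections_at_every_shell(self, k):
        skel = _star_graph(k, arm_length=30.0)
        profile = sholl(skel, step_um=5.0)
        inside = profile.radii_um <= 30.0
        assert np.all(profile.intersections[inside] == k)
        assert np.all(profile.intersections[~inside] == 0)
        assert profile.n_processes == k
        assert profile.total_length_um == pytest.approx(30.0 * k, rel=1e-9)

    def test_bifurcation_doubles_count_beyond_branch_point(self):
        trunk = np.array([[0.0, 0.0, t] for t in np.linspace(0, 15, 6)])
        child_a = np.array([[0.0, t, 15.0 + t] for t in np.linspace(0, 10, 5)])
        child_b = np.array([[0.0, -t, 15.0 + t] for t in np.linspace(0, 10, 5)])
        child_a[:, 2] = 15.0 + np.linspace(0, 10, 5)
        child_b[:, 2] = 15.0 + np.linspace(0, 10, 5)
        skel = skeleton_from_polylines([trunk, child_a, child_b], root_pos=np.zeros(3))
        profile = sholl(skel, step_um=5.0)
        r = profile.radii_um
        assert np.all(profile.intersections[r <= 15.0] == 1)
        assert np.all(profile.intersections[(r > 16.0) & (r <= 25.0)] == 2)

    def test_matches_brute_force_crossing_oracle_on_random_trees(self):
        """Edge-by-edge, shell-by-shell crossing enumeration, exact match."""
        for seed in range(10):
            model = build_cell_model(n_primary=4, branch_prob=0.5, length_scale=25.0, seed=seed)
            skel = skeleton_from_polylines(
                [b.points for b in model.branches], root_pos=model.soma_center, soma_radius_um=model.soma_radius
            )
            step = 5.0
            profile = sholl(skel, step_um=step)
            root = skel.node_pos(skel.root)
            for shell_idx, r in enumerate(profile.radii_um):
                crossings = 0
                for a, b in skel.graph.edges:
                    da = np.linalg.norm(skel.node_pos(a) - root)
                    db = np.linalg.norm(skel.node_pos(b) - root)
                    lo, hi = min(da, db), max(da, db)
                    if lo < r <= hi:
                        crossings += 1
                assert profile.intersections[shell_idx] == crossings


class TestTotalProcessLength:
    def test_three_four_five_triangle(self):
        skel = skeleton_from_polylines([np.array([[0.0, 0.0, 0.0], [0.0, 3.0, 4.0]])], root_pos=np.zeros(3))
        assert total_process_length(skel) == pytest.approx(5.0)

    def test_invariant_to_polyline_order(self):
        model = build_cell_model(3, 0.5, 20.0, seed=2)
        lines = [b.points for b in model.branches]
        a = total_process_length(skeleton_from_polylines(lines, np.zeros(3)))
        b = total_process_length(skeleton_from_polylines(lines[::-1], np.zeros(3)))
        assert a == pytest.approx(b, rel=1e-12)

    def test_model_graph_length_equals_ground_truth(self):
        model = build_cell_model(5, 0.5, 25.0, seed=4)
        skel = skeleton_from_polylines([b.points for b in model.branches], model.soma_center)
        assert total_process_length(skel) == pytest.approx(model.L_true, rel=1e-9)


class TestSkeletonizeCell:
    def _acq(self):
        return AcquisitionConfig(
            fov_xy=100.0, voxel_size_xy=1.0, stack_depth=24.0, voxel_size_z=2.0, n_frames=2, noise_model=None
        )

    def test_straight_tube_yields_single_path_of_known_length(self):
        from microdyn.simulate import Branch, CellModel

        acq = self._acq()
        arm = Branch(points=np.array([[0.0, 0.0, -20.0], [0.0, 0.0, 20.0]]), radius=1.5, parent=-1, depth=0)
        model = CellModel(soma_center=np.array([0.0, 0.0, -20.0]), soma_radius=1.6, branches=[arm])
        mask = render_cell(model, acq)
        skel = skeletonize_cell(mask, acq.voxel_size_xy, acq.voxel_size_z)
        leaves = [n for n in skel.graph.nodes if skel.graph.degree(n) == 1]
        assert len(leaves) == 2  # a simple path
        length = total_process_length(skel)
        assert length == pytest.approx(40.0, abs=4.0)

    def test_five_arm_cell_recovers_five_tips(self):
        acq = self._acq()
        model = build_cell_model(5, 0.0, 25.0, seed=6)
        mask = render_cell(model, acq)
        skel = skeletonize_cell(mask, acq.voxel_size_xy, acq.voxel_size_z, soma_centroid=np.array([12.0, 49.5, 49.5]))
        leaves = [n for n in skel.graph.nodes if skel.graph.degree(n) == 1 and n != skel.root]
        assert len(leaves) == 5

    def test_total_length_close_to_model_truth(self):
        acq = self._acq()
        model = build_cell_model(4, 0.0, 25.0, seed=8)
        mask = render_cell(model, acq)
        skel = skeletonize_cell(mask, acq.voxel_size_xy, acq.voxel_size_z)
        measured = total_process_length(skel, exclude_radius_um=model.soma_radius)
        assert measured == pytest.approx(model.L_true, rel=0.12)

    def test_sphere_collapses_to_compact_root(self):
        from microdyn.simulate import CellModel

        acq = self._acq()
        model = CellModel(soma_center=np.zeros(3), soma_radius=5.0, branches=[])
        mask = render_cell(model, acq)
        skel = skeletonize_cell(mask, acq.voxel_size_xy, acq.voxel_size_z)
        assert total_process_length(skel) < 2 * model.soma_radius

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            skeletonize_cell(np.zeros((4, 8, 8), bool), 1.0, 2.0)


class TestCellVolume:
    def test_cuboid_arithmetic(self):
        mask = np.zeros((8, 12, 12), bool)
        mask[1:6, 1:11, 1:11] = True  # 5 x 10 x 10 voxels
        assert cell_volume(mask, 0.5, 2.0) == pytest.approx(500 * 0.5**2 * 2.0)

    def test_additive_over_disjoint_masks(self, rng):
        a = rng.random((4, 10, 10)) > 0.7
        b = (rng.random((4, 10, 10)) > 0.7) & ~a
        assert cell_volume(a | b, 1.0, 2.0) == pytest.approx(
            cell_volume(a, 1.0, 2.0) + cell_volume(b, 1.0, 2.0)
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            cell_volume(np.zeros((2, 2, 2), bool), 1.0, 1.0)


class TestCompartmentRatio:
    def _setup(self):
        cell = np.zeros((4, 20, 20), bool)
        cell[:, 2:18, 2:18] = True
        soma = np.zeros_like(cell)
        soma[:, 8:12, 8:12] = True
        return cell, soma

    def test_equal_signal_gives_unit_ratio(self):
        cell, soma = self._setup()
        signal = np.zeros_like(cell)
        signal[:, 9:11, 9:11] = True  # 4 px/frame in soma
        signal[:, 3:5, 3:7] = True  # 8 px/frame... adjust to 4
        signal[:, 3:5, 3:7] = False
        signal[:, 3:5, 3:5] = True  # 4 px/frame in processes
        res = compartment_ratio(cell, soma, signal)
        assert res.process_to_soma_ratio == pytest.approx(1.0)

    def test_signal_only_in_soma_gives_zero(self):
        cell, soma = self._setup()
        res = compartment_ratio(cell, soma, soma.copy())
        assert res.process_to_soma_ratio == pytest.approx(0.0)
        assert res.ratio_defined

    def test_zero_soma_signal_flagged_undefined(self):
        cell, soma = self._setup()
        signal = np.zeros_like(cell)
        signal[:, 3:5, 3:5] = True
        res = compartment_ratio(cell, soma, signal)
        assert not res.ratio_defined
        assert math.isnan(res.process_to_soma_ratio)

    def test_signal_outside_cell_ignored(self):
        cell, soma = self._setup()
        signal = np.ones_like(cell)  # covers everything incl. background
        res = compartment_ratio(cell, soma, signal)
        expected = (cell.sum() - soma.sum()) / soma.sum()
        assert res.process_to_soma_ratio == pytest.approx(expected)
        assert res.signal_per_cell_volume == pytest.approx(1.0)

    def test_planted_three_to_one_recovered(self, rng):
        """Puncta planted with 3:1 process:soma volume ratio are recovered."""
        cell, soma = self._setup()
        proc_idx = np.argwhere(cell & ~soma)
        soma_idx = np.argwhere(soma)
        signal = np.zeros_like(cell)
        n_soma = 40
        for i in rng.choice(len(soma_idx), n_soma, replace=False):
            signal[tuple(soma_idx[i])] = True
        for i in rng.choice(len(proc_idx), 3 * n_soma, replace=False):
            signal[tuple(proc_idx[i])] = True
        res = compartment_ratio(cell, soma, signal)
        assert res.process_to_soma_ratio == pytest.approx(3.0, abs=1e-9)


class TestSwcExport:
    def test_round_trip_structure(self, tmp_path):
        skel = _star_graph(3)
        path = tmp_path / "cell.swc"
        write_swc(skel, path)
        rows = [line.split() for line in path.read_text().strip().splitlines()]
        assert len(rows) == skel.n_nodes
        ids = {int(r[0]) for r in rows}
        assert ids == set(range(1, skel.n_nodes + 1))
        assert sum(1 for r in rows if int(r[6]) == -1) == 1  # single root
        for r in rows[1:]:
            assert int(r[6]) in ids or int(r[6]) == -1


class TestBranchSegments:
    def test_star_counts_arms(self):
        assert count_branch_segments(_star_graph(5)) == 5

    def test_single_path_is_one_segment(self):
        skel = skeleton_from_polylines([np.array([[0.0, 0.0, t] for t in range(5)])], np.zeros(3))
        assert count_branch_segments(skel) == 1
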