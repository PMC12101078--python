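"""Minimum-image distance engine against exhaustive and external oracles."""

import math

import numpy as np
import pytest

from membind import (
    AnalysisConfig,
    Frame,
    SelectionError,
    min_distance_frame,
    min_distance_trace,
    per_residue_min_distance,
)

from conftest import make_params, random_frame
from membind import simulate_binding_trajectory
from membind.synthetic import BOUND_THRESHOLD


def exhaustive_min_distance(coords_a, coords_b, box, axes) -> float:
    """Independent oracle: plain double loop with explicit minimum image."""
    best = math.inf
    for a in coords_a:
        for b in coords_b:
            d2 = 0.0
            for ax in range(3):
                d = a[ax] - b[ax]
                if ax in axes:
                    d -= box[ax] * round(d / box[ax])
                d2 += d * d
            best = min(best, d2)
    return math.sqrt(best)


AXES = {"xyz": (0, 1, 2), "xy": (0, 1), "none": ()}


class TestMinDistanceFrame:
    def test_coincident_points_give_zero(self):
        frame = Frame(0.0, (17, 17, 25), np.array([[1, 1, 5], [1, 1, 5.0], [9, 9, 9]]))
        assert min_distance_frame(frame, [0], [1], "xyz") == 0.0

    def test_minimum_image_wraps_across_the_box(self):
        frame = Frame(0.0, (17, 17, 25), np.array([[0.5, 1, 1], [16.5, 1, 1.0]]))
        assert min_distance_frame(frame, [0], [1], "xyz") == pytest.approx(1.0, abs=1e-12)
        assert min_distance_frame(frame, [0], [1], "none") == pytest.approx(16.0, abs=1e-12)

    @pytest.mark.parametrize("pbc_mode", ["xyz", "xy", "none"])
    def test_agrees_with_exhaustive_oracle(self, pbc_mode):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            frame, a, b = random_frame(rng, 40, 60)
            got = min_distance_frame(frame, a, b, pbc_mode)
            want = exhaustive_min_distance(
                frame.coords[a], frame.coords[b], frame.box, AXES[pbc_mode]
            )
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("pbc_mode", ["xyz", "xy", "none"])
    def test_tree_accelerator_matches_brute_force(self, pbc_mode):
        rng = np.random.default_rng(7)
        for _ in range(25):
            frame, a, b = random_frame(rng, 50, 70)
            brute = min_distance_frame(frame, a, b, pbc_mode, force="brute")
            tree = min_distance_frame(frame, a, b, pbc_mode, force="tree")
            assert tree == pytest.approx(brute, abs=1e-12)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        frame, a, b = random_frame(rng, 20, 30)
        assert min_distance_frame(frame, a, b, "xyz") == min_distance_frame(frame, b, a, "xyz")

    def test_adding_particles_never_increases_minimum(self):
        rng = np.random.default_rng(4)
        frame, a, b = random_frame(rng, 30, 50)
        full = min_distance_frame(frame, a, b, "xyz")
        sub = min_distance_frame(frame, a, b[:10], "xyz")
        assert full <= sub + 1e-15

    def test_invariant_under_integer_box_translation(self):
        rng = np.random.default_rng(5)
        frame, a, b = random_frame(rng, 10, 10)
        before = min_distance_frame(frame, a, b, "xyz")
        shifted = frame.coords.copy()
        shifted[a] += frame.box * np.array([2.0, -1.0, 3.0])
        frame2 = Frame(0.0, frame.box, shifted)
        assert min_distance_frame(frame2, a, b, "xyz") == pytest.approx(before, abs=1e-9)

    def test_bounded_by_half_box_diagonal_under_full_pbc(self):
        rng = np.random.default_rng(6)
        frame, a, b = random_frame(rng, 5, 5)
        half_diag = np.linalg.norm(frame.box / 2)
        assert min_distance_frame(frame, a, b, "xyz") <= half_diag

    def test_empty_or_overlapping_groups_rejected(self):
        frame = Frame(0.0, (5, 5, 5), np.zeros((4, 3)))
        with pytest.raises(SelectionError):
            min_distance_frame(frame, [], [1], "xyz")
        with pytest.raises(SelectionError):
            min_distance_frame(frame, [0, 1], [1, 2], "xyz")

    def test_against_mdanalysis_distance_array(self):
        """Cross-check against an independent periodic-distance implementation."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from MDAnalysis.lib.distances import distance_array
        rng = np.random.default_rng(11)
        for _ in range(10):
            frame, a, b = random_frame(rng, 30, 40)
            box_angstrom = np.concatenate([frame.box * 10.0, [90.0, 90.0, 90.0]])
            ref = distance_array(
                (frame.coords[a] * 10.0).astype(np.float64),
                (frame.coords[b] * 10.0).astype(np.float64),
                box=box_angstrom,
            ).min() / 10.0
            # MDAnalysis computes in single precision; compare accordingly
            assert min_distance_frame(frame, a, b, "xyz") == pytest.approx(ref, abs=1e-5)


class TestTraces:
    def test_rigid_translation_gives_unit_increments(self):
        from membind import LipidComposition, Particle, Role, Topology, Trajectory

        particles = [
            Particle(1, 1, "ALA", "BB", Role.PROTEIN),
            Particle(2, 2, "DOPC", "PO4", Role.LIPID_HEAD, "DOPC", "lower"),
        ]
        topo = Topology(particles, LipidComposition({"DOPC": 1.0}))
        coords = np.array(
            [[[0, 0, 2.0 + i], [0, 0, 1.0]] for i in range(3)], dtype=float
        )
        traj = Trajectory(topo, np.arange(3.0), np.tile([50, 50, 50.0], (3, 1)), coords)
        trace = min_distance_trace(traj, config=AnalysisConfig(pbc_mode="none"))
        assert np.allclose(trace.values, [1.0, 2.0, 3.0])

    def test_trace_matches_frame_wise_computation(self, small_trajectory):
        traj, _ = small_trajectory
        config = AnalysisConfig()
        trace = min_distance_trace(traj, config=config)
        prot = traj.topology.protein_indices()
        mem = traj.topology.membrane_indices()
        for i in range(0, traj.n_frames, 37):
            assert trace.values[i] == pytest.approx(
                min_distance_frame(traj.frame(i), prot, mem, "xyz"), abs=1e-12
            )

    def test_bound_only_trajectory_stays_below_threshold(self, bound_only_trajectory):
        traj, _ = bound_only_trajectory
        trace = min_distance_trace(traj)
        assert np.all(trace.values <= BOUND_THRESHOLD)


class TestPerResidue:
    def test_single_residue_matrix_equals_global_trace(self):
        params = make_params(n_residues=1, interface_residues=frozenset({1}), n_frames=100)
        traj, _ = simulate_binding_trajectory(params)
        mat = per_residue_min_distance(traj)
        trace = min_distance_trace(traj)
        assert mat.values.shape[0] == 1
        assert np.allclose(mat.values[0], trace.values, atol=1e-12)

    def test_rowwise_minimum_equals_global_trace(self, small_trajectory):
        traj, _ = small_trajectory
        mat = per_residue_min_distance(traj)
        trace = min_distance_trace(traj)
        assert np.allclose(mat.values.min(axis=0), trace.values, atol=1e-9)

    def test_matches_exhaustive_per_residue_oracle(self):
        params = make_params(n_residues=5, beads_per_residue=2,
                             interface_residues=frozenset({2, 3}), n_frames=20)
        traj, _ = simulate_binding_trajectory(params)
        mat = per_residue_min_distance(traj)
        topo = traj.topology
        mem = topo.membrane_indices()
        for fi in range(traj.n_frames):
            frame = traj.frame(fi)
            for ri, resid in enumerate(mat.residue_indices):
                beads = [
                    i for i, p in enumerate(topo.particles)
                    if p.role.value == "protein" and p.residue_index == resid
                ]
                want = exhaustive_min_distance(
                    frame.coords[beads], frame.coords[mem], frame.box, (0, 1, 2)
                )
                assert mat.values[ri, fi] == pytest.approx(want, abs=1e-12)
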