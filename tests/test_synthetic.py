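"""Synthetic generator: bilayer construction, chain statistics, guarantees."""

import numpy as np
import pytest

from membind import (
    LipidComposition,
    ParameterError,
    Role,
    build_bilayer,
    build_protein,
    min_distance_trace,
    per_residue_min_distance,
    simulate_binding_trajectory,
)
from membind.synthetic import (
    BOUND_THRESHOLD,
    CONTACT_CUTOFF,
    HALF_THICKNESS,
    GroundTruth,
    _largest_remainder_counts,
)

from conftest import make_params


class TestBilayer:
    def test_lipid_count_follows_area_per_lipid(self):
        # floor(6*6 / 0.64) = 56 lipids per leaflet
        topo, _ = build_bilayer(LipidComposition({"DOPC": 1.0}), box=(6, 6, 10),
                                area_per_lipid=0.64, seed=0)
        heads = topo.indices(role=Role.LIPID_HEAD)
        assert heads.size == 2 * 56
        assert all(p.lipid_class == "DOPC" for p in topo.particles)

    def test_composition_rounding_is_exact_for_exact_fractions(self):
        # 10 lipids per leaflet: 6 DOPC + 4 DOPA each
        comp = LipidComposition({"DOPC": 0.6, "DOPA": 0.4})
        topo, _ = build_bilayer(comp, box=(3.2, 2.0, 10.0), area_per_lipid=0.64, seed=1)
        for leaflet in ("upper", "lower"):
            heads = topo.indices(role=Role.LIPID_HEAD, leaflet=leaflet)
            classes = [topo.particles[i].lipid_class for i in heads]
            assert classes.count("DOPC") == 6 and classes.count("DOPA") == 4

    def test_largest_remainder_within_one_lipid_per_class(self):
        counts = _largest_remainder_counts({"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}, 10)
        assert sum(counts.values()) == 10
        assert all(abs(c - 10 / 3) <= 1.0 for c in counts.values())

    def test_leaflets_centred_on_midplane(self):
        topo, frame = build_bilayer(LipidComposition({"DOPC": 1.0}), box=(6, 6, 10), seed=0)
        upper = topo.indices(role=Role.LIPID_HEAD, leaflet="upper")
        lower = topo.indices(role=Role.LIPID_HEAD, leaflet="lower")
        assert np.allclose(frame.coords[upper, 2], 5.0 + HALF_THICKNESS)
        assert np.allclose(frame.coords[lower, 2], 5.0 - HALF_THICKNESS)

    def test_deterministic_for_fixed_seed(self):
        comp = LipidComposition({"DOPC": 0.5, "DOPA": 0.5})
        _, f1 = build_bilayer(comp, box=(6, 6, 10), seed=42)
        _, f2 = build_bilayer(comp, box=(6, 6, 10), seed=42)
        assert np.array_equal(f1.coords, f2.coords)
        _, f3 = build_bilayer(comp, box=(6, 6, 10), seed=43)
        assert not np.array_equal(f1.coords, f3.coords)

    def test_too_small_cross_section_rejected(self):
        with pytest.raises(ParameterError):
            build_bilayer(LipidComposition({"DOPC": 1.0}), box=(1, 1, 10),
                          area_per_lipid=0.64, seed=0)


class TestProtein:
    def test_bead_count_and_residue_multiplicity(self):
        params = make_params(n_residues=5, beads_per_residue=2,
                             interface_residues=frozenset({2}))
        particles, coords = build_protein(params)
        assert len(particles) == 10 and coords.shape == (10, 3)
        resids = [p.residue_index for p in particles]
        assert all(resids.count(r) == 2 for r in range(1, 6))

    def test_lowest_bead_sits_exactly_at_start_offset(self):
        params = make_params()
        _, coords = build_protein(params)
        upper_plane = params.box[2] / 2.0 + HALF_THICKNESS
        assert abs(coords[:, 2].min() - upper_plane - 2.5) < 1e-9

    def test_same_seed_identical_geometry(self):
        params = make_params()
        _, c1 = build_protein(params, seed=9)
        _, c2 = build_protein(params, seed=9)
        assert np.array_equal(c1, c2)


class TestBindingChain:
    def test_absorbing_unbound_never_binds(self):
        params = make_params(p_bind=0.0, p_unbind=0.3, initial_state="unbound",
                             n_frames=1000)
        traj, truth = simulate_binding_trajectory(params)
        assert truth.true_occupancy == 0.0
        trace = min_distance_trace(traj)
        assert np.all(trace.values > BOUND_THRESHOLD)

    def test_absorbing_bound_stays_bound(self):
        params = make_params(p_bind=0.3, p_unbind=0.0, initial_state="bound",
                             n_frames=1000)
        traj, truth = simulate_binding_trajectory(params)
        assert truth.true_occupancy == 1.0
        trace = min_distance_trace(traj)
        assert np.all(trace.values <= BOUND_THRESHOLD)

    def test_stationary_occupancy_within_chain_3sigma(self):
        # symmetric chain p=q=0.1: occupancy 0.5, lag-1 autocorrelation
        # rho = 1-p-q = 0.8, var(mean) ~ 0.25 * (1+rho)/(1-rho) / n
        params = make_params(box=(4, 4, 14), n_residues=8,
                             interface_residues=frozenset({2, 3}),
                             p_bind=0.1, p_unbind=0.1, n_frames=20000, seed=17)
        _, truth = simulate_binding_trajectory(params)
        band = 3 * np.sqrt(0.25 * 9 / 20000)
        assert abs(truth.true_occupancy - 0.5) <= band

    def test_ground_truth_occupancy_is_exact_mean(self, small_trajectory):
        _, truth = small_trajectory
        assert truth.true_occupancy == np.mean(truth.state_sequence)

    def test_ground_truth_json_roundtrip(self, small_trajectory, tmp_path):
        _, truth = small_trajectory
        truth.save(tmp_path / "gt.json")
        loaded = GroundTruth.load(tmp_path / "gt.json")
        assert np.array_equal(loaded.state_sequence, truth.state_sequence)
        assert loaded.interface_residues == truth.interface_residues
        assert loaded.true_depths == truth.true_depths


class TestGeneratorGuarantees:
    def test_bound_and_unbound_margins_hold_per_frame(self, small_trajectory):
        traj, truth = small_trajectory
        mat = per_residue_min_distance(traj)
        iface_rows = np.isin(mat.residue_indices, sorted(truth.interface_residues))
        bound = truth.state_sequence
        if bound.any():
            # every interface residue contacts the membrane in every bound frame
            assert np.all(mat.values[np.ix_(iface_rows, bound)] < CONTACT_CUTOFF)
            # non-interface residues never register contact
            assert np.all(mat.values[np.ix_(~iface_rows, bound)] >= CONTACT_CUTOFF)
        if (~bound).any():
            global_min = mat.values[:, ~bound].min(axis=0)
            assert np.all(global_min > BOUND_THRESHOLD)

    def test_bit_identical_for_same_seed_different_otherwise(self):
        t1, _ = simulate_binding_trajectory(make_params(seed=33))
        t2, _ = simulate_binding_trajectory(make_params(seed=33))
        t3, _ = simulate_binding_trajectory(make_params(seed=34))
        assert np.array_equal(t1.coords, t2.coords)
        assert not np.array_equal(t1.coords, t3.coords)


class TestParameterValidation:
    def test_interface_residue_outside_range_rejected(self):
        with pytest.raises(ParameterError, match="interface"):
            make_params(interface_residues=frozenset({99}))

    def test_rest_altitude_too_low_reports_margin(self):
        with pytest.raises(ParameterError, match="rest altitude"):
            make_params(rest_altitude=0.5)

    def test_depth_incompatible_with_contact_guarantee_rejected(self):
        with pytest.raises(ParameterError, match="depth"):
            make_params(bound_depths=0.45)

    def test_transition_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError):
            make_params(p_bind=1.5)
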