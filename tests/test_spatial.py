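"""Spatial statistics: exact oracles, invariances, generator round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carboxysome.config import PoseSimConfig
from carboxysome.simulate import simulate_carboxysome
from carboxysome.spatial import (assign_layers, axis_radial_angles,
                                 estimate_core, layer_profile,
                                 nearest_neighbour_distances,
                                 neighbour_pair_distances, pose_axes,
                                 radial_distances, summarize_population)
from conftest import rigid_transform


def _pose_frame(xyz, tilt_deg=0.0):
    xyz = np.atleast_2d(xyz)
    return pd.DataFrame({
        "carboxysome_id": "cb", "x_A": xyz[:, 0], "y_A": xyz[:, 1],
        "z_A": xyz[:, 2], "rot_deg": 0.0, "tilt_deg": tilt_deg,
        "psi_deg": 0.0})


class TestCore:
    def test_single_and_symmetric(self):
        assert np.allclose(estimate_core([[0.0, 0.0, 0.0]]), 0.0)
        assert np.allclose(estimate_core([[-5.0, 0, 0], [5.0, 0, 0]]), 0.0)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_core(np.empty((0, 3)))

    def test_noiseless_simulation_recovers_true_centre(self):
        cfg = PoseSimConfig(position_jitter_sd_A=0.0,
                            orientation_noise_sd_deg=0.0)
        centre = np.array([500.0, -200.0, 80.0])
        poses, _ = simulate_carboxysome(cfg, 169.0, seed=5, centre=centre)
        core = estimate_core(poses[["x_A", "y_A", "z_A"]].to_numpy())
        assert np.abs(core - centre).max() < 1e-9


class TestRadialDistances:
    def test_basic_values_and_order(self):
        core = np.zeros(3)
        pts = np.array([[0, 0, 0], [0, 0, 120.0], [0, 50.0, 0]])
        assert radial_distances(pts, core).tolist() == [0.0, 120.0, 50.0]

    def test_noiseless_simulation_radii_match_truth(
            self, noiseless_carboxysome):
        poses, truth = noiseless_carboxysome
        xyz = poses[["x_A", "y_A", "z_A"]].to_numpy()
        r = radial_distances(xyz, estimate_core(xyz))
        assert np.abs(r - truth["true_radius_A"].to_numpy()).max() < 1e-6


class TestAssignLayers:
    def test_single_radius(self):
        layers, summary = assign_layers(np.array([0.0]), 120.0)
        assert layers.tolist() == [1]
        assert summary["count"].tolist() == [1]

    def test_noiseless_lattice_is_exact(self, noiseless_carboxysome):
        poses, truth = noiseless_carboxysome
        xyz = poses[["x_A", "y_A", "z_A"]].to_numpy()
        r = radial_distances(xyz, estimate_core(xyz))
        layers, summary = assign_layers(r, 120.0)
        assert np.array_equal(layers, truth["layer"].to_numpy())
        assert summary["count"].tolist() == [1, 19, 77, 174, 309]

    def test_jittered_radii_mostly_recovered(self):
        rng = np.random.default_rng(5)
        true_layers = rng.integers(1, 6, 200)
        radii = np.abs((true_layers - 1) * 120.0 + rng.normal(0, 15, 200))
        layers, _ = assign_layers(radii, 120.0)
        assert (layers == true_layers).mean() >= 0.99

    def test_mean_radius_strictly_increasing(self, population):
        poses, _ = population
        group = poses[poses["carboxysome_id"] == "cb_000"]
        prof = layer_profile(group)
        assert prof.layers["mean_radius_A"].is_monotonic_increasing


class TestNeighbourDistances:
    def test_pair(self):
        d = nearest_neighbour_distances([[0, 0, 0], [120.0, 0, 0]])
        assert d.tolist() == [120.0, 120.0]

    def test_triangular_patch_all_equal(self):
        s = 104.0
        pts = [(i * s + (j % 2) * s / 2, j * s * np.sqrt(3) / 2, 0.0)
               for i in range(5) for j in range(5)]
        assert np.allclose(nearest_neighbour_distances(pts), s)

    @pytest.mark.parametrize("n", [5, 60, 500])
    def test_matches_brute_force_all_pairs(self, n):
        rng = np.random.default_rng(n)
        pts = rng.uniform(0, 600, (n, 3))
        fast = nearest_neighbour_distances(pts)
        gram = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(gram, np.inf)
        assert np.allclose(fast, gram.min(axis=1))
        # cutoff variant against the same exhaustive matrix
        cutoff = 160.0
        brute = gram[np.triu_indices(n, 1)]
        brute = np.sort(brute[brute <= cutoff])
        assert np.allclose(np.sort(neighbour_pair_distances(pts, cutoff)),
                           brute)

    def test_fewer_than_two_is_an_error(self):
        with pytest.raises(ValueError):
            nearest_neighbour_distances([[0, 0, 0]])


class TestAxisRadialAngles:
    @pytest.mark.parametrize("tilt,expected", [(0.0, 0.0), (90.0, 90.0),
                                               (30.0, 30.0), (150.0, 30.0)])
    def test_constructed_tilt(self, tilt, expected):
        # particle on the +z axis, 4-fold axis tilted by `tilt` from z
        poses = _pose_frame([[0.0, 0.0, 300.0]], tilt_deg=tilt)
        theta = axis_radial_angles(pose_axes(poses),
                                   poses[["x_A", "y_A", "z_A"]].to_numpy(),
                                   np.zeros(3))
        assert theta[0] == pytest.approx(expected, abs=1e-9)

    def test_particle_at_core_is_missing_not_error(self):
        poses = _pose_frame([[0.0, 0.0, 0.0], [0.0, 0.0, 120.0]])
        theta = axis_radial_angles(pose_axes(poses),
                                   poses[["x_A", "y_A", "z_A"]].to_numpy(),
                                   np.zeros(3))
        assert np.isnan(theta[0]) and theta[1] == pytest.approx(0.0)

    def test_bounded_and_flip_invariant(self, population):
        poses, _ = population
        group = poses[poses["carboxysome_id"] == "cb_001"]
        xyz = group[["x_A", "y_A", "z_A"]].to_numpy()
        axes = pose_axes(group)
        core = estimate_core(xyz)
        theta = axis_radial_angles(axes, xyz, core)
        ok = ~np.isnan(theta)
        assert (theta[ok] >= 0.0).all() and (theta[ok] <= 90.0).all()
        flipped = axis_radial_angles(-axes, xyz, core)
        assert np.allclose(theta[ok], flipped[ok], atol=1e-9)


class TestRigidInvariance:
    @given(seed=st.integers(0, 50))
    @settings(max_examples=12, deadline=None, derandomize=True)
    def test_statistics_unchanged_by_rotation_translation(self, seed):
        cfg = PoseSimConfig(seed=3)
        poses, _ = simulate_carboxysome(cfg, 169.0, seed=3)
        moved = rigid_transform(poses, seed=seed)

        for frame in (poses, moved):
            xyz = frame[["x_A", "y_A", "z_A"]].to_numpy()
            core = estimate_core(xyz)
            frame.attrs["radii"] = radial_distances(xyz, core)
            frame.attrs["nn"] = nearest_neighbour_distances(xyz)
            frame.attrs["theta"] = axis_radial_angles(
                pose_axes(frame), xyz, core)
        assert np.allclose(poses.attrs["radii"], moved.attrs["radii"],
                           atol=1e-6)
        assert np.allclose(poses.attrs["nn"], moved.attrs["nn"], atol=1e-6)
        assert np.allclose(poses.attrs["theta"], moved.attrs["theta"],
                           atol=1e-6, equal_nan=True)
        same = assign_layers(poses.attrs["radii"], 120.0)[0]
        other = assign_layers(moved.attrs["radii"], 120.0)[0]
        assert np.array_equal(same, other)


class TestSummarizePopulation:
    def test_single_particle_carboxysome(self):
        poses = _pose_frame([[10.0, 20.0, 30.0]])
        _, per_carb, pop = summarize_population(poses)
        assert per_carb["n_particles"].tolist() == [1]
        assert per_carb["n_layers"].tolist() == [1]
        assert pop["layer_count_histogram"] == {}  # not an intact particle

    def test_layer_counts_conserved(self, population_summary):
        particles, per_carb, _ = population_summary
        sums = particles.groupby("carboxysome_id")["layer"].size()
        assert (sums.to_numpy() == per_carb.set_index("carboxysome_id")
                ["n_particles"].to_numpy()).all()

    def test_population_structure(self, population_summary):
        _, per_carb, pop = population_summary
        assert pop["modal_layer_count"] == 5
        assert pop["fraction_4_to_6_layers"] > 0.9
        assert sum(pop["layer_count_histogram"].values()) == len(per_carb)

    def test_layers_recovered_against_generator_truth(
            self, population, population_summary):
        _, truth = population
        particles, _, _ = population_summary
        agreement = (particles["layer"].to_numpy()
                     == truth["layer"].to_numpy()).mean()
        assert agreement >= 0.99
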