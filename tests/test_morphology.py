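import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import special_ortho_group

import dpdsolvex as dx
from dpdsolvex import morphology as mor
from dpdsolvex.fixtures import FixtureSpec, make_fixture, polymer_indices
from dpdsolvex.state import A, B, G, W


def chain_pair_state(b_gap, box=20.0):
    """Two 3-bead chains (A-B-B) whose nearest B beads sit ``b_gap`` apart."""
    chain1 = np.array([[5.0, 5.0, 5.0], [6.0, 5.0, 5.0], [7.0, 5.0, 5.0]])
    chain2 = chain1 + np.array([1.0 + b_gap, 0.0, 0.0])
    pos = np.vstack([chain1, chain2])
    species = np.array([A, B, B, A, B, B], dtype=np.int8)
    state = dx.SystemState(
        positions=pos, velocities=np.zeros_like(pos), species=species,
        bonds=np.array([[0, 1], [1, 2], [3, 4], [4, 5]]), box_edge=box,
        chain_of=np.array([0, 0, 0, 1, 1, 1], dtype=np.int64))
    state.wrap()
    return state


class TestClusterIdentification:
    def test_contact_below_cutoff_merges_chains(self):
        clusters = dx.find_clusters(chain_pair_state(1.4))
        assert clusters.n_clusters == 1
        assert clusters.n_agg.tolist() == [2]

    def test_contact_beyond_cutoff_keeps_chains_apart(self):
        clusters = dx.find_clusters(chain_pair_state(1.6))
        assert clusters.n_clusters == 2
        assert sorted(clusters.n_agg.tolist()) == [1, 1]

    def test_hydrophilic_contacts_do_not_merge(self):
        # A beads adjacent, B beads far: still two clusters
        chain1 = np.array([[5.0, 5.0, 5.0], [6.0, 5.0, 5.0], [7.0, 5.0, 5.0]])
        chain2 = np.array([[4.5, 5.0, 5.0], [3.5, 5.0, 5.0], [2.5, 5.0, 5.0]])
        pos = np.vstack([chain1, chain2])
        state = dx.SystemState(
            positions=pos, velocities=np.zeros_like(pos),
            species=np.array([A, B, B, A, B, B], dtype=np.int8),
            bonds=np.array([[0, 1], [1, 2], [3, 4], [4, 5]]), box_edge=20.0,
            chain_of=np.array([0, 0, 0, 1, 1, 1], dtype=np.int64))
        assert dx.find_clusters(state).n_clusters == 2

    def test_contacts_across_periodic_boundary(self):
        state = chain_pair_state(1.4, box=20.0)
        # slide the pair so the contact spans the x boundary
        state.positions += np.array([12.0, 0.0, 0.0])
        state.wrap()
        assert state.positions[:, 0].min() < 2.0  # second chain wrapped
        assert dx.find_clusters(state).n_clusters == 1

    def test_matches_brute_force_union_find(self, small_mixture):
        state = small_mixture
        clusters = dx.find_clusters(state)

        # independent O(n^2) oracle over B beads with naive union-find
        parent = list(range(state.n_chains))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        b_idx = np.flatnonzero(state.species == B)
        for u in range(len(b_idx)):
            for v in range(u + 1, len(b_idx)):
                d = dx.minimum_image(
                    state.positions[b_idx[u]] - state.positions[b_idx[v]],
                    state.box_edge)
                if np.linalg.norm(d) < 1.5:
                    cu = find(state.chain_of[b_idx[u]])
                    cv = find(state.chain_of[b_idx[v]])
                    parent[cu] = cv
        oracle = [find(c) for c in range(state.n_chains)]
        for c1 in range(state.n_chains):
            for c2 in range(state.n_chains):
                same_oracle = oracle[c1] == oracle[c2]
                same_impl = (clusters.assignment[c1] ==
                             clusters.assignment[c2])
                assert same_oracle == same_impl

    def test_translation_invariance(self, small_mixture):
        state = small_mixture.copy()
        ref = dx.find_clusters(state).assignment
        state.positions += np.array([2.7, -1.3, 4.1])
        state.wrap()
        moved = dx.find_clusters(state).assignment
        np.testing.assert_array_equal(ref, moved)

    def test_partition_bookkeeping(self, small_mixture):
        clusters = dx.find_clusters(small_mixture)
        assert clusters.n_agg.sum() == small_mixture.n_chains
        all_beads = np.concatenate(clusters.members)
        assert len(all_beads) == len(set(all_beads.tolist()))


class TestGyrationDescriptor:
    def test_unit_cube_corners(self):
        corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                            for k in (0, 1)], dtype=float)
        d = dx.gyration_descriptor(corners)
        np.testing.assert_allclose(d.eigenvalues, 0.25)
        assert d.r31 == pytest.approx(1.0) and d.r21 == pytest.approx(1.0)
        assert d.rg2 == pytest.approx(0.75)

    def test_collinear_points_are_degenerate(self):
        line = np.outer(np.arange(5.0), [1.0, 1.0, 0.0])
        d = dx.gyration_descriptor(line)
        assert d.degenerate
        assert np.isinf(d.r31) and np.isinf(d.r21)

    def test_single_point_is_degenerate(self):
        d = dx.gyration_descriptor(np.zeros((1, 3)))
        assert d.degenerate

    @given(st.integers(0, 2**31 - 1))
    def test_rotation_invariance_of_eigenvalues(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(40, 3)) * [3.0, 1.5, 0.7]
        rot = special_ortho_group.rvs(3, random_state=rng)
        d1 = dx.gyration_descriptor(pts)
        d2 = dx.gyration_descriptor(pts @ rot.T)
        np.testing.assert_allclose(d1.eigenvalues, d2.eigenvalues,
                                   rtol=1e-9, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_trace_identity(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-4, 4, size=(25, 3))
        d = dx.gyration_descriptor(pts + rng.normal(size=3) * 10)
        msd = np.mean(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1))
        assert d.rg2 == pytest.approx(d.eigenvalues.sum(), rel=1e-12)
        assert d.rg2 == pytest.approx(msd, rel=1e-9)

    def test_cylinder_aspect_morph_monotone(self):
        """Shrinking a cylinder toward a sphere drives r31 and r32 toward 1
        together — the elongated-to-spherical transition signature."""
        r31s, r32s = [], []
        for aspect in (5.0, 3.0, 2.0, 1.2, 0.87):
            spec = FixtureSpec(kind="cylinder", radius=1.5, aspect=aspect,
                               n_b=2000, n_a=0, n_w=0, seed=4)
            state = make_fixture(spec)
            coords = dx.unwrap_cluster(state, polymer_indices(state))
            d = dx.gyration_descriptor(coords)
            r31s.append(d.r31)
            r32s.append(d.r32)
        assert all(a > b for a, b in zip(r31s, r31s[1:]))
        assert r31s[0] > 20 and abs(r31s[-1] - 1.0) < 0.3


class TestShapeClassification:
    @pytest.mark.parametrize("ratios, label", [
        ((1.05, 1.03, 1.02), "spheroidal"),
        ((8.0, 5.0, 1.6), "flat-cylindrical"),
        ((6.0, 5.8, 1.03), "elongated"),
    ])
    def test_labels(self, ratios, label):
        r31, r32, r21 = ratios
        d = mor.ShapeDescriptor(np.eye(3), np.array([1.0, r21, r31]),
                                r31, r32, r21, 1.0 + r21 + r31, 100)
        assert dx.classify_shape(d) == label

    def test_degenerate_flag_wins(self):
        d = dx.gyration_descriptor(np.outer(np.arange(4.0), [1, 0, 0]))
        assert dx.classify_shape(d) == "degenerate"


class TestDensityProfile:
    def test_uniform_gas_is_flat(self):
        state = make_fixture(FixtureSpec(
            kind="uniform-gas", n_b=4000, n_a=0, n_w=4000, box_edge=12.0,
            seed=8))
        prof = dx.density_profile(state, polymer_indices(state),
                                  mode="radial", n_bins=6, r_max=5.0)
        # every shell flat to within Poisson counting noise (5 sigma)
        expected = 4000 / 12.0 ** 3 * prof.bin_volumes
        resid = np.abs(prof.counts[B] - expected)
        assert np.all(resid < 5.0 * np.sqrt(expected))

    def test_counts_conserved_per_species(self, small_mixture):
        state = small_mixture
        clusters = dx.find_clusters(state)
        members = clusters.members[clusters.largest()]
        prof = dx.density_profile(state, members, mode="radial", n_bins=10,
                                  r_max=2.9)
        np.testing.assert_allclose(prof.density * prof.bin_volumes,
                                   prof.counts)
        # binned totals recover the per-species bead counts inside r_max
        com = dx.unwrap_cluster(state, members).mean(axis=0)
        r = np.linalg.norm(
            dx.minimum_image(state.positions - com, state.box_edge), axis=1)
        for sp in range(4):
            expected = int(((r < 2.9) & (state.species == sp)).sum())
            assert prof.counts[sp].sum() == expected

    def test_vesicle_profile_has_shell_peak_and_water_core(self):
        state = make_fixture(FixtureSpec(
            kind="hollow-shell", radius=4.0, thickness=1.0, n_b=2000,
            n_a=400, n_w=3000, seed=9))
        prof = dx.density_profile(state, polymer_indices(state),
                                  mode="radial", n_bins=24, r_max=8.0)
        centers = prof.bin_centers
        peak_r = centers[np.argmax(prof.density[B])]
        assert peak_r == pytest.approx(4.0, abs=0.5)
        # interior water plateau: W present well inside the shell
        inner = centers < 2.0
        assert prof.density[W][inner].mean() > 0.3

    def test_long_axis_mode_brackets_cylinder_length(self):
        state = make_fixture(FixtureSpec(
            kind="cylinder", radius=1.5, aspect=4.0, n_b=3000, n_a=0,
            n_w=0, seed=10))
        prof = dx.density_profile(state, polymer_indices(state),
                                  mode="long-axis", n_bins=30, r_max=10.0,
                                  slab_radius=2.0)
        centers = prof.bin_centers
        occupied = centers[prof.density[B] > 0.1]
        assert occupied.min() == pytest.approx(-6.0, abs=1.0)
        assert occupied.max() == pytest.approx(6.0, abs=1.0)

    def test_unknown_mode_rejected(self, small_mixture):
        clusters = dx.find_clusters(small_mixture)
        with pytest.raises(ValueError):
            dx.density_profile(small_mixture, clusters.members[0],
                               mode="spiral")


class TestCavities:
    def test_solid_sphere_has_none(self):
        state = make_fixture(FixtureSpec(kind="solid-sphere", n_b=2000,
                                         seed=11))
        report = dx.detect_cavities(state, polymer_indices(state))
        assert report.count == 0

    def test_hollow_shell_has_exactly_one(self):
        state = make_fixture(FixtureSpec(
            kind="hollow-shell", radius=4.0, thickness=1.2, n_b=2500,
            n_w=3000, seed=12))
        report = dx.detect_cavities(state, polymer_indices(state))
        assert report.count == 1
        # the cavity encloses the interior water
        assert report.n_w_inside[0] > 100
        # roughly the interior ball, eroded by the occupancy radius
        inner = 4.0 - 1.2 / 2 - 0.75
        assert report.volumes[0] == pytest.approx(4 / 3 * np.pi * inner ** 3,
                                                  rel=0.5)

    def test_punched_shell_leaks_to_the_outside(self):
        state = make_fixture(FixtureSpec(
            kind="shell-with-hole", radius=4.0, thickness=1.2,
            hole_angle_deg=50.0, n_b=2500, n_w=2000, seed=13))
        report = dx.detect_cavities(state, polymer_indices(state))
        assert report.count == 0

    def test_invalid_spacing_rejected(self, small_mixture):
        clusters = dx.find_clusters(small_mixture)
        with pytest.raises(ValueError):
            dx.detect_cavities(small_mixture, clusters.members[0],
                               lattice_spacing=0.0)


class TestAggregateClassification:
    def test_hollow_shell_is_a_vesicle(self):
        state = make_fixture(FixtureSpec(
            kind="hollow-shell", radius=4.0, thickness=1.2, n_b=2500,
            n_a=500, n_w=3000, seed=14))
        assert dx.classify_aggregate(
            state, polymer_indices(state)).label == "vesicle"

    def test_oblate_solid_is_a_disk(self):
        state = make_fixture(FixtureSpec(
            kind="oblate-disk", radius=5.0, aspect=4.0, n_b=3000, n_a=600,
            seed=15))
        assert dx.classify_aggregate(
            state, polymer_indices(state)).label == "disk"

    def test_interleaved_blob_is_llps_like(self):
        state = make_fixture(FixtureSpec(
            kind="mixed-blob", radius=4.0, n_b=900, n_a=300, n_w=800,
            n_g=800, seed=16))
        report = dx.classify_aggregate(state, polymer_indices(state))
        assert report.label == "LLPS-like"
        assert abs(report.segregation_index) < 0.15

    def test_solid_sphere_with_corona_is_a_micelle(self):
        state = make_fixture(FixtureSpec(
            kind="solid-sphere", radius=4.0, n_b=2000, n_a=500, n_w=1500,
            seed=17))
        report = dx.classify_aggregate(state, polymer_indices(state))
        assert report.label == "micelle"
        assert report.segregation_index > 0.15  # corona outside the core

    def test_tiny_cluster_is_degenerate(self, small_mixture):
        report = dx.classify_aggregate(small_mixture, np.array([0, 1, 2]))
        assert report.label == "degenerate"


class TestUnwrapping:
    def test_cluster_straddling_boundary_is_made_contiguous(self):
        state = chain_pair_state(1.4, box=20.0)
        state.positions[:, 0] += 13.5  # push the pair across the x boundary
        state.wrap()
        clusters = dx.find_clusters(state)
        coords = dx.unwrap_cluster(state, clusters.members[0])
        assert coords[:, 0].max() - coords[:, 0].min() < 6.0

    def test_unwrapped_shape_matches_unwrapped_reference(self):
        ref = chain_pair_state(1.4, box=20.0)
        d_ref = dx.gyration_descriptor(ref.positions)
        moved = chain_pair_state(1.4, box=20.0)
        moved.positions[:, 0] += 13.5
        moved.wrap()
        coords = dx.unwrap_cluster(moved,
                                   dx.find_clusters(moved).members[0])
        d_mov = dx.gyration_descriptor(coords)
        np.testing.assert_allclose(d_mov.eigenvalues, d_ref.eigenvalues,
                                   atol=1e-9)
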