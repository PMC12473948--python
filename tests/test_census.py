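import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octagg import (AggregateCensus, ClusterSet, Frame, MoleculeTopology,
                    Trajectory, build_conformation, census,
                    census_timeseries, classify_pair, cluster_frame, count_hbonds,
                    detect_equilibrium, molecule_centroid, pair_distance_trace,
                    ring_plane)
from octagg.synth import ClusterPlant, PlantSpec, hexagon_template, _rot_x90
from conftest import UnionFind

BOX = np.array([40.0, 40.0, 40.0])
HEX = hexagon_template()


def two_hexagon_frame(offset_vec, rot_b=np.eye(3), center=np.array([20.0, 20.0, 20.0])):
    """Two hexagons: A at `center` in the z=0 plane, B displaced by offset_vec."""
    coords = np.vstack([center + HEX, center + np.asarray(offset_vec) + (rot_b @ HEX.T).T])
    return Frame(time=0.0, box=BOX, coords=coords)


def hex_topology(n):
    return [MoleculeTopology(f"m{i}", tuple(range(6 * i, 6 * i + 6)), ("C",) * 6,
                             (tuple(range(6 * i, 6 * i + 6)),))
            for i in range(n)]


class TestCentroid:
    def test_two_atom_midpoint(self):
        mol = MoleculeTopology("m", (0, 1), ("C", "C"))
        frame = Frame(0.0, (10, 10, 10), [[0, 0, 0], [2, 0, 0]])
        assert molecule_centroid(frame, mol) == pytest.approx([1, 0, 0])

    def test_molecule_split_across_boundary_unwrapped(self):
        mol = MoleculeTopology("m", (0, 1), ("C", "C"))
        frame = Frame(0.0, (10, 10, 10), [[9.8, 1, 1], [0.2, 1, 1]])
        c = molecule_centroid(frame, mol)
        # centroid is at x = 10.0 == 0.0 under PBC, never the naive 5.0
        assert c[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_atom_is_its_own_centroid(self):
        mol = MoleculeTopology("m", (0,), ("C",))
        frame = Frame(0.0, (10, 10, 10), [[3.3, 4.4, 5.5]])
        assert molecule_centroid(frame, mol) == pytest.approx([3.3, 4.4, 5.5])

    def test_mass_weighting_pulls_toward_heavy_atom(self):
        mol = MoleculeTopology("m", (0, 1), ("H", "Br"))
        frame = Frame(0.0, (20, 20, 20), [[0, 0, 0], [2, 0, 0]])
        c = molecule_centroid(frame, mol, weighting="mass")
        assert c[0] == pytest.approx(2 * 79.904 / (79.904 + 1.008))


class TestRingPlane:
    def test_planar_hexagon_normal_is_z(self):
        frame = Frame(0.0, BOX, np.array([20.0, 20, 20]) + HEX)
        _, n = ring_plane(frame, range(6))
        assert abs(n[2]) == pytest.approx(1.0, abs=1e-12)

    def test_rotation_carries_the_normal(self):
        frame = Frame(0.0, BOX, np.array([20.0, 20, 20]) + (_rot_x90() @ HEX.T).T)
        _, n = ring_plane(frame, range(6))
        assert abs(n[1]) == pytest.approx(1.0, abs=1e-12)

    def test_puckered_ring_matches_direct_leastsquares_oracle(self):
        rng = np.random.default_rng(11)
        pts = HEX + rng.normal(scale=0.15, size=(6, 3))
        frame = Frame(0.0, BOX, np.array([20.0, 20, 20]) + pts)
        _, n = ring_plane(frame, range(6))
        # independent oracle: smallest eigenvector of the scatter matrix,
        # computed via an explicit eigendecomposition
        centered = pts - pts.mean(axis=0)
        w, v = np.linalg.eigh(centered.T @ centered)
        oracle = v[:, 0]
        assert min(np.linalg.norm(n - oracle), np.linalg.norm(n + oracle)) < 1e-6

    def test_collinear_atoms_rejected(self):
        frame = Frame(0.0, BOX, [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            ring_plane(frame, range(5))


class TestClassifyPair:
    @pytest.mark.parametrize("offset, rot, expected", [
        ((0, 0, 3.5), np.eye(3), "face-to-face"),           # eclipsed sandwich
        ((1.5, 0, 3.4), np.eye(3), "offset-face-to-face"),  # slipped parallel, d=3.72
        ((0, 0, 4.5), np.eye(3), None),                     # parallel but too far
        ((0, 0, 4.5), _rot_x90(), "edge-to-face"),          # perpendicular, 5.0 cutoff
        ((0, 0, 5.5), _rot_x90(), None),                    # beyond every cutoff
    ], ids=["f2f", "offset", "parallel-too-far", "e2f", "beyond-all"])
    def test_conformer_assignment_and_cutoffs(self, criteria, offset, rot, expected):
        frame = two_hexagon_frame(offset, rot)
        a, b = hex_topology(2)
        contact = classify_pair(frame, a, b, criteria)
        if expected is None:
            assert contact is None
        else:
            assert contact is not None and contact.conformer == expected

    def test_classification_is_symmetric(self, criteria):
        frame = two_hexagon_frame((1.2, 0.3, 3.3))
        a, b = hex_topology(2)
        ab = classify_pair(frame, a, b, criteria)
        ba = classify_pair(frame, b, a, criteria)
        assert (ab is None) == (ba is None)
        if ab is not None:
            assert ab.conformer == ba.conformer
            assert ab.distance == pytest.approx(ba.distance)

    def test_enlarging_cutoffs_never_loses_contacts(self, criteria, small_planted):
        _, traj = small_planted
        frame = traj.frames[0]
        n_base = len(cluster_frame(frame, traj.topology, criteria).clusters)
        wide = dataclasses.replace(criteria, cutoff_f2f=3.9, cutoff_offset=4.5,
                                   cutoff_e2f=6.5)
        n_wide = len(cluster_frame(frame, traj.topology, wide).clusters)
        assert n_wide <= n_base  # more contacts merge clusters, never split them

    def test_ring_pair_mode_agrees_on_single_ring_molecules(self, criteria):
        frame = two_hexagon_frame((0, 0, 3.5))
        a, b = hex_topology(2)
        ring_mode = dataclasses.replace(criteria, mode="ring-pair")
        c1 = classify_pair(frame, a, b, criteria)
        c2 = classify_pair(frame, a, b, ring_mode)
        assert c1.conformer == c2.conformer == "face-to-face"

    def test_ring_pair_mode_requires_rings(self, criteria):
        frame = Frame(0.0, BOX, np.zeros((2, 3)) + [[10, 10, 10], [10, 10, 14]])
        a = MoleculeTopology("a", (0,), ("C",))
        b = MoleculeTopology("b", (1,), ("C",))
        ring_mode = dataclasses.replace(criteria, mode="ring-pair")
        with pytest.raises(ValueError, match="ring"):
            classify_pair(frame, a, b, ring_mode)


class TestClusterFrame:
    def test_transitive_chain_is_one_trimer(self, criteria):
        coords = np.vstack([np.array([20.0, 20, 10 + 3.5 * i]) + HEX for i in range(3)])
        frame = Frame(0.0, BOX, coords)
        cs = cluster_frame(frame, hex_topology(3), criteria)
        assert cs.size_counts() == {3: 1}

    def test_no_contacts_gives_all_monomers(self, criteria):
        coords = np.vstack([np.array([5.0 + 10 * i, 20, 20]) + HEX for i in range(3)])
        frame = Frame(0.0, BOX, coords)
        cs = cluster_frame(frame, hex_topology(3), criteria)
        assert cs.size_counts() == {1: 3}

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_equals_union_find_oracle(self, criteria, seed):
        spec = PlantSpec(n_molecules=10, box_edge=28.0,
                         clusters=(ClusterPlant(2), ClusterPlant(3, "edge-to-face")),
                         seed=seed)
        traj = build_conformation(spec)
        frame = traj.frames[0]
        cs = cluster_frame(frame, traj.topology, criteria)
        uf = UnionFind([m.molecule_id for m in traj.topology])
        for i, a in enumerate(traj.topology):
            for b in traj.topology[i + 1:]:
                if classify_pair(frame, a, b, criteria) is not None:
                    uf.union(a.molecule_id, b.molecule_id)
        assert set(cs.clusters) == uf.partition()

    def test_census_invariant_under_lattice_translation(self, criteria, small_planted):
        _, traj = small_planted
        frame = traj.frames[0]
        shifted = Frame(frame.time, frame.box, frame.coords + frame.box * [1, -2, 3])
        c0 = census(cluster_frame(frame, traj.topology, criteria))
        c1 = census(cluster_frame(shifted, traj.topology, criteria))
        assert dict(c0.counts) == dict(c1.counts)


def cluster_set(n, size_counts):
    """Build a ClusterSet with the given {size: count} inventory."""
    clusters, idx = [], 0
    for size, count in size_counts.items():
        for _ in range(count):
            clusters.append(frozenset(f"m{idx + j}" for j in range(size)))
            idx += size
    for j in range(n - idx):
        clusters.append(frozenset({f"s{j}"}))
    return ClusterSet(time=0.0, clusters=tuple(clusters), n_molecules=n)


class TestCensus:
    @pytest.mark.parametrize("n, inventory, expected", [
        (34, {2: 7, 3: 1}, {"monomer": 50.0, "dimer": 41.2, "trimer": 8.8}),
        (15, {2: 3}, {"monomer": 60.0, "dimer": 40.0, "trimer": 0.0}),
        (61, {2: 4}, {"monomer": 86.9, "dimer": 13.1, "trimer": 0.0}),
        (61, {2: 6}, {"monomer": 80.3, "dimer": 19.7, "trimer": 0.0}),
    ])
    def test_reported_percentage_cells(self, n, inventory, expected):
        c = census(cluster_set(n, inventory))
        for species, value in expected.items():
            assert c.percentages[species] == pytest.approx(value)

    @given(st.integers(min_value=1, max_value=80), st.data())
    @settings(max_examples=100, deadline=None)
    def test_conservation_and_percentages_sum_to_100(self, n, data):
        remaining, inventory = n, {}
        for size in (4, 3, 2):
            k = data.draw(st.integers(min_value=0, max_value=remaining // size))
            if k:
                inventory[size] = k
                remaining -= size * k
        c = census(cluster_set(n, inventory))
        assert sum(k * cnt for k, cnt in c.counts.items()) == n
        # each of the four displayed categories carries at most 0.05 rounding error
        assert sum(c.percentages.values()) == pytest.approx(100.0, abs=0.2)

    def test_empty_frame_census_undefined(self):
        with pytest.raises(ValueError):
            census(ClusterSet(time=0.0, clusters=(), n_molecules=0))


def staged_trajectory(criteria, dimer_counts, box=36.0, n=10):
    """Frames with a growing number of planted dimers at times 0, 10, 20..."""
    frames = []
    for i, nd in enumerate(dimer_counts):
        spec = PlantSpec(n_molecules=n, box_edge=box,
                         clusters=tuple(ClusterPlant(2) for _ in range(nd)), seed=50 + i)
        f = build_conformation(spec).frames[0]
        frames.append(Frame(time=10.0 * i, box=f.box, coords=f.coords))
    topo = build_conformation(PlantSpec(n_molecules=n, box_edge=box, seed=0)).topology
    return Trajectory(topology=topo, frames=frames)


class TestTimeseries:
    def test_constant_planted_clusters_give_identical_censuses(self, criteria, small_planted):
        spec, traj0 = small_planted
        frames = [Frame(10.0 * i, traj0.frames[0].box, traj0.frames[0].coords)
                  for i in range(4)]
        traj = Trajectory(topology=traj0.topology, frames=frames)
        series = census_timeseries(traj, [0, 10, 20, 30], criteria)
        assert len({tuple(sorted(c.counts.items())) for c in series}) == 1

    def test_staged_growth_gives_monotone_dimer_percentage(self, criteria):
        traj = staged_trajectory(criteria, [0, 1, 2, 3])
        series = census_timeseries(traj, [0, 10, 20, 30], criteria)
        dimers = [c.percentages["dimer"] for c in series]
        assert dimers == sorted(dimers) and dimers[0] < dimers[-1]

    def test_checkpoint_beyond_span_rejected(self, criteria, small_planted):
        _, traj = small_planted
        with pytest.raises(ValueError, match="outside"):
            census_timeseries(traj, [99.0], criteria)


class TestPairTrace:
    def test_static_pair_gives_constant_series(self, criteria):
        frame0 = two_hexagon_frame((0, 0, 4.0))
        topo = hex_topology(2)
        frames = [Frame(float(i), BOX, frame0.coords) for i in range(3)]
        traj = Trajectory(topology=topo, frames=frames)
        dists, fractions = pair_distance_trace(traj, "m0", "m1", criteria)
        assert np.ptp(dists) == pytest.approx(0.0, abs=1e-12)
        assert dists[0] == pytest.approx(4.0)
        # 4.0 A is inside the edge-to-face cutoff only
        assert fractions == {"face-to-face": 0.0, "offset-face-to-face": 0.0,
                             "edge-to-face": 1.0}

    def test_bound_fraction_matches_planted_occupancy(self, criteria):
        topo = hex_topology(2)
        near = two_hexagon_frame((0, 0, 3.5)).coords
        far = two_hexagon_frame((15.0, 0, 0)).coords
        frames = [Frame(float(i), BOX, near if i < 3 else far) for i in range(6)]
        traj = Trajectory(topology=topo, frames=frames)
        _, fractions = pair_distance_trace(traj, "m0", "m1", criteria)
        assert fractions["face-to-face"] == pytest.approx(0.5)

    def test_identical_molecules_rejected(self, criteria, small_planted):
        _, traj = small_planted
        with pytest.raises(ValueError):
            pair_distance_trace(traj, "mol-0", "mol-0", criteria)


def census_series(monomer_dimer_pairs):
    out = []
    for t, (mono_n, dim_n) in enumerate(monomer_dimer_pairs):
        out.append(census(cluster_set(mono_n + 2 * dim_n, {2: dim_n})))
        out[-1] = AggregateCensus(time=float(t * 10), n_molecules=out[-1].n_molecules,
                                  counts=out[-1].counts)
    return out


class TestDetectEquilibrium:
    def test_constant_series_is_stable_from_the_start(self):
        series = census_series([(18, 3)] * 6)
        assert detect_equilibrium(series, window=2) == 0.0

    def test_strictly_growing_series_never_stabilizes(self):
        series = census_series([(24, 0), (20, 2), (16, 4), (12, 6), (8, 8)])
        assert detect_equilibrium(series, window=2) is None

    def test_single_excursion_declares_stability_after_it(self):
        # one transient cell, then the stationary composition returns
        series = census_series([(17, 7), (19, 6), (17, 7), (17, 7), (17, 7), (17, 7)])
        assert detect_equilibrium(series, window=2, tol=5.0) == 20.0

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(ValueError):
            detect_equilibrium(census_series([(18, 3)] * 3), window=5)


class TestHydrogenBonds:
    def test_ideal_linear_geometry_counts_one(self):
        # O-H ... O, H-A distance 1.84, D-H-A angle 180 degrees
        frame = Frame(0.0, (20, 20, 20),
                      [[5.0, 5, 5], [5.96, 5, 5], [7.8, 5, 5]])
        assert count_hbonds(frame, donors=[(0, 1)], acceptors=[2]) == 1

    def test_distant_pair_counts_zero(self):
        frame = Frame(0.0, (20, 20, 20),
                      [[5.0, 5, 5], [5.96, 5, 5], [10.0, 5, 5]])
        assert count_hbonds(frame, donors=[(0, 1)], acceptors=[2]) == 0

    def test_missing_hydrogen_rejected(self):
        frame = Frame(0.0, (20, 20, 20), [[5.0, 5, 5], [7.8, 5, 5]])
        with pytest.raises(ValueError, match="hydrogen"):
            count_hbonds(frame, donors=[(0, 5)], acceptors=[1])

    @pytest.mark.parametrize("seed", range(5))
    def test_random_frames_match_naive_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        box = np.array([12.0, 12.0, 12.0])
        n_donors, n_acc = 4, 6
        coords = rng.uniform(0, 12.0, size=(2 * n_donors + n_acc, 3))
        donors = [(2 * i, 2 * i + 1) for i in range(n_donors)]
        acceptors = list(range(2 * n_donors, 2 * n_donors + n_acc))
        frame = Frame(0.0, box, coords)

        def naive():
            from conftest import brute_force_min_image
            count = 0
            for d, h in donors:
                for a in acceptors:
                    dist = brute_force_min_image(coords[h], coords[a], box)
                    if dist > 3.5:
                        continue
                    # reconstruct minimum-image vectors by image enumeration
                    best_hd = min(((coords[d] + np.array([i, j, k]) * box - coords[h])
                                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)),
                                  key=lambda v: np.linalg.norm(v))
                    best_ha = min(((coords[a] + np.array([i, j, k]) * box - coords[h])
                                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)),
                                  key=lambda v: np.linalg.norm(v))
                    cosang = np.dot(best_hd, best_ha) / (
                        np.linalg.norm(best_hd) * np.linalg.norm(best_ha))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 130.0:
                        count += 1
            return count

        assert count_hbonds(frame, donors, acceptors) == naive()
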