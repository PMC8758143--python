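"""AIS extraction, truncation, radius, depth alignment, synapse coordinates."""

import numpy as np
import pytest
from scipy.sparse.csgraph import dijkstra

from chandelier.ais import (
    align_depth_axis,
    extract_ais,
    mean_radius,
    synapse_coordinates,
    truncate_ais,
)
from chandelier.skeleton import SkeletonGraph, read_swc, write_swc


def _branched_chain():
    """50-node chain with a 3-um side branch attached at node 20."""
    n = 50
    pos = np.zeros((n + 3, 3))
    pos[:n, 1] = np.arange(n) * 1000.0
    # side branch sticks out in +x at 1 um spacing
    for k in range(3):
        pos[n + k] = [1000.0 * (k + 1), 20_000.0, 0.0]
    edges = [(i, i + 1) for i in range(n - 1)]
    edges += [(20, n), (n, n + 1), (n + 1, n + 2)]
    return SkeletonGraph(
        positions=pos, radii=np.full(n + 3, 500.0), edges=np.asarray(edges)
    )


class TestExtractAIS:
    def test_on_path_nodes_returned(self, chain_skeleton):
        ais = extract_ais(chain_skeleton, [0, 0, 0], [0, 40_000, 0])
        assert len(ais) == 41
        assert np.allclose(ais.arclength, np.arange(41))

    def test_side_branch_excluded_by_padding(self):
        """Geodesic-ellipse rule vs brute-force dijkstra on the small graph."""
        skel = _branched_chain()
        top, bottom = [0, 0, 0], [0, 40_000, 0]
        ais = extract_ais(skel, top, bottom, padding=1000.0)
        # oracle: full geodesic distance matrix
        d = dijkstra(skel.adjacency(), directed=False)
        i_top, i_bot = 0, 40
        d_ais = d[i_top, i_bot]
        expected = {
            v for v in range(len(skel))
            if d[i_top, v] + d[i_bot, v] <= d_ais + 1000.0
        }
        got = {skel.nearest_node(p) for p in ais.positions}
        assert got == expected
        # branch nodes beyond 0.5 um of detour are excluded
        assert 51 not in got and 52 not in got

    def test_huge_padding_returns_all_nodes(self):
        skel = _branched_chain()
        ais = extract_ais(skel, [0, 0, 0], [0, 40_000, 0], padding=1e12)
        assert len(ais) == len(skel)

    def test_padding_monotonicity(self):
        skel = _branched_chain()
        sizes = [
            len(extract_ais(skel, [0, 0, 0], [0, 40_000, 0], padding=pad))
            for pad in (0.0, 500.0, 1000.0, 2000.0, 1e9)
        ]
        assert sizes == sorted(sizes)

    def test_same_node_anchors_error(self, chain_skeleton):
        with pytest.raises(ValueError):
            extract_ais(chain_skeleton, [0, 0, 0], [0, 100, 0])

    def test_node_order_in_file_is_irrelevant(self, tmp_path):
        """Extracted+truncated node set ignores SWC row permutation."""
        skel = _branched_chain()
        path = tmp_path / "a.swc"
        write_swc(skel, path)
        lines = path.read_text().splitlines()
        header, body = lines[0], lines[1:]
        rng = np.random.default_rng(0)
        # reparenting under permutation is nontrivial; permute leaf-safe order
        perm = body[::-1]
        (tmp_path / "b.swc").write_text("\n".join([header] + perm) + "\n")
        s2 = read_swc(tmp_path / "b.swc")
        a1 = truncate_ais(extract_ais(skel, [0, 0, 0], [0, 40_000, 0]), 37.0)
        a2 = truncate_ais(extract_ais(s2, [0, 0, 0], [0, 40_000, 0]), 37.0)
        set1 = {tuple(p) for p in a1.positions}
        set2 = {tuple(p) for p in a2.positions}
        assert set1 == set2


class TestTruncate:
    def test_keeps_nodes_within_cutoff(self, chain_skeleton):
        ais = extract_ais(chain_skeleton, [0, 0, 0], [0, 49_000, 0])
        t = truncate_ais(ais, 37.0)
        assert t.total_length == 37.0
        assert len(t) == 38

    def test_cutoff_above_length_is_identity(self, chain_skeleton):
        ais = extract_ais(chain_skeleton, [0, 0, 0], [0, 40_000, 0])
        t = truncate_ais(ais, 100.0)
        assert len(t) == len(ais)

    def test_synapse_depth_filter(self, chain_skeleton):
        ais = extract_ais(chain_skeleton, [0, 0, 0], [0, 49_000, 0])
        t = truncate_ais(ais, 37.0)
        depths = np.array([5.0, 20.0, 36.0, 40.0])
        kept = depths[depths <= t.total_length]
        assert list(kept) == [5.0, 20.0, 36.0]

    def test_nonpositive_cutoff_rejected(self, chain_skeleton):
        ais = extract_ais(chain_skeleton, [0, 0, 0], [0, 40_000, 0])
        with pytest.raises(ValueError):
            truncate_ais(ais, 0.0)


class TestMeanRadius:
    def test_constant_radius(self, chain_skeleton):
        ais = extract_ais(chain_skeleton, [0, 0, 0], [0, 49_000, 0])
        assert mean_radius(ais) == pytest.approx(0.5)

    def test_radius_ramp_hand_computed(self):
        """r(s) = s/10 um on 1-um-spaced nodes, window [5, 38] inclusive."""
        n = 50
        pos = np.zeros((n, 3))
        pos[:, 1] = np.arange(n) * 1000.0
        radii_um = np.arange(n) / 10.0
        skel = SkeletonGraph(
            positions=pos, radii=radii_um * 1000.0,
            edges=np.column_stack([np.arange(n - 1), np.arange(1, n)]),
        )
        ais = extract_ais(skel, [0, 0, 0], [0, 49_000, 0])
        expected = np.mean([s / 10.0 for s in range(5, 39)])
        assert mean_radius(ais) == pytest.approx(expected)

    def test_single_node_in_window(self):
        pos = np.array([[0, 0, 0], [0, 6000.0, 0], [0, 50_000.0, 0]])
        skel = SkeletonGraph(
            positions=pos, radii=np.array([200.0, 1000.0, 200.0]),
            edges=np.array([[0, 1], [1, 2]]),
        )
        ais = extract_ais(skel, [0, 0, 0], [0, 50_000, 0])
        assert mean_radius(ais) == pytest.approx(1.0)

    def test_empty_window_rejected(self, chain_skeleton):
        ais = extract_ais(chain_skeleton, [0, 0, 0], [0, 3000, 0])
        with pytest.raises(ValueError):
            mean_radius(ais, window=(5.0, 38.0))


class TestAlignDepthAxis:
    def _ais_with_direction(self, vec, cell_id=0):
        from chandelier.ais import AISDomain

        vec = np.asarray(vec, float)
        pos = np.array([[0.0, 0, 0], vec * 10_000])
        return AISDomain(
            cell_id=cell_id, positions=pos, radii=np.array([500.0, 500.0]),
            arclength=np.array([0.0, 10.0]), top=pos[0], bottom=pos[1],
        )

    def test_already_aligned_is_identity(self):
        ais = [self._ais_with_direction([0, -1, 0])]
        rot = align_depth_axis(ais)
        assert np.allclose(rot.as_matrix(), np.eye(3), atol=1e-9)

    def test_30_degree_tilt_in_xy_plane(self):
        c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
        tilted = [self._ais_with_direction([s, -c, 0.0])]
        rot = align_depth_axis(tilted)
        v = rot.apply([s, -c, 0.0])
        assert np.allclose(v, [0, -1, 0], atol=1e-9)

    def test_random_directions_mean_maps_onto_axis(self):
        rng = np.random.default_rng(7)
        vecs = rng.normal(size=(30, 3))
        vecs[:, 1] = -np.abs(vecs[:, 1]) - 1  # pointing generally down
        ais = [self._ais_with_direction(v, i) for i, v in enumerate(vecs)]
        rot = align_depth_axis(ais)
        unit = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        m = rot.apply(unit.mean(axis=0))
        m /= np.linalg.norm(m)
        assert abs(m[0]) < 1e-9 and abs(m[2]) < 1e-9 and m[1] < 0


class TestSynapseCoordinates:
    def _vertical_ais(self, n=40):
        from chandelier.ais import AISDomain

        pos = np.zeros((n, 3))
        pos[:, 1] = np.arange(n) * 1000.0
        return AISDomain(
            cell_id=0, positions=pos, radii=np.full(n, 500.0),
            arclength=np.arange(n, dtype=float), top=pos[0], bottom=pos[-1],
        )

    def test_plus_x_offset_has_zero_orientation(self):
        ais = self._vertical_ais()
        coords = synapse_coordinates(ais, [[500.0, 10_000.0, 0.0]])
        assert coords[0].depth == pytest.approx(10.0)
        assert coords[0].orientation == pytest.approx(0.0)
        assert not coords[0].degenerate

    def test_on_axis_synapse_flagged_degenerate(self):
        ais = self._vertical_ais()
        coords = synapse_coordinates(ais, [[0.0, 10_000.0, 0.0]])
        assert coords[0].degenerate
        assert coords[0].orientation == 0.0

    def test_helical_placement_recovers_known_angles(self):
        """Synapses on a helix around a straight AIS: angles are analytic."""
        ais = self._vertical_ais()
        angles = np.linspace(-np.pi, np.pi, 17, endpoint=False)
        depths_nm = np.linspace(2000, 35_000, 17)
        pts = np.column_stack(
            [800 * np.cos(angles), depths_nm, 800 * np.sin(angles)]
        )
        coords = synapse_coordinates(ais, pts)
        got = np.array([c.orientation for c in coords])
        assert np.allclose(got, angles, atol=1e-6)

    def test_far_synapse_raises_with_offender_list(self):
        ais = self._vertical_ais()
        with pytest.raises(ValueError, match="99"):
            synapse_coordinates(
                ais, [[50_000.0, 0.0, 0.0]], synapse_ids=[99]
            )

    def test_depth_invariant_under_rigid_transform(self):
        """Rigid motion of skeleton + synapses leaves depths unchanged."""
        from scipy.spatial.transform import Rotation
        from chandelier.ais import AISDomain

        ais = self._vertical_ais()
        pts = np.array([[500.0, 7000.0, 0.0], [-300, 22_000, 400.0]])
        before = [c.depth for c in synapse_coordinates(ais, pts)]
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 0.7])
        shift = np.array([1e5, -2e5, 3e4])
        pos2 = rot.apply(ais.positions) + shift
        ais2 = AISDomain(
            cell_id=0, positions=pos2, radii=ais.radii,
            arclength=ais.arclength, top=pos2[0], bottom=pos2[-1],
        )
        after = [
            c.depth
            for c in synapse_coordinates(ais2, rot.apply(pts) + shift)
        ]
        assert np.allclose(before, after)
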