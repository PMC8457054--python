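"""Skeleton-to-graph conversion and the three cleaning procedures."""

import numpy as np
import pytest

from netskel.graphify import (
    CleaningParams,
    Link,
    NetworkGraph,
    Node,
    classify_voxels,
    clean_graph,
    collect_close_nodes,
    extract_graph,
    graph_to_skeleton,
    merge_canal_nodes,
    prune_side_chains,
)
from netskel.skeletonize import Skeleton, thin_volume
from netskel.volume_io import BinaryVolume, VoxelGeometry

GEOM = VoxelGeometry(1.0, 1.0, 1.0, "sigma")


def _skel(data):
    return Skeleton(data=data, geometry=GEOM)


def _line(n=11):
    v = np.zeros((3, 3, n), bool)
    v[1, 1, :] = True
    return v


def _diamond_ring(r=5):
    """Closed 26-cycle of 4r voxels (diagonal diamond); every voxel has 2 neighbors."""
    v = np.zeros((3, 2 * r + 1, 2 * r + 1), bool)
    c = r
    for k in range(r):
        v[1, c - k, c - (r - k)] = True  # NW arc
        v[1, c - (r - k), c + k] = True  # NE
        v[1, c + k, c + (r - k)] = True  # SE
        v[1, c + (r - k), c - k] = True  # SW
    return v


def _graph_from(nodes, links):
    """Hand-built graph on a 100^3-sigma box for cleaning-rule tests."""
    g = NetworkGraph(
        nodes={n.id: n for n in nodes},
        links={l.id: l for l in links},
        geometry=GEOM,
        box=((0, 0, 0), (100, 100, 100)),
        sigma=1.0,
        source_shape=(100, 100, 100),
    )
    return g


def _node(nid, z, y, x, kind="branching"):
    return Node(id=nid, kind=kind, voxels=[(z, y, x)],
                position=np.array([z + 0.5, y + 0.5, x + 0.5]))


def _link(lid, u, v, length, path=None):
    return Link(id=lid, u=u, v=v, path=path or [], length=length)


class TestClassifyVoxels:
    def test_line_voxel_roles(self):
        labels = classify_voxels(_skel(_line(5)))
        assert labels[1, 1, 0] == 1  # terminus: D3 count 2 -> end
        assert labels[1, 1, 2] == 2  # interior: D3 count 3 -> link

    def test_y_junction_center_is_branch(self):
        v = np.zeros((3, 7, 7), bool)
        v[1, 3, 0:4] = True  # west arm into center (3,3)
        v[1, 0:3, 3] = True  # north arm
        for k in range(1, 4):
            v[1, 3 + k, 3 + k] = True  # diagonal arm
        labels = classify_voxels(_skel(v))
        assert labels[1, 3, 3] == 3  # D3 count 4 -> branching

    def test_isolated_voxel_labeled_end(self):
        v = np.zeros((3, 3, 3), bool)
        v[1, 1, 1] = True
        assert classify_voxels(_skel(v))[1, 1, 1] == 1


class TestExtractGraph:
    def test_straight_line(self):
        g = extract_graph(_skel(_line(11)))
        assert g.n_nodes == 2 and g.n_links == 1
        link = next(iter(g.links.values()))
        assert link.length == pytest.approx(10.0)
        assert len(link.path) == 11

    def test_symmetric_y(self):
        v = np.zeros((3, 13, 13), bool)
        v[1, 6, 0:7] = True
        v[1, 0:6, 6] = True
        for k in range(1, 7):
            v[1, 6 + k, 6 + k] = True
        g = extract_graph(_skel(v))
        kinds = sorted(n.kind for n in g.nodes.values())
        assert g.n_nodes == 4 and g.n_links == 3
        assert kinds == ["branching", "end", "end", "end"]

    def test_closed_ring_gets_cycle_anchor(self):
        v = _diamond_ring(5)  # 20 voxels
        g = extract_graph(_skel(v))
        assert g.n_nodes == 1 and g.n_links == 1
        node = next(iter(g.nodes.values()))
        assert node.kind == "cycle-anchor"
        link = next(iter(g.links.values()))
        assert link.u == link.v
        assert len(link.path) == 21  # 20 steps, closed
        assert link.length == pytest.approx(20 * np.sqrt(2))

    def test_anisotropic_step_lengths(self):
        geom = VoxelGeometry(0.1, 0.1, 0.3, "um")
        v = np.zeros((5, 3, 3), bool)
        v[:, 1, 1] = True  # line along z
        g = extract_graph(Skeleton(data=v, geometry=geom))
        assert next(iter(g.links.values())).length == pytest.approx(4 * 0.3)

    def test_round_trip_stability(self):
        vol = np.zeros((5, 9, 9), bool)
        vol[2, 4, :] = True
        vol[2, :, 4] = True
        g1 = extract_graph(_skel(vol))
        sk2 = graph_to_skeleton(g1)
        assert np.array_equal(sk2.data, vol)
        g2 = extract_graph(sk2)
        assert g2.n_nodes == g1.n_nodes and g2.n_links == g1.n_links
        l1 = sorted(l.length for l in g1.links.values())
        l2 = sorted(l.length for l in g2.links.values())
        assert np.allclose(l1, l2, atol=1e-9)


class TestPruneSideChains:
    def test_short_arm_pruned(self):
        nodes = [_node(0, 10, 10, 10), _node(1, 10, 10, 20, "end"),
                 _node(2, 10, 20, 10, "end"), _node(3, 10, 11, 10, "end")]
        links = [_link(0, 0, 1, 5.0), _link(1, 0, 2, 5.0), _link(2, 0, 3, 1.0)]
        g = prune_side_chains(_graph_from(nodes, links), 1.5)
        assert g.n_nodes == 3 and g.n_links == 2

    def test_boundary_length_retained(self):
        # strict '<': a side chain of exactly the threshold length stays
        nodes = [_node(0, 10, 10, 10), _node(1, 10, 10, 20, "end"),
                 _node(2, 10, 20, 10, "end"), _node(3, 10, 12, 10, "end")]
        links = [_link(0, 0, 1, 5.0), _link(1, 0, 2, 5.0), _link(2, 0, 3, 1.5)]
        g = prune_side_chains(_graph_from(nodes, links), 1.5)
        assert g.n_links == 3

    def test_isolated_short_segment_vanishes(self):
        nodes = [_node(0, 5, 5, 5, "end"), _node(1, 5, 5, 6, "end")]
        links = [_link(0, 0, 1, 1.0)]
        g = prune_side_chains(_graph_from(nodes, links), 1.5)
        assert g.n_nodes == 0 and g.n_links == 0

    def test_cascade_within_one_call(self):
        # pruning the tip exposes another short terminal link
        nodes = [_node(0, 1, 1, 1), _node(1, 1, 1, 5), _node(2, 1, 1, 9, "end"),
                 _node(3, 1, 9, 1, "end"), _node(4, 9, 1, 1, "end")]
        links = [_link(0, 0, 1, 1.0), _link(1, 1, 2, 1.0),
                 _link(2, 0, 3, 9.0), _link(3, 0, 4, 9.0)]
        g = prune_side_chains(_graph_from(nodes, links), 1.5)
        # link 1 is terminal & short -> gone with node 2; then link 0 becomes
        # terminal & short -> gone with node 1
        assert g.n_links == 2 and g.n_nodes == 3


class TestMergeCanalNodes:
    def test_two_links_concatenate(self):
        nodes = [_node(0, 1, 1, 1, "end"), _node(1, 1, 1, 10), _node(2, 1, 1, 20, "end")]
        links = [
            _link(0, 0, 1, 3.0, path=[(1, 1, 1), (1, 1, 10)]),
            _link(1, 1, 2, 4.0, path=[(1, 1, 10), (1, 1, 20)]),
        ]
        g = merge_canal_nodes(_graph_from(nodes, links))
        assert g.n_nodes == 2 and g.n_links == 1
        assert next(iter(g.links.values())).length == pytest.approx(7.0)

    def test_chain_of_five_canal_nodes(self):
        nodes = [_node(i, 1, 1, 2 * i, "branching") for i in range(7)]
        nodes[0].kind = nodes[6].kind = "end"
        links = [
            _link(i, i, i + 1, 2.0, path=[(1, 1, 2 * i), (1, 1, 2 * i + 2)])
            for i in range(6)
        ]
        g = merge_canal_nodes(_graph_from(nodes, links))
        assert g.n_nodes == 2 and g.n_links == 1
        assert next(iter(g.links.values())).length == pytest.approx(12.0)

    def test_degree_three_untouched(self):
        nodes = [_node(0, 1, 1, 1), _node(1, 1, 1, 5, "end"),
                 _node(2, 1, 5, 1, "end"), _node(3, 5, 1, 1, "end")]
        links = [_link(0, 0, 1, 4.0), _link(1, 0, 2, 4.0), _link(2, 0, 3, 4.0)]
        g = merge_canal_nodes(_graph_from(nodes, links))
        assert g.n_nodes == 4 and g.n_links == 3

    def test_total_length_exactly_conserved(self):
        nodes = [_node(0, 1, 1, 1, "end"), _node(1, 1, 1, 7), _node(2, 1, 7, 7),
                 _node(3, 1, 7, 15, "end")]
        links = [
            _link(0, 0, 1, 6.0, path=[(1, 1, 1), (1, 1, 7)]),
            _link(1, 1, 2, 6.0, path=[(1, 1, 7), (1, 7, 7)]),
            _link(2, 2, 3, 8.0, path=[(1, 7, 7), (1, 7, 15)]),
        ]
        g0 = _graph_from(nodes, links)
        g = merge_canal_nodes(g0)
        assert g.total_length() == pytest.approx(g0.total_length(), abs=1e-12)


class TestCollectCloseNodes:
    def test_two_close_nodes_merge(self):
        nodes = [_node(0, 10, 10, 10), _node(1, 10, 10, 10 + 0), _node(2, 10, 10, 30)]
        nodes[1] = _node(1, 10, 10, 10, "branching")
        nodes[1].position = nodes[0].position + np.array([0, 0, 0.5])
        links = [_link(0, 0, 2, 20.0), _link(1, 1, 2, 20.0)]
        g = collect_close_nodes(_graph_from(nodes, links), 0.9)
        assert g.n_nodes == 2

    def test_transitive_closure(self):
        # chain of 3 nodes at 0.8-sigma gaps: ends are 1.6 sigma apart but all
        # merge through the middle node
        nodes = [_node(0, 10, 10, 10), _node(1, 10, 10, 10), _node(2, 10, 10, 10),
                 _node(3, 10, 10, 40)]
        nodes[1].position = nodes[0].position + np.array([0, 0, 0.8])
        nodes[2].position = nodes[0].position + np.array([0, 0, 1.6])
        links = [_link(0, 0, 3, 30.0), _link(1, 1, 3, 30.0), _link(2, 2, 3, 30.0)]
        g = collect_close_nodes(_graph_from(nodes, links), 0.9)
        assert g.n_nodes == 2

    def test_distant_nodes_unchanged(self):
        nodes = [_node(0, 10, 10, 10), _node(1, 10, 10, 14)]
        links = [_link(0, 0, 1, 4.0)]
        g = collect_close_nodes(_graph_from(nodes, links), 0.9)
        assert g.n_nodes == 2

    def test_short_intra_cluster_link_absorbed(self):
        nodes = [_node(0, 10, 10, 10), _node(1, 10, 10, 10), _node(2, 10, 10, 30, "end"),
                 _node(3, 10, 30, 10, "end")]
        nodes[1].position = nodes[0].position + np.array([0, 0, 0.5])
        links = [_link(0, 0, 1, 0.5), _link(1, 0, 2, 20.0), _link(2, 1, 3, 20.0)]
        g = collect_close_nodes(_graph_from(nodes, links), 0.9)
        assert g.n_nodes == 3
        assert g.n_links == 2  # the 0.5-sigma intra-cluster link is absorbed


class TestCleanGraph:
    PARAMS = CleaningParams(min_side_chain=1.5, node_collect_dist=0.9)

    def test_clean_y_is_fixed_point(self):
        nodes = [_node(0, 10, 10, 10), _node(1, 10, 10, 20, "end"),
                 _node(2, 10, 20, 10, "end"), _node(3, 20, 10, 10, "end")]
        links = [_link(0, 0, 1, 10.0), _link(1, 0, 2, 10.0), _link(2, 0, 3, 10.0)]
        g = clean_graph(_graph_from(nodes, links), self.PARAMS)
        assert g.n_nodes == 4 and g.n_links == 3

    def test_spur_prune_then_canal_merge_cascade(self):
        # Y with one short spur: prune makes the junction degree 2, which
        # then canal-merges -> a single through-link remains
        nodes = [_node(0, 10, 10, 10), _node(1, 10, 10, 30, "end"),
                 _node(2, 10, 30, 10, "end"), _node(3, 10, 10, 11, "end")]
        links = [
            _link(0, 0, 1, 20.0, path=[(10, 10, 10), (10, 10, 30)]),
            _link(1, 0, 2, 20.0, path=[(10, 10, 10), (10, 30, 10)]),
            _link(2, 0, 3, 1.0, path=[(10, 10, 10), (10, 10, 11)]),
        ]
        g = clean_graph(_graph_from(nodes, links), self.PARAMS)
        assert g.n_nodes == 2 and g.n_links == 1
        assert sorted(n.kind for n in g.nodes.values()) == ["end", "end"]
        assert next(iter(g.links.values())).length == pytest.approx(40.0)

    def test_no_degree_two_nodes_after_cleaning(self):
        rngs = np.random.default_rng(3)
        vol = np.zeros((20, 20, 20), bool)
        vol[5:15, 5:15, 9:12] = rngs.random((10, 10, 3)) < 0.7
        sk = thin_volume(BinaryVolume(vol, GEOM))
        g = clean_graph(extract_graph(sk, sigma=1.0), self.PARAMS)
        deg = g.degrees()
        for nid, node in g.nodes.items():
            if node.kind != "cycle-anchor":
                assert deg[nid] != 2

    def test_cleaning_never_increases_counts(self):
        vol = np.zeros((16, 16, 16), bool)
        vol[8, 2:14, 2:14] = np.random.default_rng(5).random((12, 12)) < 0.6
        sk = thin_volume(BinaryVolume(vol, GEOM))
        g0 = extract_graph(sk, sigma=1.0)
        g = clean_graph(g0, self.PARAMS)
        assert g.n_nodes <= g0.n_nodes
        assert g.n_links <= g0.n_links


class TestGraphToSkeleton:
    def test_pruned_spur_voxels_removed(self):
        v = _line(11)
        v[1, 2, 5] = True  # 1-voxel spur on the line -> short side chain
        g0 = extract_graph(_skel(v), sigma=1.0)
        g = clean_graph(g0, CleaningParams(1.5, 0.0))
        sk = graph_to_skeleton(g)
        diff = v & ~sk.data
        assert diff.sum() >= 1 and diff[1, 2, 5]

    def test_empty_graph(self):
        g = _graph_from([], [])
        sk = graph_to_skeleton(g, shape=(5, 5, 5))
        assert sk.count() == 0

    def test_link_length_at_least_euclidean(self):
        vol = np.zeros((5, 20, 20), bool)
        vol[2, 2:18, 2:18] = np.random.default_rng(9).random((16, 16)) < 0.5
        sk = thin_volume(BinaryVolume(vol, GEOM))
        g = extract_graph(sk, sigma=1.0)
        for l in g.links.values():
            pu = np.asarray(l.path[0], float)
            pv = np.asarray(l.path[-1], float)
            assert l.length >= np.linalg.norm(pu - pv) - 1e-9
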