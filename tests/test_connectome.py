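import numpy as np
import pytest

from micoconn.connectome import (
    Bundle,
    Connectome,
    assign_endpoints,
    build_connectome,
    connection_density,
    edge_weight,
    group_bundles,
    subnetwork_extract,
)
from micoconn.deconvolution import StreamlineWeights
from micoconn.parcellation import NetworkAssignment, Parcellation, merge_atlas
from micoconn.phantom import Streamline, Tractogram


def _weights(x, kept=None):
    x = np.asarray(x, float)
    kept = np.ones_like(x, bool) if kept is None else np.asarray(kept, bool)
    return StreamlineWeights(x=x, residual_norm=0.0, kept_mask=kept)


def _line(p0, p1):
    return Streamline(np.array([p0, p1], dtype=float))


class TestEdgeWeight:
    def test_hand_computed_example(self):
        b = Bundle((1, 2), [0, 1], lengths=[10.0, 20.0], weights=[0.5, 0.3])
        assert edge_weight(b) == pytest.approx(11.0 / 15.0, abs=1e-12)

    def test_equal_weights_give_c_times_count(self, rng):
        for _ in range(100):
            n = rng.integers(1, 12)
            lengths = rng.uniform(1.0, 80.0, size=n)
            c = rng.uniform(0.05, 0.9)
            b = Bundle((1, 2), list(range(n)), lengths, np.full(n, c))
            assert edge_weight(b) == pytest.approx(c * n, rel=1e-12)

    def test_single_streamline_reduces_to_weight(self):
        b = Bundle((3, 7), [0], lengths=[37.0], weights=[0.4])
        assert edge_weight(b) == pytest.approx(0.4, abs=1e-15)

    def test_order_invariance_and_linearity(self, rng):
        lengths = rng.uniform(5, 50, size=6)
        weights = rng.uniform(0.1, 0.7, size=6)
        a = edge_weight(Bundle((1, 2), list(range(6)), lengths, weights))
        perm = rng.permutation(6)
        b = edge_weight(Bundle((1, 2), list(perm), lengths[perm], weights[perm]))
        assert a == pytest.approx(b, rel=1e-12)
        scaled = edge_weight(Bundle((1, 2), list(range(6)), lengths, 3.0 * weights))
        assert scaled == pytest.approx(3.0 * a, rel=1e-12)


class TestAssignEndpoints:
    @pytest.fixture()
    def parc(self):
        labels = np.zeros((6, 6, 6), dtype=int)
        labels[0, 0, 0] = 3
        labels[5, 5, 5] = 5
        return Parcellation(labels, voxel_size=2.0)

    def test_containing_voxel_label(self, parc):
        tg = Tractogram([_line([1, 1, 1], [11, 11, 11])])
        out = assign_endpoints(tg, parc, radius_mm=2.0)
        assert out.endpoint_rois[0] == (3, 5)

    def test_nearest_label_within_radius(self, parc):
        # endpoint just outside ROI 3's voxel, 1 voxel away from its centre
        tg = Tractogram([_line([2.5, 1, 1], [11, 11, 11])])
        out = assign_endpoints(tg, parc, radius_mm=2.0)
        assert out.endpoint_rois[0] == (3, 5)

    def test_far_endpoint_unassigned(self, parc):
        tg = Tractogram([_line([11, 1, 1], [11, 11, 11])])
        out = assign_endpoints(tg, parc, radius_mm=2.0)
        assert out.endpoint_rois[0] is None


class TestBuildConnectome:
    @pytest.fixture()
    def parc(self):
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0, 0, 0] = 1
        labels[3, 3, 3] = 2
        labels[0, 3, 0] = 3
        return Parcellation(labels, voxel_size=2.0)

    def test_iasf_and_nos_weights(self, parc):
        sl = [_line([1, 1, 1], [7, 7, 7]) for _ in range(3)]
        tg = Tractogram(sl, [(1, 2)] * 3)
        w = _weights([0.2, 0.2, 0.2])
        iasf = build_connectome(tg, w, parc, "IASF")
        nos = build_connectome(tg, w, parc, "NOS")
        i, j = 0, 1  # labels 1 and 2
        assert iasf.matrix[i, j] == pytest.approx(0.6, rel=1e-12)
        assert nos.matrix[i, j] == 3.0
        assert iasf.matrix[0, 2] == 0.0  # ROI 3 isolated

    def test_filtered_streamlines_excluded(self, parc):
        tg = Tractogram([_line([1, 1, 1], [7, 7, 7])] * 2, [(1, 2)] * 2)
        w = _weights([0.4, 0.4], kept=[True, False])
        conn = build_connectome(tg, w, parc, "NOS")
        assert conn.matrix[0, 1] == 1.0

    def test_symmetry_and_intra_roi_exclusion(self, parc):
        tg = Tractogram(
            [_line([1, 1, 1], [7, 7, 7]), _line([1, 1, 1], [1.2, 1, 1])],
            [(1, 2), (1, 1)],
        )
        conn = build_connectome(tg, _weights([0.5, 0.5]), parc)
        np.testing.assert_array_equal(conn.matrix, conn.matrix.T)
        assert np.all(np.diag(conn.matrix) == 0)

    def test_invalid_weighting_rejected(self, parc):
        tg = Tractogram([_line([1, 1, 1], [7, 7, 7])], [(1, 2)])
        with pytest.raises(ValueError):
            build_connectome(tg, _weights([0.5]), parc, "FA")


class TestSubnetworkAndDensity:
    @pytest.fixture()
    def conn(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1.0
        m[2, 3] = m[3, 2] = 2.0
        return Connectome(m, labels=np.array([1, 2, 3, 4]))

    @pytest.fixture()
    def assignment(self):
        return NetworkAssignment({1: "A", 2: "A", 3: "B", 4: "B"})

    def test_subnetwork_extraction(self, conn, assignment):
        sub = subnetwork_extract(conn, assignment, "A")
        assert sub.matrix.shape == (2, 2)
        assert sub.matrix[0, 1] == 1.0
        with pytest.raises(ValueError):
            subnetwork_extract(conn, assignment, "C")

    def test_groups_partition_all_nodes(self, conn, assignment):
        seen = set()
        for g in assignment.groups():
            seen |= set(subnetwork_extract(conn, assignment, g).labels.tolist())
        assert seen == set(conn.labels.tolist())

    def test_whole_graph_extraction_identity(self, conn):
        allg = NetworkAssignment({r: "all" for r in [1, 2, 3, 4]})
        sub = subnetwork_extract(conn, allg, "all")
        np.testing.assert_array_equal(sub.matrix, conn.matrix)

    def test_density_values(self, conn):
        assert connection_density(conn) == pytest.approx(4.0 / 12.0)
        full = Connectome(np.ones((4, 4)) - np.eye(4), np.arange(1, 5))
        assert connection_density(full) == 1.0
        empty = Connectome(np.zeros((4, 4)), np.arange(1, 5))
        assert connection_density(empty) == 0.0
        with pytest.raises(ValueError):
            connection_density(Connectome(np.zeros((1, 1)), np.array([1])))


class TestMergeAtlas:
    @staticmethod
    def _subject(roi_to_net: dict[int, str], shape=(4, 4, 1)):
        """Build masks where each ROI overlaps its named network most."""
        nets = {"A": np.zeros(shape, bool), "B": np.zeros(shape, bool)}
        nets["A"][:2] = True
        nets["B"][2:] = True
        parc = {}
        for k, (roi, net) in enumerate(roi_to_net.items()):
            mask = np.zeros(shape, bool)
            row = (0, 1) if net == "A" else (2, 3)
            mask[row[0] + 0, k % 4, 0] = True
            mask[row[1], k % 4, 0] = True
            parc[roi] = mask
        return parc, nets

    def test_argmax_overlap_assignment(self):
        shape = (4, 4, 1)
        nets = {"A": np.zeros(shape, bool), "B": np.zeros(shape, bool)}
        nets["A"][:2] = True
        nets["B"][2:] = True
        roi = np.zeros(shape, bool)
        roi[0:2, :, 0] = True  # 8 voxels in A
        roi[2, 0, 0] = True  # 1 voxel in B
        out = merge_atlas([{1: roi, 2: roi}], [nets], homolog_map={1: 2, 2: 1})
        assert out.mapping == {1: "A", 2: "A"}

    def test_agreement_threshold_discards(self):
        # modal in 7/10 subjects -> below the 80% agreement bar
        subs, net_list = [], []
        for s in range(10):
            net = "A" if s < 7 else "B"
            parc, nets = self._subject({1: net, 2: net})
            subs.append(parc)
            net_list.append(nets)
        out = merge_atlas(subs, net_list, homolog_map={1: 2, 2: 1},
                          min_agreement=0.8)
        assert out.mapping == {}
        assert set(out.discarded) == {1, 2}
        assert out.agreement[1] == pytest.approx(0.7)

    def test_homolog_disagreement_discards_both(self):
        parc, nets = self._subject({1: "A", 2: "B"})
        out = merge_atlas([parc], [nets], homolog_map={1: 2, 2: 1})
        assert out.mapping == {}
        assert set(out.discarded) == {1, 2}

    def test_retained_when_consistent(self):
        parc, nets = self._subject({1: "A", 2: "A", 3: "B", 4: "B"})
        out = merge_atlas(
            [parc] * 5, [nets] * 5, homolog_map={1: 2, 2: 1, 3: 4, 4: 3}
        )
        assert out.mapping == {1: "A", 2: "A", 3: "B", 4: "B"}
        assert out.discarded == []

    def test_zero_overlap_counts_as_disagreement(self):
        shape = (4, 4, 1)
        nets = {"A": np.zeros(shape, bool)}
        nets["A"][:2] = True
        roi_in = np.zeros(shape, bool)
        roi_in[0, 0, 0] = True
        roi_out = np.zeros(shape, bool)
        roi_out[3, 3, 0] = True  # outside every network
        out = merge_atlas([{1: roi_in, 2: roi_out}], [nets], homolog_map={})
        assert out.mapping == {1: "A"}
        assert out.discarded == [2]

    def test_subject_order_invariance(self):
        pa, na = self._subject({1: "A", 2: "A"})
        pb, nb = self._subject({1: "B", 2: "B"})
        fwd = merge_atlas([pa, pa, pa, pb], [na, na, na, nb],
                          homolog_map={1: 2, 2: 1}, min_agreement=0.7)
        rev = merge_atlas([pb, pa, pa, pa], [nb, na, na, na],
                          homolog_map={1: 2, 2: 1}, min_agreement=0.7)
        assert fwd.mapping == rev.mapping and fwd.discarded == rev.discarded


class TestBundleGrouping:
    def test_unassigned_and_intra_roi_dropped(self):
        tg = Tractogram(
            [_line([0, 0, 0], [1, 1, 1]) for _ in range(3)],
            [(1, 2), None, (3, 3)],
        )
        bundles = group_bundles(tg, _weights([0.5, 0.5, 0.5]))
        assert list(bundles) == [(1, 2)]
        assert bundles[(1, 2)].n_streamlines == 1
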