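"""Exact k-NN search, label probabilities, refusal and calibration."""

import numpy as np
import pytest

from ecknn.ec_labels import parse_ec, protein_label_set
from ecknn.model import ProjectedVector
from ecknn.retrieval import (
    LookupIndex,
    NeighborSet,
    Neighbor,
    RetrievalConfig,
    annotate_query,
    build_index,
    calibrate_distance_cutoff,
    label_probabilities,
    load_index,
    query_knn,
    save_index,
    sweep_k,
    write_annotations,
)


def _ls(*codes):
    return protein_label_set([parse_ec(c) for c in codes])


def _unit(rng, dim):
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def _make_index(vectors, labels):
    pvs = [ProjectedVector(f"id{i}", v) for i, v in enumerate(vectors)]
    return build_index(pvs, {f"id{i}": l for i, l in enumerate(labels)})


@pytest.fixture
def rng():
    return np.random.default_rng(7)


class TestBuildIndex:
    def test_single_entry(self):
        idx = _make_index([np.eye(4)[0]], [_ls("1.1.1.1")])
        assert len(idx) == 1

    def test_append_extends_search(self, rng):
        idx = _make_index([_unit(rng, 8) for _ in range(10)],
                          [_ls("1.1.1.1")] * 10)
        for i in range(5):
            idx.add(ProjectedVector(f"new{i}", _unit(rng, 8)), _ls("2.2.2.2"))
        q = ProjectedVector("q", _unit(rng, 8))
        ns = query_knn(idx, q, RetrievalConfig(k=50))
        assert len(ns.neighbors) == 15 and ns.truncated

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError):
            _make_index([np.array([0.5, 0.5])], [_ls("1.1.1.1")])

    def test_duplicate_id_rejected(self, rng):
        idx = LookupIndex()
        idx.add(ProjectedVector("x", np.eye(3)[0]), _ls("1.1.1.1"))
        with pytest.raises(ValueError, match="duplicate"):
            idx.add(ProjectedVector("x", np.eye(3)[1]), _ls("1.1.1.1"))


class TestQueryKnn:
    def test_exact_match_first(self, rng):
        vs = [_unit(rng, 16) for _ in range(20)]
        idx = _make_index(vs, [_ls("1.1.1.1")] * 20)
        ns = query_knn(idx, ProjectedVector("q", vs[7]),
                       RetrievalConfig(k=3))
        assert ns.neighbors[0].id == "id7"
        assert ns.neighbors[0].distance == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 5, 20])
    def test_matches_full_sort_oracle(self, rng, k):
        vs = [_unit(rng, 32) for _ in range(200)]
        idx = _make_index(vs, [_ls("1.1.1.1")] * 200)
        q = ProjectedVector("q", _unit(rng, 32))
        ns = query_knn(idx, q, RetrievalConfig(k=k))
        dists = np.array([1.0 - v @ q.values for v in vs])
        oracle = np.argsort(dists, kind="stable")[:k]
        assert [n.id for n in ns.neighbors] == [f"id{i}" for i in oracle]
        for n, oi in zip(ns.neighbors, oracle):
            assert n.distance == pytest.approx(max(dists[oi], 0.0), abs=1e-12)

    def test_truncation_flag(self, rng):
        idx = _make_index([_unit(rng, 4) for _ in range(3)],
                          [_ls("1.1.1.1")] * 3)
        ns = query_knn(idx, ProjectedVector("q", _unit(rng, 4)),
                       RetrievalConfig(k=5))
        assert len(ns.neighbors) == 3 and ns.truncated

    def test_exclude_self_matches_id_not_vector(self, rng):
        v = _unit(rng, 8)
        pvs = [ProjectedVector("a", v), ProjectedVector("b", v)]
        idx = build_index(pvs, {"a": _ls("1.1.1.1"), "b": _ls("1.1.1.1")})
        ns = query_knn(idx, ProjectedVector("a", v),
                       RetrievalConfig(k=2, exclude_self=True))
        assert [n.id for n in ns.neighbors] == ["b"]

    def test_equidistant_ties_keep_insertion_order(self):
        e = np.eye(3)
        idx = _make_index([e[1], e[2], e[0]], [_ls("1.1.1.1")] * 3)
        ns = query_knn(idx, ProjectedVector("q", e[0]),
                       RetrievalConfig(k=3))
        assert [n.id for n in ns.neighbors] == ["id2", "id0", "id1"]


class TestLabelProbabilities:
    def test_single_neighbor_probability_one(self, rng):
        idx = _make_index([np.eye(4)[0]], [_ls("2.3.2.27")])
        for T in (1e-3, 0.1, 1.0):
            ns = NeighborSet("q", (Neighbor("id0", 0.37),))
            probs = label_probabilities(ns, idx, T)
            assert probs["2.3.2.27"] == 1.0

    def test_equidistant_split(self):
        idx = _make_index(
            [np.eye(4)[0], np.eye(4)[1]], [_ls("1.1.1.1"), _ls("2.2.2.2")]
        )
        ns = NeighborSet("q", (Neighbor("id0", 0.3), Neighbor("id1", 0.3)))
        probs = label_probabilities(ns, idx, 1e-3)
        assert probs["1.1.1.1"] == pytest.approx(0.5)
        assert probs["2.2.2.2"] == pytest.approx(0.5)

    def test_far_label_closed_form(self):
        idx = _make_index(
            [np.eye(4)[0], np.eye(4)[1]], [_ls("1.1.1.1"), _ls("2.2.2.2")]
        )
        ns = NeighborSet("q", (Neighbor("id0", 0.1), Neighbor("id1", 0.2)))
        probs = label_probabilities(ns, idx, 1e-3)
        expected = 1.0 / (1.0 + np.exp(100.0))
        assert float(probs["2.2.2.2"]) == pytest.approx(expected, rel=1e-6)
        assert probs["2.2.2.2"] > 0.0

    def test_stabilized_at_extreme_distances(self):
        """Distances spanning [0, 2] at T=1e-3: finite, in (0, 1]."""
        idx = _make_index(
            [np.eye(4)[0], np.eye(4)[1], np.eye(4)[2]],
            [_ls("1.1.1.1"), _ls("2.2.2.2"), _ls("1.1.1.1")],
        )
        ns = NeighborSet("q", (Neighbor("id0", 0.0), Neighbor("id1", 2.0),
                               Neighbor("id2", 1.0)))
        probs = label_probabilities(ns, idx, 1e-3)
        for p in probs.values():
            assert np.isfinite(float(p))
            assert 0.0 < p <= 1.0

    def test_monotone_in_supporting_neighbors(self):
        labels = [_ls("1.1.1.1"), _ls("1.1.1.1"), _ls("2.2.2.2")]
        idx = _make_index([np.eye(4)[i] for i in range(3)], labels)
        base = NeighborSet("q", (Neighbor("id0", 0.1), Neighbor("id2", 0.1)))
        more = NeighborSet("q", base.neighbors + (Neighbor("id1", 0.4),))
        T = 0.1  # moderate temperature so the added weight is resolvable
        p_base = label_probabilities(base, idx, T)["1.1.1.1"]
        p_more = label_probabilities(more, idx, T)["1.1.1.1"]
        assert p_more > p_base
        # adding a non-carrier decreases the probability
        dil = NeighborSet("q", base.neighbors + (Neighbor("id2b", 0.4),))
        idx.add(ProjectedVector("id2b", np.eye(4)[3]), _ls("3.3.3.3"))
        p_dil = label_probabilities(dil, idx, T)["1.1.1.1"]
        assert p_dil < p_base

    def test_empty_neighbor_set_rejected(self, rng):
        idx = _make_index([np.eye(4)[0]], [_ls("1.1.1.1")])
        with pytest.raises(ValueError):
            label_probabilities(NeighborSet("q", ()), idx, 1e-3)


class TestAnnotateQuery:
    def test_refusal_beyond_cutoff(self, rng):
        v = _unit(rng, 8)
        far = _unit(rng, 8)
        far -= (far @ v) * v
        far /= np.linalg.norm(far)  # orthogonal: distance 1.0
        idx = _make_index([v], [_ls("2.3.2.27")])
        cfg = RetrievalConfig(k=1, distance_cutoff=0.38)
        assert annotate_query(idx, ProjectedVector("q", far), cfg) == []

    def test_single_neighbor_annotation(self, rng):
        v = _unit(rng, 8)
        idx = _make_index([v], [_ls("2.3.2.27")])
        cfg = RetrievalConfig(k=1, probability_threshold=0.5)
        anns = annotate_query(idx, ProjectedVector("q", v), cfg)
        assert len(anns) == 1
        assert str(anns[0].ec) == "2.3.2.27"
        assert anns[0].probability == pytest.approx(1.0)
        assert anns[0].support_distance == pytest.approx(0.0, abs=1e-12)

    def test_no_confident_label_yields_empty(self):
        e = np.eye(8)
        q = e[0] * 0.0
        q = (e[0] + e[1] + e[2]) / np.sqrt(3)
        labels = [_ls("1.1.1.1"), _ls("2.2.2.2"), _ls("3.3.3.3")]
        idx = _make_index([e[0], e[1], e[2]], labels)
        cfg = RetrievalConfig(k=3, probability_threshold=0.5, temperature=1.0)
        # equidistant neighbours with distinct labels: each p ~= 1/3 < 0.5
        anns = annotate_query(idx, ProjectedVector("q", q), cfg)
        assert anns == []

    def test_refusal_safety_property(self, rng):
        vs = [_unit(rng, 16) for _ in range(30)]
        idx = _make_index(vs, [_ls("1.1.1.1")] * 30)
        cutoff = 0.2
        cfg = RetrievalConfig(k=5, distance_cutoff=cutoff,
                              probability_threshold=0.0)
        for _ in range(50):
            q = ProjectedVector("q", _unit(rng, 16))
            nearest = query_knn(idx, q, RetrievalConfig(k=1)).neighbors[0]
            anns = annotate_query(idx, q, cfg)
            if nearest.distance > cutoff:
                assert anns == []


class TestCalibration:
    def test_interpolated_example(self):
        assert calibrate_distance_cutoff([0.1, 0.2, 0.3, 0.4], 75) == \
            pytest.approx(0.325)

    def test_constant_distances(self):
        for p in (0, 25, 75, 100):
            assert calibrate_distance_cutoff([0.38] * 7, p) == \
                pytest.approx(0.38)

    def test_matches_sort_interpolation_oracle(self):
        rng = np.random.default_rng(11)
        d = rng.gamma(2.0, 0.1, size=1000)
        got = calibrate_distance_cutoff(d, 75)
        s = np.sort(d)
        rank = 0.75 * (len(s) - 1)
        lo, hi = int(np.floor(rank)), int(np.ceil(rank))
        expect = s[lo] + (rank - lo) * (s[hi] - s[lo])
        assert got == pytest.approx(expect, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            calibrate_distance_cutoff([])


class TestSweepK:
    def test_self_lookup_k1_is_perfect(self, rng):
        vs = [_unit(rng, 8) for _ in range(12)]
        codes = [f"{1 + i % 3}.1.1.1" for i in range(12)]
        pvs = [ProjectedVector(f"id{i}", v) for i, v in enumerate(vs)]
        idx = build_index(pvs, {f"id{i}": _ls(c)
                                for i, c in enumerate(codes)})
        truth = {f"id{i}": [codes[i]] for i in range(12)}
        table = sweep_k(idx, pvs, truth, [1])
        assert table.loc[1, "sample_f1"] == pytest.approx(1.0)

    def test_row_per_k(self, rng):
        vs = [_unit(rng, 8) for _ in range(10)]
        pvs = [ProjectedVector(f"id{i}", v) for i, v in enumerate(vs)]
        idx = build_index(pvs, {f"id{i}": _ls("1.1.1.1") for i in range(10)})
        truth = {f"id{i}": ["1.1.1.1"] for i in range(10)}
        table = sweep_k(idx, pvs, truth, [1, 5, 20])
        assert list(table.index) == [1, 5, 20]


def test_index_round_trip(tmp_path, rng):
    vs = [_unit(rng, 8) for _ in range(6)]
    labels = [_ls("2.3.2.27", "1.1.1.1")] * 3 + [_ls("3.4.-.-")] * 3
    idx = _make_index(vs, labels)
    path = tmp_path / "index.npz"
    save_index(idx, path)
    back = load_index(path)
    assert back.ids == idx.ids
    assert np.array_equal(back.vectors, idx.vectors)
    assert back.depth4_labels_of("id0") == ("1.1.1.1", "2.3.2.27")
    assert back.depth4_labels_of("id5") == ()


def test_write_annotations_format(tmp_path, rng):
    from ecknn.retrieval import Annotation

    anns = {
        "q2": [],
        "q1": [Annotation("q1", parse_ec("2.3.2.27"), 0.875, 0.01)],
    }
    path = tmp_path / "ann.tsv"
    write_annotations(anns, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "query_id\tec_number\tprobability\tsupport_distance"
    assert lines[1] == "q1\t2.3.2.27\t0.875000\t0.010000"
    assert lines[2] == "q2\t-\t\t"
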