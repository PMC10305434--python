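import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import identity_oracle, mcl_reference, sw_oracle
from phagehost.clustering import (
    build_graph,
    candidate_pairs,
    dedup_proteins,
    expand_clusters,
    filter_clusters,
    global_identity,
    mcl,
    norm_score,
    self_score,
    smith_waterman,
    sw_score,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_peptides(n, max_len, seed):
    rng = np.random.default_rng(seed)
    return [
        "".join(rng.choice(list(AA), size=rng.integers(1, max_len + 1)))
        for _ in range(n)
    ]


class TestSmithWaterman:
    def test_identical_short_peptide_score(self):
        # BLOSUM62 diagonal: M=5, K=5, P=7, G=6
        score, spans = smith_waterman("MKPG", "MKPG")
        assert score == 23.0
        assert spans == (((0, 4),), ((0, 4),))

    def test_empty_sequence_scores_zero(self):
        assert smith_waterman("", "MK") == (0.0, ())

    def test_all_negative_pairs_score_zero(self):
        assert smith_waterman("MK", "PG") == (0.0, ())

    def test_agrees_with_bruteforce_oracle(self):
        peptides = _random_peptides(80, 40, seed=5)
        rng = np.random.default_rng(6)
        for _ in range(40):
            a, b = rng.choice(peptides, size=2)
            assert sw_score(a, b) == sw_oracle(a, b)

    def test_symmetry_and_self_normalization(self):
        for pep in _random_peptides(30, 30, seed=9):
            raw = sw_score(pep, pep)
            assert raw == self_score(pep)
            assert norm_score(raw, self_score(pep), self_score(pep)) == 1.0
        a, b = _random_peptides(2, 40, seed=10)
        assert sw_score(a, b) == sw_score(b, a)


class TestDedup:
    def test_identical_proteins_collapse(self):
        reps, dup = dedup_proteins({"a": "MKLVNDEQ", "b": "MKLVNDEQ"})
        assert len(reps) == 1
        assert dup == {"b": "a"}

    def test_threshold_one_keeps_single_mismatch_apart(self):
        reps, dup = dedup_proteins(
            {"a": "MKLVNDEQ", "b": "MKLVNDEW"}, identity_threshold=1.0
        )
        assert len(reps) == 2 and dup == {}

    def test_identity_below_threshold_kept_separate(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list(AA), size=100))
        b = list(a)
        for pos in rng.choice(100, size=7, replace=False):
            b[pos] = AA[(AA.index(b[pos]) + 1) % len(AA)]
        b = "".join(b)
        assert identity_oracle(a, b) == pytest.approx(0.93)
        assert global_identity(a, b) == pytest.approx(0.93)
        reps, _ = dedup_proteins({"a": a, "b": b}, identity_threshold=0.95)
        assert len(reps) == 2

    def test_greedy_is_length_ordered(self):
        # near-identical pair (40/41 columns match = 0.976): the longest
        # protein becomes the representative
        base = "MKLV" * 10
        reps, dup = dedup_proteins({"short": base, "long": base + "A"})
        assert "long" in reps and dup == {"short": "long"}


class TestCandidatePairs:
    def test_identical_sequences_reported(self):
        seq = "".join(AA) * 3
        assert candidate_pairs({"a": seq, "b": seq}) == {("a", "b")}

    def test_disjoint_alphabets_not_reported(self):
        assert candidate_pairs({"a": "A" * 30, "b": "W" * 30}) == set()

    def test_boundary_exactly_min_shared_kmers(self):
        a, b = "AAAAC", "WAAAACW"
        kmers = lambda s: {s[i : i + 4] for i in range(len(s) - 3)}
        assert len(kmers(a) & kmers(b)) == 2  # brute-force oracle
        assert candidate_pairs({"a": a, "b": b}, k=4, min_shared=2) == {("a", "b")}
        assert candidate_pairs({"a": a, "b": b}, k=4, min_shared=3) == set()


class TestBuildGraph:
    def test_identical_pair_full_weight_edge(self):
        g = build_graph({("a", "b")}, {"a": "MKPGMKPG", "b": "MKPGMKPG"})
        assert g["a"]["b"]["weight"] == 1.0

    def test_threshold_is_inclusive(self):
        prot = {"a": "MKPGWNDE", "b": "MKPGAAAA"}
        raw = sw_score(prot["a"], prot["b"])
        w = norm_score(raw, self_score(prot["a"]), self_score(prot["b"]))
        assert 0 < w < 1
        with_edge = build_graph({("a", "b")}, prot, norm_threshold=w)
        without = build_graph({("a", "b")}, prot, norm_threshold=w + 1e-9)
        assert with_edge.has_edge("a", "b")
        assert not without.has_edge("a", "b")

    def test_singleton_gets_self_loop(self):
        g = build_graph(set(), {"a": "MKPG"})
        assert g.has_edge("a", "a") and g["a"]["a"]["weight"] == 1.0


def _clique_graph(groups, bridges=()):
    g = nx.Graph()
    for group in groups:
        for n in group:
            g.add_edge(n, n, weight=1.0)
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                g.add_edge(a, b, weight=1.0)
    for a, b, w in bridges:
        g.add_edge(a, b, weight=w)
    return g


class TestMCL:
    def test_two_disjoint_triangles(self):
        g = _clique_graph([["a", "b", "c"], ["x", "y", "z"]])
        assert mcl(g) == [{"a", "b", "c"}, {"x", "y", "z"}]

    def test_single_node(self):
        g = nx.Graph()
        g.add_edge("a", "a", weight=1.0)
        assert mcl(g) == [{"a"}]

    def test_bridged_cliques_split_at_bridge(self):
        left = ["a", "b", "c", "d"]
        right = ["e", "f", "g", "h"]
        g = _clique_graph([left, right], bridges=[("d", "e", 0.1)])
        assert mcl(g, inflation=2.0) == [set(left), set(right)]

    def test_agrees_with_reference_implementation(self):
        left = ["a", "b", "c", "d"]
        right = ["e", "f", "g", "h"]
        g = _clique_graph([left, right], bridges=[("d", "e", 0.1)])
        nodes = sorted(g.nodes())
        adj = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        ref = mcl_reference(adj, inflation=2.0)
        ref_named = sorted(({nodes[i] for i in comp} for comp in ref), key=min)
        assert mcl(g, inflation=2.0) == ref_named

    def test_missing_self_loop_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        with pytest.raises(ValueError, match="self-loop"):
            mcl(g)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50)
    def test_partition_and_component_preservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        g = nx.Graph()
        for i in range(n):
            g.add_edge(i, i, weight=1.0)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    g.add_edge(i, j, weight=float(rng.uniform(0.1, 1.0)))
        partition, flow, nodes = mcl(g, return_flow=True)
        # partition of all nodes
        seen = [x for s in partition for x in s]
        assert sorted(seen) == sorted(g.nodes())
        assert len(seen) == len(set(seen))
        # converged flow matrix is column-stochastic
        sums = np.asarray(flow.sum(axis=0)).ravel()
        assert np.abs(sums - 1.0).max() < 1e-9
        # clusters never straddle connected components of the input graph
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_of[node] = ci
        for cluster in partition:
            assert len({comp_of[x] for x in cluster}) == 1


class TestExpandAndFilter:
    def test_duplicates_inherit_cluster(self):
        part = [{"r1"}, {"r2", "r3"}]
        out = expand_clusters(part, {"d1": "r2", "d2": "r2"})
        assert out == [{"r1"}, {"r2", "r3", "d1", "d2"}]

    def test_no_duplicates_is_identity(self):
        part = [{"r1"}, {"r2"}]
        assert expand_clusters(part, {}) == part

    def test_orphan_duplicate_rejected(self):
        with pytest.raises(ValueError, match="unclustered representative"):
            expand_clusters([{"r1"}], {"d1": "zz"})

    def _db(self, clusters, p2p, n_phages, min_prevalence=0.01):
        seqs = {p: "M" + "A" * (3 + len(p)) for members in clusters for p in members}
        return filter_clusters(
            clusters, p2p, n_phages, sequences=seqs, min_prevalence=min_prevalence
        )

    def test_prevalence_boundary(self):
        # 200 phages: a 1-phage cluster (0.005) is removed, a 2-phage
        # cluster (exactly 0.01) is kept — removal is strictly below 1%
        clusters = [{"a1"}, {"b1", "c1"}]
        p2p = {"a1": "pA", "b1": "pB", "c1": "pC"}
        db = self._db(clusters, p2p, 200)
        assert len(db) == 1
        assert db.clusters[0].member_ids == {"b1", "c1"}

    def test_everything_removed_is_an_error(self):
        with pytest.raises(ValueError, match="below prevalence"):
            self._db([{"a1"}], {"a1": "pA"}, 1000)

    def test_reindexed_by_descending_prevalence(self):
        clusters = [{"a1"}, {"b1", "c1", "d1"}]
        p2p = {"a1": "pA", "b1": "pB", "c1": "pC", "d1": "pD"}
        db = self._db(clusters, p2p, 4)
        assert [c.cluster_id for c in db.clusters] == [0, 1]
        assert db.clusters[0].member_ids == {"b1", "c1", "d1"}

    def test_representative_is_longest_member(self):
        clusters = [{"a1", "b1"}]
        seqs = {"a1": "MKPGMKPG", "b1": "MKPG"}
        db = filter_clusters(clusters, {"a1": "pA", "b1": "pB"}, 2, sequences=seqs)
        assert db.clusters[0].representative_id == "a1"

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=25)
    def test_filter_is_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n_phages = 50
        clusters, p2p = [], {}
        for ci in range(8):
            size = int(rng.integers(1, 10))
            members = {f"c{ci}_m{k}" for k in range(size)}
            for m in members:
                p2p[m] = f"p{rng.integers(n_phages)}"
            clusters.append(members)
        kept = {}
        for thr in (0.02, 0.08):
            try:
                db = self._db(clusters, p2p, n_phages, min_prevalence=thr)
                kept[thr] = {frozenset(c.member_ids) for c in db.clusters}
            except ValueError:
                kept[thr] = set()
        assert kept[0.08] <= kept[0.02]
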