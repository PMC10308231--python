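"""OTU clustering, neighbor joining and bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainsort.markers import (
    DistanceMatrix,
    IdentityMatrix,
    MarkerError,
    alignment_identity_matrix,
    bootstrap_supports,
    cluster_otus,
    distances_from_identity,
    identity_matrix,
    nj_tree,
    progressive_align,
)
from strainsort.seqio import MarkerProfile

from conftest import patristic, random_additive_tree, random_seq, tree_splits_from_edges


def ident(labels, pairs, default=90.0):
    n = len(labels)
    v = np.full((n, n), default)
    np.fill_diagonal(v, 100.0)
    idx = {l: i for i, l in enumerate(labels)}
    for (a, b), val in pairs.items():
        v[idx[a], idx[b]] = v[idx[b], idx[a]] = val
    return IdentityMatrix(list(labels), v)


class TestIdentityMatrix:
    def test_identical_profiles_give_100(self):
        p = [MarkerProfile(f"s{i}", "ACGTACGTAC", "GGTTGGTTGG") for i in range(3)]
        m = identity_matrix(p)
        assert np.all(m.values == 100.0)

    def test_mode_selects_marker(self):
        a = MarkerProfile("a", "ACGTACGTAC", "GGGGGGGGGG")
        b = MarkerProfile("b", "ACGTACGTAC", "CCCCCCCCCC")
        assert identity_matrix([a, b], mode="s16_only").pair("a", "b") == 100.0
        assert identity_matrix([a, b], mode="rpod_only").pair("a", "b") < 50.0

    def test_missing_marker_names_strain(self):
        a = MarkerProfile("a", "ACGTACGTAC", "")
        b = MarkerProfile("b", "ACGTACGTAC", "GGTT")
        with pytest.raises(MarkerError, match="'a'"):
            identity_matrix([a, b], mode="rpod_only")

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(MarkerError, match="symmetric"):
            IdentityMatrix(["a", "b"], np.array([[100.0, 95.0], [94.0, 100.0]]))


class TestClusterOtus:
    def test_all_similar_gives_one_otu(self):
        m = ident(["a", "b", "c"], {}, default=99.0)
        otus = cluster_otus(m)
        assert {otus.mapping[s] for s in "abc"} == {"OTU1"}

    def test_all_distant_gives_all_singletons(self):
        m = ident(["a", "b", "c"], {}, default=90.0)
        otus = cluster_otus(m)
        assert all(v == "ST" for v in otus.mapping.values())

    def test_complete_linkage_blocks_chaining(self):
        # (a,b)=99, (b,c)=99, (a,c)=97: the a-b merge wins the tie
        # lexicographically, and adding c would drop the minimum pairwise
        # similarity to 97 < 98
        m = ident(["a", "b", "c"], {("a", "b"): 99.0, ("b", "c"): 99.0, ("a", "c"): 97.0})
        otus = cluster_otus(m, threshold=98.0, linkage="complete")
        assert otus.mapping == {"a": "OTU1", "b": "OTU1", "c": "ST"}

    def test_single_linkage_chains(self):
        m = ident(["a", "b", "c"], {("a", "b"): 99.0, ("b", "c"): 99.0, ("a", "c"): 97.0})
        otus = cluster_otus(m, threshold=98.0, linkage="single")
        assert {otus.mapping[s] for s in "abc"} == {"OTU1"}

    def test_threshold_validation(self):
        m = ident(["a", "b"], {})
        with pytest.raises(MarkerError):
            cluster_otus(m, threshold=0.0)
        with pytest.raises(MarkerError):
            cluster_otus(m, threshold=101.0)

    def test_labels_ordered_by_cluster_size(self):
        m = ident(
            ["a", "b", "c", "d", "e"],
            {("a", "b"): 99.0, ("c", "d"): 99.0, ("c", "e"): 99.0, ("d", "e"): 99.0},
            default=50.0,
        )
        otus = cluster_otus(m)
        assert otus.mapping["c"] == "OTU1"  # size-3 cluster outranks size-2
        assert otus.mapping["a"] == "OTU2"

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_input_permutation(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        labels = [f"s{i}" for i in range(n)]
        v = rng.uniform(90, 100, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 100.0)
        base = cluster_otus(IdentityMatrix(labels, v)).mapping
        perm = rng.permutation(n)
        shuffled = cluster_otus(
            IdentityMatrix([labels[i] for i in perm], v[np.ix_(perm, perm)])
        ).mapping
        assert base == shuffled

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.sampled_from(["complete", "single"]))
    def test_higher_threshold_refines_partition(self, seed, linkage):
        rng = np.random.default_rng(seed)
        n = 8
        labels = [f"s{i}" for i in range(n)]
        v = rng.uniform(90, 100, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 100.0)
        m = IdentityMatrix(labels, v)
        coarse = cluster_otus(m, threshold=94.0, linkage=linkage)
        fine = cluster_otus(m, threshold=97.0, linkage=linkage)
        coarse_of = {s: next(c for c in coarse.clusters if s in c) for s in labels}
        for cluster in fine.clusters:
            anchor = coarse_of[cluster[0]]
            assert all(set(coarse_of[s]) == set(anchor) for s in cluster)

    def test_every_strain_assigned_once_no_singleton_otu(self, small_panel):
        m = identity_matrix(small_panel.marker_profiles)
        otus = cluster_otus(m)
        assert sorted(otus.mapping) == sorted(p.strain_id for p in small_panel.marker_profiles)
        from collections import Counter

        sizes = Counter(v for v in otus.mapping.values() if v != "ST")
        assert all(size >= 2 for size in sizes.values())


class TestDistances:
    def test_conversion(self):
        m = ident(["a", "b"], {("a", "b"): 98.0})
        d = distances_from_identity(m)
        assert d.values[0, 1] == pytest.approx(0.02)
        assert d.values[0, 0] == 0.0


class TestNjTree:
    def test_two_taxa_split_evenly(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.3], [0.3, 0.0]]))
        tree = nj_tree(d)
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths == {"a": pytest.approx(0.15), "b": pytest.approx(0.15)}

    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 0.2, 0.3], [0.2, 0.0, 0.4], [0.3, 0.4, 0.0]]),
        )
        tree = nj_tree(d)
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_additive_matrix_recovered_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            edges, leaves, dist = random_additive_tree(rng, n)
            tree = nj_tree(DistanceMatrix(leaves, dist))
            assert tree.topology_splits() == tree_splits_from_edges(edges, leaves)
            # patristic distances reproduce the input to numerical precision
            pat = patristic(tree)
            for i, a in enumerate(leaves):
                for j, b in enumerate(leaves):
                    if i < j:
                        assert pat[(a, b)] == pytest.approx(dist[i, j], abs=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(MarkerError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.2, 0.0]]))


class TestBootstrap:
    def _clade_alignment(self):
        rng = np.random.default_rng(9)
        base = random_seq(rng, 300)
        # two clades separated by 30 fixed differences
        other = list(base)
        for pos in rng.choice(300, size=30, replace=False):
            other[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[pos]]
        other = "".join(other)

        def jitter(seq, k):
            s = list(seq)
            for pos in rng.choice(300, size=k, replace=False):
                s[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[s[pos]]
            return "".join(s)

        labels = ["a1", "a2", "b1", "b2"]
        seqs = [jitter(base, 2), jitter(base, 2), jitter(other, 2), jitter(other, 2)]
        return labels, seqs

    def test_strong_signal_gets_full_support(self):
        labels, seqs = self._clade_alignment()
        tree = bootstrap_supports(labels, seqs, n_reps=100, seed=4)
        supports = [n.support for n in tree.root.walk() if n.children and n.support is not None]
        assert supports and all(s == 100 for s in supports)

    def test_same_seed_reproduces_supports(self):
        labels, seqs = self._clade_alignment()
        t1 = bootstrap_supports(labels, seqs, n_reps=50, seed=7)
        t2 = bootstrap_supports(labels, seqs, n_reps=50, seed=7)
        assert t1.newick() == t2.newick()

    def test_unaligned_input_rejected(self):
        with pytest.raises(MarkerError):
            bootstrap_supports(["a", "b"], ["ACGT", "ACG"], n_reps=10, seed=0)

    def test_zero_replicates_rejected(self):
        with pytest.raises(MarkerError):
            bootstrap_supports(["a", "b"], ["ACGT", "ACGT"], n_reps=0, seed=0)


class TestProgressiveAlign:
    def test_equal_length_ungapped_inputs_pass_through(self):
        rng = np.random.default_rng(3)
        seqs = [random_seq(rng, 120) for _ in range(4)]
        aligned = progressive_align(list("abcd"), seqs)
        assert [s.replace("-", "") for s in aligned] == seqs

    def test_indel_recovered_as_gap(self):
        rng = np.random.default_rng(8)
        base = random_seq(rng, 150)
        with_insert = base[:70] + "ACGTA" + base[70:]
        aligned = progressive_align(["a", "b", "c"], [base, with_insert, base])
        assert len({len(s) for s in aligned}) == 1
        assert aligned[0].replace("-", "") == base
        assert aligned[1].replace("-", "") == with_insert
        # pairwise identity on the alignment stays high
        m = alignment_identity_matrix(["a", "b", "c"], aligned)
        assert m.pair("a", "b") > 95.0
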