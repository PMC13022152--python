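"""SNP matrices, TN93 distances, NJ reconstruction and bootstrap support."""

import math

import numpy as np
import pytest

import sd1hap as s
from sd1hap.phylo import (
    DistanceMatrix,
    InestimableDistanceError,
    default_builder,
    vcf_to_seq_matrix,
)
from sd1hap.variant_io import GenotypeCall, VariantRecord


def _rec(pos, ref, alt, genotypes):
    calls = {name: GenotypeCall(name, gt, 30, 1.0) for name, gt in genotypes.items()}
    return VariantRecord("chr01", pos, ref, [alt], calls)


class TestVcfToSeqMatrix:
    def test_hom_calls_become_bases(self):
        recs = [_rec(10, "A", "G", {"x": (0, 0), "y": (1, 1)})]
        m = vcf_to_seq_matrix(recs, ["x", "y"])
        assert m.sequence(0) == "A" and m.sequence(1) == "G"

    def test_het_becomes_iupac(self):
        recs = [_rec(10, "A", "G", {"x": (0, 1)})]
        assert vcf_to_seq_matrix(recs, ["x"]).sequence(0) == "R"

    def test_absent_sample_becomes_n(self):
        recs = [_rec(10, "A", "G", {"x": (1, 1)})]
        m = vcf_to_seq_matrix(recs, ["x", "ghost"])
        assert m.sequence(1) == "N"

    def test_non_snp_records_skipped(self):
        recs = [
            _rec(10, "A", "G", {"x": (1, 1)}),
            _rec(20, "AT", "A", {"x": (1, 1)}),
        ]
        m = vcf_to_seq_matrix(recs, ["x"])
        assert m.L == 1 and list(m.positions) == [10]

    def test_matches_direct_sequence_extraction(self, small_cohort):
        """Matrix columns equal the accession sequences at SNP positions."""
        snp_recs = [r for r in small_cohort.variants if r.is_snp]
        m = vcf_to_seq_matrix(snp_recs, small_cohort.accessions)
        for i, acc in enumerate(small_cohort.accessions):
            if small_cohort.truth.label(acc) == "heterozygous":
                continue
            aligned = small_cohort.aligned_sequence_of(acc)
            for j, pos in enumerate(m.positions):
                expected = aligned[pos - 1]
                got = m.sequence(i)[j]
                if expected == "-":
                    assert got == "N"  # no genotype inside a deletion
                else:
                    assert got == expected


class TestTn93:
    def test_identical_sequences_zero(self):
        m = s.SequenceMatrix.from_strings(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert s.tn93_distance_matrix(m).values[0, 1] == 0.0

    def test_symmetry_nonnegativity(self, rng):
        for _ in range(10):
            base = rng.choice(list("ACGT"), size=60)
            data = np.repeat(base[None, :], 4, axis=0)
            hits = rng.random(data.shape) < 0.1  # moderate divergence
            data[hits] = rng.choice(list("ACGT"), size=int(hits.sum()))
            m = s.SequenceMatrix.from_strings(
                [f"s{i}" for i in range(4)], ["".join(r) for r in data]
            )
            v = s.tn93_distance_matrix(m).values
            assert np.allclose(v, v.T, equal_nan=True)
            assert (v[~np.isnan(v)] >= 0).all()

    def test_jc69_limit(self):
        """Equal frequencies + uniform substitution at p = 0.1 -> JC69 value."""
        L = 6000
        base = "ACGT" * (L // 4)
        seq2 = list(base)
        # 600 substitutions cycling evenly over reference bases and their
        # three alternatives: uniform pair usage, equal composition, p = 0.1
        cycle = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
        for j in range(600):
            i = 4 * j + (j % 4)  # ref base cycles A, C, G, T
            seq2[i] = cycle[base[i]][(j // 4) % 3]
        m = s.SequenceMatrix.from_strings(["x", "y"], [base, "".join(seq2)])
        d = s.tn93_distance_matrix(m).values[0, 1]
        jc = -0.75 * math.log(1 - 4 * 0.1 / 3)
        assert abs(d - jc) < 1e-3

    def test_pairwise_deletion_skips_ambiguous(self):
        m = s.SequenceMatrix.from_strings(["a", "b"], ["ACGTN", "ACGTA"])
        assert s.tn93_distance_matrix(m).values[0, 1] == 0.0

    def test_no_comparable_sites_inestimable(self):
        m = s.SequenceMatrix.from_strings(["a", "b", "c"], ["ANN", "NAN", "AAA"])
        dm = s.tn93_distance_matrix(m)
        assert np.isnan(dm.values[0, 1]) and not dm.estimable[0, 1]


def random_additive_tree(rng, n):
    """Random binary tree topology with positive lengths; returns
    (distance matrix, set of non-trivial bipartitions as frozensets)."""
    labels = [f"t{i}" for i in range(n)]
    # start from a star on 3 leaves, add leaves by splitting random edges
    import itertools

    nodes = {i: labels[i] for i in range(n)}
    # adjacency with branch lengths
    adj = {}

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    internal = n
    add_edge(labels[0], internal, rng.uniform(0.5, 2))
    add_edge(labels[1], internal, rng.uniform(0.5, 2))
    add_edge(labels[2], internal, rng.uniform(0.5, 2))
    for leaf in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if str(u) < str(v)]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        internal += 1
        del adj[u][v], adj[v][u]
        a = rng.uniform(0.2, 0.8) * w
        add_edge(u, internal, a)
        add_edge(v, internal, w - a)
        add_edge(leaf, internal, rng.uniform(0.5, 2))
    # all-pairs path lengths
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        # BFS path
        stack = [(labels[i], 0.0, None)]
        while stack:
            node, dist, prev = stack.pop()
            if node == labels[j]:
                D[i, j] = D[j, i] = dist
                break
            for nxt, w in adj.get(node, {}).items():
                if nxt != prev:
                    stack.append((nxt, dist + w, node))
    # bipartitions from internal edges
    def side(u, v):
        out, stack = set(), [(u, v)]
        while stack:
            node, prev = stack.pop()
            if isinstance(node, str):
                out.add(node)
            for nxt in adj.get(node, {}):
                if nxt != prev:
                    stack.append((nxt, node))
        return frozenset(out)

    anchor = labels[0]
    biparts = set()
    for u in adj:
        for v in adj[u]:
            if isinstance(u, int) and isinstance(v, int) and u < v:
                half = side(u, v)
                if 2 <= len(half) <= n - 2:
                    biparts.add(half if anchor not in half else frozenset(labels) - half)
    return labels, D, biparts


class TestNjTree:
    def test_four_taxon_additive_example(self):
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        tree = s.nj_tree(DistanceMatrix(labels, D))
        biparts = set(tree.bipartitions())
        assert biparts == {frozenset({"C", "D"})}
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert all(v == pytest.approx(1.0) for v in lengths.values())
        internal = next(iter(tree.bipartitions().values()))
        assert internal.length == pytest.approx(2.0)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = s.nj_tree(DistanceMatrix(["a", "b", "c"], D))
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_additive_topology_recovery(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 7))
            labels, D, truth = random_additive_tree(rng, n)
            tree = s.nj_tree(DistanceMatrix(labels, D))
            assert set(tree.bipartitions()) == truth

    def test_matches_skbio_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        n = 6
        labels, D, _ = random_additive_tree(rng, n)
        ours = s.nj_tree(DistanceMatrix(labels, D))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        sk_biparts = set()
        anchor = labels[0]
        all_set = frozenset(labels)
        for node in sk_tree.non_tips():
            half = frozenset(t.name for t in node.tips())
            if 2 <= len(half) <= n - 2:
                sk_biparts.add(half if anchor not in half else all_set - half)
        assert set(ours.bipartitions()) == sk_biparts

    def test_inestimable_entry_names_pair(self):
        D = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(InestimableDistanceError, match="t0.*t2"):
            s.nj_tree(DistanceMatrix(["t0", "t1", "t2"], D))

    def test_internal_edge_count_bound(self, rng):
        labels, D, _ = random_additive_tree(rng, 8)
        tree = s.nj_tree(DistanceMatrix(labels, D))
        assert len(tree.bipartitions()) <= 8 - 3


class TestBootstrap:
    def _matrix_with_clear_split(self):
        """Balanced-composition alignment: two 3-leaf clusters 6 sites apart."""
        base = "ACGTACGTACGTACGTACGT"
        far = "GTACGT" + base[6:]
        seqs = [
            base,
            base[:19] + "C",
            base[:17] + "A" + base[18] + "C",
            far,
            far[:19] + "C",
            far[:17] + "A" + far[18] + "C",
        ]
        return s.SequenceMatrix.from_strings([f"s{i}" for i in range(6)], seqs)

    def test_unanimous_split_gets_full_support(self):
        """Every column carries the same split, so its support is 100%."""
        from sd1hap.phylo import nj_tree as _nj, tn93_distance_matrix as _dist

        m = s.SequenceMatrix.from_strings(
            [f"s{i}" for i in range(6)], ["A" * 12] * 3 + ["G" * 12] * 3
        )
        builder = lambda mat: _nj(_dist(mat, model="p"))  # noqa: E731
        tree = s.bootstrap_support(m, builder=builder, replicates=100, seed=1,
                                   collapse_below=0)
        supports = {k: v.support for k, v in tree.bipartitions().items()}
        key = frozenset({"s3", "s4", "s5"})
        assert supports[key] == pytest.approx(100.0)

    def test_no_collapse_keeps_binary(self):
        m = self._matrix_with_clear_split()
        tree = s.bootstrap_support(m, replicates=50, seed=1, collapse_below=0)
        assert len(tree.bipartitions()) == 6 - 3

    def test_collapse_reduces_or_keeps_edges(self):
        m = self._matrix_with_clear_split()
        t0 = s.bootstrap_support(m, replicates=50, seed=1, collapse_below=0)
        t60 = s.bootstrap_support(m, replicates=50, seed=1, collapse_below=60)
        assert len(t60.bipartitions()) <= len(t0.bipartitions())
        for node in t60.bipartitions().values():
            assert node.support >= 60

    def test_seed_determinism(self):
        m = self._matrix_with_clear_split()
        t1 = s.bootstrap_support(m, replicates=60, seed=42)
        t2 = s.bootstrap_support(m, replicates=60, seed=42)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_within_range(self):
        m = self._matrix_with_clear_split()
        tree = s.bootstrap_support(m, replicates=80, seed=3, collapse_below=0)
        for node in tree.bipartitions().values():
            assert 0.0 <= node.support <= 100.0

    def test_newick_parses_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        m = self._matrix_with_clear_split()
        tree = s.bootstrap_support(m, replicates=50, seed=9, collapse_below=0)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == {
            f"s{i}" for i in range(6)
        }
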