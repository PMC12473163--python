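import itertools
import math

import dendropy
import numpy as np
import pytest

from markerscreen.seq_core import read_newick
from markerscreen.tree_lite import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    k2p_distance,
    neighbor_joining,
    normalise_split,
    pairwise_distance,
    rf_distance,
)

from conftest import make_alignment


def random_additive_matrix(rng, n_taxa):
    """A distance matrix that is exactly additive on a random binary tree.

    Returns (taxa, matrix, newick) where path lengths on the tree generate
    the matrix, so NJ must recover the topology.
    """
    taxa = [f"t{i}" for i in range(n_taxa)]
    # build a random binary topology by sequential joins with random lengths
    items = list(taxa)
    rng.shuffle(items)
    parts = {t: f"{t}" for t in items}
    lengths = {}
    active = list(items)
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.05, 1.0, size=2).round(3)
        new = f"({parts[a]}:{la},{parts[b]}:{lb})"
        key = f"anc{len(parts)}"
        parts[key] = new
        active = [x for x in active if x not in (a, b)] + [key]
    la, lb = rng.uniform(0.05, 1.0, size=2).round(3)
    if len(active) == 2:
        nwk = f"({parts[active[0]]}:{la},{parts[active[1]]}:{lb});"
    tree = read_newick(nwk)
    pdm = tree.phylogenetic_distance_matrix()
    ns = tree.taxon_namespace
    d = np.zeros((n_taxa, n_taxa))
    for a, b in itertools.combinations(range(n_taxa), 2):
        dist = pdm.patristic_distance(ns.get_taxon(taxa[a]), ns.get_taxon(taxa[b]))
        d[a, b] = d[b, a] = dist
    return tuple(taxa), d, nwk


class TestK2P:
    def test_closed_form_grid(self):
        for P in np.linspace(0.0, 0.3, 7):
            for Q in np.linspace(0.0, 0.2, 5):
                expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
                assert k2p_distance(P, Q) == pytest.approx(expected, abs=1e-12)

    def test_zero_at_origin(self):
        assert k2p_distance(0.0, 0.0) == 0.0

    def test_reference_point(self):
        assert k2p_distance(0.1, 0.05) == pytest.approx(0.1701812, abs=1e-5)

    def test_saturation_flagged_infinite(self):
        assert math.isinf(k2p_distance(0.5, 0.0))

    def test_identical_sequences_zero_distance(self):
        aln = make_alignment({"a": "ACGTACGTAC", "b": "ACGTACGTAC"})
        for model in ("p", "k2p"):
            assert pairwise_distance(aln, model).value("a", "b") == 0.0

    def test_k2p_dominates_p_distance(self, rng):
        for _ in range(20):
            n = 200
            x = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
            y = list(x)
            for pos in rng.choice(n, size=30, replace=False):
                y[pos] = "ACGT"[int(rng.integers(0, 4))]
            aln = make_alignment({"a": x, "b": "".join(y)})
            p = pairwise_distance(aln, "p").value("a", "b")
            k = pairwise_distance(aln, "k2p").value("a", "b")
            if math.isfinite(k):
                assert k >= p
                if p == 0:
                    assert k == 0

    def test_pairwise_deletion(self):
        aln = make_alignment({"a": "ACGT--NN", "b": "AGGTACGT"})
        # scored columns: 0..3 only -> 1 mismatch (C/G) in 4
        assert pairwise_distance(aln, "p").value("a", "b") == pytest.approx(0.25)

    def test_disjoint_coverage_flagged_nan(self):
        aln = make_alignment({"a": "AC--", "b": "--GT"})
        assert math.isnan(pairwise_distance(aln, "p").value("a", "b"))


class TestNeighborJoining:
    def test_recovers_four_taxon_topology(self):
        # additive matrix for ((a,b),(c,d)) with internal branch 3
        taxa = ("a", "b", "c", "d")
        d = np.array(
            [
                [0, 2, 7, 7],
                [2, 0, 7, 7],
                [7, 7, 0, 2],
                [7, 7, 2, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        assert normalise_split({"a", "b"}, taxa) in bipartitions(tree)

    def test_deterministic_on_ties(self):
        taxa = ("a", "b", "c")
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        t1 = neighbor_joining(DistanceMatrix(taxa, d))
        t2 = neighbor_joining(DistanceMatrix(taxa, d))
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_rooting_on_absent_taxon_errors(self):
        taxa = ("a", "b", "c")
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        with pytest.raises(ValueError, match="outgroup"):
            neighbor_joining(DistanceMatrix(taxa, d), outgroup="zz")

    def test_infinite_entries_rejected_with_pairs(self):
        taxa = ("a", "b", "c")
        d = np.array([[0, np.inf, 4], [np.inf, 0, 4], [4, 4, 0]])
        with pytest.raises(ValueError, match="'a', 'b'|\\('a', 'b'\\)"):
            neighbor_joining(DistanceMatrix(taxa, d))

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            taxa, d, nwk = random_additive_matrix(rng, n)
            tree = neighbor_joining(DistanceMatrix(taxa, d))
            assert rf_distance(tree, read_newick(nwk)) == 0

    def test_branch_lengths_nonnegative(self, rng):
        taxa, d, _ = random_additive_matrix(rng, 6)
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0


class TestRf:
    def test_identical_trees(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert rf_distance(t, read_newick("((a:1,b:1):1,(c:1,d:1):1);")) == 0

    def test_alternative_quartet_resolutions(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    def test_star_vs_resolved(self):
        star = read_newick("(a,b,c,d,e);")
        resolved = read_newick("(((a,b),c),(d,e));")
        internal = len(bipartitions(resolved))
        assert rf_distance(star, resolved) == internal

    def test_leaf_set_mismatch(self):
        with pytest.raises(ValueError, match="leaf sets differ"):
            rf_distance(read_newick("((a,b),c);"), read_newick("((a,b),d);"))

    def test_agrees_with_dendropy(self, rng):
        """Cross-check the split-set implementation against dendropy."""
        for _ in range(10):
            n = int(rng.integers(4, 8))
            _, _, nwk1 = random_additive_matrix(rng, n)
            _, _, nwk2 = random_additive_matrix(rng, n)
            ns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=ns)
            d2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=ns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            got = rf_distance(read_newick(nwk1), read_newick(nwk2))
            assert got == expected


@pytest.fixture(scope="module")
def split_alignment():
    """Two clades separated by 12 fixed differences over 300 bp."""
    rng = np.random.default_rng(7)
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
    clade_cols = rng.choice(300, size=12, replace=False)
    rows = {}
    for i in range(4):
        rows[f"in{i}"] = base
    derived = list(base)
    for c in clade_cols:
        derived[c] = {"A": "G", "G": "A", "C": "T", "T": "C"}[derived[c]]
    for i in range(4):
        rows[f"out{i}"] = "".join(derived)
    # sprinkle private tip variation so rows are not identical
    for t in list(rows):
        row = list(rows[t])
        for c in rng.choice(300, size=3, replace=False):
            row[c] = "ACGT"[int(rng.integers(0, 4))]
        rows[t] = "".join(row)
    return make_alignment(rows, "split")


class TestBootstrap:
    def test_single_replicate_support_binary(self, split_alignment):
        _, support = bootstrap_support(split_alignment, n_reps=1, seed=5)
        assert set(support.values()) <= {0.0, 100.0}

    def test_seed_reproducibility(self, split_alignment):
        _, s1 = bootstrap_support(split_alignment, n_reps=25, seed=11)
        _, s2 = bootstrap_support(split_alignment, n_reps=25, seed=11)
        assert s1 == s2

    def test_planted_split_strongly_supported(self, split_alignment):
        tree, support = bootstrap_support(split_alignment, n_reps=100, seed=3)
        focal = normalise_split(
            {t for t in split_alignment.taxa if t.startswith("in")},
            split_alignment.taxa,
        )
        assert support[focal] >= 95.0
        # the support value is attached to a node label on the tree
        labels = {n.label for n in tree.preorder_internal_node_iter()}
        assert str(int(round(support[focal]))) in labels
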