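"""Desk-scale distance trees: p/K2P distances, NJ, bootstrap, RF.

This stage exists so that clade recovery (e.g. a two-lineage split) is
testable inside the package without external ML/BI tools.  The Kimura
two-parameter (K2P) model is used because its transition/transversion
structure mirrors the screening statistics:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition and transversion proportions over the columns
where both sequences carry unambiguous bases (pairwise deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .informativeness import MISSING_CODE, encode_alignment
from .seq_core import LocusAlignment
from .supermatrix import Supermatrix


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal; inf = undefined, nan = no overlap

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    @property
    def has_undefined(self) -> bool:
        off = ~np.eye(len(self.taxa), dtype=bool)
        return bool(np.isinf(self.d[off]).any() or np.isnan(self.d[off]).any())


def k2p_distance(P: float, Q: float) -> float:
    """Closed-form K2P distance; inf where the log arguments leave (0, 1]."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1 * math.sqrt(w2))


def pairwise_distance(
    data: LocusAlignment | Supermatrix, model: str = "k2p"
) -> DistanceMatrix:
    """Pairwise p or K2P distances with pairwise deletion of missing data.

    Pairs sharing zero scored columns get ``nan``; saturated pairs whose
    K2P log argument is non-positive get ``inf`` (flagged, not raised —
    :func:`neighbor_joining` refuses such matrices explicitly).
    """
    model = model.lower()
    if model not in ("p", "k2p"):
        raise ValueError(f"model must be 'p' or 'k2p', got {model!r}")
    aln = data.to_alignment() if isinstance(data, Supermatrix) else data
    if len(aln.taxa) < 2:
        raise ValueError("need >= 2 taxa for distances")
    arr = encode_alignment(aln)
    return DistanceMatrix(aln.taxa, _distances_from_encoded(arr, model))


def _distances_from_encoded(arr: np.ndarray, model: str) -> np.ndarray:
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        ai = arr[i]
        for j in range(i + 1, n):
            aj = arr[j]
            valid = (ai != MISSING_CODE) & (aj != MISSING_CODE)
            m = int(valid.sum())
            if m == 0:
                dij = math.nan
            else:
                vi, vj = ai[valid], aj[valid]
                diff = vi != vj
                if model == "p":
                    dij = float(diff.sum()) / m
                else:
                    ti = int((diff & ((vi % 2) == (vj % 2))).sum())
                    tv = int(diff.sum()) - ti
                    dij = k2p_distance(ti / m, tv / m)
            d[i, j] = d[j, i] = dij
    return d


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(
    dm: DistanceMatrix, outgroup: str | None = None
) -> dendropy.Tree:
    """Canonical NJ (Q-criterion) with deterministic tie-breaking.

    Ties on Q are broken by the lexicographically smallest leaf label under
    each candidate node.  Negative branch lengths are clamped to zero with
    the deficit moved to the sister branch.  When *outgroup* is given the
    tree is rerooted on that leaf's edge (midpoint).
    """
    if dm.has_undefined:
        bad = [
            (dm.taxa[i], dm.taxa[j])
            for i in range(len(dm.taxa))
            for j in range(i + 1, len(dm.taxa))
            if not np.isfinite(dm.d[i, j])
        ]
        raise ValueError(f"undefined distances for pairs: {bad}")
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa for NJ")
    if outgroup is not None and outgroup not in dm.taxa:
        raise ValueError(f"outgroup {outgroup!r} is not in the matrix")

    ns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    labels: list[str] = []  # min leaf label under each active node (tie-break key)
    for t in dm.taxa:
        node = dendropy.Node()
        node.taxon = ns.new_taxon(t)
        nodes.append(node)
        labels.append(t)
    D = dm.d.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                la, lb = labels[active[a]], labels[active[b]]
                key = (q, min(la, lb), max(la, lb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        vi = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        # distances from the new node to the remaining actives
        new_index = len(nodes)
        D = np.pad(D, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            duk = max(0.5 * (D[i, c] + D[j, c] - dij), 0.0)
            D[new_index, c] = D[c, new_index] = duk
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [c for c in active if c not in (i, j)] + [new_index]

    i, j = active
    root = dendropy.Node()
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    half = max(D[i, j] / 2.0, 0.0)
    nodes[i].edge.length = half
    nodes[j].edge.length = half
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    if outgroup is not None:
        leaf = tree.find_node_for_taxon(ns.get_taxon(outgroup))
        elen = leaf.edge.length or 0.0
        tree.reroot_at_edge(leaf.edge, length1=elen / 2.0, length2=elen / 2.0)
        tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, RF, bootstrap


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as leaf-label sets, normalised for unrootedness.

    Each internal edge yields the split side that excludes the overall
    lexicographically smallest leaf, so rooted and unrooted encodings of
    the same topology compare equal.
    """
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    all_leaves = frozenset(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def normalise_split(side, all_taxa) -> frozenset[str]:
    """Normalise one side of a bipartition the way :func:`bipartitions` does.

    Use this to look up a clade of interest in the split sets / support
    maps, which store the side excluding the lexicographically smallest
    taxon.
    """
    all_taxa = frozenset(all_taxa)
    side = frozenset(side)
    if min(all_taxa) in side:
        side = all_taxa - side
    return side


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds distance: splits present in exactly one tree."""
    l1 = {l.taxon.label for l in t1.leaf_node_iter()}
    l2 = {l.taxon.label for l in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def bootstrap_support(
    data: LocusAlignment | Supermatrix,
    model: str = "k2p",
    n_reps: int = 100,
    seed: int = 0,
    outgroup: str | None = None,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree with nonparametric bootstrap support on internal nodes.

    Columns are resampled with replacement *n_reps* times; support is the
    percentage of replicates whose NJ tree contains each original split.
    Deterministic for a fixed seed.  Returns the supported tree and the
    split -> support map.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    aln = data.to_alignment() if isinstance(data, Supermatrix) else data
    base = neighbor_joining(pairwise_distance(aln, model), outgroup=outgroup)
    base_splits = bipartitions(base)
    counts = {split: 0 for split in base_splits}
    rng = np.random.default_rng(seed)
    arr = encode_alignment(aln)
    L = aln.length
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep_dm = DistanceMatrix(aln.taxa, _distances_from_encoded(arr[:, idx], model))
        rep_splits = bipartitions(neighbor_joining(rep_dm))
        for split in base_splits:
            if split in rep_splits:
                counts[split] += 1
    support = {s: 100.0 * c / n_reps for s, c in counts.items()}
    # annotate internal nodes
    leaves = sorted(l.taxon.label for l in base.leaf_node_iter())
    ref, all_leaves = leaves[0], frozenset(leaves)
    for node in base.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if side in support:
            node.label = str(int(round(support[side])))
    return base, support
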