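"""Robinson-Foulds and matching-split tree distances with Yule normalization.

Both metrics operate on the nontrivial bipartitions (splits) the internal
edges of each tree induce on the shared leaf set. RF is the cardinality of
the symmetric difference of the two split sets (not halved). MS solves a
minimum-cost perfect matching between the two split multisets — padded with
trivial splits when the counts differ — where the cost of pairing split
A1|B1 with A2|B2 is n minus the best agreement over the two orientations;
the assignment is solved exactly (Hungarian algorithm).

Because raw values grow with tree size, distances are normalized by the
Monte-Carlo mean distance between independent random Yule (pure-birth)
topologies on the same leaf count, following common tree-comparison
practice: a normalized distance near 1 means "as different as two random
trees".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment

from .rnaio import PairphyError, Tree


@dataclass
class TreeDistanceResult:
    metric: str  # 'RF' or 'MS'
    raw: float
    yule_mean: float
    normalized: float
    n_replicates: int
    seed: int


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def split_set(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as frozensets of the side NOT containing a
    fixed reference leaf (the lexicographically smallest label)."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    all_leaves = frozenset(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def _check_leaf_sets(t1: Tree, t2: Tree) -> list[str]:
    l1 = sorted(lf.taxon.label for lf in t1.leaf_node_iter())
    l2 = sorted(lf.taxon.label for lf in t2.leaf_node_iter())
    if l1 != l2:
        raise PairphyError("trees have different leaf sets")
    return l1


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Symmetric-difference cardinality of the nontrivial split sets."""
    _check_leaf_sets(t1, t2)
    return len(split_set(t1) ^ split_set(t2))


def ms_distance(t1: Tree, t2: Tree) -> float:
    """Matching-split distance (topology only), exact via the Hungarian
    algorithm; unmatched splits pair with the trivial empty split at cost
    min(|A|, |B|)."""
    leaves = _check_leaf_sets(t1, t2)
    n = len(leaves)
    all_set = frozenset(leaves)
    s1 = sorted(split_set(t1), key=sorted)
    s2 = sorted(split_set(t2), key=sorted)
    size = max(len(s1), len(s2))
    if size == 0:
        return 0.0
    cost = np.zeros((size, size))
    for i in range(size):
        for j in range(size):
            a = s1[i] if i < len(s1) else None
            b = s2[j] if j < len(s2) else None
            if a is None and b is None:
                cost[i, j] = 0.0
            elif a is None:
                cost[i, j] = min(len(b), n - len(b))
            elif b is None:
                cost[i, j] = min(len(a), n - len(a))
            else:
                ac, bc = all_set - a, all_set - b
                agree = max(
                    len(a & b) + len(ac & bc),
                    len(a & bc) + len(ac & b),
                )
                cost[i, j] = n - agree
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


_METRICS = {"RF": rf_distance, "MS": ms_distance}


# ---------------------------------------------------------------------------
# Yule normalization
# ---------------------------------------------------------------------------

def random_yule_topology(labels: list[str], rng: np.random.Generator) -> Tree:
    """Random pure-birth topology by sequential random joins (equal-rate
    Yule shape); branch lengths are irrelevant to the topology metrics."""
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(lab)
        nodes.append(nd)
    while len(nodes) > 2:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        parent = dendropy.Node()
        for idx in sorted((int(i), int(j)), reverse=True):
            parent.add_child(nodes.pop(idx))
        nodes.append(parent)
    for nd in nodes:
        tree.seed_node.add_child(nd)
    return tree


def yule_mean_distance(
    metric: str, n_leaves: int, n_replicates: int = 1000, seed: int = 0
) -> float:
    """Monte-Carlo mean metric distance between independent Yule topology
    pairs on ``n_leaves`` leaves."""
    if n_leaves < 4:
        raise PairphyError("Yule normalization needs >= 4 leaves")
    if n_replicates < 100:
        raise PairphyError("use >= 100 replicates for a stable normalizer")
    fn = _METRICS[metric.upper()]
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_leaves)]
    total = 0.0
    for _ in range(n_replicates):
        total += fn(
            random_yule_topology(labels, rng), random_yule_topology(labels, rng)
        )
    return total / n_replicates


def yule_normalize(
    raw: float,
    metric: str,
    n_leaves: int,
    n_replicates: int = 1000,
    seed: int = 0,
) -> TreeDistanceResult:
    """Divide a raw distance by the mean distance between random Yule trees
    of the same size; reproducible given the seed."""
    mean = yule_mean_distance(metric, n_leaves, n_replicates, seed)
    return TreeDistanceResult(
        metric=metric.upper(),
        raw=raw,
        yule_mean=mean,
        normalized=raw / mean if mean > 0 else 0.0,
        n_replicates=n_replicates,
        seed=seed,
    )


def tree_distance(
    t1: Tree,
    t2: Tree,
    metric: str = "RF",
    normalize: bool = True,
    n_replicates: int = 1000,
    seed: int = 0,
) -> TreeDistanceResult:
    """One-call raw + Yule-normalized distance between two trees."""
    leaves = _check_leaf_sets(t1, t2)
    raw = float(_METRICS[metric.upper()](t1, t2))
    if not normalize:
        return TreeDistanceResult(metric.upper(), raw, float("nan"), float("nan"), 0, seed)
    return yule_normalize(raw, metric, len(leaves), n_replicates, seed)


def all_binary_topologies(labels: list[str]) -> list[Tree]:
    """Every unrooted binary topology on the labels (testing aid; counts
    1, 3, 15, 105 for 4-7 leaves)."""
    if len(labels) < 4:
        raise PairphyError("need >= 4 labels")

    def build(newicks: list[str], rest: list[str]) -> list[str]:
        if not rest:
            return newicks
        lab, remaining = rest[0], rest[1:]
        out = []
        for nwk in newicks:
            # insert the new leaf on every edge: every internal comma-free
            # subtree position; represent trees as nested tuples instead
            out.extend(_insert_everywhere(nwk, lab))
        return build(out, remaining)

    def _insert_everywhere(tree_tuple, lab):
        results = []

        def recurse(node, path):
            if isinstance(node, tuple):
                for i, child in enumerate(node):
                    recurse(child, path + [i])
            results.append(path)

        recurse(tree_tuple, [])
        out = []
        for path in results:
            if not path:
                continue  # cannot attach above the unrooted core
            out.append(_attach(tree_tuple, path, lab))
        return out

    def _attach(node, path, lab):
        if not path:
            return (node, lab)
        i = path[0]
        return tuple(
            _attach(ch, path[1:], lab) if j == i else ch
            for j, ch in enumerate(node)
        )

    core = (labels[0], labels[1], labels[2])
    tuples = build([core], labels[3:])

    def to_newick(node) -> str:
        if isinstance(node, tuple):
            return "(" + ",".join(to_newick(c) for c in node) + ")"
        return node

    trees = []
    for tp in tuples:
        trees.append(
            dendropy.Tree.get(data=to_newick(tp) + ";", schema="newick")
        )
    return trees
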