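"""Tree model, Newick I/O and bootstrap tree-set analytics.

Trees are :class:`dendropy.Tree` objects; replicate collections are
:class:`dendropy.TreeList` objects sharing one taxon namespace.  Internal
node labels carry bootstrap supports as percentages (0-100).

The monophyly summariser follows the rename/condense recipe used for
bootstrap sets of rRNA trees: each replicate is rooted to the outgroup,
every leaf is renamed to its group label, clades whose leaves all share one
label are condensed to a single leaf, and a group is scored monophyletic in
that replicate iff its label then occurs exactly once.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .alignment import GroupMap

__all__ = [
    "parse_newick",
    "write_newick",
    "read_treeset",
    "treeset_from_strings",
    "leaf_labels",
    "bipartitions",
    "node_support",
    "reroot",
    "monophyly_support",
    "bipartition_support",
    "rf_distance",
    "rf_within",
    "mean_node_support",
    "attach_supports",
    "jackknife_variants",
    "trim_taxa",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse one Newick string; supports are read from internal-node labels."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed newick: {exc}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = [lab for lab, c in Counter(labels).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def read_treeset(path) -> dendropy.TreeList:
    """Read a multi-Newick file into a TreeList with one shared namespace."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    _check_common_leafset(trees)
    return trees


def treeset_from_strings(texts: list[str]) -> dendropy.TreeList:
    trees = dendropy.TreeList.get(data="\n".join(texts), schema="newick")
    _check_common_leafset(trees)
    return trees


def _check_common_leafset(trees: dendropy.TreeList) -> None:
    if not trees:
        raise ValueError("empty tree set")
    ref = leaf_labels(trees[0])
    for i, t in enumerate(trees[1:], start=1):
        if leaf_labels(t) != ref:
            raise ValueError(f"tree {i} has a different leaf set from tree 0")


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial unrooted bipartitions, each canonicalised as the side that
    does not contain the lexicographically smallest leaf label."""
    all_leaves = leaf_labels(tree)
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= below[id(ch)]
            below[id(node)] = frozenset(acc)
            side = below[id(node)]
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
    return splits


def node_support(node: dendropy.Node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def _below_sets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= below[ch]
            below[node] = frozenset(acc)
    return below


def reroot(tree: dendropy.Tree, outgroup: set[str]) -> dendropy.Tree:
    """Root a (copy of the) tree on the edge separating the outgroup.

    If the outgroup is not monophyletic in the unrooted tree, the root is
    placed at the smallest cluster containing it and a warning is issued.
    """
    if not outgroup:
        raise ValueError("outgroup must be non-empty")
    leaves = leaf_labels(tree)
    outgroup = set(outgroup)
    if not outgroup <= leaves:
        raise ValueError(f"outgroup taxa not in tree: {sorted(outgroup - leaves)}")
    if outgroup == leaves:
        raise ValueError("outgroup cannot be the whole leaf set")

    t = tree.clone(depth=1)
    t.is_rooted = True
    below = _below_sets(t)
    target = frozenset(outgroup)
    complement = frozenset(leaves - outgroup)

    exact_edge = None
    best_edge = None
    best_size = None
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = below[node]
        if side == target or side == complement:
            exact_edge = node.edge
            break
        # minimal cluster containing the outgroup, on either side of the edge
        for cluster in (side, frozenset(leaves) - side):
            if outgroup <= cluster and (best_size is None or len(cluster) < best_size):
                best_size = len(cluster)
                best_edge = node.edge
    edge = exact_edge
    if edge is None:
        warnings.warn(
            "outgroup is not monophyletic; rooting at the smallest spanning clade",
            stacklevel=2,
        )
        edge = best_edge
    if edge is None:  # outgroup spans everything but the root: keep rooting
        return t
    if edge.length is not None:
        half = edge.length / 2.0
        t.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    else:
        t.reroot_at_edge(edge, update_bipartitions=False)
    return t


def _maximal_pure_counts(tree: dendropy.Tree, label_of: dict[str, str]) -> Counter:
    """Count, per group label, the maximal clades whose leaves all carry it.

    Equivalent to renaming leaves to group labels, condensing single-label
    clades, and counting label occurrences in the condensed tree.
    """
    pure: dict[dendropy.Node, str | None] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            pure[node] = label_of[node.taxon.label]
        else:
            child_labels = {pure[ch] for ch in node.child_nodes()}
            pure[node] = child_labels.pop() if len(child_labels) == 1 else None
    counts: Counter = Counter()
    for node in tree.preorder_node_iter():
        lab = pure[node]
        if lab is not None and (node.parent_node is None or pure[node.parent_node] is None):
            counts[lab] += 1
    return counts


def monophyly_support(trees: dendropy.TreeList, groups: GroupMap) -> dict[str, float]:
    """Percentage of replicates in which each group label is monophyletic.

    Each replicate is rooted to the outgroup first, mirroring the rooted
    rename/condense/count pipeline.
    """
    if not trees:
        raise ValueError("empty tree set")
    leaves = leaf_labels(trees[0])
    groups.check_covers(leaves)
    if not groups.outgroup:
        raise ValueError("group map must define an outgroup for rooting")
    label_of = {t: groups.groups[t] for t in leaves}
    labels = sorted({label_of[t] for t in leaves})
    mono: Counter = Counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-monophyletic outgroup warned per set, not per tree
        for tree in trees:
            rooted = reroot(tree, set(groups.outgroup) & set(leaves))
            counts = _maximal_pure_counts(rooted, label_of)
            for lab in labels:
                if counts.get(lab, 0) == 1:
                    mono[lab] += 1
    n = len(trees)
    return {lab: 100.0 * mono[lab] / n for lab in labels}


def bipartition_support(trees: dendropy.TreeList, split: tuple[set[str], set[str]]) -> float:
    """Percentage of trees whose unrooted bipartition set contains ``split``."""
    if not trees:
        raise ValueError("empty tree set")
    leaves = leaf_labels(trees[0])
    a, b = frozenset(split[0]), frozenset(split[1])
    if a | b != leaves or a & b:
        raise ValueError("split must bipartition the leaf set")
    if min(len(a), len(b)) < 2:
        raise ValueError("trivial split (singleton side)")
    anchor = min(leaves)
    canon = b if anchor in a else a
    hits = sum(1 for t in trees if canon in bipartitions(t))
    return 100.0 * hits / len(trees)


def _common_namespace_pair(t1: dendropy.Tree, t2: dendropy.Tree):
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=write_newick(t1), schema="newick", taxon_namespace=ns,
        suppress_internal_node_taxa=True,
    )
    b = dendropy.Tree.get(
        data=write_newick(t2), schema="newick", taxon_namespace=ns,
        suppress_internal_node_taxa=True,
    )
    return a, b


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unnormalised Robinson-Foulds distance (bipartition symmetric difference)."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, only-in-second={sorted(l2 - l1)}"
        )
    a, b = _common_namespace_pair(t1, t2)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def rf_within(trees: dendropy.TreeList) -> tuple[float, float]:
    """Mean and SD of pairwise RF distances over all unordered pairs."""
    if len(trees) < 2:
        raise ValueError("need at least two trees")
    _check_common_leafset(trees)
    ns = dendropy.TaxonNamespace()
    common = dendropy.TreeList.get(
        data="\n".join(write_newick(t) for t in trees),
        schema="newick",
        taxon_namespace=ns,
    )
    for t in common:
        t.encode_bipartitions()
    dists = []
    for i in range(len(common)):
        for j in range(i + 1, len(common)):
            dists.append(treecompare.symmetric_difference(common[i], common[j]))
    arr = np.asarray(dists, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def mean_node_support(tree: dendropy.Tree, outgroup: set[str] | None = None) -> tuple[float, float]:
    """Mean and SD of internal-node supports, excluding the root and, when an
    outgroup is given, the outgroup-incident root edge (whose support merely
    duplicates the root split)."""
    below = _below_sets(tree) if outgroup else {}
    skip: set[int] = set()
    if outgroup:
        og = frozenset(outgroup)
        for node, side in below.items():
            if side == og:
                skip.add(id(node))
    supports = []
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None or id(node) in skip:
            continue
        s = node_support(node)
        if s is not None:
            supports.append(s)
    if not supports:
        raise ValueError("tree carries no internal-node supports")
    arr = np.asarray(supports, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def attach_supports(best: dendropy.Tree, trees: dendropy.TreeList) -> dendropy.Tree:
    """Label each internal edge of ``best`` with the % of replicate trees
    containing its bipartition."""
    leaves = leaf_labels(best)
    anchor = min(leaves)
    rep_splits = [bipartitions(t) for t in trees]
    out = best.clone(depth=1)
    below = _below_sets(out)
    for node in out.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = below[node]
        if anchor in side:
            side = frozenset(leaves) - side
        if not (2 <= len(side) <= len(leaves) - 2):
            continue
        pct = 100.0 * sum(1 for s in rep_splits if side in s) / len(rep_splits)
        node.label = f"{pct:.1f}"
    return out


def jackknife_variants(
    taxa: list[str],
    groups: GroupMap,
    clades: list[str],
    include_mitochondria: bool = True,
) -> dict[str, list[str]]:
    """One taxon subset per named clade, equal to ``taxa`` minus that clade.

    With ``include_mitochondria=False`` the mitochondrial taxa are dropped
    from every subset as well, mirroring the plus/minus-mitochondria design.
    """
    out: dict[str, list[str]] = {}
    for clade in clades:
        members = groups.members(clade) & set(taxa)
        if not members:
            raise ValueError(f"clade {clade!r} has no members among the supplied taxa")
        drop = set(members)
        if not include_mitochondria:
            drop |= groups.mitochondria
        out[clade] = [t for t in taxa if t not in drop]
    return out


def trim_taxa(
    tree: dendropy.Tree,
    groups: GroupMap,
    support_threshold: float = 95.0,
    target: int | None = None,
) -> list[str]:
    """Thin densely sampled clades: within each maximal clade whose support
    exceeds the threshold and whose leaves share one group label, keep only
    the leaf with the longest terminal branch (ties break to the smallest
    taxon id).  Returns the surviving taxon subset."""
    if not (0 < support_threshold <= 100):
        raise ValueError("support threshold must lie in (0, 100]")
    label_of = {leaf.taxon.label: groups.groups[leaf.taxon.label] for leaf in tree.leaf_node_iter()}
    below = _below_sets(tree)
    pure: dict[dendropy.Node, str | None] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            pure[node] = label_of[node.taxon.label]
        else:
            child_labels = {pure[ch] for ch in node.child_nodes()}
            pure[node] = child_labels.pop() if len(child_labels) == 1 else None

    kept = sorted(label_of)
    eligible: list[tuple[float, dendropy.Node]] = []
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None or pure[node] is None:
            continue
        parent_eligible = (
            pure[node.parent_node] is not None
            and node.parent_node.parent_node is not None
            and (node_support(node.parent_node) or 0.0) > support_threshold
        )
        s = node_support(node)
        if s is not None and s > support_threshold and not parent_eligible:
            eligible.append((s, node))

    eligible.sort(key=lambda sn: (-sn[0], min(below[sn[1]])))
    removed: set[str] = set()
    for _, node in eligible:
        if target is not None and len(kept) - len(removed) <= target:
            break
        members = sorted(below[node])
        lengths = {
            leaf.taxon.label: (leaf.edge.length or 0.0)
            for leaf in node.leaf_iter()
        }
        best_len = max(lengths[t] for t in members)
        survivor = min(t for t in members if lengths[t] == best_len)
        for t in members:
            if t != survivor:
                removed.add(t)
                if target is not None and len(kept) - len(removed) <= target:
                    break
    return [t for t in kept if t not in removed]
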