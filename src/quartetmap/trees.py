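"""Quartet topologies, internal rootings, tree classification and split profiles.

For any four taxa (or taxon groups) exactly three fully resolved unrooted
topologies exist — the three ways of pairing four labels into two cherries.
Each unrooted topology has five branches, so placing a root on any of them
yields five rooted derivatives, 15 rooted trees in total.  Two rooted trees
that unroot to the same topology differ only in character polarisation;
trees from different columns of that 3 x 5 table are genuinely incongruent.
This module provides that enumeration, classifies arbitrary Newick trees to
their underlying group-level quartet topology, counts one-per-group quartet
draws, and summarises split agreement across collections of trees.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "QuartetTopology",
    "RootedQuartetTree",
    "SplitProfile",
    "ClassificationError",
    "enumerate_quartet_topologies",
    "rooted_derivatives",
    "all_rooted_quartet_trees",
    "classify_tree",
    "count_quartets",
    "split_agreement",
    "read_trees",
    "read_tree",
]


class ClassificationError(ValueError):
    """A taxon group is not a split of the (restricted) tree."""


@dataclasses.dataclass(frozen=True)
class QuartetTopology:
    """Unordered pairing of four labels into two cherries, e.g. {a,b} | {c,d}."""

    pairs: frozenset[frozenset[str]]

    @classmethod
    def of(cls, pair1: Iterable[str], pair2: Iterable[str]) -> "QuartetTopology":
        p1, p2 = frozenset(pair1), frozenset(pair2)
        if len(p1) != 2 or len(p2) != 2 or p1 & p2:
            raise ValueError("a quartet topology needs two disjoint label pairs")
        return cls(frozenset({p1, p2}))

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(x for pair in self.pairs for x in pair)

    def __str__(self) -> str:
        sides = sorted(tuple(sorted(p)) for p in self.pairs)
        return " | ".join("(" + ",".join(s) + ")" for s in sides)


# A rooted quartet tree is a nested structure: leaves are label strings,
# internal nodes are frozensets of two subtrees.  frozenset nesting makes
# left/right order irrelevant and equality/hashing structural.
_Node = str | frozenset


def _leafset(node: _Node) -> frozenset[str]:
    if isinstance(node, str):
        return frozenset({node})
    return frozenset(x for child in node for x in _leafset(child))


def _node_newick(node: _Node) -> str:
    if isinstance(node, str):
        return node
    parts = sorted((_node_newick(c) for c in node))
    return "(" + ",".join(parts) + ")"


@dataclasses.dataclass(frozen=True)
class RootedQuartetTree:
    """Rooted binary tree on 4 labels; one of a topology's 5 rooted derivatives."""

    node: frozenset

    @property
    def labels(self) -> frozenset[str]:
        return _leafset(self.node)

    def unroot(self) -> QuartetTopology:
        """Recover the parent unrooted topology (the unique 2+2 cherry pairing)."""
        stack = [self.node]
        while stack:
            sub = stack.pop()
            if isinstance(sub, str):
                continue
            leaves = _leafset(sub)
            if len(leaves) == 2:
                return QuartetTopology.of(leaves, self.labels - leaves)
            stack.extend(sub)
        raise ValueError("not a valid 4-leaf binary tree")  # pragma: no cover

    def to_newick(self) -> str:
        return _node_newick(self.node) + ";"

    def __str__(self) -> str:
        return _node_newick(self.node)


def enumerate_quartet_topologies(labels: Iterable[str]) -> set[QuartetTopology]:
    """The three unrooted topologies on exactly four distinct labels."""
    lab = sorted(set(labels))
    if len(lab) != 4:
        raise ValueError(f"need exactly 4 distinct labels, got {len(lab)}")
    a, b, c, d = lab
    return {
        QuartetTopology.of((a, b), (c, d)),
        QuartetTopology.of((a, c), (b, d)),
        QuartetTopology.of((a, d), (b, c)),
    }


def rooted_derivatives(topology: QuartetTopology) -> set[RootedQuartetTree]:
    """The five rooted trees obtained by placing the root on each branch.

    For topology (a,b)|(c,d): the balanced tree ((a,b),(c,d)) (root on the
    internal branch) and the four ladders x,(y,(c,d)) from rooting on a
    pendant branch.
    """
    (p1, p2) = sorted(topology.pairs, key=lambda p: sorted(p))
    (a, b), (c, d) = sorted(p1), sorted(p2)
    fs = frozenset
    trees = {
        fs({fs({a, b}), fs({c, d})}),
        fs({a, fs({b, fs({c, d})})}),
        fs({b, fs({a, fs({c, d})})}),
        fs({c, fs({d, fs({a, b})})}),
        fs({d, fs({c, fs({a, b})})}),
    }
    return {RootedQuartetTree(t) for t in trees}


def all_rooted_quartet_trees(labels: Iterable[str]) -> set[RootedQuartetTree]:
    """All 15 rooted trees on four labels (5 per unrooted topology)."""
    out: set[RootedQuartetTree] = set()
    for topo in enumerate_quartet_topologies(labels):
        out |= rooted_derivatives(topo)
    return out


# ---------------------------------------------------------------------------
# Newick handling

def read_trees(path: str | Path) -> list[dendropy.Tree]:
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", taxon_namespace=tns, preserve_underscores=True
    )
    return list(trees)


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a single tree from a Newick string or a file path."""
    text = str(source)
    if not text.lstrip().startswith("("):
        text = Path(source).read_text()
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _clade_leafsets(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf set under each node (both trivial and internal clades)."""
    sets: dict[int, frozenset[str]] = {}
    out = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = frozenset({node.taxon.label})
        else:
            s = frozenset().union(*(sets[id(c)] for c in node.child_nodes()))
        sets[id(node)] = s
        out.append(s)
    return out


def classify_tree(
    tree: dendropy.Tree | str,
    group_map: Mapping[str, str],
    groups: Sequence[str] | None = None,
) -> QuartetTopology:
    """Induced quartet topology of four taxon groups on an arbitrary tree.

    The tree is restricted to the taxa mapped to the four groups; each group
    must then form a split (be cohesive) of the restricted unrooted tree.
    Rooting of the input never affects the result.
    """
    if isinstance(tree, str):
        tree = read_tree(tree)
    if groups is None:
        groups = sorted(set(group_map.values()))
    if len(groups) != 4:
        raise ValueError(f"need exactly 4 groups, got {len(groups)}")
    members: dict[str, set[str]] = {g: set() for g in groups}
    tree_leaves = _leaf_labels(tree)
    for taxon, g in group_map.items():
        if g in members and taxon in tree_leaves:
            members[g].add(taxon)
    for g in groups:
        if not members[g]:
            raise ValueError(f"group {g!r} has no taxa on the tree")

    keep = set().union(*members.values())
    sub = tree.extract_tree_with_taxa_labels(labels=keep)
    all_leaves = frozenset(_leaf_labels(sub))
    leafsets = set(_clade_leafsets(sub))
    leafsets |= {all_leaves - s for s in leafsets}  # unrooted: both sides count

    for g in groups:
        gs = frozenset(members[g])
        if gs not in leafsets:
            raise ClassificationError(f"group {g!r} is not a split of the restricted tree")

    for g1, g2 in itertools.combinations(groups, 2):
        side = frozenset(members[g1] | members[g2])
        if side not in leafsets:
            continue
        other = [g for g in groups if g not in (g1, g2)]
        return QuartetTopology.of((g1, g2), other)
    raise ClassificationError(
        "no group pairing forms a split; the restricted tree is unresolved at the group level"
    )


def count_quartets(group_map: Mapping[str, str], groups: Sequence[str]) -> int:
    """Number of one-taxon-per-group quartet draws: the product of group sizes."""
    sizes = Counter(group_map.values())
    total = 1
    for g in groups:
        if sizes[g] == 0:
            raise ValueError(f"group {g!r} is empty")
        total *= sizes[g]
    return total


# ---------------------------------------------------------------------------
# Split agreement across trees (Fig.-5-style summary)

@dataclasses.dataclass
class SplitProfile:
    """Occurrence counts of nontrivial bipartitions across a set of trees."""

    counts: dict[tuple[str, ...], int]
    n_trees: int

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def n_in_all(self) -> int:
        return sum(1 for c in self.counts.values() if c == self.n_trees)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# trees\t{self.n_trees}\n# distinct_splits\t{self.n_distinct}\n")
            fh.write(f"# splits_in_all\t{self.n_in_all}\nsplit\tcount\n")
            for split, c in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write("|".join(split) + f"\t{c}\n")


def _nontrivial_splits(tree: dendropy.Tree, all_taxa: frozenset[str]) -> set[tuple[str, ...]]:
    n = len(all_taxa)
    splits: set[tuple[str, ...]] = set()
    for s in _clade_leafsets(tree):
        if len(s) < 2 or len(s) > n - 2:
            continue
        side_a = tuple(sorted(s))
        side_b = tuple(sorted(all_taxa - s))
        splits.add(min(side_a, side_b))  # canonical: lexicographically smaller side
    return splits


def split_agreement(trees: Sequence[dendropy.Tree]) -> SplitProfile:
    """Count how often each nontrivial split occurs across trees on one taxon set."""
    if len(trees) < 2:
        raise ValueError("need at least two trees")
    taxon_sets = [frozenset(_leaf_labels(t)) for t in trees]
    if len(set(taxon_sets)) != 1:
        raise ValueError("trees are not on identical taxon sets")
    all_taxa = taxon_sets[0]
    counter: Counter[tuple[str, ...]] = Counter()
    for t in trees:
        counter.update(_nontrivial_splits(t, all_taxa))
    return SplitProfile(counts=dict(counter), n_trees=len(trees))
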