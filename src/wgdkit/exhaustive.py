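"""Exhaustive cross-checks for reconciliation.

This module provides an independent, brute-force definition of the
duplication/loss parsimony score: it enumerates *every* valid gene-to-species
node mapping (not just the LCA mapping) and scores each by explicitly walking
species-tree paths, then minimizes.  It also enumerates all canonical
species-labeled gene-tree topologies up to a leaf count, so the fast LCA
implementation can be validated against first principles on small instances.
"""
from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Iterator

from .trees import GeneTree, Node, SpeciesTree

# ---------------------------------------------------------------------------
# canonical enumeration of species-colored rooted binary topologies
# ---------------------------------------------------------------------------


def colored_topologies(n_leaves: int, colors: tuple[str, ...]):
    """All canonical rooted binary topologies with exactly ``n_leaves`` leaves,
    each leaf colored by a species name.  Trees are nested tuples; a leaf is a
    color string, an internal node a sorted pair of subtrees.  Canonical form
    (sorted children, deduplicated) quotients out child-order symmetry, to
    which reconciliation is invariant.
    """

    @lru_cache(maxsize=None)
    def gen(n: int) -> tuple:
        if n == 1:
            return tuple((c,) for c in colors)
        out = set()
        for k in range(1, n // 2 + 1):
            for left in gen(k):
                for right in gen(n - k):
                    out.add(tuple(sorted((left, right), key=repr)))
        return tuple(sorted(out, key=repr))

    return gen(n_leaves)


def topology_to_gene_tree(shape, convention=None) -> GeneTree:
    counter = itertools.count(1)

    def build(t) -> Node:
        node = Node()
        if len(t) == 1 and isinstance(t[0], str):
            node.species = t[0]
            node.gene_id = f"g{next(counter)}"
            return node
        for sub in t:
            node.add_child(build(sub))
        return node

    from .trees import DEFAULT_CONVENTION

    return GeneTree(build(shape), convention or DEFAULT_CONVENTION)


# ---------------------------------------------------------------------------
# brute-force duplication/loss minimization over all valid mappings
# ---------------------------------------------------------------------------


def _species_chain(st: SpeciesTree, top: Node, bottom: Node) -> list[Node]:
    """Species nodes from ``top`` down to ``bottom`` inclusive."""
    chain = [bottom]
    node = bottom
    while node is not top:
        node = node.parent
        if node is None:
            raise ValueError("top is not an ancestor of bottom")
        chain.append(node)
    chain.reverse()
    return chain


def _score_mapping(gt: GeneTree, st: SpeciesTree, mapping: dict[Node, Node]) -> tuple[int, int]:
    dups = 0
    losses = 0
    for node in gt.root.preorder():
        if node.is_leaf:
            continue
        s = mapping[node]
        if any(mapping[c] is s for c in node.children):
            is_dup = True
        else:
            # children map strictly below s: the node is a speciation only if
            # they descend through two different child branches of s
            branches = []
            for child in node.children:
                chain = _species_chain(st, s, mapping[child])
                branches.append(chain[1])
            is_dup = len(set(id(b) for b in branches)) < len(branches)
        dups += int(is_dup)
        for child in node.children:
            chain = _species_chain(st, s, mapping[child])
            # each skipped species node on the way down loses a sister lineage;
            # a duplication's copy additionally enters at the mapped node itself
            skipped = chain[:-1] if is_dup else chain[1:-1]
            losses += len(skipped)
    return dups, losses


def _valid_mappings(gt: GeneTree, st: SpeciesTree) -> Iterator[dict[Node, Node]]:
    nodes = list(gt.root.postorder())
    mapping: dict[Node, Node] = {}

    def ancestors_inclusive(s: Node) -> list[Node]:
        out = [s]
        while s.parent is not None:
            s = s.parent
            out.append(s)
        return out

    def assign(i: int) -> Iterator[dict[Node, Node]]:
        if i == len(nodes):
            yield dict(mapping)
            return
        node = nodes[i]
        if node.is_leaf:
            mapping[node] = st.leaf(node.species)
            yield from assign(i + 1)
            return
        low = mapping[node.children[0]]
        for child in node.children[1:]:
            low = st.lca(low, mapping[child])
        for candidate in ancestors_inclusive(low):
            mapping[node] = candidate
            yield from assign(i + 1)

    yield from assign(0)


def brute_force_min_events(gt: GeneTree, st: SpeciesTree) -> tuple[int, int]:
    """Minimum (duplications, losses) over every valid node mapping.

    Minimization is lexicographic: fewest duplications first, then fewest
    losses among duplication-minimal mappings.
    """
    best: tuple[int, int] | None = None
    for mapping in _valid_mappings(gt, st):
        score = _score_mapping(gt, st, mapping)
        if best is None or score < best:
            best = score
    assert best is not None
    return best
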