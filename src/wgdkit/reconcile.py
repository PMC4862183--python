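"""LCA gene-tree/species-tree reconciliation under duplication/loss parsimony.

Every gene-tree node is mapped to the last common ancestor (in the species
tree) of its leaf species.  An internal node is a duplication iff its mapping
coincides with one of its children's mappings; otherwise it is a speciation.
Losses are the classical parsimony count: each species-tree edge skipped by a
gene-tree edge implies a lost lineage, and a duplication whose child maps
strictly below it loses the sister branch at the duplication's own node.
"""
from __future__ import annotations

import dataclasses
from typing import Optional

from .trees import GeneTree, Node, SpeciesTree, TreeError

DUPLICATION = "duplication"
SPECIATION = "speciation"


class ReconcileError(TreeError):
    pass


@dataclasses.dataclass
class Reconciliation:
    gene_tree: GeneTree
    species_tree: SpeciesTree
    mapping: dict[Node, Node]
    event: dict[Node, str]
    duplication_count: int
    loss_count: int
    #: set when root_min_dup had to fall back to a secondary/tertiary tie-break
    tiebreak_used: bool = False

    def duplications(self) -> list[Node]:
        return [n for n, e in self.event.items() if e == DUPLICATION]


def lca_reconcile(gt: GeneTree, st: SpeciesTree) -> Reconciliation:
    """Standard LCA mapping; minimal duplication/loss counts for this rooting."""
    mapping: dict[Node, Node] = {}
    event: dict[Node, str] = {}
    for node in gt.root.postorder():
        if node.is_leaf:
            if node.species not in st.taxa:
                raise ReconcileError(
                    f"leaf {node.gene_id!r} has species {node.species!r} "
                    f"not present in the species tree"
                )
            mapping[node] = st.leaf(node.species)
        else:
            m = mapping[node.children[0]]
            for child in node.children[1:]:
                m = st.lca(m, mapping[child])
            mapping[node] = m
            is_dup = any(mapping[c] is m for c in node.children)
            event[node] = DUPLICATION if is_dup else SPECIATION
            node.event = event[node]

    dups = sum(1 for e in event.values() if e == DUPLICATION)
    losses = 0
    for node, ev in event.items():
        for child in node.children:
            d = st.depth[mapping[child]] - st.depth[mapping[node]]
            losses += d if ev == DUPLICATION else d - 1
    return Reconciliation(gt, st, mapping, event, dups, losses)


# ---------------------------------------------------------------------------
# rooting by duplication minimization
# ---------------------------------------------------------------------------

def _unrooted_adjacency(gt: GeneTree):
    """Adjacency map + edge support map of the unrooted topology.

    The rooted tree's two root edges collapse into a single unrooted edge.
    Returns (adjacency, edge_support, edges) with edges in a deterministic
    post-order enumeration.
    """
    adj: dict[Node, list[Node]] = {}
    support: dict[frozenset, Optional[float]] = {}

    def connect(a: Node, b: Node, s: Optional[float]):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
        support[frozenset((id(a), id(b)))] = s

    root = gt.root
    for node in root.preorder():
        for child in node.children:
            if node is root and len(root.children) == 2:
                continue  # handled below as one edge
            connect(node, child, child.support)
    if len(root.children) == 2:
        a, b = root.children
        s = a.support if a.support is not None else b.support
        connect(a, b, s)

    edges = []
    seen = set()
    for node in root.postorder():
        for nb in adj.get(node, []):
            key = frozenset((id(node), id(nb)))
            if key not in seen:
                seen.add(key)
                edges.append((node, nb))
    return adj, support, edges


def _build_rooted(edge, adj, support, convention, scale) -> GeneTree:
    a, b = edge

    def build(node: Node, prev: Node) -> Node:
        new = Node()
        new.species, new.gene_id, new.chromosome = node.species, node.gene_id, node.chromosome
        new.label = node.label
        neighbours = [n for n in adj[node] if n is not prev]
        if node.is_leaf and not neighbours:
            return new
        for nb in neighbours:
            child = build(nb, node)
            child.support = support[frozenset((id(node), id(nb)))]
            new.add_child(child)
        return new

    root = Node()
    left, right = build(a, b), build(b, a)
    s = support[frozenset((id(a), id(b)))]
    left.support = right.support = s
    root.add_child(left)
    root.add_child(right)
    return GeneTree(root, convention, support_scale=scale)


def root_min_dup(gt: GeneTree, st: SpeciesTree, outgroup: Optional[str] = None) -> Reconciliation:
    """Root an (un)rooted gene tree on the edge minimizing duplications.

    Ties are broken by loss count, then by preferring a rooting where one side
    of the root is exactly the outgroup-taxon leaves, then by edge enumeration
    order.  Returns the reconciliation of the winning rooted tree.
    """
    if len(gt) < 3:
        raise ReconcileError("rooting needs at least 3 leaves")
    adj, support, edges = _unrooted_adjacency(gt)
    scored = []
    for index, edge in enumerate(edges):
        candidate = _build_rooted(edge, adj, support, gt.convention, gt.support_scale)
        rec = lca_reconcile(candidate, st)
        if outgroup is not None:
            sides = [frozenset(l.species for l in c.leaves()) for c in candidate.root.children]
            og_rank = 0 if any(side == {outgroup} for side in sides) else 1
        else:
            og_rank = 1
        scored.append(((rec.duplication_count, rec.loss_count, og_rank, index), rec))
    key, rec = min(scored, key=lambda kr: kr[0])
    rec.tiebreak_used = sum(1 for k, _ in scored if k[:2] == key[:2]) > 1
    rec.gene_tree.name = gt.name
    return rec


def split_root_duplications(gt: GeneTree, st: SpeciesTree) -> list[GeneTree]:
    """Split duplication-rooted trees until every tree starts with a speciation.

    Single-leaf fragments are discarded; each surviving tree is independent
    and should be re-reconciled by the caller.
    """
    rec = lca_reconcile(gt, st)
    if rec.event.get(gt.root) != DUPLICATION:
        return [gt]
    out: list[GeneTree] = []
    for i, child in enumerate(gt.root.children):
        if child.is_leaf:
            continue
        sub = child.copy()
        sub.parent = None
        sub.support = None
        name = f"{gt.name}.{i}" if gt.name else None
        out.extend(split_root_duplications(
            GeneTree(sub, gt.convention, gt.support_scale, name), st))
    return out
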