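"""Gene and species trees, leaf-label conventions, and WGD branch annotations.

The species tree is the coordinate system every duplication is mapped onto.
Whole-genome duplication (WGD) events are attached to species-tree branches,
identified by the branch's child clade (the set of taxa below it).  Gene-tree
leaves carry ``(species, gene_id, chromosome)`` decoded from the newick leaf
label; the default convention is ``SPECIES|GENEID|CHROM`` with the chromosome
field optional.
"""
from __future__ import annotations

import dataclasses
import io
import re
from typing import Iterable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Base class for tree construction/validation errors."""


class NewickParseError(TreeError):
    """Malformed newick input (message carries the parser's position)."""


class LabelError(TreeError):
    """A leaf label does not match the declared convention."""


@dataclasses.dataclass(frozen=True)
class LabelConvention:
    """Field order and separator used to encode gene-leaf metadata in labels."""

    fields: tuple[str, ...] = ("species", "gene_id", "chromosome")
    sep: str = "|"

    def decode(self, label: str) -> dict[str, Optional[str]]:
        parts = label.split(self.sep)
        if len(parts) < 2 or len(parts) > len(self.fields):
            raise LabelError(
                f"leaf label {label!r} does not match convention "
                f"{self.sep.join(f.upper() for f in self.fields)}"
            )
        out: dict[str, Optional[str]] = {f: None for f in self.fields}
        for field, value in zip(self.fields, parts):
            out[field] = value if value != "" else None
        if out.get("species") is None or out.get("gene_id") is None:
            raise LabelError(f"leaf label {label!r} is missing species or gene id")
        return out

    def encode(self, species: str, gene_id: str, chromosome: Optional[str] = None) -> str:
        values = {"species": species, "gene_id": gene_id, "chromosome": chromosome or ""}
        for field, value in values.items():
            if value and self.sep in value:
                raise LabelError(f"{field} value {value!r} contains the separator {self.sep!r}")
        return self.sep.join(values[f] for f in self.fields)


DEFAULT_CONVENTION = LabelConvention()


class Node:
    """A node of a (gene or species) tree.

    ``support`` is stored normalized to [0, 1]; ``timing`` and ``event`` are
    filled in by reconciliation/classification.
    """

    __slots__ = (
        "children",
        "parent",
        "label",
        "support",
        "species",
        "gene_id",
        "chromosome",
        "event",
        "timing",
    )

    def __init__(self, label: Optional[str] = None):
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.label = label
        self.support: Optional[float] = None
        self.species: Optional[str] = None
        self.gene_id: Optional[str] = None
        self.chromosome: Optional[str] = None
        self.event: Optional[str] = None
        self.timing: Optional[str] = None

    # -- structure ---------------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def path_to_root(self) -> list["Node"]:
        out, node = [], self
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def copy(self) -> "Node":
        new = Node(self.label)
        new.support = self.support
        new.species, new.gene_id, new.chromosome = self.species, self.gene_id, self.chromosome
        new.event, new.timing = self.event, self.timing
        for child in self.children:
            new.add_child(child.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"<Leaf {self.species}|{self.gene_id}>"
        return f"<Node n_leaves={len(self.leaves())} event={self.event} timing={self.timing}>"


class GeneTree:
    """A tree over gene copies; leaves carry (species, gene_id, chromosome)."""

    def __init__(self, root: Node, convention: LabelConvention = DEFAULT_CONVENTION,
                 support_scale: float = 1.0, name: Optional[str] = None):
        self.root = root
        self.convention = convention
        self.support_scale = support_scale
        self.name = name
        if len(root.leaves()) < 2:
            raise TreeError("a gene tree needs at least 2 leaves")

    @property
    def rooted(self) -> bool:
        return len(self.root.children) == 2

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def species_set(self) -> set[str]:
        return {leaf.species for leaf in self.leaves()}

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy(), self.convention, self.support_scale, self.name)

    def __len__(self) -> int:
        return len(self.leaves())


class SpeciesTree:
    """Rooted binary species tree with named WGD events on branches.

    Events are attached to the branch above a node; the node is identified by
    its clade (set of descendant taxa).  Nested events must be ordered: an
    event of a later round (numeric prefix of its name, e.g. ``3R`` < ``4R``)
    must lie strictly below any earlier round on the same root-to-leaf path.
    """

    def __init__(self, root: Node):
        self.root = root
        self._index()
        self.wgd_events: dict[str, Node] = {}

    def _index(self) -> None:
        leaves = self.root.leaves()
        names = [leaf.label for leaf in leaves]
        if len(names) != len(set(names)):
            raise TreeError("species tree taxon names must be unique")
        for node in self.root.preorder():
            if not node.is_leaf and len(node.children) != 2:
                raise TreeError("polytomies are not allowed in species trees")
        self.taxa = set(names)
        self._leaf_by_name = {leaf.label: leaf for leaf in leaves}
        self.depth: dict[Node, int] = {}
        self.clade: dict[Node, frozenset[str]] = {}
        for node in self.root.preorder():
            self.depth[node] = 0 if node.parent is None else self.depth[node.parent] + 1
        for node in self.root.postorder():
            if node.is_leaf:
                self.clade[node] = frozenset([node.label])
            else:
                self.clade[node] = frozenset().union(*(self.clade[c] for c in node.children))
        self._node_by_clade = {clade: node for node, clade in self.clade.items()}

    # -- queries -----------------------------------------------------------
    def leaf(self, taxon: str) -> Node:
        try:
            return self._leaf_by_name[taxon]
        except KeyError:
            raise TreeError(f"unknown taxon {taxon!r}") from None

    def node_for_clade(self, taxa: Iterable[str]) -> Node:
        clade = frozenset(taxa)
        node = self._node_by_clade.get(clade)
        if node is None:
            raise TreeError(f"no species-tree branch has child clade {sorted(clade)}")
        return node

    def lca(self, a: Node, b: Node) -> Node:
        while self.depth[a] > self.depth[b]:
            a = a.parent
        while self.depth[b] > self.depth[a]:
            b = b.parent
        while a is not b:
            a, b = a.parent, b.parent
        return a

    def is_ancestor(self, a: Node, b: Node, strict: bool = False) -> bool:
        """True iff ``a`` is an ancestor of ``b`` (equal counts unless strict)."""
        if a is b:
            return not strict
        node = b.parent
        while node is not None:
            if node is a:
                return True
            node = node.parent
        return False

    def distance(self, a: Node, b: Node) -> int:
        anc = self.lca(a, b)
        return (self.depth[a] - self.depth[anc]) + (self.depth[b] - self.depth[anc])

    # -- WGD annotation ----------------------------------------------------
    @staticmethod
    def _round_of(name: str) -> Optional[int]:
        m = re.match(r"(\d+)", name)
        return int(m.group(1)) if m else None

    def annotate_wgd(self, event_name: str, clade: Iterable[str]) -> "SpeciesTree":
        if event_name in self.wgd_events:
            raise TreeError(f"duplicate WGD event name {event_name!r}")
        node = self.node_for_clade(clade)
        for other_name, other_node in self.wgd_events.items():
            if other_node is node:
                raise TreeError(
                    f"branch above clade {sorted(self.clade[node])} already carries "
                    f"event {other_name!r}"
                )
            if self.is_ancestor(node, other_node) or self.is_ancestor(other_node, node):
                r_new, r_old = self._round_of(event_name), self._round_of(other_name)
                if r_new is not None and r_old is not None:
                    ancestral, descendant = (
                        (event_name, other_name) if self.is_ancestor(node, other_node)
                        else (other_name, event_name)
                    )
                    if self._round_of(ancestral) > self._round_of(descendant):
                        raise TreeError(
                            f"WGD ordering violated: {ancestral} cannot be ancestral "
                            f"to {descendant}"
                        )
        self.wgd_events[event_name] = node
        return self

    def wgd_rounds(self) -> list[tuple[str, Node]]:
        """Events sorted root-ward first (by depth, then by numeric round)."""
        return sorted(
            self.wgd_events.items(),
            key=lambda kv: (self.depth[kv[1]], self._round_of(kv[0]) or 0),
        )


# ---------------------------------------------------------------------------
# newick I/O (parsing via dendropy; writing is a small local serializer)
# ---------------------------------------------------------------------------

def _dendropy_tree(text: str) -> dendropy.Tree:
    if not text or not text.strip():
        raise NewickParseError("empty newick string")
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from None


def _convert(dnode, resolve_polytomies: bool) -> Node:
    node = Node()
    children = dnode.child_nodes()
    if not children:
        node.label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
        return node
    node.label = dnode.label
    for child in children:
        node.add_child(_convert(child, resolve_polytomies))
    if resolve_polytomies:
        while len(node.children) > 2:
            a = node.children.pop(0)
            b = node.children.pop(0)
            joint = Node()
            joint.support = 0.0
            joint.add_child(a)
            joint.add_child(b)
            a.parent = b.parent = joint
            joint.parent = node
            node.children.insert(0, joint)
    return node


def _assign_supports(root: Node) -> float:
    """Interpret numeric internal labels as supports; return the input scale."""
    values = []
    for node in root.preorder():
        if node.is_leaf or node.parent is None:
            continue
        if node.label is not None:
            try:
                values.append((node, float(node.label)))
            except ValueError:
                continue
    if not values:
        return 1.0
    scale = 100.0 if max(v for _, v in values) > 1.0 else 1.0
    for node, value in values:
        node.support = value / scale
        node.label = None
    return scale


def parse_gene_tree(text: str, convention: LabelConvention = DEFAULT_CONVENTION,
                    name: Optional[str] = None) -> GeneTree:
    dtree = _dendropy_tree(text)
    root = _convert(dtree.seed_node, resolve_polytomies=False)
    # a trifurcating root encodes an unrooted tree; deeper polytomies are
    # resolved arbitrarily with zero support
    for node in list(root.preorder()):
        limit = 3 if node is root else 2
        while len(node.children) > limit:
            a = node.children.pop(0)
            b = node.children.pop(0)
            joint = Node()
            joint.support = 0.0
            joint.add_child(a)
            joint.add_child(b)
            joint.parent = node
            node.children.insert(0, joint)
    scale = _assign_supports(root)
    n_leaves = 0
    for leaf in root.leaves():
        meta = convention.decode(leaf.label or "")
        leaf.species = meta.get("species")
        leaf.gene_id = meta.get("gene_id")
        leaf.chromosome = meta.get("chromosome")
        n_leaves += 1
    if n_leaves < 2:
        raise TreeError("a gene tree needs at least 2 leaves")
    gene_ids = [leaf.gene_id for leaf in root.leaves()]
    if len(gene_ids) != len(set(gene_ids)):
        raise TreeError("gene ids must be unique within a family")
    return GeneTree(root, convention, support_scale=scale, name=name)


def parse_species_tree(text: str) -> SpeciesTree:
    dtree = _dendropy_tree(text)
    root = _convert(dtree.seed_node, resolve_polytomies=False)
    _assign_supports(root)
    return SpeciesTree(root)


def parse_newick(text: str, label_convention: Optional[LabelConvention] = DEFAULT_CONVENTION):
    """Parse newick into a GeneTree (with a convention) or SpeciesTree (None)."""
    if label_convention is None:
        return parse_species_tree(text)
    return parse_gene_tree(text, label_convention)


_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}:;,']")


def _format_label(label: str) -> str:
    if _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_num(x: float) -> str:
    s = f"{x:.6g}"
    return s


def write_newick(tree, include_support: bool = True, event_tags: bool = False) -> str:
    """Serialize a GeneTree or SpeciesTree back to newick.

    With ``event_tags`` each internal node gets a ``[&&event=...,timing=...]``
    comment recording reconciliation/classification results.
    """
    if isinstance(tree, SpeciesTree):
        root, convention, scale = tree.root, None, 1.0
    else:
        root, convention, scale = tree.root, tree.convention, tree.support_scale

    def render(node: Node) -> str:
        if node.is_leaf:
            if convention is not None and node.species is not None:
                label = convention.encode(node.species, node.gene_id, node.chromosome)
            else:
                label = node.label or ""
            return _format_label(label)
        inner = ",".join(render(c) for c in node.children)
        out = f"({inner})"
        if include_support and node.support is not None and node.parent is not None:
            out += _fmt_num(node.support * scale)
        elif node.label:
            out += _format_label(node.label)
        if event_tags and node.event is not None:
            tag = f"event={node.event}"
            if node.timing is not None:
                tag += f",timing={node.timing}"
            out += f"[&&{tag}]"
        return out

    return render(root) + ";"


# ---------------------------------------------------------------------------
# the default study system: seven teleost taxa, nested 3R and 4R events
# ---------------------------------------------------------------------------

GAR, ZEBRAFISH, TILAPIA, FUGU, PIKE, SALMON, TROUT = (
    "gar", "zebrafish", "tilapia", "fugu", "pike", "salmon", "trout",
)
TELEOSTS = (ZEBRAFISH, TILAPIA, FUGU, PIKE, SALMON, TROUT)
SALMONIDS = (SALMON, TROUT)


def teleost_species_tree() -> SpeciesTree:
    """Seven-taxon species tree: gar outgroup, 3R on the teleost stem, 4R on
    the salmonid stem."""
    st = parse_species_tree(
        "(gar,(zebrafish,((tilapia,fugu),(pike,(salmon,trout)))));"
    )
    st.annotate_wgd("3R", TELEOSTS)
    st.annotate_wgd("4R", SALMONIDS)
    return st


def species_tree_from_config(config: dict) -> SpeciesTree:
    """Build a WGD-annotated species tree from a config mapping.

    Expected keys: ``newick`` (string) and ``wgd`` (mapping of event name to
    the list of taxa below the event's branch).
    """
    st = parse_species_tree(config["newick"])
    for name, clade in config.get("wgd", {}).items():
        st.annotate_wgd(name, clade)
    return st
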