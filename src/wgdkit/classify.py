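"""Assign duplication nodes a timing class relative to nested WGD events.

For the salmonid system the classes are ``3R`` (teleost WGD), ``4R``
(salmonid WGD), ``post3R_pre4R`` (small-scale duplication between the two),
``post4R`` (salmonid-lineage small-scale duplication) and ``pre3R``
(outgroup-lineage small-scale duplication, outside the teleost clade).

Classification proceeds root-down over a reconciled gene tree:

1.  A duplication mapped exactly to a WGD branch's child node is that WGD,
    unless the root-to-node path already carries the same WGD (per-lineage
    limit: one event per known WGD), in which case it is demoted to the
    small-scale class of the interval below that WGD.
2.  A duplication mapped strictly between the two WGD branches is
    unambiguously a between-WGD small-scale duplication.
3.  A duplication mapped below a WGD branch (or to a non-focal side branch)
    is ambiguous: it may be a small-scale duplication or a loss-eroded WGD.
    The chromosome check fires first (all focal-species descendants on one
    chromosome on both sides -> tandem small-scale duplication); otherwise the
    ancestral-WGD heuristic applies: if the relevant WGD already occurs on the
    path the node is a small-scale duplication, else it is declared the WGD.
4.  In relaxed mode, a further pass promotes weakly supported small-scale
    calls adjacent to the most recent WGD branch to that WGD on focal-species
    paths where it was not found; rigid mode skips this pass.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Optional

from .reconcile import DUPLICATION, Reconciliation, lca_reconcile
from .trees import GeneTree, Node, SpeciesTree, TreeError

EVIDENCE_TOPOLOGY = "topology"
EVIDENCE_CHROMOSOME = "chromosome"
EVIDENCE_ANCESTRAL = "heuristic_ancestral"
EVIDENCE_RELAXED = "relaxed_promotion"


@dataclasses.dataclass
class DupEvent:
    family: Optional[str]
    node_id: str
    node: Node
    timing: str
    evidence: frozenset[str]
    chromosomes_left: frozenset[str]
    chromosomes_right: frozenset[str]
    mapped_clade: frozenset[str]
    support: Optional[float] = None


@dataclasses.dataclass
class ClassifiedFamily:
    family: Optional[str]
    tree: GeneTree
    reconciliation: Reconciliation
    events: list[DupEvent]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev.timing] = out.get(ev.timing, 0) + 1
        return out


class WgdClassifier:
    """Timing classifier for a species tree carrying two nested WGD events.

    Parameters
    ----------
    st:
        Species tree annotated with exactly two WGD events, the first
        strictly ancestral to the second (e.g. 3R and 4R).
    focal:
        Focal taxon whose chromosome assignments drive the tandem check.
    mode:
        ``"rigid"`` (topology taken at face value) or ``"relaxed"``
        (weakly supported misplacements near the recent WGD are promoted).
    support_threshold:
        Supports below this are treated as phylogenetic noise by the
        relaxed pass.
    promote_distance:
        Maximum species-tree edge distance between a candidate's mapped
        node and the recent WGD branch for relaxed promotion.
    """

    def __init__(self, st: SpeciesTree, focal: str, mode: str = "rigid",
                 support_threshold: float = 0.7, promote_distance: int = 1):
        rounds = st.wgd_rounds()
        if len(rounds) != 2:
            raise TreeError("classification requires exactly two annotated WGD events")
        (self.w1, self.node1), (self.w2, self.node2) = rounds
        if not st.is_ancestor(self.node1, self.node2, strict=True):
            raise TreeError("the first WGD must be strictly ancestral to the second")
        if focal not in st.taxa:
            raise TreeError(f"unknown focal taxon {focal!r}")
        if mode not in ("rigid", "relaxed"):
            raise TreeError(f"mode must be 'rigid' or 'relaxed', got {mode!r}")
        self.st = st
        self.focal = focal
        self.mode = mode
        self.support_threshold = support_threshold
        self.promote_distance = promote_distance
        self.between_class = f"post{self.w1}_pre{self.w2}"
        self.after_class = f"post{self.w2}"
        self.before_class = f"pre{self.w1}"

    # -- helpers -----------------------------------------------------------
    @property
    def classes(self) -> tuple[str, ...]:
        return (self.w1, self.w2, self.between_class, self.after_class, self.before_class)

    def interval_below(self, wgd_name: str) -> str:
        return self.between_class if wgd_name == self.w1 else self.after_class

    def _focal_chromosomes(self, node: Node) -> frozenset[str]:
        return frozenset(
            leaf.chromosome for leaf in node.leaves()
            if leaf.species == self.focal and leaf.chromosome
        )

    def _zone(self, m: Node):
        st = self.st
        if m is self.node1:
            return ("wgd", self.w1)
        if m is self.node2:
            return ("wgd", self.w2)
        if st.is_ancestor(self.node1, m, strict=True) and st.is_ancestor(m, self.node2, strict=True):
            return ("fixed", self.between_class)
        if st.is_ancestor(self.node2, m, strict=True):
            return ("ambiguous", self.w2)
        if st.is_ancestor(self.node1, m, strict=True):
            return ("ambiguous", self.w1)
        return ("fixed", self.before_class)

    @staticmethod
    def _events_above(node: Node) -> set[str]:
        out = set()
        anc = node.parent
        while anc is not None:
            if anc.timing is not None:
                out.add(anc.timing)
            anc = anc.parent
        return out

    def _ssd_class_for(self, m: Node) -> str:
        return (self.after_class
                if self.st.is_ancestor(self.node2, m, strict=True)
                else self.between_class)

    # -- classification ----------------------------------------------------
    def classify_family(self, gt: GeneTree, family: Optional[str] = None,
                        rec: Optional[Reconciliation] = None) -> ClassifiedFamily:
        """Classify every duplication node of a speciation-rooted gene tree."""
        family = family if family is not None else gt.name
        if rec is None:
            rec = lca_reconcile(gt, self.st)
        for node in gt.root.preorder():
            node.timing = None

        events: list[DupEvent] = []
        for node in gt.root.preorder():
            if rec.event.get(node) != DUPLICATION:
                continue
            m = rec.mapping[node]
            kind, value = self._zone(m)
            evidence = {EVIDENCE_TOPOLOGY}
            if kind == "fixed":
                timing = value
            elif kind == "wgd":
                timing = (self.interval_below(value)
                          if value in self._events_above(node) else value)
            else:  # ambiguous: tandem check first, then ancestral-WGD heuristic
                left = self._focal_chromosomes(node.children[0])
                right = self._focal_chromosomes(node.children[1])
                if left and right and len(left | right) == 1:
                    timing = self._ssd_class_for(m)
                    evidence = {EVIDENCE_CHROMOSOME}
                else:
                    evidence = {EVIDENCE_ANCESTRAL}
                    timing = (self.interval_below(value)
                              if value in self._events_above(node) else value)
            node.timing = timing
            events.append(self._event(family, node, rec, timing, evidence))

        fam = ClassifiedFamily(family, gt, rec, events)
        if self.mode == "relaxed":
            self._relaxed_pass(fam)
        return fam

    def _event(self, family, node, rec, timing, evidence) -> DupEvent:
        leaves = node.leaves()
        node_id = f"{leaves[0].gene_id}~{leaves[-1].gene_id}"
        return DupEvent(
            family=family,
            node_id=node_id,
            node=node,
            timing=timing,
            evidence=frozenset(evidence),
            chromosomes_left=self._focal_chromosomes(node.children[0]),
            chromosomes_right=self._focal_chromosomes(node.children[1]),
            mapped_clade=rec.species_tree.clade[rec.mapping[node]],
            support=node.support,
        )

    # -- relaxed promotion -------------------------------------------------
    def _weakly_supported(self, node: Node) -> bool:
        supports = [node.support] + [c.support for c in node.children]
        present = [s for s in supports if s is not None]
        if len(present) < len(supports):
            return True  # missing support counts as unknown, hence weak
        return min(present) < self.support_threshold

    def _relaxed_pass(self, fam: ClassifiedFamily) -> None:
        rec = fam.reconciliation
        by_node = {ev.node: ev for ev in fam.events}
        focal_leaves = [l for l in fam.tree.leaves() if l.species == self.focal]
        for leaf in focal_leaves:
            path = leaf.path_to_root()
            if any(n.timing == self.w2 for n in path):
                continue
            candidates = [
                n for n in path
                if n.timing in (self.between_class, self.after_class)
                and self.st.distance(rec.mapping[n], self.node2) <= self.promote_distance
            ]
            # most root-ward candidate first: promoting it covers the path
            candidates.sort(key=lambda n: -len(n.path_to_root()))
            for node in reversed(candidates):
                left = self._focal_chromosomes(node.children[0])
                right = self._focal_chromosomes(node.children[1])
                if not left or not right or (left & right):
                    continue
                if not self._weakly_supported(node):
                    continue
                node.timing = self.w2
                ev = by_node[node]
                ev.timing = self.w2
                ev.evidence = ev.evidence | {EVIDENCE_RELAXED}
                break


def classify_families(trees: Iterable[GeneTree], st: SpeciesTree, focal: str,
                      mode: str = "rigid", **kwargs) -> list[ClassifiedFamily]:
    clf = WgdClassifier(st, focal, mode=mode, **kwargs)
    return [clf.classify_family(gt) for gt in trees]
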