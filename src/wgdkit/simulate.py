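"""Synthetic gene families, interaction sets and expression triplets with
known ground truth.

The family simulator walks gene lineages down a WGD-annotated species tree:
at each WGD branch a lineage retains the duplicate with the class retention
probability; small-scale duplications (SSDs) appear as presence draws on the
between-WGD backbone (mapping to the first speciation below the ancient WGD
on the path toward the recent one) and on the focal species' terminal branch
(tandem, sharing the parent's chromosome token).  WGD copies receive
distinct chromosome tokens, tandem copies share one - the minimal chromosome
model that makes the tandem-vs-WGD heuristic exercisable.  Optional topology
noise applies a nearest-neighbour interchange (NNI) around a retained
recent-WGD duplication and lowers the rearranged edge's support, emulating
the phylogenetic error the relaxed classification mode is designed to
absorb.

Expression triplets use tissue-program profiles: conserved and
neofunctionalized genes are dominant-tissue programs (a neofunctionalized
duplicate acquires a new dominant tissue), while subfunctionalization starts
from a broadly expressed ancestor whose on-tissues the duplicates partition
into complementary halves, so each half correlates weakly with the ancestor
but their sum reconstitutes it.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import pandas as pd

from .coretention import InteractionSet
from .expression import CONSERVED, NEOFUNCTIONALIZED, SUBFUNCTIONALIZED
from .trees import GeneTree, Node, SpeciesTree, teleost_species_tree


class SimulationError(ValueError):
    pass


@dataclasses.dataclass
class SimParams:
    """Retention-model parameters for the family simulator.

    Probabilities are per surviving lineage crossing the respective branch;
    ``ssd_rate`` is the expected number of SSDs per lineage per interval
    (converted to a presence probability ``1 - exp(-rate * retention)``),
    unless the explicit conditional presence probabilities are given.
    """

    q3: float = 0.55
    q4: float = 0.50
    q4_given_3R: Optional[float] = None
    ssd_rate: float = 0.3
    ssd_retention: float = 0.5
    p34_prob_given_3R: Optional[float] = None
    p34_prob_no_3R: Optional[float] = None
    post4R_prob_given_4R: Optional[float] = None
    post4R_prob_no_4R: Optional[float] = None
    partner_rho: float = 0.0
    topo_noise: float = 0.0
    base_support: float = 0.95
    noise_support: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("q3", "q4", "ssd_retention", "partner_rho", "topo_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.ssd_rate < 0:
            raise SimulationError("ssd_rate must be >= 0")

    @property
    def ssd_presence(self) -> float:
        return 1.0 - math.exp(-self.ssd_rate * self.ssd_retention)

    def p34_prob(self, had_3r: bool) -> float:
        if had_3r and self.p34_prob_given_3R is not None:
            return self.p34_prob_given_3R
        if not had_3r and self.p34_prob_no_3R is not None:
            return self.p34_prob_no_3R
        return self.ssd_presence

    def post4r_prob(self, had_4r: bool) -> float:
        if had_4r and self.post4R_prob_given_4R is not None:
            return self.post4R_prob_given_4R
        if not had_4r and self.post4R_prob_no_4R is not None:
            return self.post4R_prob_no_4R
        return self.ssd_presence


@dataclasses.dataclass
class FamilyTruth:
    family: str
    three_r: bool
    #: per recent-WGD crossing lineage: retained flag and ancestral context
    four_r: list[dict]
    between: list[dict]
    post4r: list[dict]
    noise_applied: bool = False

    @property
    def n_4r_true(self) -> int:
        return sum(row["retained"] for row in self.four_r)


class FamilySimulator:
    """Simulate gene families over a two-WGD species tree (default: the
    seven-taxon teleost tree with 3R and 4R)."""

    def __init__(self, params: SimParams, st: Optional[SpeciesTree] = None,
                 focal: str = "salmon"):
        self.params = params
        self.st = st if st is not None else teleost_species_tree()
        rounds = self.st.wgd_rounds()
        if len(rounds) != 2:
            raise SimulationError("the simulator needs exactly two WGD events")
        (self.w1, self.node1), (self.w2, self.node2) = rounds
        if focal not in self.st.clade[self.node2]:
            raise SimulationError("the focal taxon must descend from the recent WGD")
        self.focal = focal
        # the between-WGD SSD site: first node below the ancient WGD on the
        # path toward the recent WGD branch
        node = self.node2
        while node.parent is not self.node1:
            node = node.parent
        self.p34_site = node
        self.rng = np.random.default_rng(params.seed)

    # -- single family -----------------------------------------------------
    def sim_family(self, family: str) -> tuple[GeneTree, FamilyTruth]:
        rng = self.rng
        self._gene_counter = 0
        self._chrom_counter = 0
        truth = FamilyTruth(family, False, [], [], [])

        def new_chrom() -> int:
            self._chrom_counter += 1
            return self._chrom_counter

        def leaf(species: str, chrom: int) -> Node:
            self._gene_counter += 1
            node = Node()
            node.species = species
            node.gene_id = f"{family}_{species}_{self._gene_counter}"
            node.chromosome = f"{species[:3]}{chrom}"
            return node

        def dup(left: Node, right: Node) -> Node:
            node = Node()
            node.add_child(left)
            node.add_child(right)
            return node

        def lineage(snode, chrom: int, had: frozenset) -> Node:
            # events on the branch above snode, processed root-ward first
            if snode is self.node1:
                retained = rng.random() < self.params.q3
                truth.three_r = truth.three_r or retained
                if retained:
                    ctx = had | {self.w1}
                    return dup(below(snode, chrom, ctx), below(snode, new_chrom(), ctx))
                return below(snode, chrom, had)
            if snode is self.node2:
                q = self.params.q4
                if self.w1 in had and self.params.q4_given_3R is not None:
                    q = self.params.q4_given_3R
                retained = rng.random() < q
                truth.four_r.append({
                    "retained": retained,
                    "had_3R": self.w1 in had, "had_p34": "p34" in had,
                })
                if retained:
                    ctx = had | {self.w2}
                    return dup(below(snode, chrom, ctx), below(snode, new_chrom(), ctx))
                return below(snode, chrom, had)
            if snode is self.p34_site:
                present = rng.random() < self.params.p34_prob(self.w1 in had)
                truth.between.append({"retained": present, "had_3R": self.w1 in had})
                if present:
                    ctx = had | {"p34"}
                    return dup(below(snode, chrom, ctx), below(snode, chrom, ctx))
                return below(snode, chrom, had)
            if snode.is_leaf and snode.label == self.focal:
                present = rng.random() < self.params.post4r_prob(self.w2 in had)
                truth.post4r.append({
                    "retained": present,
                    "had_4R": self.w2 in had, "had_3R": self.w1 in had,
                })
                if present:
                    return dup(leaf(self.focal, chrom), leaf(self.focal, chrom))
                return leaf(self.focal, chrom)
            return below(snode, chrom, had)

        def below(snode, chrom: int, had: frozenset) -> Node:
            if snode.is_leaf:
                return leaf(snode.label, chrom)
            node = Node()
            for child in snode.children:
                node.add_child(lineage(child, chrom, had))
            return node

        root = below(self.st.root, new_chrom(), frozenset())
        for node in root.preorder():
            if not node.is_leaf and node.parent is not None:
                node.support = self.params.base_support
        tree = GeneTree(root, name=family)
        if self.params.topo_noise > 0 and rng.random() < self.params.topo_noise:
            truth.noise_applied = self._apply_nni(tree)
        return tree, truth

    def _apply_nni(self, tree: GeneTree) -> bool:
        """Displace one retained recent-WGD duplication by an NNI across its
        parent edge, lowering the rearranged edge's support."""
        st = self.st
        candidates = []
        for node in tree.root.preorder():
            if node.is_leaf or node.parent is None or len(node.children) != 2:
                continue
            # a recent-WGD duplication: both children span the WGD clade
            sides = [{l.species for l in c.leaves()} for c in node.children]
            wgd_taxa = set(st.clade[self.node2])
            if all(side and side <= wgd_taxa for side in sides) and \
                    all(len(side) > 1 for side in sides):
                if len(node.parent.children) == 2:
                    candidates.append(node)
        if not candidates:
            return False
        d = candidates[int(self.rng.integers(len(candidates)))]
        parent = d.parent
        sibling = next(c for c in parent.children if c is not d)
        c2 = d.children[1]
        # exchange sibling and c2
        d.children[1] = sibling
        sibling.parent = d
        parent.children[parent.children.index(sibling)] = c2
        c2.parent = parent
        d.support = self.params.noise_support
        return True

    def sim_families(self, n: int, prefix: str = "fam") -> list[tuple[GeneTree, FamilyTruth]]:
        return [self.sim_family(f"{prefix}{i:05d}") for i in range(n)]


def sim_families(n: int, params: SimParams, st: Optional[SpeciesTree] = None,
                 focal: str = "salmon") -> list[tuple[GeneTree, FamilyTruth]]:
    return FamilySimulator(params, st, focal).sim_families(n)


# ---------------------------------------------------------------------------
# interacting-partner retention
# ---------------------------------------------------------------------------


def sim_interactions(n_pairs: int, params: SimParams, marginal: Optional[float] = None,
                     n_isolated: int = 0) -> tuple[InteractionSet, dict[str, bool]]:
    """Interacting pairs with bivariate-Bernoulli retention.

    Both partners are retained marginally with probability ``marginal``
    (default: the recent-WGD retention ``q4``); the pair correlation is
    ``partner_rho``: P(both) = q^2 + rho * q * (1 - q).  ``rho = 0``
    reproduces independence.  ``n_isolated`` extra genes without partners
    are drawn with the marginal probability.
    """
    q = params.q4 if marginal is None else marginal
    rho = params.partner_rho
    if not 0.0 < q < 1.0:
        raise SimulationError("marginal retention must lie strictly in (0, 1)")
    p11 = q * q + rho * q * (1 - q)
    p1_given_1 = p11 / q
    p1_given_0 = (q - p11) / (1 - q)
    if not (0 <= p1_given_1 <= 1 and 0 <= p1_given_0 <= 1):
        raise SimulationError(f"infeasible (rho={rho}, q={q}) combination")
    rng = np.random.default_rng(params.seed)
    pairs: set[frozenset] = set()
    retained: dict[str, bool] = {}
    for i in range(n_pairs):
        a, b = f"pair{i:05d}a", f"pair{i:05d}b"
        ra = rng.random() < q
        rb = rng.random() < (p1_given_1 if ra else p1_given_0)
        retained[a], retained[b] = bool(ra), bool(rb)
        pairs.add(frozenset((a, b)))
    for i in range(n_isolated):
        retained[f"solo{i:05d}"] = bool(rng.random() < q)
    return InteractionSet(pairs, "binding"), retained


# ---------------------------------------------------------------------------
# expression triplets
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ExprSimParams:
    n_tissues: int = 15
    class_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)  # conserved, neo, sub
    noise_sd: float = 0.2
    #: expression level of an active tissue (log-space mean) and background
    high: float = 8.0
    low: float = 0.5
    level_sd: float = 0.10
    #: tissues where the broadly expressed ancestor of a subfunctionalized
    #: pair is inactive
    sub_off_tissues: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_tissues < 4:
            raise SimulationError("need at least 4 tissues")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise SimulationError("class mix must sum to 1")


def sim_triplets(params: ExprSimParams, n: int):
    """Simulate ``n`` duplicate/outgroup triplets with known divergence class.

    Returns ``(dup_matrix, outgroup_matrix, triplet_table, truth)`` where the
    matrices are genes x tissues DataFrames, the table holds the
    (dup1, dup2, outgroup_ortholog) ids, and truth is the list of true class
    labels in triplet order.
    """
    rng = np.random.default_rng(params.seed)
    T = params.n_tissues
    tissues = [f"tissue{t + 1:02d}" for t in range(T)]

    def program(dominant: int) -> np.ndarray:
        prof = np.exp(rng.normal(np.log(params.low), params.level_sd, size=T))
        prof[dominant] = np.exp(rng.normal(np.log(params.high), params.level_sd))
        return prof

    def broad(off_tissues: np.ndarray) -> np.ndarray:
        prof = np.exp(rng.normal(np.log(params.high), params.level_sd, size=T))
        prof[off_tissues] = np.exp(
            rng.normal(np.log(params.low), params.level_sd, size=len(off_tissues)))
        return prof

    def noisy(prof: np.ndarray) -> np.ndarray:
        if params.noise_sd == 0:
            return prof.copy()
        return prof * np.exp(rng.normal(0.0, params.noise_sd, size=T))

    classes = rng.choice(
        [CONSERVED, NEOFUNCTIONALIZED, SUBFUNCTIONALIZED],
        size=n, p=list(params.class_mix))
    dup_rows, og_rows, table_rows, truth = {}, {}, [], []
    for i, cls in enumerate(classes):
        d1, d2, og_id = f"t{i:05d}.1", f"t{i:05d}.2", f"og{i:05d}"
        if cls == SUBFUNCTIONALIZED:
            order = rng.permutation(T)
            off, on_tissues = order[:params.sub_off_tissues], order[params.sub_off_tissues:]
            og = broad(off)
            half = len(on_tissues) // 2
            # the tissue partition is inherited; absolute levels have drifted,
            # so each half gets fresh on-levels rather than the ancestor's
            dup1, dup2 = np.zeros(T), np.zeros(T)
            dup1[on_tissues[:half]] = np.exp(
                rng.normal(np.log(params.high), params.level_sd, size=half))
            dup2[on_tissues[half:]] = np.exp(
                rng.normal(np.log(params.high), params.level_sd,
                           size=len(on_tissues) - half))
            dup1, dup2 = noisy(dup1), noisy(dup2)
        elif cls == NEOFUNCTIONALIZED:
            dom = int(rng.integers(T))
            og = program(dom)
            new_dom = int(rng.integers(T - 1))
            if new_dom >= dom:
                new_dom += 1
            dup1, dup2 = noisy(og), noisy(program(new_dom))
            if rng.random() < 0.5:
                dup1, dup2 = dup2, dup1
        else:
            og = program(int(rng.integers(T)))
            dup1, dup2 = noisy(og), noisy(og)
        dup_rows[d1], dup_rows[d2], og_rows[og_id] = dup1, dup2, og
        table_rows.append({"dup1": d1, "dup2": d2, "outgroup_ortholog": og_id})
        truth.append(str(cls))
    dup_matrix = pd.DataFrame.from_dict(dup_rows, orient="index", columns=tissues)
    og_matrix = pd.DataFrame.from_dict(og_rows, orient="index", columns=tissues)
    return dup_matrix, og_matrix, pd.DataFrame(table_rows), truth
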