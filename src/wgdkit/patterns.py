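"""Canonical duplicate-retention patterns for the two-WGD teleost system.

Sixteen reference gene-tree topologies (named ``a`` through ``p``) span the
combinations of retained 3R / 4R duplicates and small-scale duplications a
salmonid gene family can exhibit, from the fully duplicated case down to a
family whose topology matches the species tree.  Each pattern carries the
per-class duplication counts its topology encodes, making the set a golden
suite for the timing classifier.  Tandem copies share a chromosome token;
WGD copies lie on distinct chromosomes.
"""
from __future__ import annotations

import itertools

from .trees import GeneTree, parse_gene_tree

#: expected per-class duplication counts per pattern
PATTERN_EVENT_COUNTS: dict[str, dict[str, int]] = {
    "a": {"3R": 1, "post3R_pre4R": 1, "4R": 3, "post4R": 6},
    "b": {"3R": 1, "post3R_pre4R": 1, "4R": 3},
    "c": {"3R": 1, "post3R_pre4R": 1, "post4R": 3},
    "d": {"3R": 1, "post3R_pre4R": 1},
    "e": {"3R": 1, "4R": 2, "post4R": 4},
    "f": {"3R": 1, "4R": 2},
    "g": {"3R": 1, "post4R": 2},
    "h": {"3R": 1},
    "i": {"post3R_pre4R": 1, "4R": 2, "post4R": 4},
    "j": {"post3R_pre4R": 1, "4R": 2},
    "k": {"post3R_pre4R": 1, "post4R": 2},
    "l": {"post3R_pre4R": 1},
    "m": {"4R": 1, "post4R": 2},
    "n": {"4R": 1},
    "o": {"post4R": 1},
    "p": {},
}


class _Builder:
    def __init__(self, pattern: str):
        self.pattern = pattern
        self._gene = itertools.count(1)
        self._chrom = itertools.count(1)

    def new_chrom(self) -> int:
        return next(self._chrom)

    def leaf(self, species: str, chrom: int) -> str:
        return f"{species}|{self.pattern}{next(self._gene)}|{species[:3]}{chrom}"

    def salmon(self, chrom: int, tandem: bool) -> str:
        if tandem:
            return f"({self.leaf('salmon', chrom)},{self.leaf('salmon', chrom)})"
        return self.leaf("salmon", chrom)

    def salmonids(self, chrom: int, four_r: bool, tandems: bool) -> str:
        """The salmonid part of one pre-4R lineage."""
        def pair(c):
            return f"({self.salmon(c, tandems)},{self.leaf('trout', c)})"
        if four_r:
            return f"({pair(chrom)},{pair(self.new_chrom())})"
        return pair(chrom)

    def post_zeb(self, chrom: int, four_r: bool, tandems: bool) -> str:
        """One lineage below the zebrafish split: (tilapia,fugu) | (pike, salmonids)."""
        return (f"(({self.leaf('tilapia', chrom)},{self.leaf('fugu', chrom)}),"
                f"({self.leaf('pike', chrom)},{self.salmonids(chrom, four_r, tandems)}))")

    def teleosts(self, chrom: int, p34: bool, four_r: bool, tandems: bool) -> str:
        """One post-3R teleost lineage, optionally carrying a between-WGD SSD."""
        if p34:
            inner = (f"({self.post_zeb(chrom, four_r, tandems)},"
                     f"{self.post_zeb(chrom, four_r, tandems)})")
        else:
            inner = self.post_zeb(chrom, four_r, tandems)
        return f"({self.leaf('zebrafish', chrom)},{inner})"


def pattern_newick(pattern: str) -> str:
    """Newick text for one of the sixteen reference patterns."""
    if pattern not in PATTERN_EVENT_COUNTS:
        raise KeyError(f"unknown pattern {pattern!r}")
    b = _Builder(pattern)
    # (three_r, p34_on_first_copy, four_r, tandems)
    spec = {
        "a": (True, True, True, True),
        "b": (True, True, True, False),
        "c": (True, True, False, True),
        "d": (True, True, False, False),
        "e": (True, False, True, True),
        "f": (True, False, True, False),
        "g": (True, False, False, True),
        "h": (True, False, False, False),
        "i": (False, True, True, True),
        "j": (False, True, True, False),
        "k": (False, True, False, True),
        "l": (False, True, False, False),
        "m": (False, False, True, True),
        "n": (False, False, True, False),
        "o": (False, False, False, True),
        "p": (False, False, False, False),
    }[pattern]
    three_r, p34, four_r, tandems = spec
    if three_r:
        copy1 = b.teleosts(b.new_chrom(), p34, four_r, tandems)
        copy2 = b.teleosts(b.new_chrom(), False, four_r, tandems)
        teleost_part = f"({copy1},{copy2})"
    else:
        teleost_part = b.teleosts(b.new_chrom(), p34, four_r, tandems)
    return f"({b.leaf('gar', b.new_chrom())},{teleost_part});"


def pattern_tree(pattern: str) -> GeneTree:
    return parse_gene_tree(pattern_newick(pattern), name=pattern)


def pattern_suite() -> dict[str, GeneTree]:
    """All sixteen reference trees keyed by pattern name."""
    return {p: pattern_tree(p) for p in PATTERN_EVENT_COUNTS}
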