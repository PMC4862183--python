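"""Gene-family quality control: pairwise alignment statistics, identity/gap
thresholds, and single-linkage family construction.

The five canonical QC profiles combine a phylogeny mode with thresholds on
pairwise percent identity and on the fraction of aligned columns containing
a gap:

1. relaxed, identity >= 50 %, no gap threshold
2. relaxed, no thresholds
3. relaxed, identity >= 50 %, gap fraction <= 50 %
4. rigid, no thresholds
5. rigid, identity >= 50 %, gap fraction <= 50 %
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import networkx as nx
from Bio import SeqIO


class QCError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PairStats:
    seq_a: str
    seq_b: str
    percent_identity: float
    fraction_gaps: float

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise QCError(f"percent identity {self.percent_identity} out of [0, 100]")
        if not 0.0 <= self.fraction_gaps <= 1.0:
            raise QCError(f"gap fraction {self.fraction_gaps} out of [0, 1]")

    @property
    def key(self) -> frozenset:
        return frozenset((self.seq_a, self.seq_b))


@dataclasses.dataclass(frozen=True)
class QCProfile:
    min_percent_identity: Optional[float] = None
    max_fraction_gaps: Optional[float] = None
    phylogeny_mode: str = "relaxed"

    def __post_init__(self):
        if self.min_percent_identity is not None and not 0 <= self.min_percent_identity <= 100:
            raise QCError("min_percent_identity out of range")
        if self.max_fraction_gaps is not None and not 0 <= self.max_fraction_gaps <= 1:
            raise QCError("max_fraction_gaps out of range")
        if self.phylogeny_mode not in ("relaxed", "rigid"):
            raise QCError("phylogeny_mode must be 'relaxed' or 'rigid'")

    def passes(self, stats: PairStats) -> bool:
        if (self.min_percent_identity is not None
                and stats.percent_identity < self.min_percent_identity):
            return False
        if (self.max_fraction_gaps is not None
                and stats.fraction_gaps > self.max_fraction_gaps):
            return False
        return True


#: the five dataset variants, keyed by preset id
QC_PRESETS: dict[int, QCProfile] = {
    1: QCProfile(50.0, None, "relaxed"),
    2: QCProfile(None, None, "relaxed"),
    3: QCProfile(50.0, 0.5, "relaxed"),
    4: QCProfile(None, None, "rigid"),
    5: QCProfile(50.0, 0.5, "rigid"),
}

GAP_CHARS = frozenset("-.")


def pair_stats(name_a: str, aligned_a: str, name_b: str, aligned_b: str) -> PairStats:
    """Identity over residue-residue columns; gap fraction over all columns."""
    if len(aligned_a) != len(aligned_b):
        raise QCError(
            f"aligned lengths differ for {name_a}/{name_b}: "
            f"{len(aligned_a)} vs {len(aligned_b)}"
        )
    if not aligned_a:
        raise QCError("empty alignment")
    matches = residue_cols = gap_cols = 0
    for ca, cb in zip(aligned_a.upper(), aligned_b.upper()):
        a_gap, b_gap = ca in GAP_CHARS, cb in GAP_CHARS
        if a_gap or b_gap:
            gap_cols += 1
            continue
        residue_cols += 1
        matches += ca == cb
    if residue_cols == 0:
        raise QCError(f"no residue-residue overlap between {name_a} and {name_b}")
    return PairStats(name_a, name_b,
                     100.0 * matches / residue_cols,
                     gap_cols / len(aligned_a))


def pair_stats_from_alignment(records: Sequence) -> list[PairStats]:
    """All pairwise statistics from an MSA (any sequence of (id, seq) or
    SeqRecord objects); per pair, columns gapped in both members are dropped
    first so the statistics behave like an induced pairwise alignment."""
    items = []
    for rec in records:
        if hasattr(rec, "id"):
            items.append((rec.id, str(rec.seq)))
        else:
            items.append((rec[0], str(rec[1])))
    out = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (na, sa), (nb, sb) = items[i], items[j]
            cols = [(ca, cb) for ca, cb in zip(sa, sb)
                    if not (ca in GAP_CHARS and cb in GAP_CHARS)]
            out.append(pair_stats(na, "".join(c[0] for c in cols),
                                  nb, "".join(c[1] for c in cols)))
    return out


def read_alignment_fasta(path) -> list:
    return list(SeqIO.parse(path, "fasta"))


@dataclasses.dataclass
class FilterResult:
    retained: set[str]
    removed: list[str]
    singleton: bool


def filter_family(members: Iterable[str], stats: Iterable[PairStats],
                  profile: QCProfile) -> FilterResult:
    """Iteratively drop worst offenders until every member passes the profile
    against at least one other retained member.

    The worst offender is the failing member with the lowest mean identity to
    the other retained members (ties broken lexicographically).  Families
    reduced below 2 members are flagged singleton.
    """
    members = set(members)
    by_pair: dict[frozenset, PairStats] = {}
    for s in stats:
        by_pair[s.key] = s
    for a in members:
        for b in members:
            if a < b and frozenset((a, b)) not in by_pair:
                raise QCError(f"missing pair statistics for ({a}, {b})")

    retained = set(members)
    removed: list[str] = []
    while len(retained) >= 2:
        failing = []
        for m in retained:
            ok = any(profile.passes(by_pair[frozenset((m, o))])
                     for o in retained if o != m)
            if not ok:
                mean_ident = sum(
                    by_pair[frozenset((m, o))].percent_identity
                    for o in retained if o != m
                ) / (len(retained) - 1)
                failing.append((mean_ident, m))
        if not failing:
            break
        failing.sort()
        worst = failing[0][1]
        retained.discard(worst)
        removed.append(worst)
    singleton = len(retained) < 2
    if singleton:
        removed.extend(sorted(retained))
        retained = set()
    return FilterResult(retained, removed, singleton)


def single_linkage(edges: Iterable[tuple[str, str]]) -> list[set[str]]:
    """Families as connected components of the homology-hit graph."""
    graph = nx.Graph()
    for a, b in edges:
        graph.add_edge(a, b)
    components = [set(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: sorted(c)[0])
    return components
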