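"""Co-retention of physically interacting partners across a WGD.

Interactions come from a STRING-style export restricted to the ``binding``
interaction mode (direct physical contact).  Each retained gene contributes
one trial per interacting partner; the co-retention probability is the
fraction of those trials whose partner is retained at the same WGD.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .retention import ZTestResult, pooled_two_proportion_z

logger = logging.getLogger(__name__)


class InteractionError(ValueError):
    pass


@dataclasses.dataclass
class InteractionSet:
    pairs: set[frozenset]
    mode: str = "binding"

    def partners(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for pair in self.pairs:
            a, b = tuple(pair)
            out.setdefault(a, set()).add(b)
            out.setdefault(b, set()).add(a)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


_ID_COLUMNS = (("protein1", "protein2"), ("gene1", "gene2"), ("item_id_a", "item_id_b"))


def load_interactions(table: Union[str, pd.DataFrame], mode_filter: str = "binding",
                      min_score: Optional[float] = None) -> InteractionSet:
    """Read a STRING-export-like TSV; keep rows matching the interaction mode,
    optionally above a combined-score cutoff; collapse duplicates and drop
    self-pairs with a warning."""
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.read_csv(table, sep="\t")
    cols = None
    for ca, cb in _ID_COLUMNS:
        if ca in df.columns and cb in df.columns:
            cols = (ca, cb)
            break
    if cols is None or "mode" not in df.columns:
        raise InteractionError(
            "interaction table needs two id columns "
            "(protein1/protein2) and a 'mode' column"
        )
    sub = df[df["mode"] == mode_filter]
    if min_score is not None and "score" in df.columns:
        sub = sub[sub["score"] >= min_score]
    pairs: set[frozenset] = set()
    for a, b in zip(sub[cols[0]], sub[cols[1]]):
        if a == b:
            logger.warning("dropping self-interaction %r", a)
            continue
        pairs.add(frozenset((str(a), str(b))))
    return InteractionSet(pairs, mode_filter)


@dataclasses.dataclass
class CoretentionStats:
    p_coretained: Optional[float]
    p_retained_with_partners: Optional[float]
    p_retained_no_partners: Optional[float]
    n_trials: int
    n_unmapped: int
    z_tests: dict[str, ZTestResult]

    def as_dict(self) -> dict:
        return {
            "p_coretained": self.p_coretained,
            "p_retained_with_partners": self.p_retained_with_partners,
            "p_retained_no_partners": self.p_retained_no_partners,
            "n_trials": self.n_trials,
            "n_unmapped": self.n_unmapped,
            "z_tests": {
                name: {"z": zt.z, "p_value": zt.p_value,
                       "x1": zt.x1, "n1": zt.n1, "x2": zt.x2, "n2": zt.n2}
                for name, zt in self.z_tests.items()
            },
        }


def retention_from_events(table: pd.DataFrame, ortholog_map: Mapping[str, str],
                          event_class: str) -> dict[str, bool]:
    """Resolve interaction gene ids to classified lineage segments and read
    off their retention flag for ``event_class``.

    ``ortholog_map`` maps a gene id to a ``(family, segment)`` key formatted
    ``family:segment`` or simply to a family id (first matching row wins).
    """
    sub = table[table["event_class"] == event_class]
    by_family: dict[str, bool] = {}
    by_segment: dict[str, bool] = {}
    for row in sub.itertuples(index=False):
        fam = str(row.family)
        by_segment[f"{fam}:{row.segment}"] = bool(row.retained)
        by_family.setdefault(fam, False)
        by_family[fam] = by_family[fam] or bool(row.retained)
    out: dict[str, bool] = {}
    for gene, key in ortholog_map.items():
        key = str(key)
        if key in by_segment:
            out[gene] = by_segment[key]
        elif key in by_family:
            out[gene] = by_family[key]
    return out


def coretention_stats(retained: Mapping[str, bool], interactions: InteractionSet,
                      pair_counting: str = "gene") -> CoretentionStats:
    """Co-retention statistics at one WGD.

    ``retained`` maps gene id -> retained-at-the-WGD flag (see
    :func:`retention_from_events` to derive it from an event table).
    ``pair_counting="gene"`` counts one trial per (retained gene, partner);
    ``"pair"`` counts each unordered pair once.
    """
    if pair_counting not in ("gene", "pair"):
        raise InteractionError("pair_counting must be 'gene' or 'pair'")
    partners = interactions.partners()
    n_unmapped = sum(1 for g in partners if g not in retained)

    co_trials = co_hits = 0          # partner retained | gene retained
    bg_trials = bg_hits = 0          # partner retained | gene not retained
    if pair_counting == "gene":
        for gene, parts in partners.items():
            if gene not in retained:
                continue
            mapped = [p for p in parts if p in retained]
            if retained[gene]:
                co_trials += len(mapped)
                co_hits += sum(retained[p] for p in mapped)
            else:
                bg_trials += len(mapped)
                bg_hits += sum(retained[p] for p in mapped)
    else:
        for pair in interactions.pairs:
            a, b = tuple(pair)
            if a not in retained or b not in retained:
                continue
            if retained[a] or retained[b]:
                co_trials += 1
                co_hits += retained[a] and retained[b]

    with_p = [g for g in retained if g in partners]
    without_p = [g for g in retained if g not in partners]
    p_with = (sum(retained[g] for g in with_p) / len(with_p)) if with_p else None
    p_without = (sum(retained[g] for g in without_p) / len(without_p)) if without_p else None
    p_co = co_hits / co_trials if co_trials else None

    z_tests: dict[str, ZTestResult] = {}
    if co_trials and bg_trials:
        z_tests["partner_retained_given_retained_vs_not"] = pooled_two_proportion_z(
            co_hits, co_trials, bg_hits, bg_trials)
    if with_p and without_p:
        z_tests["retained_with_vs_without_partners"] = pooled_two_proportion_z(
            sum(retained[g] for g in with_p), len(with_p),
            sum(retained[g] for g in without_p), len(without_p))
    return CoretentionStats(p_co, p_with, p_without, co_trials, n_unmapped, z_tests)
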