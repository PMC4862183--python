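"""Retention opportunities, conditional retention probabilities, and the
pooled two-proportion z-test.

A WGD doubles every gene, so each surviving gene lineage that crosses a WGD
branch is one *opportunity* for a retained duplicate; the lineage *retained*
the duplicate iff a duplication node of that WGD class lies at the crossing.
Expected copy numbers follow ``base * 2**n_retained_WGDs``; discrepancies are
losses or small-scale duplications.  Small-scale duplication (SSD) classes
are counted as presence/absence per lineage interval: the between-WGD
interval per lineage entering it, and the post-recent-WGD interval per focal
species terminal segment.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy import stats as _stats

from .classify import ClassifiedFamily, WgdClassifier
from .reconcile import DUPLICATION
from .trees import Node


class RetentionError(ValueError):
    pass


def expected_copies(n_wgd_retained: int, base: int = 1) -> int:
    """Copies expected after ``n_wgd_retained`` retained WGDs: base * 2**n."""
    if n_wgd_retained < 0 or base < 1:
        raise RetentionError("expected_copies needs n_wgd_retained >= 0 and base >= 1")
    return base * (2 ** n_wgd_retained)


# ---------------------------------------------------------------------------
# opportunity enumeration
# ---------------------------------------------------------------------------


def _wgd_crossings(fam: ClassifiedFamily, clf: WgdClassifier, wgd_name: str):
    """(entry_node, retained, context) for every surviving lineage crossing
    the branch of ``wgd_name``; context is the set of timings above the
    crossing on that lineage."""
    st = clf.st
    wnode = clf.node1 if wgd_name == clf.w1 else clf.node2
    post_taxa = st.clade[wnode]
    rec = fam.reconciliation
    earlier = {clf.before_class} | ({clf.w1, clf.between_class} if wgd_name == clf.w2 else set())
    rows: list[tuple[Node, bool, frozenset[str]]] = []

    def descend(v: Node, had: frozenset[str]) -> None:
        if not v.is_leaf and rec.event.get(v) == DUPLICATION:
            t = v.timing
            if t == wgd_name:
                rows.append((v, True, had))
                return
            if t in earlier:
                for child in v.children:
                    if {l.species for l in child.leaves()} & post_taxa:
                        descend(child, had | {t})
                return
            # a later-interval duplication: the crossing happened above it
            rows.append((v, False, had))
            return
        if v.is_leaf:
            if v.species in post_taxa:
                rows.append((v, False, had))
            return
        m = rec.mapping[v]
        if st.is_ancestor(m, wnode, strict=True):
            for child in v.children:
                if {l.species for l in child.leaves()} & post_taxa:
                    descend(child, had)
            return
        rows.append((v, False, had))

    if {l.species for l in fam.tree.leaves()} & post_taxa:
        descend(fam.tree.root, frozenset())
    return rows


def _descend_interval(fam: ClassifiedFamily, clf: WgdClassifier, start: Node,
                      ssd_class: str, stop_taxa: frozenset[str],
                      toward: str) -> Optional[bool]:
    """Walk one lineage from ``start`` toward ``toward``-species leaves and
    report whether an ``ssd_class`` duplication occurs before the interval
    ends (``stop_taxa`` reached as a crossing/terminal).  Returns None when
    the lineage does not survive toward the target."""
    rec = fam.reconciliation
    v = start
    while True:
        if not v.is_leaf and rec.event.get(v) == DUPLICATION:
            if v.timing == ssd_class:
                return True
            if v.timing in (clf.w2, clf.after_class) and ssd_class == clf.between_class:
                return False  # reached the recent WGD crossing
            # other duplications split the lineage; follow the side that
            # still leads toward the target
            nxt = [c for c in v.children
                   if any(l.species == toward for l in c.leaves())]
            if not nxt:
                return None
            v = nxt[0]
            continue
        if v.is_leaf:
            return False if v.species in stop_taxa or v.species == toward else None
        nxt = [c for c in v.children
               if any(l.species == toward for l in c.leaves())]
        if not nxt:
            return None
        v = nxt[0]


def lineage_table(families: Iterable[ClassifiedFamily], clf: WgdClassifier) -> pd.DataFrame:
    """Per-lineage opportunity rows over all families.

    Columns: family, event_class, segment, retained, had_<W1>, had_<W2>,
    had_<between>.  One row per opportunity:

    * class W1 (ancient WGD): one per lineage entering its branch;
    * class W2 (recent WGD): one per surviving lineage crossing its branch;
    * between class: one per lineage traversing the inter-WGD interval;
    * post class: one per focal-species terminal segment.
    """
    st = clf.st
    had_w1, had_w2, had_bt = f"had_{clf.w1}", f"had_{clf.w2}", f"had_{clf.between_class}"
    records = []

    def add(fam, cls, seg, retained, had: frozenset[str]):
        records.append({
            "family": fam.family, "event_class": cls, "segment": seg,
            "retained": bool(retained),
            had_w1: clf.w1 in had, had_w2: clf.w2 in had,
            had_bt: clf.between_class in had,
        })

    for fam in families:
        if any(ev.timing is None for ev in fam.events):
            raise RetentionError(f"family {fam.family!r} has unclassified events")
        seg = 0
        w1_rows = _wgd_crossings(fam, clf, clf.w1)
        for _, retained, had in w1_rows:
            add(fam, clf.w1, seg, retained, had)
            seg += 1
        w2_rows = _wgd_crossings(fam, clf, clf.w2)
        for _, retained, had in w2_rows:
            add(fam, clf.w2, seg, retained, had)
            seg += 1
        # between-WGD interval: one lineage per copy leaving the ancient WGD
        for node, retained, had in w1_rows:
            copies = node.children if retained else [node]
            ctx = had | ({clf.w1} if retained else set())
            for copy in copies:
                found = _descend_interval(
                    fam, clf, copy, clf.between_class,
                    stop_taxa=st.clade[clf.node2], toward=clf.focal)
                if found is not None:
                    add(fam, clf.between_class, seg, found, ctx)
                    seg += 1
        # post-recent-WGD interval: focal terminal segment per crossing copy
        for node, retained, had in w2_rows:
            copies = node.children if retained else [node]
            ctx = had | ({clf.w2} if retained else set())
            for copy in copies:
                found = _descend_interval(
                    fam, clf, copy, clf.after_class,
                    stop_taxa=frozenset(), toward=clf.focal)
                if found is not None:
                    add(fam, clf.after_class, seg, found, ctx)
                    seg += 1
    columns = ["family", "event_class", "segment", "retained", had_w1, had_w2, had_bt]
    return pd.DataFrame.from_records(records, columns=columns)


@dataclasses.dataclass
class RetentionEstimate:
    retained: int
    total: int

    @property
    def undefined(self) -> bool:
        return self.total == 0

    @property
    def probability(self) -> Optional[float]:
        return None if self.undefined else self.retained / self.total


def opportunities(table: pd.DataFrame, event_class: str,
                  given: Optional[Mapping[str, bool]] = None) -> RetentionEstimate:
    """Retained/total opportunities for a class, optionally conditioned on
    ancestral context, e.g. ``given={"3R": True}``."""
    sub = table[table["event_class"] == event_class]
    if given:
        for cls, value in given.items():
            col = f"had_{cls}"
            if col not in table.columns:
                raise RetentionError(f"unknown conditioning class {cls!r}")
            sub = sub[sub[col] == bool(value)]
    return RetentionEstimate(int(sub["retained"].sum()), int(len(sub)))


def conditional_retention(table: pd.DataFrame, event_class: str,
                          given: Mapping[str, bool]) -> RetentionEstimate:
    return opportunities(table, event_class, given=given)


# ---------------------------------------------------------------------------
# pooled two-proportion z-test
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ZTestResult:
    z: float
    p_value: float
    x1: int
    n1: int
    x2: int
    n2: int

    @property
    def undefined(self) -> bool:
        return math.isnan(self.z)


def pooled_two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)), two-sided p.

    phat pools both samples; a pooled proportion of exactly 0 or 1 leaves z
    undefined (returned as NaN with p 1.0).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise RetentionError("counts must satisfy 0 <= x <= n and n >= 1")
    phat = (x1 + x2) / (n1 + n2)
    if phat in (0.0, 1.0):
        return ZTestResult(float("nan"), 1.0, x1, n1, x2, n2)
    z = (x1 / n1 - x2 / n2) / math.sqrt(phat * (1 - phat) * (1 / n1 + 1 / n2))
    p = 2.0 * _stats.norm.sf(abs(z))
    return ZTestResult(z, min(p, 1.0), x1, n1, x2, n2)


def retention_report(table: pd.DataFrame, clf: WgdClassifier) -> dict:
    """JSON-ready per-class probabilities, conditionals and z-tests."""
    report: dict = {"classes": {}, "conditionals": {}, "z_tests": {}}
    for cls in (clf.w1, clf.w2, clf.between_class, clf.after_class):
        est = opportunities(table, cls)
        report["classes"][cls] = {
            "retained": est.retained, "opportunities": est.total,
            "probability": est.probability,
        }
    contrasts = [
        (clf.w2, {clf.w1: True}, {clf.w1: False}),
        (clf.between_class, {clf.w1: True}, {clf.w1: False}),
        (clf.after_class, {clf.w2: True}, {clf.w2: False}),
    ]
    for cls, ga, gb in contrasts:
        ea, eb = opportunities(table, cls, ga), opportunities(table, cls, gb)
        name = f"{cls}|{list(ga)[0]}"
        report["conditionals"][name] = {
            "given_true": {"retained": ea.retained, "opportunities": ea.total,
                           "probability": ea.probability},
            "given_false": {"retained": eb.retained, "opportunities": eb.total,
                            "probability": eb.probability},
        }
        if not ea.undefined and not eb.undefined:
            zt = pooled_two_proportion_z(ea.retained, ea.total, eb.retained, eb.total)
            report["z_tests"][name] = {
                "z": None if zt.undefined else zt.z, "p_value": zt.p_value,
                "x1": zt.x1, "n1": zt.n1, "x2": zt.x2, "n2": zt.n2,
            }
    return report
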