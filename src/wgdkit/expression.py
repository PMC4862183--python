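"""Regulatory divergence of duplicate pairs against a pre-duplication
outgroup ortholog.

A triplet is (duplicate1, duplicate2, outgroup ortholog), each an expression
profile over the same ordered tissue list.  Duplicates assigned to the same
co-expression cluster are *conserved*.  Duplicates in different clusters are
*neofunctionalized* when exactly one of them still correlates with the
outgroup (Pearson p < 0.03), and *subfunctionalized* when neither does
(both p > 0.05) while the element-wise sum of the duplicates' raw profiles
does (p < 0.03) - the partitioned halves jointly reconstitute the ancestral
pattern.  Triplets in the 0.03-0.05 buffer zone stay unclassified.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

FLAT_CLUSTER = -1  #: label for constant (zero-variance) profiles

CONSERVED = "conserved"
NEOFUNCTIONALIZED = "neofunctionalized"
SUBFUNCTIONALIZED = "subfunctionalized"
UNCLASSIFIED = "unclassified"
CALL_CLASSES = (CONSERVED, NEOFUNCTIONALIZED, SUBFUNCTIONALIZED, UNCLASSIFIED)


class ExpressionError(ValueError):
    pass


@dataclasses.dataclass
class ExpressionTriplet:
    dup1: np.ndarray
    dup2: np.ndarray
    outgroup: np.ndarray
    tissues: Optional[Sequence[str]] = None
    name: Optional[str] = None

    def __post_init__(self):
        self.dup1 = np.asarray(self.dup1, dtype=float)
        self.dup2 = np.asarray(self.dup2, dtype=float)
        self.outgroup = np.asarray(self.outgroup, dtype=float)
        n = len(self.outgroup)
        if not (len(self.dup1) == len(self.dup2) == n) or n < 3:
            raise ExpressionError("triplet profiles must share a length >= 3")
        if min(self.dup1.min(), self.dup2.min(), self.outgroup.min()) < 0:
            raise ExpressionError("expression values must be non-negative")


@dataclasses.dataclass
class DivergenceCall:
    call: str
    r_dup1: float
    r_dup2: float
    r_sum: float
    p_dup1: float
    p_dup2: float
    p_sum: float
    clusters_differ: Optional[bool]
    name: Optional[str] = None


def pearson_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Sample Pearson r with its t-transform p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ExpressionError("pearson_test needs equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ExpressionError("correlation undefined for a constant profile")
    res = _stats.pearsonr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def onoff(profile, tau: float) -> np.ndarray:
    """Binary on/off call per tissue: expression above ``tau`` is on."""
    if tau < 0:
        raise ExpressionError("tau must be non-negative")
    return np.asarray(profile, dtype=float) > tau


def coexpression_clusters(matrix: pd.DataFrame, k: Optional[int] = None,
                          k_range: tuple[int, int] = (2, 20)) -> pd.Series:
    """Average-linkage hierarchical clustering on 1 - Pearson r distance.

    ``k=None`` selects k in ``k_range`` by maximum mean silhouette (on the
    same precomputed distance).  Constant-profile genes go to a dedicated
    flat cluster (label -1) and do not participate in the clustering.
    Deterministic for a fixed input.
    """
    values = matrix.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    labels = pd.Series(FLAT_CLUSTER, index=matrix.index, dtype=int)
    idx = np.flatnonzero(variable)
    n = len(idx)
    if n == 0:
        return labels
    if n == 1:
        labels.iloc[idx] = 1
        return labels
    corr = np.corrcoef(values[idx])
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    if k is not None:
        if k < 2 or k > n:
            raise ExpressionError(f"k={k} out of range for {n} clusterable genes")
        assignment = fcluster(tree, t=k, criterion="maxclust")
    else:
        lo, hi = k_range
        hi = min(hi, n - 1)
        best = None
        for kk in range(max(2, lo), hi + 1):
            cand = fcluster(tree, t=kk, criterion="maxclust")
            if len(set(cand)) < 2:
                continue
            score = silhouette_score(dist, cand, metric="precomputed")
            if best is None or score > best[0]:
                best = (score, cand)
        if best is None:
            assignment = fcluster(tree, t=2, criterion="maxclust")
        else:
            assignment = best[1]
    labels.iloc[idx] = assignment
    return labels


def classify_triplet(triplet: ExpressionTriplet, labels: Mapping[str, int],
                     dup1_id: Optional[str] = None, dup2_id: Optional[str] = None,
                     p_on: float = 0.03, p_off: float = 0.05,
                     alternative: str = "two-sided",
                     relaxed_sub: bool = False) -> DivergenceCall:
    """Apply the ordered conserved/neo/sub rules to one triplet.

    ``labels`` holds co-expression cluster labels for the two duplicates
    (keyed by ``dup1_id``/``dup2_id``, defaulting to ``<name>.1/.2``).
    ``relaxed_sub`` weakens the subfunctionalization requirement from
    *both* duplicates uncorrelated to *at least one*.
    """
    d1 = dup1_id if dup1_id is not None else f"{triplet.name}.1"
    d2 = dup2_id if dup2_id is not None else f"{triplet.name}.2"
    try:
        c1, c2 = labels[d1], labels[d2]
        clusters_differ = bool(c1 != c2)
    except KeyError as exc:
        raise ExpressionError(f"missing cluster label for {exc}") from None

    nan = float("nan")
    try:
        r1, p1 = pearson_test(triplet.dup1, triplet.outgroup, alternative)
        r2, p2 = pearson_test(triplet.dup2, triplet.outgroup, alternative)
        rs, ps = pearson_test(triplet.dup1 + triplet.dup2, triplet.outgroup, alternative)
    except ExpressionError:
        return DivergenceCall(UNCLASSIFIED, nan, nan, nan, nan, nan, nan,
                              clusters_differ, triplet.name)

    if not clusters_differ:
        call = CONSERVED
    elif (p1 < p_on) != (p2 < p_on):
        call = NEOFUNCTIONALIZED
    else:
        uncorrelated = ((p1 > p_off) or (p2 > p_off)) if relaxed_sub \
            else ((p1 > p_off) and (p2 > p_off))
        call = SUBFUNCTIONALIZED if (uncorrelated and ps < p_on) else UNCLASSIFIED
    return DivergenceCall(call, r1, r2, rs, p1, p2, ps, clusters_differ, triplet.name)


def onoff_divergence(triplet: ExpressionTriplet, tau: float = 1.0) -> str:
    """Alternative on/off-state classification of a triplet.

    Conserved: both duplicates reproduce the outgroup's on-tissue set.
    Subfunctionalized: the duplicates partition it (union equals it, each a
    proper subset).  Neofunctionalized: a duplicate is on in a tissue where
    the outgroup is off.  Anything else is unclassified.
    """
    og = frozenset(np.flatnonzero(onoff(triplet.outgroup, tau)))
    s1 = frozenset(np.flatnonzero(onoff(triplet.dup1, tau)))
    s2 = frozenset(np.flatnonzero(onoff(triplet.dup2, tau)))
    if s1 == og and s2 == og:
        return CONSERVED
    if (s1 - og) or (s2 - og):
        return NEOFUNCTIONALIZED
    if s1 | s2 == og and s1 < og and s2 < og:
        return SUBFUNCTIONALIZED
    return UNCLASSIFIED


def summarize_divergence(calls: Iterable[DivergenceCall]) -> dict:
    """Counts and fractions per call class plus the diverged fraction."""
    calls = list(calls)
    counts = {cls: 0 for cls in CALL_CLASSES}
    diverged = 0
    for call in calls:
        counts[call.call] += 1
        diverged += bool(call.clusters_differ)
    total = len(calls)
    return {
        "total": total,
        "counts": counts,
        "fractions": {cls: (counts[cls] / total if total else 0.0) for cls in counts},
        "diverged_fraction": (diverged / total) if total else 0.0,
    }


# ---------------------------------------------------------------------------
# cohort-level convenience: matrices + triplet table -> calls
# ---------------------------------------------------------------------------


def classify_cohort(dup_matrix: pd.DataFrame, outgroup_matrix: pd.DataFrame,
                    triplet_table: pd.DataFrame, k: Optional[int] = None,
                    **kwargs) -> list[DivergenceCall]:
    """Cluster the duplicate expression matrix, then classify every triplet.

    ``triplet_table`` needs columns ``dup1``, ``dup2``, ``outgroup_ortholog``
    referring to row labels of the two matrices (tissue columns must match).
    """
    required = {"dup1", "dup2", "outgroup_ortholog"}
    if not required <= set(triplet_table.columns):
        raise ExpressionError(f"triplet table needs columns {sorted(required)}")
    if list(dup_matrix.columns) != list(outgroup_matrix.columns):
        raise ExpressionError("duplicate and outgroup matrices must share tissues")
    labels = coexpression_clusters(dup_matrix, k=k)
    calls = []
    for row in triplet_table.itertuples(index=False):
        triplet = ExpressionTriplet(
            dup_matrix.loc[row.dup1].to_numpy(),
            dup_matrix.loc[row.dup2].to_numpy(),
            outgroup_matrix.loc[row.outgroup_ortholog].to_numpy(),
            tissues=list(dup_matrix.columns),
            name=str(row.dup1),
        )
        calls.append(classify_triplet(triplet, labels, dup1_id=row.dup1,
                                      dup2_id=row.dup2, **kwargs))
    return calls
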