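"""Agreement between informativeness measures.

Three complementary views of how similarly two measures rate the same
markers: Spearman rank correlation of the raw scores, Cohen's kappa on
decile groupings (with the full contingency table for mosaic plots),
and overlap patterns of the top-n marker sets encoded as 5-digit binary
membership vectors in the fixed order (delta, fst, fic, sic, i_n).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .measures import MEASURES, MeasureScores

__all__ = [
    "KappaResult",
    "OverlapPattern",
    "spearman",
    "decile_groups",
    "kappa_deciles",
    "overlap_patterns",
    "pairwise_spearman",
    "pairwise_kappa",
]


@dataclass
class KappaResult:
    """Cohen's kappa with its ingredients.

    kappa = (Pr(a) - Pr(e)) / (1 - Pr(e)) where Pr(a) is the observed
    agreement proportion (diagonal mass of the contingency table) and
    Pr(e) the chance agreement from the marginals.  kappa <= 1 always;
    values below 0 indicate worse-than-chance agreement and are reported
    as-is (``negative`` flag set) rather than clamped.
    """

    kappa: float
    pr_a: float
    pr_e: float
    table: pd.DataFrame

    @property
    def negative(self) -> bool:
        return self.kappa < 0.0


@dataclass(frozen=True)
class OverlapPattern:
    """Membership pattern of a marker across the five top-n sets.

    ``pattern`` is a 5-character binary string ordered (delta, fst, fic,
    sic, i_n); e.g. '11001' marks a marker selected by delta, fst and
    i_n but not by fic or sic.
    """

    pattern: str
    count: int


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (ties get averaged ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman is undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def decile_groups(
    scores: MeasureScores, measure: str, n_groups: int = 10
) -> np.ndarray:
    """Assign each marker a decile group by informativeness.

    Group 1 holds the most informative tenth, group ``n_groups`` the
    least.  Group sizes are equal up to +-1 (the first ``M mod 10``
    groups get the extra marker).  Ties in score are resolved by the
    global (chrom, pos, marker_id) tie-break baked into the ranks, so
    labels are deterministic.  Returned in the order of ``scores.df``.
    """
    M = len(scores)
    if M < n_groups:
        raise ValueError(f"need at least {n_groups} markers, have {M}")
    ranks = scores.ranks(measure)
    base, extra = divmod(M, n_groups)
    sizes = np.full(n_groups, base, dtype=np.int64)
    sizes[:extra] += 1
    bounds = np.cumsum(sizes)
    return np.searchsorted(bounds, ranks, side="left") + 1


def kappa_deciles(groups_a: Sequence[int], groups_b: Sequence[int]) -> KappaResult:
    """Chance-corrected agreement of two groupings of the same markers."""
    a = np.asarray(groups_a)
    b = np.asarray(groups_b)
    if a.shape != b.shape:
        raise ValueError("groupings must cover the same markers")
    labels_a, labels_b = set(a.tolist()), set(b.tolist())
    if labels_a != labels_b:
        raise ValueError(f"group label sets disagree: {sorted(labels_a)} vs {sorted(labels_b)}")
    labels = sorted(labels_a)
    table = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    table = table.reindex(index=labels, columns=labels, fill_value=0)
    counts = table.to_numpy(dtype=float)
    n = counts.sum()
    pr_a = float(np.trace(counts) / n)
    pr_e = float(np.sum(counts.sum(axis=1) * counts.sum(axis=0)) / n**2)
    kappa = 1.0 if pr_e == 1.0 else (pr_a - pr_e) / (1.0 - pr_e)
    return KappaResult(kappa=float(kappa), pr_a=pr_a, pr_e=pr_e, table=table)


def overlap_patterns(
    top_sets: Sequence[set], labels: Sequence[str] = MEASURES
) -> tuple[list[OverlapPattern], dict[tuple[str, str], int]]:
    """Membership patterns of markers across the five top-n sets.

    Returns the pattern counts over the union of the sets (patterns with
    zero count omitted) and the 10 pairwise intersection sizes.
    """
    if len(top_sets) != len(labels):
        raise ValueError(f"expected {len(labels)} sets, got {len(top_sets)}")
    sets = [set(s) for s in top_sets]
    union = set().union(*sets) if sets else set()
    counts: dict[str, int] = {}
    for marker in union:
        pattern = "".join("1" if marker in s else "0" for s in sets)
        counts[pattern] = counts.get(pattern, 0) + 1
    patterns = [
        OverlapPattern(pattern=p, count=c) for p, c in sorted(counts.items(), reverse=True)
    ]
    pairwise = {
        (labels[i], labels[j]): len(sets[i] & sets[j])
        for i, j in combinations(range(len(sets)), 2)
    }
    return patterns, pairwise


def pairwise_spearman(
    scores: MeasureScores, measures: Sequence[str] = MEASURES
) -> pd.DataFrame:
    """Matrix of Spearman correlations between measure score vectors."""
    mat = pd.DataFrame(np.eye(len(measures)), index=measures, columns=measures)
    for a, b in combinations(measures, 2):
        rho = spearman(scores.values(a), scores.values(b))
        mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


def pairwise_kappa(
    scores: MeasureScores,
    measures: Sequence[str] = MEASURES,
    n_groups: int = 10,
) -> tuple[pd.DataFrame, Mapping[tuple[str, str], KappaResult]]:
    """Pairwise decile-based Cohen's kappa between measures."""
    groups = {m: decile_groups(scores, m, n_groups) for m in measures}
    mat = pd.DataFrame(np.eye(len(measures)), index=measures, columns=measures)
    results: dict[tuple[str, str], KappaResult] = {}
    for a, b in combinations(measures, 2):
        res = kappa_deciles(groups[a], groups[b])
        results[(a, b)] = res
        mat.loc[a, b] = mat.loc[b, a] = res.kappa
    return mat, results
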