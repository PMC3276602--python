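"""AIM panel construction from measure scores.

Turns per-marker informativeness scores into ordered marker panels:

* :func:`distance_filter` — greedy, score-priority enforcement of a
  minimum physical spacing (default 100 kb) between selected markers on
  the same chromosome, a cheap stand-in for LD pruning;
* :func:`select` — top-n, top-fraction and score-cutoff selection rules
  (with the literature cutoff registry delta>=0.3, F_ST>=0.4, FIC>=2.0,
  SIC>=0.3, I_n>=0.3);
* :func:`combined_rank` — AVE/MIN combined rankings across the five
  measures.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .measures import MEASURES, MeasureScores, rank_descending

__all__ = [
    "Panel",
    "SelectionRule",
    "DEFAULT_CUTOFFS",
    "COMBINED",
    "distance_filter",
    "select",
    "combined_rank",
]

#: published cutoff values used with each measure
DEFAULT_CUTOFFS = {"delta": 0.3, "fst": 0.4, "fic": 2.0, "sic": 0.3, "i_n": 0.3}

#: combined-ranking pseudo-measures
COMBINED = ("ave", "min")


@dataclass(frozen=True)
class SelectionRule:
    """Record of how a panel was cut down: rule kind, parameter, spacing."""

    kind: Literal["all", "top_n", "top_fraction", "cutoff"]
    value: float | None = None
    min_bp: int = 0


@dataclass
class Panel:
    """An ordered AIM panel with provenance.

    ``df`` columns: marker_id, chrom, pos, score, rank — sorted by rank
    (1 = most informative).  ``measure`` is one of the five measures or
    'ave'/'min'; for the combined rankings ``score`` is the combined
    rank score (smaller is better) while ``rank`` is always 1-based in
    informativeness order.
    """

    measure: str
    df: pd.DataFrame
    rule: SelectionRule = field(default_factory=lambda: SelectionRule("all"))

    def __post_init__(self) -> None:
        if self.df["marker_id"].duplicated().any():
            raise ValueError("panel markers must be unique")
        self.df = self.df.sort_values("rank", kind="stable").reset_index(drop=True)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.df["marker_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def head(self, n: int) -> "Panel":
        return select(self, top_n=n)


def _panel_frame(scores: MeasureScores, measure: str) -> pd.DataFrame:
    """marker frame in rank order for a measure or combined ranking."""
    if measure in COMBINED:
        return combined_rank(scores, method=measure)
    scores._check(measure)
    df = scores.df[["marker_id", "chrom", "pos", measure, f"rank_{measure}"]].copy()
    df.columns = ["marker_id", "chrom", "pos", "score", "rank"]
    return df


def distance_filter(
    scores: MeasureScores, measure: str, min_bp: int = 100_000
) -> Panel:
    """Greedy spacing filter in descending informativeness order.

    Markers are visited best-rank first; a candidate is rejected when an
    already selected marker on the same chromosome lies strictly closer
    than ``min_bp`` (markers exactly ``min_bp`` apart are both kept).
    Every marker not excluded by that rule ends up in the panel, so the
    most informative markers always take priority over nearby weaker
    ones.
    """
    if min_bp < 0:
        raise ValueError("min_bp must be >= 0")
    df = _panel_frame(scores, measure).sort_values("rank", kind="stable")
    keep = []
    taken: dict[str, list[int]] = {}
    for row in df.itertuples(index=False):
        positions = taken.setdefault(str(row.chrom), [])
        i = bisect_left(positions, row.pos)
        if i > 0 and row.pos - positions[i - 1] < min_bp:
            continue
        if i < len(positions) and positions[i] - row.pos < min_bp:
            continue
        insort(positions, row.pos)
        keep.append(row)
    out = pd.DataFrame(keep, columns=df.columns)
    out["rank"] = np.arange(1, len(out) + 1)
    return Panel(measure=measure, df=out, rule=SelectionRule("all", min_bp=min_bp))


def select(
    panel_or_scores: Panel | MeasureScores,
    top_n: int | None = None,
    top_fraction: float | None = None,
    cutoff: float | None = None,
    measure: str | None = None,
) -> Panel:
    """Apply a selection rule to a panel (or directly to scores).

    Exactly one of ``top_n``, ``top_fraction`` or ``cutoff`` must be
    given; ``cutoff=True`` (or any non-numeric truthy value) uses the
    published default threshold for the measure.  ``top_fraction`` keeps
    ``ceil(q * M)`` markers so a positive fraction never yields an empty
    panel; ``top_n`` larger than the panel is an error, not a silent
    truncation.
    """
    if isinstance(panel_or_scores, MeasureScores):
        if measure is None:
            raise ValueError("measure is required when selecting from scores")
        panel = Panel(measure=measure, df=_panel_frame(panel_or_scores, measure))
    else:
        panel = panel_or_scores
    given = [x is not None for x in (top_n, top_fraction, cutoff)]
    if sum(given) != 1:
        raise ValueError("give exactly one of top_n, top_fraction, cutoff")

    df = panel.df
    if top_n is not None:
        if not (0 <= top_n <= len(df)):
            raise ValueError(f"top_n={top_n} outside panel size {len(df)}")
        out = df.head(top_n).copy()
        rule = SelectionRule("top_n", float(top_n), panel.rule.min_bp)
    elif top_fraction is not None:
        if not (0.0 < top_fraction <= 1.0):
            raise ValueError("top_fraction must lie in (0, 1]")
        out = df.head(math.ceil(top_fraction * len(df))).copy()
        rule = SelectionRule("top_fraction", float(top_fraction), panel.rule.min_bp)
    else:
        if panel.measure in COMBINED:
            raise ValueError("cutoff selection is undefined for combined rankings")
        thr = cutoff if isinstance(cutoff, (int, float)) and not isinstance(cutoff, bool) else DEFAULT_CUTOFFS[panel.measure]
        out = df[df["score"] >= thr].copy()
        rule = SelectionRule("cutoff", float(thr), panel.rule.min_bp)
    return Panel(measure=panel.measure, df=out.reset_index(drop=True), rule=rule)


def combined_rank(scores: MeasureScores, method: str = "ave") -> pd.DataFrame:
    """Combined marker ranking across the five measures.

    AVE scores each marker by the mean of its five per-measure ranks,
    MIN by the minimum; the final ranking is ascending in that combined
    score with the standard (chrom, pos, marker_id) tie-break.  Returns
    a frame with columns marker_id, chrom, pos, score (the combined rank
    score; smaller is better) and rank.
    """
    method = method.lower()
    if method not in COMBINED:
        raise ValueError(f"method must be one of {COMBINED}, got {method!r}")
    missing = [m for m in MEASURES if m not in scores.measures]
    if missing:
        raise ValueError(f"combined ranking needs all five measures; missing {missing}")
    rank_mat = np.stack([scores.ranks(m) for m in MEASURES], axis=1).astype(float)
    combined = rank_mat.mean(axis=1) if method == "ave" else rank_mat.min(axis=1)
    # ascending combined score == descending negated score
    rank = rank_descending(
        -combined,
        scores.chrom_codes(),
        scores.df["pos"].to_numpy(),
        scores.marker_ids,
    )
    out = scores.df[["marker_id", "chrom", "pos"]].copy()
    out["score"] = combined
    out["rank"] = rank
    return out.sort_values("rank", kind="stable").reset_index(drop=True)
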