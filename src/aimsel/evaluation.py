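"""Assessment of AIM panels: classification, accuracy of ancestry recovery.

* :func:`lda_accuracy_curve` — cross-validated two-class linear
  discriminant accuracy as a function of the number of top-ranked AIMs
  (pooled covariance with a small ridge term; priors proportional to
  class sizes).
* :func:`markers_needed` — smallest panel reaching a target accuracy.
* :func:`rmse_bias` — RMSE of individual ancestry estimates against
  simulated truth and the absolute bias of the population mean.
* :func:`random_subset_experiment` — repeated estimation from random
  subsets drawn out of top-1/2/5/10% panels, the protocol that separates
  measures once their very top picks coincide.
* :func:`sensitivity_overlap` — overlap between panels scored under two
  different assumed admixture proportions (FIC/SIC sensitivity to m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestry import AncestryEstimate, GenotypeMatrix, estimate_ancestry
from .measures import (
    MEASURES,
    AdmixtureSpec,
    FrequencyTable,
    MeasureScores,
    score_table,
)
from .panels import COMBINED, Panel, distance_filter, select

__all__ = [
    "DiscriminantModel",
    "EvalReport",
    "lda_accuracy_curve",
    "markers_needed",
    "rmse_bias",
    "random_subset_experiment",
    "sensitivity_overlap",
    "NOT_REACHED",
]

#: sentinel returned by markers_needed when the curve never crosses
NOT_REACHED = None


@dataclass
class DiscriminantModel:
    """Two-class linear discriminant with pooled ridge-regularized covariance.

    The discriminant direction is w = S^-1 (mu1 - mu0) with S the pooled
    within-class covariance plus a ridge term lambda*I, lambda =
    ridge_scale * trace(S) / p.  Classification is by largest posterior
    with priors proportional to the training class sizes.
    """

    means: np.ndarray  # (2, p)
    cov_inv: np.ndarray  # (p, p)
    priors: np.ndarray  # (2,)
    ridge: float

    @classmethod
    def fit(cls, X0: np.ndarray, X1: np.ndarray, ridge_scale: float = 1e-6) -> "DiscriminantModel":
        X0 = np.atleast_2d(np.asarray(X0, dtype=float))
        X1 = np.atleast_2d(np.asarray(X1, dtype=float))
        n0, p = X0.shape
        n1 = X1.shape[0]
        if n0 < 2 or n1 < 2:
            raise ValueError("each class needs at least 2 samples")
        mu = np.stack([X0.mean(axis=0), X1.mean(axis=0)])
        S0 = np.cov(X0, rowvar=False, ddof=1).reshape(p, p)
        S1 = np.cov(X1, rowvar=False, ddof=1).reshape(p, p)
        S = ((n0 - 1) * S0 + (n1 - 1) * S1) / (n0 + n1 - 2)
        lam = ridge_scale * np.trace(S) / p
        if lam == 0.0:
            lam = ridge_scale  # degenerate all-constant training data
        S = S + lam * np.eye(p)
        priors = np.array([n0, n1], dtype=float) / (n0 + n1)
        return cls(means=mu, cov_inv=np.linalg.inv(S), priors=priors, ridge=lam)

    @property
    def w(self) -> np.ndarray:
        """Discriminant projection weights."""
        return self.cov_inv @ (self.means[1] - self.means[0])

    def scores(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) linear discriminant scores (log posterior up to const)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], 2))
        for k in range(2):
            a = self.cov_inv @ self.means[k]
            out[:, k] = X @ a - 0.5 * self.means[k] @ a + math.log(self.priors[k])
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.scores(X), axis=1)


def _impute_train_means(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN entries by the training-column mean (0.0 if all NaN)."""
    if not (np.isnan(Xtr).any() or np.isnan(Xte).any()):
        return Xtr, Xte
    col = np.nanmean(np.where(np.isnan(Xtr), np.nan, Xtr), axis=0)
    col = np.where(np.isnan(col), 0.0, col)
    fill = lambda X: np.where(np.isnan(X), col, X)
    return fill(Xtr), fill(Xte)


def lda_accuracy_curve(
    G0: GenotypeMatrix,
    G1: GenotypeMatrix,
    scores: MeasureScores,
    measure: str,
    n_grid: Sequence[int],
    ridge_scale: float = 1e-6,
    cv: int | str = "loo",
) -> dict[int, float]:
    """Cross-validated LDA accuracy vs number of top-ranked AIMs.

    For each n in ``n_grid`` the top-n markers of ``measure`` are used
    as features; accuracy is leave-one-out by default (``cv="loo"``) or
    k-fold for an integer ``cv``.  Missing genotypes are imputed with
    the training-fold marker mean.
    """
    order = scores.df.sort_values(f"rank_{measure}", kind="stable")["marker_id"]
    avail = set(G0.marker_ids) & set(G1.marker_ids)
    marker_order = [m for m in order if m in avail]
    n_grid = list(n_grid)
    if not n_grid or max(n_grid) > len(marker_order):
        raise ValueError(f"n_grid must be within 1..{len(marker_order)}")
    X0 = G0.subset_markers(marker_order).g.astype(float)
    X1 = G1.subset_markers(marker_order).g.astype(float)
    X0[X0 == GenotypeMatrix.MISSING] = np.nan
    X1[X1 == GenotypeMatrix.MISSING] = np.nan
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(len(X0), dtype=int), np.ones(len(X1), dtype=int)])
    n_samples = len(y)
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("each class needs at least 2 samples")
    if cv == "loo":
        folds = [np.array([i]) for i in range(n_samples)]
    else:
        k = int(cv)
        folds = [np.arange(n_samples)[i::k] for i in range(k)]

    curve: dict[int, float] = {}
    for n in n_grid:
        Xn = X[:, :n]
        correct = 0
        for test_idx in folds:
            train = np.setdiff1d(np.arange(n_samples), test_idx)
            ytr = y[train]
            if (ytr == 0).sum() < 2 or (ytr == 1).sum() < 2:
                raise ValueError("a training fold has < 2 samples in a class")
            Xtr, Xte = _impute_train_means(Xn[train], Xn[test_idx])
            model = DiscriminantModel.fit(Xtr[ytr == 0], Xtr[ytr == 1], ridge_scale)
            correct += int(np.sum(model.predict(Xte) == y[test_idx]))
        curve[int(n)] = correct / n_samples
    return curve


def markers_needed(curve: Mapping[int, float], threshold: float):
    """Smallest panel size in the curve with accuracy >= threshold.

    Returns :data:`NOT_REACHED` (None) when the curve never crosses.
    The literal definition is applied: the first crossing counts even if
    the curve later dips below the threshold.
    """
    if not curve:
        raise ValueError("curve is empty")
    for n in sorted(curve):
        if curve[n] >= threshold:
            return n
    return NOT_REACHED


def rmse_bias(
    est: AncestryEstimate, truth_ids: Sequence[str], q_true: Sequence[float]
) -> dict[str, float]:
    """RMSE of individual estimates and absolute bias of the mean.

    rmse = sqrt(mean((q_i - q̂_i)^2)) over the M matched individuals;
    bias = |mean(q̂) - mean(q)|.  Sample ids must match one-to-one.
    """
    truth = pd.Series(np.asarray(q_true, dtype=float), index=list(truth_ids))
    ids = list(est.sample_ids)
    if set(ids) != set(truth.index):
        raise ValueError("sample ids of estimate and truth do not match")
    q = truth.loc[ids].to_numpy()
    ok = ~est.all_missing
    diff = q[ok] - est.q_hat[ok]
    return {
        "rmse": float(np.sqrt(np.mean(diff**2))),
        "bias": float(abs(np.mean(est.q_hat[ok]) - np.mean(q[ok]))),
        "n": int(ok.sum()),
    }


@dataclass
class EvalReport:
    """Bundle of evaluation outputs for export."""

    accuracy_curves: dict[str, dict[int, float]] = field(default_factory=dict)
    rmse: dict[str, float] = field(default_factory=dict)
    bias: dict[str, float] = field(default_factory=dict)
    subset_stats: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy_curves": {m: {str(k): v for k, v in c.items()} for m, c in self.accuracy_curves.items()},
            "rmse": self.rmse,
            "bias": self.bias,
        }
        if self.subset_stats is not None:
            out["subset_stats"] = self.subset_stats.to_dict(orient="records")
        return out


def random_subset_experiment(
    scores: MeasureScores,
    table: FrequencyTable,
    G: GenotypeMatrix,
    reference_mean: float,
    fractions: Sequence[float] = (0.01, 0.02, 0.05, 0.10),
    subset_size: int = 20,
    n_rep: int = 100,
    seed: int = 0,
    measures: Sequence[str] = MEASURES + COMBINED,
    min_bp: int = 0,
    grid_points: int = 1001,
) -> pd.DataFrame:
    """Ancestry estimation from random subsets of top-fraction panels.

    For each ranking scheme (the five measures plus AVE/MIN combined
    ranks) and each top fraction, ``n_rep`` subsets of ``subset_size``
    markers are drawn uniformly without replacement from the
    top-fraction panel; the population mean ancestry is estimated from
    each subset and its signed error against ``reference_mean``
    recorded.  Fully reproducible from ``seed``.

    Returns a frame with one row per (measure, fraction): mean_error,
    sd_error, mean_abs_error, n_subsets, panel_size.
    """
    if subset_size < 1 or n_rep < 1:
        raise ValueError("subset_size and n_rep must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for measure in measures:
        panel = distance_filter(scores, measure, min_bp=min_bp)
        for frac in fractions:
            pool = select(panel, top_fraction=frac)
            if subset_size > len(pool):
                raise ValueError(
                    f"subset_size {subset_size} exceeds top-{frac:.0%} panel "
                    f"of {len(pool)} markers for {measure}"
                )
            pool_ids = pool.marker_ids
            errors = np.empty(n_rep)
            for r in range(n_rep):
                ids = rng.choice(pool_ids, size=subset_size, replace=False)
                sub = Panel(measure=measure, df=pool.df[pool.df["marker_id"].isin(set(ids))])
                est = estimate_ancestry(G, table, panel=sub, grid_points=grid_points)
                errors[r] = est.mean_q_hat - reference_mean
            rows.append(
                {
                    "measure": measure,
                    "fraction": frac,
                    "mean_error": float(np.mean(errors)),
                    "sd_error": float(np.std(errors, ddof=1)),
                    "mean_abs_error": float(np.mean(np.abs(errors))),
                    "n_subsets": n_rep,
                    "panel_size": len(pool),
                }
            )
    return pd.DataFrame(rows)


def sensitivity_overlap(
    table: FrequencyTable,
    measure: str,
    m: float,
    m_prime: float,
    fraction: float = 0.01,
    min_bp: int = 0,
    log_base: str = "e",
) -> dict[str, float]:
    """Overlap of top-fraction panels scored under two admixture proportions.

    Scores the table twice (contribution m and m'), builds the two
    top-``fraction`` panels for ``measure`` and counts markers selected
    by both ('11'), only the first ('10') and only the second ('01'),
    with percentages relative to the union.  Measures that ignore m
    (delta, fst, i_n) serve as controls and give 100% '11'.
    """
    sets = []
    for mm in (m, m_prime):
        sc = score_table(table, AdmixtureSpec(m1=mm), log_base=log_base)
        panel = select(distance_filter(sc, measure, min_bp=min_bp), top_fraction=fraction)
        sets.append(set(panel.marker_ids))
    both = len(sets[0] & sets[1])
    only_m = len(sets[0] - sets[1])
    only_mp = len(sets[1] - sets[0])
    union = both + only_m + only_mp
    return {
        "11": both,
        "10": only_m,
        "01": only_mp,
        "pct_11": 100.0 * both / union if union else 100.0,
        "pct_10": 100.0 * only_m / union if union else 0.0,
        "pct_01": 100.0 * only_mp / union if union else 0.0,
        "panel_size": len(sets[0]),
    }
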