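"""Maximum-likelihood estimation of global admixture proportions.

For an individual from a two-way admixed population, the expected
frequency of the reference allele at marker l is the linear mixture
f_l(q) = q*p1_l + (1-q)*p2_l of the ancestral frequencies, where q is
the individual's ancestry fraction from population 1.  Assuming
Hardy-Weinberg proportions within the individual and independence
between markers (panels are distance-filtered), the genotype g_l (0, 1
or 2 copies of the reference allele) is Binomial(2, f_l(q)), giving the
log-likelihood

    ll(q) = sum_l [ g_l log f_l + (2 - g_l) log(1 - f_l) + log C(2, g_l) ].

ll is concave in q (log of an affine function), so the maximizer over
[0, 1] is unique whenever some marker has p1 != p2; it is located by a
coarse grid followed by bounded scalar refinement.  Frequencies are
clamped to [eps, 1-eps] so fixed alleles cannot produce -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .measures import AdmixtureSpec, FrequencyTable
from .panels import Panel

__all__ = [
    "GenotypeMatrix",
    "AncestryEstimate",
    "NonIdentifiableError",
    "admixed_freq",
    "loglik_admixture",
    "estimate_ancestry",
]

_LOG_BINOM = np.array([0.0, math.log(2.0), 0.0])


class NonIdentifiableError(ValueError):
    """The ancestry proportion is not identifiable from the panel."""


class GenotypeMatrix:
    """Individuals x markers counts of the reference allele.

    ``g`` is an int8 array with entries 0/1/2 and -1 for a missing call.
    """

    MISSING = -1

    def __init__(self, sample_ids: Sequence[str], marker_ids: Sequence[str], g):
        g = np.asarray(g)
        if g.ndim != 2 or g.shape != (len(sample_ids), len(marker_ids)):
            raise ValueError("g must be (n_samples, n_markers)")
        valid = np.isin(g, (-1, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotypes must be 0, 1, 2 or -1 (missing)")
        self.sample_ids = np.asarray(sample_ids, dtype=object)
        self.marker_ids = np.asarray(marker_ids, dtype=object)
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")
        self.g = g.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.g == self.MISSING

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        """Column subset in the requested marker order."""
        index = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            cols = [index[m] for m in marker_ids]
        except KeyError as e:
            raise KeyError(f"marker {e.args[0]!r} not in genotype matrix") from None
        return GenotypeMatrix(self.sample_ids, list(marker_ids), self.g[:, cols])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.g, columns=self.marker_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        if "sample_id" not in df.columns:
            raise ValueError("missing required column 'sample_id'")
        markers = [c for c in df.columns if c != "sample_id"]
        return cls(df["sample_id"].tolist(), markers, df[markers].to_numpy())

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_markers} markers)"


@dataclass
class AncestryEstimate:
    """Per-individual ML admixture proportions for population 1.

    ``q_hat`` is NaN for individuals with no usable genotype (flagged in
    ``all_missing`` and excluded from ``mean_q_hat``).
    """

    sample_ids: np.ndarray
    q_hat: np.ndarray
    loglik: np.ndarray
    n_markers: int
    panel: str = ""
    all_missing: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.all_missing is None:
            self.all_missing = np.zeros(len(self.q_hat), dtype=bool)

    @property
    def mean_q_hat(self) -> float:
        used = self.q_hat[~self.all_missing]
        return float(np.mean(used)) if len(used) else float("nan")

    @property
    def sd_q_hat(self) -> float:
        used = self.q_hat[~self.all_missing]
        return float(np.std(used, ddof=1)) if len(used) > 1 else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "q_hat_pop1": self.q_hat,
                "loglik": self.loglik,
                "n_markers_used": self.n_markers,
            }
        )


def admixed_freq(p1, p2, spec: AdmixtureSpec | None = None):
    """Expected admixed reference-allele frequency m1*p1 + (1-m1)*p2."""
    spec = spec or AdmixtureSpec()
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    out = spec.m1 * p1 + spec.m2 * p2
    return float(out) if out.ndim == 0 else out


def _clamped_mixture(q, p1: np.ndarray, p2: np.ndarray, eps: float) -> np.ndarray:
    f = np.multiply.outer(np.atleast_1d(np.asarray(q, dtype=float)), p1 - p2) + p2
    return np.clip(f, eps, 1.0 - eps)


def loglik_admixture(
    g: Sequence[int],
    p1: Sequence[float],
    p2: Sequence[float],
    q: float,
    eps: float = 1e-6,
) -> float:
    """Binomial log-likelihood of one individual's genotypes at ancestry q.

    Missing genotypes (-1) are skipped (complete-case per marker); the
    mixture frequency is clamped to [eps, 1-eps] so the result is always
    finite.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    g = np.asarray(g)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if not (g.shape == p1.shape == p2.shape):
        raise ValueError("g, p1, p2 must have matching lengths")
    use = g != GenotypeMatrix.MISSING
    g = g[use].astype(np.int64)
    f = _clamped_mixture(q, p1[use], p2[use], eps)[0]
    return float(
        np.sum(g * np.log(f) + (2 - g) * np.log(1.0 - f) + _LOG_BINOM[g])
    )


def _grid_loglik(G: np.ndarray, p1, p2, qs: np.ndarray, eps: float) -> np.ndarray:
    """(n_samples, n_grid) log-likelihood surface, missing-aware."""
    miss = G == GenotypeMatrix.MISSING
    A = np.where(miss, 0, G).astype(np.float64)  # copies of reference allele
    B = np.where(miss, 0, 2 - G).astype(np.float64)
    const = np.where(miss, 0.0, _LOG_BINOM[np.where(miss, 0, G)]).sum(axis=1)
    F = _clamped_mixture(qs, p1, p2, eps)  # (n_grid, L)
    return A @ np.log(F).T + B @ np.log(1.0 - F).T + const[:, None]


def estimate_ancestry(
    G: GenotypeMatrix,
    table: FrequencyTable,
    panel: Panel | None = None,
    eps: float = 1e-6,
    grid_points: int = 1001,
    panel_label: str = "",
) -> AncestryEstimate:
    """ML estimate of each individual's population-1 ancestry fraction.

    The likelihood is maximized over q in [0, 1] by evaluating a
    ``grid_points`` grid and refining the best point with bounded scalar
    optimization (the likelihood is concave, so this brackets the unique
    maximizer).  Population labels are canonicalized internally so that
    swapping the two populations maps every estimate to exactly 1 - q̂.

    Raises :class:`NonIdentifiableError` when the panel is monomorphic
    between the populations (flat likelihood).  Individuals with every
    genotype missing are flagged and excluded from the mean.
    """
    if table.n_pops != 2:
        raise ValueError("estimation requires a two-population frequency table")
    marker_ids = list(panel.marker_ids) if panel is not None else [
        m for m in G.marker_ids if m in set(table.marker_ids)
    ]
    if not marker_ids:
        raise ValueError("no markers shared between genotypes and table")
    sub = G.subset_markers(marker_ids)
    ftab = table.subset(marker_ids)
    lookup = {m: i for i, m in enumerate(ftab.marker_ids)}
    idx = [lookup[m] for m in marker_ids]
    p1 = ftab.freqs(ftab.pop_names[0])[idx]
    p2 = ftab.freqs(ftab.pop_names[1])[idx]
    if np.any(np.isnan(p1)) or np.any(np.isnan(p2)):
        raise ValueError("panel contains markers with missing frequencies")

    if np.max(np.abs(p1 - p2)) < 1e-12:
        raise NonIdentifiableError(
            "panel is monomorphic between populations: likelihood is flat in q"
        )

    # canonical orientation => exact label-swap symmetry q_hat -> 1 - q_hat
    flipped = tuple(p2) > tuple(p1)
    if flipped:
        p1, p2 = p2, p1

    qs = np.linspace(0.0, 1.0, grid_points)
    LL = _grid_loglik(sub.g, p1, p2, qs, eps)
    all_missing = (sub.g == GenotypeMatrix.MISSING).all(axis=1)
    best = np.argmax(LL, axis=1)
    step = 1.0 / (grid_points - 1)

    q_hat = np.full(sub.n_samples, np.nan)
    loglik = np.full(sub.n_samples, np.nan)
    for i in range(sub.n_samples):
        if all_missing[i]:
            continue
        g_i = sub.g[i]

        def nll(q: float) -> float:
            return -loglik_admixture(g_i, p1, p2, q, eps)

        q0 = qs[best[i]]
        lo, hi = max(0.0, q0 - step), min(1.0, q0 + step)
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-9})
        candidates = [(float(-res.fun), float(res.x)), (float(LL[i, best[i]]), float(q0))]
        ll_best, q_best = max(candidates)
        q_hat[i] = q_best
        loglik[i] = ll_best

    if flipped:
        q_hat = 1.0 - q_hat
    return AncestryEstimate(
        sample_ids=sub.sample_ids,
        q_hat=q_hat,
        loglik=loglik,
        n_markers=len(marker_ids),
        panel=panel_label or (panel.measure if panel is not None else ""),
        all_missing=all_missing,
    )
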