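"""Per-marker statistics of ancestry informativeness for biallelic SNPs.

Five measures are implemented, all operating on reference-allele
frequencies in two (or, for :func:`informativeness_assignment`, K >= 2)
ancestral populations:

``delta``
    absolute allele-frequency difference |p1 - p2|.
``fst_pair``
    two-population biallelic F_ST, the fraction of total allelic variance
    attributable to between-population differentiation.
``fic``
    Fisher information content of a marker for the admixture proportion,
    evaluated at an assumed contribution m1 of population 1; favors
    markers near fixation in the majority-contribution population.
``sic``
    Shannon information content: the entropy of the admixed allele
    distribution minus the mixture of ancestral entropies; requires m1.
``informativeness_assignment``
    Rosenberg's I_n, the expected log likelihood ratio for assigning an
    allele to its source population versus an averaged population;
    defined for K >= 2 populations and N >= 2 alleles.

All entropy-based measures use the natural logarithm by default; base 2
is available via ``log_base="2"``.  The choice rescales values but never
changes ranks.  The convention 0*log(0) = 0 is applied throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AdmixtureSpec",
    "FrequencyTable",
    "MeasureScores",
    "UnsupportedMeasureError",
    "MEASURES",
    "delta",
    "fst_pair",
    "fic",
    "sic",
    "informativeness_assignment",
    "score_table",
    "rank_descending",
]

#: canonical measure order used everywhere (overlap patterns, reports)
MEASURES = ("delta", "fst", "fic", "sic", "i_n")

_LOG_SCALE = {"e": 1.0, "2": math.log(2.0)}


class UnsupportedMeasureError(ValueError):
    """A measure was requested in a setting where it is not defined."""


def _log_scale(log_base: str) -> float:
    try:
        return _LOG_SCALE[str(log_base)]
    except KeyError:
        raise ValueError(f"log_base must be 'e' or '2', got {log_base!r}") from None


def _check_freq(name: str, p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(np.isnan(p)) or np.any((p < 0.0) | (p > 1.0)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return p


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log(p) with the entropy convention 0*log(0) = 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0.0
    out[pos] = p[pos] * np.log(p[pos])
    return out


def _entropy2(p: np.ndarray) -> np.ndarray:
    """Natural-log entropy of the biallelic distribution (p, 1-p)."""
    return -(_xlogx(p) + _xlogx(1.0 - p))


def _scalar_or_array(x: np.ndarray, scalar: bool):
    return float(x) if scalar else x


@dataclass(frozen=True)
class AdmixtureSpec:
    """Assumed ancestral contributions to a two-way admixed population.

    Parameters
    ----------
    m1 : float
        Contribution of ancestral population 1; population 2 contributes
        ``1 - m1``.  The default 0.8 reflects the common practice of
        fixing the majority contribution at 80% when computing FIC/SIC.
    """

    m1: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.m1 <= 1.0):
            raise ValueError(f"m1 must lie in [0, 1], got {self.m1}")

    @property
    def m2(self) -> float:
        return 1.0 - self.m1

    @property
    def m(self) -> tuple[float, float]:
        return (self.m1, self.m2)


def _chrom_sort_key(label: str):
    """Natural chromosome ordering: numeric labels first, then lexicographic."""
    s = str(label)
    m = re.fullmatch(r"(?:chr)?(\d+)", s, flags=re.IGNORECASE)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, s)


class FrequencyTable:
    """Reference-allele frequencies of biallelic markers in K populations.

    Wraps a DataFrame with columns ``marker_id``, ``chrom``, ``pos`` and
    one ``freq_<pop>`` column per population (frequency of the reference
    allele), plus an optional ``missing_fraction`` column.  Markers are
    stored sorted by (chromosome, position) with natural chromosome
    order; marker ids must be unique.  NaN frequencies are allowed and
    mean "not typed in that population" (see ``aimsel.io.filter_shared``).
    """

    def __init__(self, df: pd.DataFrame, pop_names: Sequence[str] | None = None):
        df = df.copy()
        for col in ("marker_id", "chrom", "pos"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if pop_names is None:
            pop_names = [c[5:] for c in df.columns if c.startswith("freq_")]
        if not pop_names:
            raise ValueError("no freq_<pop> columns found")
        for pop in pop_names:
            col = f"freq_{pop}"
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
            vals = df[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= -1e-9) & (vals <= 1.0 + 1e-9))
            if not np.all(ok):
                raise ValueError(f"frequencies in {col} outside [0, 1]")
            df[col] = np.clip(vals, 0.0, 1.0)
        if df["marker_id"].duplicated().any():
            dups = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()[:5]
            raise ValueError(f"duplicate marker ids, e.g. {dups}")
        pos = df["pos"].to_numpy()
        if np.any(pd.isna(pos)) or np.any(np.asarray(pos, dtype=float) < 1):
            raise ValueError("positions must be >= 1 (1-based bp)")
        if "missing_fraction" not in df.columns:
            df["missing_fraction"] = 0.0
        order = sorted(
            range(len(df)),
            key=lambda i: (_chrom_sort_key(df["chrom"].iat[i]), int(df["pos"].iat[i])),
        )
        df = df.iloc[order].reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)
        self.df = df
        self.pop_names: tuple[str, ...] = tuple(str(p) for p in pop_names)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        marker_id: Sequence[str],
        chrom: Sequence,
        pos: Sequence[int],
        freqs: Mapping[str, Sequence[float]],
        missing_fraction: Sequence[float] | None = None,
    ) -> "FrequencyTable":
        data = {"marker_id": list(marker_id), "chrom": list(chrom), "pos": list(pos)}
        for pop, f in freqs.items():
            data[f"freq_{pop}"] = np.asarray(f, dtype=float)
        if missing_fraction is not None:
            data["missing_fraction"] = np.asarray(missing_fraction, dtype=float)
        return cls(pd.DataFrame(data), pop_names=list(freqs))

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.df["marker_id"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def missing_fraction(self) -> np.ndarray:
        return self.df["missing_fraction"].to_numpy(dtype=float)

    def chrom_codes(self) -> np.ndarray:
        """Integer codes encoding natural chromosome order."""
        uniq = sorted(set(map(str, self.df["chrom"])), key=_chrom_sort_key)
        lookup = {c: i for i, c in enumerate(uniq)}
        return np.array([lookup[str(c)] for c in self.df["chrom"]], dtype=np.int64)

    def freqs(self, pop: str) -> np.ndarray:
        """Reference-allele frequency vector for one population."""
        if pop not in self.pop_names:
            raise KeyError(f"unknown population {pop!r}; have {self.pop_names}")
        return self.df[f"freq_{pop}"].to_numpy(dtype=float)

    def mean_freqs(self) -> np.ndarray:
        """Across-population mean reference-allele frequency, p-bar."""
        mat = np.stack([self.freqs(p) for p in self.pop_names])
        return mat.mean(axis=0)

    def allele_freq_matrix(self, marker_id: str) -> np.ndarray:
        """K x 2 matrix of (reference, alternate) frequencies for one marker."""
        idx = np.flatnonzero(self.marker_ids == marker_id)
        if idx.size == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        p = np.array([self.freqs(pop)[idx[0]] for pop in self.pop_names])
        return np.column_stack([p, 1.0 - p])

    def subset(self, marker_ids: Sequence[str]) -> "FrequencyTable":
        """Subset to the given markers (result re-sorted by genome order)."""
        wanted = set(marker_ids)
        missing = wanted - set(self.marker_ids)
        if missing:
            raise KeyError(f"markers not in table: {sorted(missing)[:5]}")
        return FrequencyTable(
            self.df[self.df["marker_id"].isin(wanted)].reset_index(drop=True),
            pop_names=self.pop_names,
        )

    def __repr__(self) -> str:
        return f"FrequencyTable({len(self)} markers, pops={list(self.pop_names)})"


# ----------------------------------------------------------------------
# scalar / vector measures
# ----------------------------------------------------------------------

def delta(p1, p2):
    """Absolute allele-frequency difference |p1 - p2|.

    1 means a fixed difference (perfect ancestry information), 0 means
    identical frequencies (no information).  Symmetric in population
    order and in the choice of reference allele.
    """
    scalar = np.isscalar(p1) and np.isscalar(p2)
    p1 = _check_freq("p1", p1)
    p2 = _check_freq("p2", p2)
    return _scalar_or_array(np.abs(p1 - p2), scalar)


def fst_pair(p1, p2):
    """Two-population biallelic F_ST: (p1-p2)^2 / [(p1+p2)(2-(p1+p2))].

    Ranges over [0, 1].  A marker monomorphic for the same allele in both
    populations (0/0 case) is defined to score 0 — it carries no ancestry
    information.  Invariant to swapping populations or alleles.
    """
    scalar = np.isscalar(p1) and np.isscalar(p2)
    p1 = _check_freq("p1", p1)
    p2 = _check_freq("p2", p2)
    s = p1 + p2
    den = s * (2.0 - s)
    num = (p1 - p2) ** 2
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0.0)
    return _scalar_or_array(out, scalar)


def fic(p1, p2, spec: AdmixtureSpec | None = None):
    """Fisher information content of a marker for the admixture fraction.

    FIC = sum_j delta_j^2 / pA_j with pA_j = p2_j + m1 * delta_j the
    expected admixed frequency of allele j.  Requires m1 strictly inside
    (0, 1).  When some pA_j = 0 with delta_j != 0 the information is
    unbounded and ``inf`` is returned (ranks above every finite score);
    a term with delta_j = 0 contributes 0 even at pA_j = 0.
    """
    spec = spec or AdmixtureSpec()
    if not (0.0 < spec.m1 < 1.0):
        raise ValueError(f"fic requires m1 strictly in (0, 1), got {spec.m1}")
    scalar = np.isscalar(p1) and np.isscalar(p2)
    p1 = _check_freq("p1", p1)
    p2 = _check_freq("p2", p2)
    d = p1 - p2
    pa1 = p2 + spec.m1 * d
    pa2 = 1.0 - pa1
    d2 = d * d
    with np.errstate(divide="ignore"):
        t1 = np.where(d2 == 0.0, 0.0, np.divide(d2, pa1, out=np.full_like(d2, np.inf), where=pa1 > 0.0))
        t2 = np.where(d2 == 0.0, 0.0, np.divide(d2, pa2, out=np.full_like(d2, np.inf), where=pa2 > 0.0))
    return _scalar_or_array(t1 + t2, scalar)


def sic(p1, p2, spec: AdmixtureSpec | None = None, log_base: str = "e"):
    """Shannon information content of a marker for ancestry.

    SIC = H(pA) - m1*H(p1) - m2*H(p2), the Jensen gap of the entropy at
    the admixed mixture pA = m1*p1 + m2*p2; nonnegative by concavity and
    0 exactly when p1 = p2.
    """
    spec = spec or AdmixtureSpec()
    scalar = np.isscalar(p1) and np.isscalar(p2)
    p1 = _check_freq("p1", p1)
    p2 = _check_freq("p2", p2)
    pa = spec.m1 * p1 + spec.m2 * p2
    val = _entropy2(pa) - spec.m1 * _entropy2(p1) - spec.m2 * _entropy2(p2)
    val = np.maximum(val, 0.0) / _log_scale(log_base)
    return _scalar_or_array(val, scalar)


def informativeness_assignment(freqs, log_base: str = "e"):
    """Informativeness for assignment I_n of one locus.

    Parameters
    ----------
    freqs : (K, N) array
        Allele frequencies; row i is the distribution over the N alleles
        in population i and must sum to 1.

    Returns
    -------
    float in [0, log K]: the expected log likelihood ratio of assigning
    an allele to its population of origin versus an "average" population
    with the across-population mean frequencies.  0 iff all populations
    share identical frequencies.
    """
    mat = np.asarray(freqs, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("freqs must be a K x N matrix with K >= 2, N >= 2")
    if np.any((mat < -1e-9) | (mat > 1.0 + 1e-9)):
        raise ValueError("frequencies must lie in [0, 1]")
    if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each population row must sum to 1")
    K = mat.shape[0]
    pbar = mat.mean(axis=0)
    val = float(np.sum(-_xlogx(pbar) + _xlogx(mat).sum(axis=0) / K))
    return min(max(val, 0.0), math.log(K)) / _log_scale(log_base)


# ----------------------------------------------------------------------
# table-level scoring and ranking
# ----------------------------------------------------------------------

def rank_descending(
    values: np.ndarray,
    chrom_codes: np.ndarray,
    pos: np.ndarray,
    marker_ids: np.ndarray,
) -> np.ndarray:
    """Rank values descending (1 = largest), ties broken by (chrom, pos, id).

    ``inf`` ranks above every finite value.  Deterministic: the tie-break
    is a total order, so ranks are a permutation of 1..M.
    """
    id_codes = np.empty(len(marker_ids), dtype=np.int64)
    id_codes[np.argsort(marker_ids, kind="stable")] = np.arange(len(marker_ids))
    order = np.lexsort((id_codes, pos, chrom_codes, -np.asarray(values, dtype=float)))
    ranks = np.empty(len(values), dtype=np.int64)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


@dataclass
class MeasureScores:
    """Per-marker values and ranks of the five informativeness measures.

    ``df`` columns: marker_id, chrom, pos, one column per computed
    measure, one ``rank_<measure>`` column each (1 = most informative),
    and a ``monomorphic`` flag for markers fixed for the same allele in
    both populations (scored 0 on every measure).
    """

    df: pd.DataFrame
    m1: float
    log_base: str
    measures: tuple[str, ...]
    pop_names: tuple[str, ...] = ()
    chrom_codes_: np.ndarray = field(default=None, repr=False)

    def values(self, measure: str) -> np.ndarray:
        self._check(measure)
        return self.df[measure].to_numpy(dtype=float)

    def ranks(self, measure: str) -> np.ndarray:
        self._check(measure)
        return self.df[f"rank_{measure}"].to_numpy(dtype=np.int64)

    def _check(self, measure: str) -> None:
        if measure not in self.measures:
            raise KeyError(f"measure {measure!r} not scored; have {self.measures}")

    @property
    def marker_ids(self) -> np.ndarray:
        return self.df["marker_id"].to_numpy()

    def chrom_codes(self) -> np.ndarray:
        if self.chrom_codes_ is None:
            uniq = sorted(set(map(str, self.df["chrom"])), key=_chrom_sort_key)
            lookup = {c: i for i, c in enumerate(uniq)}
            self.chrom_codes_ = np.array(
                [lookup[str(c)] for c in self.df["chrom"]], dtype=np.int64
            )
        return self.chrom_codes_

    def __len__(self) -> int:
        return len(self.df)


def score_table(
    table: FrequencyTable,
    spec: AdmixtureSpec | None = None,
    log_base: str = "e",
    measures: Iterable[str] = MEASURES,
) -> MeasureScores:
    """Score every marker in ``table`` with the requested measures.

    delta, fst, fic and sic are pairwise statistics and require exactly
    two populations; i_n accepts any K >= 2.  Markers monomorphic for
    the same allele in both populations are flagged and score 0 on all
    measures.  Ranks are descending-value with the deterministic
    (chrom, pos, marker_id) tie-break.
    """
    spec = spec or AdmixtureSpec()
    measures = tuple(measures)
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    pairwise = [m for m in measures if m != "i_n"]
    if table.n_pops != 2 and pairwise:
        raise UnsupportedMeasureError(
            f"measures {pairwise} are defined for exactly two populations "
            f"(table has {table.n_pops}); only i_n supports K > 2"
        )
    P = np.stack([table.freqs(p) for p in table.pop_names]) if len(table) else np.zeros(
        (table.n_pops, 0)
    )
    if np.any(np.isnan(P)):
        raise ValueError(
            "table contains NaN frequencies; apply aimsel.io.filter_shared first"
        )
    out = table.df[["marker_id", "chrom", "pos"]].copy()
    scale = _log_scale(log_base)
    if len(table):
        mono = np.all(P == P[0], axis=0) & ((P[0] == 0.0) | (P[0] == 1.0))
    else:
        mono = np.zeros(0, dtype=bool)
    out["monomorphic"] = mono

    if table.n_pops == 2 and len(table):
        p1, p2 = P[0], P[1]
    else:
        p1 = p2 = np.zeros(len(table))
    for m in measures:
        if m == "delta":
            vals = np.abs(p1 - p2)
        elif m == "fst":
            vals = fst_pair(p1, p2) if len(table) else np.zeros(0)
        elif m == "fic":
            vals = fic(p1, p2, spec) if len(table) else np.zeros(0)
        elif m == "sic":
            vals = sic(p1, p2, spec, log_base=log_base) if len(table) else np.zeros(0)
        elif m == "i_n":
            if len(table):
                K = P.shape[0]
                # stack (K, 2, M): reference and alternate allele frequencies
                cube = np.stack([P, 1.0 - P], axis=1)
                pbar = cube.mean(axis=0)  # (2, M)
                vals = (-_xlogx(pbar) + _xlogx(cube).sum(axis=0) / K).sum(axis=0)
                vals = np.clip(vals, 0.0, math.log(K)) / scale
            else:
                vals = np.zeros(0)
        out[m] = np.where(mono, 0.0, vals) if len(table) else vals

    codes = table.chrom_codes()
    for m in measures:
        out[f"rank_{m}"] = rank_descending(
            out[m].to_numpy(dtype=float), codes, table.positions, table.marker_ids
        )
    return MeasureScores(
        df=out,
        m1=spec.m1,
        log_base=log_base,
        measures=measures,
        pop_names=table.pop_names,
        chrom_codes_=codes,
    )
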