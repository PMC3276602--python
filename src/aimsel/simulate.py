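"""Self-contained synthetic data: ancestral frequencies, panel genotypes,
and a forward-time admixed population with tracked true ancestry.

Ancestral allele frequencies follow the Balding-Nichols model: the
ancestral frequency of each marker is drawn Uniform(0.05, 0.95) (common
variants only, mirroring a MAF > 5% filter) and each population's
frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), so F is a one-parameter
differentiation knob with E[F_ST] on the order of F.

The admixed deme is founded by ``n_founders`` diploids, each assigned
wholly to population 1 with probability ``m0`` and given haplotypes
drawn per-locus from that population's frequencies.  It then undergoes
``generations`` rounds of discrete non-overlapping random mating
(monoecious, no selfing, constant deme size, no mutation or selection)
with Poisson/Haldane recombination (``recomb_rate`` Morgans per bp,
crossover positions uniform along each chromosome).  Every allele copy
carries an ancestry label propagated through meiosis; an individual's
true ancestry q_i is the fraction of its 2L allele copies labelled
population 1 — exactly the quantity the genotype-based estimator
targets.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .ancestry import GenotypeMatrix
from .measures import FrequencyTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_ancestral_freqs",
    "generate_panel_genotypes",
    "simulate_admixed",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic admixture scenario.

    Defaults mimic a CEU/YRI-like two-way admixture: F = 0.15 gives a
    strongly differentiated founder pair, m0 = 0.7 the 70:30 average
    contribution, 10 generations of mating since founding.  A CHB/JPT-
    like scenario uses m0 = 0.72 with a roughly ten-fold smaller F.
    """

    n_markers: int = 20_000
    chrom_lengths: tuple[int, ...] = tuple([20_000_000] * 10)
    fst: float = 0.15  # Balding-Nichols differentiation F
    m0: float = 0.7  # initial population-1 contribution
    generations: int = 10
    n_admixed: int = 100
    n_founders: int = 200
    recomb_rate: float = 1e-8  # Morgans per bp (1 cM/Mb)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie strictly in (0, 1)")
        if not (0.0 <= self.m0 <= 1.0):
            raise ValueError("m0 must lie in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if min(self.n_markers, self.n_admixed, self.n_founders) < 1:
            raise ValueError("all counts must be positive")
        if not self.chrom_lengths or min(self.chrom_lengths) < 1:
            raise ValueError("chrom_lengths must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Known per-individual ancestry of the simulated admixed sample.

    ``q_true[i]`` equals the fraction of individual i's 2L allele
    copies carrying a population-1 ancestry label.  ``ancestry`` is the
    full (n, 2, L) label array (1 = population 1) from which q_true is
    derived.
    """

    sample_ids: np.ndarray
    q_true: np.ndarray
    ancestry: np.ndarray | None = None

    @property
    def mean_q_true(self) -> float:
        return float(np.mean(self.q_true))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "q_true": self.q_true})


def _marker_layout(config: SimConfig, rng: np.random.Generator):
    """Assign markers to chromosomes proportional to length, positions unique."""
    lengths = np.asarray(config.chrom_lengths, dtype=float)
    weights = lengths / lengths.sum()
    counts = np.floor(config.n_markers * weights).astype(int)
    remainder = config.n_markers - counts.sum()
    order = np.argsort(-(config.n_markers * weights - counts), kind="stable")
    counts[order[:remainder]] += 1
    chroms, positions = [], []
    for c, (count, length) in enumerate(zip(counts, config.chrom_lengths), start=1):
        pos: set[int] = set()
        while len(pos) < count:
            draw = rng.integers(1, length + 1, size=count - len(pos))
            pos.update(int(x) for x in draw)
        chroms.extend([str(c)] * count)
        positions.extend(sorted(pos))
    return np.array(chroms), np.array(positions, dtype=np.int64)


def generate_ancestral_freqs(
    config: SimConfig, pop_names: Sequence[str] = ("pop1", "pop2")
) -> FrequencyTable:
    """Balding-Nichols reference-allele frequencies for two populations."""
    rng = np.random.default_rng(config.seed)
    chroms, positions = _marker_layout(config, rng)
    p_anc = rng.uniform(0.05, 0.95, config.n_markers)
    shape = (1.0 - config.fst) / config.fst
    freqs = {
        pop: rng.beta(p_anc * shape, (1.0 - p_anc) * shape) for pop in pop_names
    }
    ids = [f"m{i:06d}" for i in range(config.n_markers)]
    return FrequencyTable.from_arrays(ids, chroms, positions, freqs)


def generate_panel_genotypes(
    table: FrequencyTable, pop: str, n: int, seed: int = 0
) -> GenotypeMatrix:
    """HWE genotypes for n individuals from one ancestral population."""
    rng = np.random.default_rng(seed)
    p = table.freqs(pop)
    if np.any(np.isnan(p)):
        raise ValueError("table has missing frequencies for this population")
    g = rng.binomial(2, p, size=(n, len(p))).astype(np.int8)
    ids = [f"{pop}_{i:04d}" for i in range(n)]
    return GenotypeMatrix(ids, list(table.marker_ids), g)


def _gamete_mask(
    rng: np.random.Generator,
    chrom_slices: list[tuple[slice, np.ndarray, int]],
    recomb_rate: float,
    L: int,
) -> np.ndarray:
    """Which parental haplotype (0/1) each locus of a gamete comes from."""
    mask = np.empty(L, dtype=np.int8)
    for sl, pos, length in chrom_slices:
        n_cross = rng.poisson(length * recomb_rate) if recomb_rate > 0 else 0
        start = rng.integers(2)
        if n_cross == 0:
            mask[sl] = start
            continue
        cross = np.sort(rng.uniform(0.0, length, n_cross))
        seg = np.searchsorted(cross, pos)
        mask[sl] = (start + seg) % 2
    return mask


def simulate_admixed(
    table: FrequencyTable, config: SimConfig, keep_ancestry: bool = True
) -> tuple[GenotypeMatrix, SimTruth]:
    """Forward-simulate the admixed deme and sample genotypes plus truth.

    The deme size stays at ``config.n_founders``; ``config.n_admixed``
    individuals are sampled without replacement from the final
    generation.  With ``generations = 0`` the founders themselves are
    sampled, so every haplotype is single-ancestry.
    """
    if table.n_pops != 2:
        raise ValueError("simulation requires a two-population table")
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders for random mating")
    if config.n_admixed > config.n_founders:
        raise ValueError("n_admixed cannot exceed the deme size (n_founders)")
    rng = np.random.default_rng(config.seed)
    L = len(table)
    p1 = table.freqs(table.pop_names[0])
    p2 = table.freqs(table.pop_names[1])
    if np.any(np.isnan(p1)) or np.any(np.isnan(p2)):
        raise ValueError("table contains missing frequencies")

    # per-chromosome marker blocks (table is genome-sorted)
    chrom_slices = []
    chroms = table.chroms
    positions = table.positions
    start = 0
    lengths = dict(zip((str(i + 1) for i in range(len(config.chrom_lengths))),
                       config.chrom_lengths))
    for c in pd.unique(chroms):
        end = start + int(np.sum(chroms == c))
        length = lengths.get(str(c), int(positions[start:end].max()))
        chrom_slices.append((slice(start, end), positions[start:end].astype(float), length))
        start = end

    N = config.n_founders
    founder_pop1 = rng.random(N) < config.m0
    hap_labels = np.repeat(founder_pop1, 2)  # haplotype order: ind0 hapA, ind0 hapB, ...
    p_sel = np.where(hap_labels[:, None], p1[None, :], p2[None, :])
    alleles = (rng.random((2 * N, L)) < p_sel).astype(np.int8)
    ancestry = np.repeat(hap_labels.astype(np.int8)[:, None], L, axis=1).copy()

    for _ in range(config.generations):
        mothers = rng.integers(0, N, size=N)
        fathers = rng.integers(0, N, size=N)
        clash = mothers == fathers
        while clash.any():
            fathers[clash] = rng.integers(0, N, size=int(clash.sum()))
            clash = mothers == fathers
        new_alleles = np.empty_like(alleles)
        new_ancestry = np.empty_like(ancestry)
        for child in range(N):
            for h, parent in enumerate((mothers[child], fathers[child])):
                mask = _gamete_mask(rng, chrom_slices, config.recomb_rate, L)
                a0, a1 = alleles[2 * parent], alleles[2 * parent + 1]
                c0, c1 = ancestry[2 * parent], ancestry[2 * parent + 1]
                row = 2 * child + h
                new_alleles[row] = np.where(mask == 0, a0, a1)
                new_ancestry[row] = np.where(mask == 0, c0, c1)
        alleles, ancestry = new_alleles, new_ancestry

    chosen = rng.choice(N, size=config.n_admixed, replace=False)
    rows = np.stack([2 * chosen, 2 * chosen + 1], axis=1).reshape(-1)
    g = (alleles[rows[0::2]] + alleles[rows[1::2]]).astype(np.int8)
    anc = ancestry[rows].reshape(config.n_admixed, 2, L)
    q_true = anc.mean(axis=(1, 2))
    ids = [f"adm_{i:04d}" for i in range(config.n_admixed)]
    truth = SimTruth(
        sample_ids=np.array(ids, dtype=object),
        q_true=q_true.astype(float),
        ancestry=anc if keep_ancestry else None,
    )
    return GenotypeMatrix(ids, list(table.marker_ids), g), truth
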