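"""Separate-sex Beverton-Holt demography with female-limited viability selection.

Each generation: (1) sex-specific mean gamete pools are formed by averaging
the per-genotype gamete distributions over the adult males and females; (2)
offspring genotype probabilities follow from random union of gametes; (3) the
offspring total T is drawn Poisson around the Beverton-Holt mean
M = 2 R_m F / (1 + (R_m - 1) N/K), whose all-wild-type fixed point is K; (4)
offspring are assigned (sex, genotype) and survive to adulthood — females with
probability equal to their genotype fitness, males unconditionally — in a
single categorical draw through the hybrid multinomial sampler, so counts are
exactly conserved. Extinction is declared when either sex has no adults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DriveParams
from .reproduction import ReproductionTables
from .sampling import hybrid_multinomial

__all__ = ["PopulationState", "expected_offspring_total", "next_generation"]

FEMALE, MALE = 0, 1


@dataclass
class PopulationState:
    """Adult counts by sex and diploid genotype at one generation.

    ``counts`` has shape (2, n_genotypes) with row 0 = females, row 1 = males.
    """

    generation: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2:
            raise ValueError("counts must have shape (2, n_genotypes)")
        if (self.counts < 0).any():
            raise ValueError("negative individual counts")

    @property
    def n_females(self) -> int:
        return int(self.counts[FEMALE].sum())

    @property
    def n_males(self) -> int:
        return int(self.counts[MALE].sum())

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def is_extinct(self) -> bool:
        """No males or no females: the population cannot reproduce."""
        return self.n_females == 0 or self.n_males == 0

    def haplotype_counts(self, tables: ReproductionTables) -> np.ndarray:
        """Chromosome counts per haplotype over all adults of both sexes."""
        per_geno = self.counts.sum(axis=0).astype(float)
        return per_geno @ tables.chromosome_of

    def haplotype_frequencies(self, tables: ReproductionTables) -> np.ndarray:
        chrom = self.haplotype_counts(tables)
        total = chrom.sum()
        if total == 0:
            return np.zeros_like(chrom)
        return chrom / total

    @classmethod
    def wild_type(cls, params: DriveParams, tables: ReproductionTables) -> "PopulationState":
        """All-wild-type population of size K, even sex ratio."""
        counts = np.zeros((2, tables.n_geno), dtype=np.int64)
        wt_geno = tables.genotype_index(0, 0)
        counts[FEMALE, wt_geno] = params.K // 2
        counts[MALE, wt_geno] = params.K - params.K // 2
        return cls(generation=0, counts=counts)


def expected_offspring_total(state: PopulationState, params: DriveParams) -> float:
    """Beverton-Holt mean offspring count M = 2 R_m F / (1 + (R_m-1) N/K)."""
    n_f = state.n_females
    n_t = state.total
    if n_f == 0:
        return 0.0
    return 2.0 * params.R_m * n_f / (1.0 + (params.R_m - 1.0) * n_t / params.K)


def next_generation(
    state: PopulationState,
    tables: ReproductionTables,
    params: DriveParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance one generation; returns the new adult population state."""
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if state.is_extinct:
        return PopulationState(state.generation + 1, np.zeros_like(state.counts))

    male_counts = state.counts[MALE].astype(float)
    female_counts = state.counts[FEMALE].astype(float)
    male_pool = male_counts @ tables.G / male_counts.sum()
    female_pool = female_counts @ tables.G / female_counts.sum()
    if not (np.isfinite(male_pool).all() and np.isfinite(female_pool).all()):
        raise FloatingPointError("non-finite gamete pool")

    offspring_probs = tables.offspring_distribution(male_pool, female_pool)

    mean_total = expected_offspring_total(state, params)
    if params.deterministic_offspring:
        total = int(round(mean_total))
    else:
        total = int(rng.poisson(mean_total))
    n_geno = tables.n_geno
    new_counts = np.zeros((2, n_geno), dtype=np.int64)
    if total > 0:
        # categories: adult male genotypes, adult female genotypes (survival
        # already applied), and non-surviving females
        cat = np.concatenate(
            [
                0.5 * offspring_probs,
                0.5 * offspring_probs * tables.female_w,
            ]
        )
        cat = np.append(cat, max(0.0, 1.0 - cat.sum()))
        draws = hybrid_multinomial(
            total,
            cat,
            rng,
            threshold=params.sampler_threshold,
            exact_cutoff=params.exact_sampler_cutoff,
        )
        new_counts[MALE] = draws[:n_geno]
        new_counts[FEMALE] = draws[n_geno : 2 * n_geno]
    return PopulationState(state.generation + 1, new_counts)
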