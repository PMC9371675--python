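"""Female fitness, gamete generation and offspring genotype probabilities.

Gamete generation in W/D heterozygous germlines models, independently at each
cleavable (W) site: homing (HDR) with probability eps*(1-nu), NHEJ repair to a
functional R allele with eps*nu*beta, NHEJ to a nonfunctional N allele with
eps*nu*(1-beta), and no cut with 1-eps. A single homing event converts the
whole chromosome to drive, so the total non-drive gamete fraction from such a
genotype is (1/2) * [1 - eps*(1-nu)]**(m-r), where r is the number of already
resistant (uncleavable) sites. After conversion, every remaining W site of a
non-drive gamete mutates de novo to R with probability xi*mu and to N with
probability (1-xi)*mu. Multi-site terms are kept exactly (no linearization in
mu). Fitness costs act on female survival only; males have fitness 1.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np

from .genetics import (
    Genotype,
    Haplotype,
    enumerate_genotypes,
    enumerate_haplotypes,
    genotype_index,
    haplotype_index,
)
from .params import DriveParams

__all__ = [
    "site_pair_fitness",
    "female_fitness",
    "gamete_distribution",
    "offspring_genotype_distribution",
    "ReproductionTables",
]


def _fitness_table(params: DriveParams) -> dict[frozenset, float]:
    s, h, h_N, sigma = params.s, params.h, params.h_N, params.sigma
    table = {
        frozenset(("W",)): 1.0,
        frozenset(("W", "R")): 1.0 - sigma,
        frozenset(("W", "N")): 1.0 - h_N * s,
        frozenset(("W", "D")): 1.0 - h * s,
        frozenset(("R",)): max(0.0, 1.0 - 2.0 * sigma),
        frozenset(("R", "N")): (1.0 - sigma) * (1.0 - h_N * s),
        frozenset(("R", "D")): 1.0 - sigma,
        frozenset(("N",)): 1.0 - s,
        frozenset(("N", "D")): 1.0 - s,
        frozenset(("D",)): 1.0 - s,
    }
    if params.fitness_overrides:
        for key, value in params.fitness_overrides.items():
            pair = frozenset(key.upper())
            if pair not in table:
                raise ValueError(f"unknown fitness override pair {key!r}")
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"fitness override {key!r}={value} outside [0, 1]")
            table[pair] = float(value)
    return table


def site_pair_fitness(a: str, b: str, params: DriveParams) -> float:
    """Symmetric per-site female survival factor for the allele pair (a, b)."""
    for x in (a, b):
        if x not in ("W", "R", "N", "D"):
            raise ValueError(f"unknown allele symbol {x!r}")
    return _fitness_table(params)[frozenset((a, b))]


def _site_vector(h: Haplotype) -> tuple[str, ...]:
    """Canonical (sorted W,R,N) per-site allele vector; all-D for drive."""
    if h.is_drive:
        return ("D",) * h.m
    n_w, n_r, n_n = h.counts
    return ("W",) * n_w + ("R",) * n_r + ("N",) * n_n


def female_fitness(g: Genotype, params: DriveParams) -> float:
    """Survival probability of a female, multiplicative over the m sites.

    The two haplotypes' canonical allele vectors are aligned position-wise (the
    model tracks multisets, not positions, so this fixes the pairing between
    two mosaic haplotypes); the drive haplotype contributes D at every site.
    """
    haps = enumerate_haplotypes(params.m)
    table = _fitness_table(params)
    va, vb = _site_vector(haps[g.i]), _site_vector(haps[g.j])
    w = 1.0
    for a, b in zip(va, vb):
        w *= table[frozenset((a, b))]
    return w


def _compositions(n: int):
    """All (k1, k2, k3) with k1+k2+k3 = n, together with multinomial(n; k)."""
    for k1 in range(n + 1):
        for k2 in range(n - k1 + 1):
            k3 = n - k1 - k2
            yield (k1, k2, k3), comb(n, k1) * comb(n - k1, k2)


def _cleaved_gamete_classes(h: Haplotype, params: DriveParams):
    """Outcome classes of one chromosome ``h`` transmitted from an h/D germline.

    Returns (dict counts -> prob of non-drive mosaic outcomes, prob of D),
    per transmitted gamete from this chromosome (i.e. conditional on the
    gamete deriving from ``h`` rather than its drive partner).
    """
    n_w, n_r, n_n = h.counts
    p_w = 1.0 - params.epsilon
    p_r = params.epsilon * params.nu * params.beta
    p_n = params.epsilon * params.nu * (1.0 - params.beta)
    classes: dict[tuple[int, int, int], float] = {}
    total_nondrive = 0.0
    for (k_w, k_r, k_n), coef in _compositions(n_w):
        pr = coef * p_w**k_w * p_r**k_r * p_n**k_n
        if pr == 0.0:
            continue
        out = (k_w, n_r + k_r, n_n + k_n)
        classes[out] = classes.get(out, 0.0) + pr
        total_nondrive += pr
    return classes, 1.0 - total_nondrive


def _mutate_classes(classes: dict, params: DriveParams) -> dict:
    """Apply per-W-site de novo mutation to a dict of non-drive gamete classes."""
    mu, xi = params.mu, params.xi
    if mu == 0.0:
        return dict(classes)
    p_stay = 1.0 - mu
    p_r = xi * mu
    p_n = (1.0 - xi) * mu
    out: dict[tuple[int, int, int], float] = {}
    for (n_w, n_r, n_n), q in classes.items():
        for (k_w, k_r, k_n), coef in _compositions(n_w):
            pr = coef * p_stay**k_w * p_r**k_r * p_n**k_n
            if pr == 0.0:
                continue
            key = (k_w, n_r + k_r, n_n + k_n)
            out[key] = out.get(key, 0.0) + q * pr
    return out


def gamete_distribution(g: Genotype, params: DriveParams) -> np.ndarray:
    """Probability vector over haplotypes of a gamete from genotype ``g``.

    Drive conversion (in W/D-type germlines of either sex) acts first, then de
    novo mutation of remaining W sites; the drive haplotype neither cleaves
    itself nor mutates. The returned vector sums to 1.
    """
    haps = enumerate_haplotypes(params.m)
    index = haplotype_index(params.m)
    h1, h2 = haps[g.i], haps[g.j]
    pool = np.zeros(len(haps))
    drive_idx = len(haps) - 1

    if h1.is_drive and h2.is_drive:
        pool[drive_idx] = 1.0
        return pool

    if h1.is_drive or h2.is_drive:
        h = h2 if h1.is_drive else h1
        classes, p_converted = _cleaved_gamete_classes(h, params)
        # half the gametes carry the drive chromosome; of the other half, a
        # fraction p_converted was homed to drive
        pool[drive_idx] += 0.5 + 0.5 * p_converted
        classes = {k: 0.5 * v for k, v in classes.items()}
    else:
        classes = {}
        for h in (h1, h2):
            key = h.counts
            classes[key] = classes.get(key, 0.0) + 0.5

    for (n_w, n_r, n_n), q in _mutate_classes(classes, params).items():
        pool[index["W" * n_w + "R" * n_r + "N" * n_n]] += q
    return pool


def offspring_genotype_distribution(
    male_pool: np.ndarray, female_pool: np.ndarray
) -> np.ndarray:
    """Genotype probabilities from the random union of one gamete per parent."""
    male_pool = np.asarray(male_pool, dtype=float)
    female_pool = np.asarray(female_pool, dtype=float)
    for name, p in (("male", male_pool), ("female", female_pool)):
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError(f"{name} gamete pool is not a probability vector")
    outer = np.outer(male_pool, female_pool)
    iu, ju = np.triu_indices(len(male_pool))
    probs = outer[iu, ju] + np.where(iu != ju, outer[ju, iu], 0.0)
    return probs


class ReproductionTables:
    """Precomputed per-parameter arrays used by the generation loop.

    Attributes
    ----------
    haplotypes, genotypes : canonical enumerations for ``params.m``.
    G : (n_genotypes, n_haplotypes) gamete distribution per parental genotype.
    female_w : (n_genotypes,) female survival probabilities.
    chromosome_of : (n_genotypes, n_haplotypes) chromosome dosage (0/1/2) each
        genotype contributes to each haplotype.
    fully_resistant : boolean haplotype mask (R or N at all m sites).
    """

    def __init__(self, params: DriveParams):
        self.params = params
        self.haplotypes = enumerate_haplotypes(params.m)
        self.genotypes = enumerate_genotypes(params.m)
        self.n_hap = len(self.haplotypes)
        self.n_geno = len(self.genotypes)
        self.drive_index = self.n_hap - 1
        self.G = np.array([gamete_distribution(g, params) for g in self.genotypes])
        self.female_w = np.array([female_fitness(g, params) for g in self.genotypes])
        self.pair_i = np.array([g.i for g in self.genotypes])
        self.pair_j = np.array([g.j for g in self.genotypes])
        self.chromosome_of = np.zeros((self.n_geno, self.n_hap))
        for k, g in enumerate(self.genotypes):
            self.chromosome_of[k, g.i] += 1
            self.chromosome_of[k, g.j] += 1
        self.fully_resistant = np.array(
            [(not h.is_drive) and h.is_fully_resistant() for h in self.haplotypes]
        )
        self._iu, self._ju = np.triu_indices(self.n_hap)

    def genotype_index(self, i: int, j: int) -> int:
        return genotype_index(i, j, self.n_hap)

    def offspring_distribution(
        self, male_pool: np.ndarray, female_pool: np.ndarray
    ) -> np.ndarray:
        outer = np.outer(male_pool, female_pool)
        iu, ju = self._iu, self._ju
        return outer[iu, ju] + np.where(iu != ju, outer[ju, iu], 0.0)
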