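"""Model parameters for multiplexed suppression-drive simulations.

``DriveParams`` collects every rate, fitness and demographic constant of the
model. Defaults follow the study conditions for a *doublesex*-like target in
*Anopheles gambiae*: cleavage efficiency eps = 0.95 and NHEJ rate nu = 0.05 per
generation per heterozygous target site, a target-site mutation rate
mu = 18 * 3e-9 (an 18 bp site at the Drosophila per-base rate), lethal
nonfunctional homozygotes (s = 1) with dominance h = 0.3 against W/D and
h_N = 0.02 against W/N, and drive released at allele frequency 0.1 in males.

``TheoryConstants`` holds the calibration constants of the closed-form
critical-population-size formulas (gamma_n, gamma_m, gamma, s_b, tau).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

BASE_PAIR_MUTATION_RATE = 3e-9
TARGET_SITE_LENGTH = 18
#: per-generation mutation rate of one whole target site
DEFAULT_MU = TARGET_SITE_LENGTH * BASE_PAIR_MUTATION_RATE  # 5.4e-8

_UNIT_INTERVAL_FIELDS = (
    "epsilon", "nu", "beta", "xi", "mu", "sigma", "s", "h", "h_N",
)


@dataclass
class DriveParams:
    """All rates, fitness parameters and demography of one simulation setup.

    Parameters
    ----------
    m : number of gRNAs / target sites within the locus.
    K : carrying capacity of the Beverton-Holt regulation; identified with the
        effective population size N of the analytic formulas.
    epsilon : per-site cleavage probability in W/D germlines, per generation.
    nu : fraction of cleavage events resolved by NHEJ (rather than homing).
    beta : fraction of NHEJ repair products that are functional (R vs N).
    xi : fraction of de novo target-site mutations that are functional.
    mu : de novo mutation rate per target site per generation.
    sigma : heterozygous fitness cost of a functional resistant allele R
        (female survival, absence of drive).
    s : homozygous fitness cost of nonfunctional alleles (D or N); 1 = lethal
        to female fertility/survival.
    h : dominance of the drive allele against W (leaky somatic expression).
    h_N : dominance of N against W.
    R_m : intrinsic per-capita growth rate at low density.
    release_freq : drive allele frequency introduced in males at t = 0.
    resistance_threshold : summed frequency of fully resistant haplotypes at
        which a replicate is classified as resistant.
    max_generations : censoring horizon after drive release.
    standing_variation : run a pre-release burn-in of ``burn_in_multiplier/sigma``
        generations so R variants start from mutation-selection balance.
    burn_in_multiplier : multiplier on the 1/sigma burn-in length.
    deterministic_offspring : draw the offspring total as round(M) instead of
        Poisson(M) (pure Wright-Fisher mode for calibration tests).
    sampler_threshold : expected-count boundary between the Poisson (rare) and
        Gaussian (common) blocks of the hybrid multinomial sampler.
    exact_sampler_cutoff : totals at or below this use exact multinomial draws.
    fitness_overrides : optional map like ``{"RD": 0.99}`` replacing individual
        site-pair fitness factors.
    """

    m: int
    K: int
    epsilon: float = 0.95
    nu: float = 0.05
    beta: float = 0.0
    xi: float = 1.0
    mu: float = DEFAULT_MU
    sigma: float = 0.01
    s: float = 1.0
    h: float = 0.3
    h_N: float = 0.02
    R_m: float = 6.0
    release_freq: float = 0.1
    resistance_threshold: float = 0.95
    max_generations: int = 1000
    standing_variation: bool = False
    burn_in_multiplier: float = 1.0
    deterministic_offspring: bool = False
    sampler_threshold: float = 10.0
    exact_sampler_cutoff: int = 1_000_000
    fitness_overrides: dict | None = None

    def __post_init__(self):
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        for name in _UNIT_INTERVAL_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.R_m <= 1.0:
            raise ValueError(f"R_m must exceed 1 for a viable population, got {self.R_m}")
        if not 0.0 <= self.release_freq < 1.0:
            raise ValueError(f"release_freq must lie in [0, 1), got {self.release_freq}")
        if not 0.0 < self.resistance_threshold <= 1.0:
            raise ValueError("resistance_threshold must lie in (0, 1]")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.burn_in_multiplier <= 0:
            raise ValueError("burn_in_multiplier must be positive")
        if self.sampler_threshold < 0:
            raise ValueError("sampler_threshold must be non-negative")
        if self.standing_variation and self.sigma == 0.0:
            raise ValueError(
                "burn-in length 1/sigma is infinite at sigma=0; "
                "disable standing_variation or set sigma > 0"
            )

    def with_(self, **changes) -> "DriveParams":
        """A copy with the given fields replaced (validation re-runs)."""
        return replace(self, **changes)


def _default_gamma_m() -> dict[int, float]:
    return {1: 0.76, 2: 6.0, 3: 55.0}


@dataclass
class TheoryConstants:
    """Fitted constants of the critical-population-size formulas.

    gamma_n : NHEJ-pathway constant; ~0.2 for all m.
    gamma_m : de novo pathway constants per m (0.76, 6, 55 for m = 1..3);
        for other m extrapolated as ``s_b_denovo * tau**m``.
    s_b_denovo, tau : effective establishment benefit and accumulation
        timescale (generations) behind the gamma_m sequence.
    gamma : standing-variation scaling constant (~2).
    s_b : establishment benefit of a resistant haplotype against drive used in
        the standing-variation formula (~0.5).
    """

    gamma_n: float = 0.2
    gamma_m: dict[int, float] = field(default_factory=_default_gamma_m)
    s_b_denovo: float = 0.09
    tau: float = 8.5
    gamma: float = 2.0
    s_b: float = 0.5

    def __post_init__(self):
        for name in ("gamma_n", "s_b_denovo", "tau", "gamma", "s_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.gamma_m.values()):
            raise ValueError("gamma_m entries must be positive")

    def gamma_m_for(self, m: int) -> float:
        """gamma_m from the fitted table, else the s_b * tau**m extrapolation."""
        if m in self.gamma_m:
            return self.gamma_m[m]
        return self.s_b_denovo * self.tau**m
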