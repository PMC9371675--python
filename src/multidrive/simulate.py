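"""Replicate orchestration: burn-in, drive release, outcome classification.

A replicate optionally equilibrates standing variation for
``burn_in_multiplier / sigma`` generations (mutation and selection, no drive),
releases drive homozygous males so the drive allele frequency among male
chromosomes equals ``release_freq`` (0.1 by default), and then iterates
generations until one of three endpoints: *resistance* — the summed frequency
of fully resistant haplotypes (R or N at all m sites) over all adult
chromosomes reaches ``resistance_threshold`` (0.95); *elimination* — the
population loses one or both sexes; or *censored* at ``max_generations``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import FEMALE, MALE, PopulationState, next_generation
from .params import DriveParams
from .reproduction import ReproductionTables

__all__ = [
    "ReplicateOutcome",
    "BurnInDiagnostics",
    "burn_in",
    "introduce_drive",
    "run_replicate",
    "resistance_probability",
    "replicate_rng",
]

RESISTANCE, ELIMINATION, CENSORED = "resistance", "elimination", "censored"


@dataclass
class ReplicateOutcome:
    """Classified endpoint of one replicate simulation."""

    outcome: str
    t_resistance: int | None
    t_elimination: int | None
    final_freqs: np.ndarray
    final_total: int
    generations_run: int


@dataclass
class BurnInDiagnostics:
    """Scaled inputs of the mutation-selection equilibrium reached by burn-in.

    theta = 4*N*xi*mu (scaled functional mutation input) and alpha = 4*N*sigma
    (scaled selection) are the shape and rate parameters of the gamma law that
    approximates the equilibrium R-frequency distribution when 4*N*sigma > 1.
    """

    theta: float
    alpha: float
    generations: int
    r_frequency: float


def replicate_rng(base_seed: int, *stream_key: int) -> np.random.Generator:
    """Independent generator for one replicate stream.

    Streams are derived as ``SeedSequence(base_seed, spawn_key=stream_key)``,
    so (base_seed, N-index, replicate-index) determines every random draw.
    """
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(int(k) for k in stream_key))
    return np.random.Generator(np.random.PCG64(ss))


def burn_in_generations(params: DriveParams) -> int:
    return math.ceil(params.burn_in_multiplier / params.sigma)


def burn_in(
    params: DriveParams,
    rng: np.random.Generator,
    tables: ReproductionTables | None = None,
) -> tuple[PopulationState, BurnInDiagnostics]:
    """Equilibrate standing variation before release (no drive present).

    Runs ceil(burn_in_multiplier / sigma) generations from an all-wild-type
    population of size K with de novo mutation and selection acting.
    """
    if params.sigma <= 0.0:
        raise ValueError("burn-in requires sigma > 0 (its length is 1/sigma)")
    tables = tables or ReproductionTables(params)
    state = PopulationState.wild_type(params, tables)
    n_gen = burn_in_generations(params)
    for _ in range(n_gen):
        state = next_generation(state, tables, params, rng)
        if state.is_extinct:  # pragma: no cover - K would have to be tiny
            break
    freqs = state.haplotype_frequencies(tables)
    r_freq = _functional_r_frequency(freqs, tables)
    diag = BurnInDiagnostics(
        theta=4.0 * params.K * params.xi * params.mu,
        alpha=4.0 * params.K * params.sigma,
        generations=n_gen,
        r_frequency=r_freq,
    )
    return state, diag


def _functional_r_frequency(freqs: np.ndarray, tables: ReproductionTables) -> float:
    """Mean per-site frequency of the functional R allele across haplotypes."""
    m = tables.params.m
    weight = np.array(
        [0 if h.is_drive else h.counts[1] / m for h in tables.haplotypes]
    )
    return float(freqs @ weight)


def introduce_drive(
    state: PopulationState,
    params: DriveParams,
    tables: ReproductionTables,
    rng: np.random.Generator,
) -> PopulationState:
    """Release drive-homozygous males at allele frequency ``release_freq``.

    Replaces uniformly chosen males with D/D males so that the D frequency
    among male chromosomes equals the release frequency; females and the total
    population size are untouched.
    """
    if state.n_males == 0:
        raise ValueError("cannot release drive into a population with no males")
    n_release = int(round(params.release_freq * state.n_males))
    if n_release == 0:
        return state
    counts = state.counts.copy()
    removed = rng.multivariate_hypergeometric(counts[MALE], n_release)
    counts[MALE] -= removed
    dd = tables.genotype_index(tables.drive_index, tables.drive_index)
    counts[MALE, dd] += n_release
    return PopulationState(state.generation, counts)


def run_replicate(
    params: DriveParams,
    rng: np.random.Generator,
    tables: ReproductionTables | None = None,
    record_trajectory: bool = False,
) -> ReplicateOutcome | tuple[ReplicateOutcome, pd.DataFrame]:
    """Run one full replicate and classify its endpoint.

    Generations are counted from the release of drive at t = 0. When
    ``record_trajectory`` is set, also returns a per-generation table of the
    total population size and haplotype frequencies.
    """
    tables = tables or ReproductionTables(params)
    if params.standing_variation:
        state, _ = burn_in(params, rng, tables)
    else:
        state = PopulationState.wild_type(params, tables)
    state = introduce_drive(state, params, tables, rng)
    state = PopulationState(0, state.counts)

    rows = []
    freqs = state.haplotype_frequencies(tables)
    t_res = None
    t_elim = None
    while True:
        if record_trajectory:
            rows.append((state.generation, state.total, *freqs))
        resistant_freq = float(freqs[tables.fully_resistant].sum())
        if resistant_freq >= params.resistance_threshold and state.total > 0:
            t_res = state.generation
            outcome = RESISTANCE
            break
        if state.is_extinct:
            t_elim = state.generation
            outcome = ELIMINATION
            break
        if state.generation >= params.max_generations:
            outcome = CENSORED
            break
        state = next_generation(state, tables, params, rng)
        freqs = state.haplotype_frequencies(tables)

    result = ReplicateOutcome(
        outcome=outcome,
        t_resistance=t_res,
        t_elimination=t_elim,
        final_freqs=freqs,
        final_total=state.total,
        generations_run=state.generation,
    )
    if record_trajectory:
        columns = ["generation", "total"] + [h.label for h in tables.haplotypes]
        return result, pd.DataFrame(rows, columns=columns)
    return result


def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for a binomial proportion."""
    from scipy import stats

    alpha = 1.0 - level
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def resistance_probability(
    params: DriveParams,
    N_grid,
    n_reps: int = 500,
    base_seed: int = 0,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate the probability of resistance on a grid of population sizes.

    For each N in ``N_grid`` the carrying capacity K is set to N and
    ``n_reps`` independent replicates are run on separate seed streams.

    Returns
    -------
    summary : per-N table with the resistance fraction and its 95%
        Clopper-Pearson interval.
    outcomes : per-replicate table (N, replicate, outcome, event times and
        final haplotype frequencies in labeled columns).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    summary_rows = []
    outcome_rows = []
    hap_labels = None
    for n_idx, N in enumerate(N_grid):
        p = params.with_(K=int(N))
        tables = ReproductionTables(p)
        if hap_labels is None:
            hap_labels = [h.label for h in tables.haplotypes]
        n_resistant = 0
        for rep in range(n_reps):
            rng = replicate_rng(base_seed, n_idx, rep)
            res = run_replicate(p, rng, tables)
            n_resistant += res.outcome == RESISTANCE
            outcome_rows.append(
                {
                    "N": int(N),
                    "replicate": rep,
                    "outcome": res.outcome,
                    "t_resistance": res.t_resistance,
                    "t_elimination": res.t_elimination,
                    "final_total": res.final_total,
                    **{f"freq_{lab}": f for lab, f in zip(hap_labels, res.final_freqs)},
                }
            )
        lo, hi = _binomial_ci(n_resistant, n_reps)
        summary_rows.append(
            {
                "N": int(N),
                "n_reps": n_reps,
                "n_resistant": n_resistant,
                "p_hat": n_resistant / n_reps,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
        if progress:  # pragma: no cover - cosmetic
            print(f"N={N:g}: p_hat={n_resistant / n_reps:.3f} ({n_resistant}/{n_reps})")
    return pd.DataFrame(summary_rows), pd.DataFrame(outcome_rows)
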