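"""Closed-form theory of resistance: critical sizes, gRNA counts, sigmoid fits.

The probability that resistance evolves before a suppression drive eliminates
a population of effective size N follows p = 1 - exp(-N / N*), where the
critical population size N* depends on the resistance pathway:

* NHEJ mutants generated during drive spread:
      N*_n = 1 / (4 gamma_n (eps nu beta)^m),           gamma_n ~ 0.2;
* de novo single-nucleotide mutants:
      N*_d = 1 / (4 gamma_m (xi mu)^m),                 gamma_m = s_b tau^m;
* standing variation at mutation-selection balance:
      N*_s = 1 / (4 xi mu m (gamma xi mu / sigma)^(m-1) ln(1 + s_b/(m sigma)));
* both NHEJ and standing variation: 1/N* = 1/N*_n + 1/N*_s.

These feed practical design questions: the smallest number of gRNAs m keeping
the probability of resistance below p at a target population size, and the
amplification ratio N*_d / N*_s quantifying how much weakly deleterious
standing variation increases the risk of resistance relative to de novo
mutation alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .params import DriveParams, TheoryConstants

__all__ = [
    "p_resistance",
    "contour_N",
    "critical_N_nhej",
    "critical_N_denovo",
    "critical_N_standing",
    "critical_N_combined",
    "min_m_nhej",
    "min_m_standing",
    "amplification_ratio",
    "SigmoidFit",
    "fit_sigmoid",
    "implied_gamma_n",
]

_MAX_M = 64  # search bound for minimal-m brute force


def p_resistance(N, N_star: float):
    """Probability of resistance p = 1 - exp(-N/N*)."""
    if N_star <= 0:
        raise ValueError(f"N_star must be positive, got {N_star}")
    N = np.asarray(N, dtype=float)
    if (N < 0).any():
        raise ValueError("N must be non-negative")
    out = -np.expm1(-N / N_star)
    return float(out) if out.ndim == 0 else out


def contour_N(p: float, N_star: float) -> float:
    """Population size at which the probability of resistance equals p."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if N_star <= 0:
        raise ValueError(f"N_star must be positive, got {N_star}")
    return N_star * math.log(1.0 / (1.0 - p))


def critical_N_nhej(params: DriveParams, consts: TheoryConstants) -> float:
    """Critical size for resistance via functional NHEJ mutants."""
    rate = params.epsilon * params.nu * params.beta
    if rate == 0.0:
        return math.inf
    return 1.0 / (4.0 * consts.gamma_n * rate**params.m)


def critical_N_denovo(params: DriveParams, consts: TheoryConstants) -> float:
    """Critical size for resistance via de novo functional SNP mutants."""
    rate = params.xi * params.mu
    if rate == 0.0:
        return math.inf
    return 1.0 / (4.0 * consts.gamma_m_for(params.m) * rate**params.m)


def critical_N_standing(params: DriveParams, consts: TheoryConstants) -> float:
    """Critical size for resistance via standing variation (plus de novo).

    Evaluates N*_s = 1 / [4 xi mu m (gamma xi mu / sigma)^(m-1)
    ln(1 + s_b / (m sigma))]; requires sigma > 0 (the formula describes
    mutation-selection balance before release).
    """
    if params.sigma <= 0.0:
        raise ValueError("standing-variation critical size requires sigma > 0")
    xi_mu = params.xi * params.mu
    if xi_mu == 0.0:
        return math.inf
    m = params.m
    denom = (
        4.0
        * xi_mu
        * m
        * (consts.gamma * xi_mu / params.sigma) ** (m - 1)
        * math.log1p(consts.s_b / (m * params.sigma))
    )
    return 1.0 / denom


def critical_N_combined(params: DriveParams, consts: TheoryConstants) -> float:
    """Harmonic combination 1/N* = 1/N*_n + 1/N*_s of the two pathways."""
    n_n = critical_N_nhej(params, consts)
    n_s = critical_N_standing(params, consts)
    if math.isinf(n_n) and math.isinf(n_s):
        return math.inf
    return 1.0 / (1.0 / n_n + 1.0 / n_s)


def _min_m_brute(N: float, p: float, critical_fn) -> int:
    """Smallest m with contour_N(p, N*(m)) >= N, i.e. resistance prob <= p at N."""
    for m in range(1, _MAX_M + 1):
        n_star = critical_fn(m)
        if math.isinf(n_star) or contour_N(p, n_star) >= N:
            return m
    raise RuntimeError(f"no m <= {_MAX_M} suppresses resistance below p={p} at N={N:g}")


def min_m_nhej(
    N: float, p: float, params: DriveParams, consts: TheoryConstants
) -> int:
    """Minimal gRNA count keeping NHEJ-only resistance probability below p.

    The closed form inverts the NHEJ critical-size power law,
    m > [ln(ln(1/(1-p)) / (4 gamma_n)) - ln N] / ln(eps nu beta);
    it is cross-checked against (and, on disagreement at the rounding
    boundary, overridden by) a brute-force search over the critical size.
    """
    rate = params.epsilon * params.nu * params.beta
    if not 0.0 < rate < 1.0:
        raise ValueError("eps * nu * beta must lie in (0, 1)")
    rhs = (
        math.log(math.log(1.0 / (1.0 - p)) / (4.0 * consts.gamma_n)) - math.log(N)
    ) / math.log(rate)
    closed = math.floor(rhs + 1e-9) + 1
    brute = _min_m_brute(
        N, p, lambda m: critical_N_nhej(params.with_(m=m), consts)
    )
    if closed != brute:  # pragma: no cover - rounding-boundary safety net
        warnings.warn(
            f"closed-form minimal m ({closed}) differs from brute force ({brute}); "
            "returning the brute-force value"
        )
    return brute


def min_m_standing(
    N: float,
    p: float,
    params: DriveParams,
    consts: TheoryConstants,
    method: str = "brute",
) -> int:
    """Minimal gRNA count for resistance from standing (plus de novo) SNPs.

    ``method='brute'`` (authoritative) searches the standing-variation
    critical size directly. ``method='lambert'`` evaluates the closed form
    m > W_{-1}(gamma ln(1/(1-p)) ln(gamma xi mu/sigma) /
    (4 N sigma ln(1 + s_b/sigma))) / ln(gamma xi mu / sigma), which replaces
    the weak m-dependence inside the logarithm by its m=1 value and assumes
    sigma >> xi mu; it falls back to brute force with a warning when the
    argument leaves the domain of the W_{-1} branch.
    """
    brute = _min_m_brute(
        N, p, lambda m: critical_N_standing(params.with_(m=m), consts)
    )
    if method == "brute":
        return brute
    if method != "lambert":
        raise ValueError(f"unknown method {method!r}")
    xi_mu = params.xi * params.mu
    ratio = consts.gamma * xi_mu / params.sigma
    arg = (
        consts.gamma
        / (4.0 * N * params.sigma)
        * math.log(1.0 / (1.0 - p))
        * math.log(ratio)
        / math.log1p(consts.s_b / params.sigma)
    )
    if not (-1.0 / math.e <= arg < 0.0) or ratio >= 1.0:
        warnings.warn(
            "Lambert-W closed form outside its domain; using brute-force search"
        )
        return brute
    w = special.lambertw(arg, k=-1)
    rhs = float(np.real(w)) / math.log(ratio)
    closed = math.floor(rhs + 1e-9) + 1
    return closed


def amplification_ratio(m: int, sigma: float, consts: TheoryConstants) -> float:
    """Ratio N*_d / N*_s: how much standing variation lowers the critical size.

    Equals m gamma^(m-1) ln(1 + s_b/(m sigma)) / (sigma^(m-1) gamma_m);
    large values mean resistance from weakly deleterious standing variation is
    far more likely than from de novo mutation alone.
    """
    if sigma <= 0.0:
        raise ValueError("sigma must be positive")
    return (
        m
        * consts.gamma ** (m - 1)
        * math.log1p(consts.s_b / (m * sigma))
        / (sigma ** (m - 1) * consts.gamma_m_for(m))
    )


@dataclass
class SigmoidFit:
    """Maximum-likelihood fit of p(N) = 1 - exp(-N/N*) to replicate outcomes."""

    N_star: float
    loglik: float
    ci_low: float
    ci_high: float
    boundary: str | None = None  # 'lower'/'upper' when outcomes were all 0/1

    def p(self, N):
        return p_resistance(N, self.N_star)


def _sigmoid_loglik(log_nstar: float, N: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    ratio = N / math.exp(log_nstar)
    log_p = np.log(-np.expm1(-ratio))
    return float(np.sum(k * log_p - (n - k) * ratio))


def fit_sigmoid(N, n_resistant, n_reps) -> SigmoidFit:
    """Fit the critical population size N* by binomial maximum likelihood.

    Parameters
    ----------
    N : population sizes (>= 2 distinct values unless the single-N exact
        inversion applies).
    n_resistant : resistant replicate counts per N.
    n_reps : total replicate counts per N.

    The 95% confidence interval is from the profile likelihood (chi-square,
    1 df). All-zero or all-one outcome tables pin N* to a boundary: the fit
    returns the corresponding one-sided bound with ``boundary`` set.
    """
    N = np.asarray(N, dtype=float)
    k = np.asarray(n_resistant, dtype=float)
    n = np.asarray(n_reps, dtype=float)
    if N.size == 0 or N.size != k.size or N.size != n.size:
        raise ValueError("N, n_resistant and n_reps must be equal-length, non-empty")
    if (k < 0).any() or (k > n).any() or (n < 1).any():
        raise ValueError("need 0 <= n_resistant <= n_reps and n_reps >= 1")

    if k.sum() == 0 or k.sum() == n.sum():
        # likelihood is monotone in N*: report the boundary
        boundary = "lower" if k.sum() == n.sum() else "upper"
        n_star = float(N.min() / 10 if boundary == "lower" else N.max() * 1e6)
        return SigmoidFit(
            N_star=n_star,
            loglik=0.0 if boundary == "lower" else _sigmoid_loglik(math.log(n_star), N, k, n),
            ci_low=0.0,
            ci_high=math.inf,
            boundary=boundary,
        )

    lo, hi = math.log(N.min()) - 12.0, math.log(N.max()) + 12.0
    res = optimize.minimize_scalar(
        lambda t: -_sigmoid_loglik(t, N, k, n), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    log_nstar = float(res.x)
    best = -float(res.fun)
    drop = stats.chi2.ppf(0.95, df=1) / 2.0

    def profile(t):
        return _sigmoid_loglik(t, N, k, n) - (best - drop)

    ci_lo = math.exp(optimize.brentq(profile, lo, log_nstar)) if profile(lo) < 0 else 0.0
    ci_hi = math.exp(optimize.brentq(profile, log_nstar, hi)) if profile(hi) < 0 else math.inf
    return SigmoidFit(
        N_star=math.exp(log_nstar), loglik=best, ci_low=ci_lo, ci_high=ci_hi
    )


def implied_gamma_n(N_star: float, params: DriveParams) -> float:
    """gamma_n implied by a fitted N* under the NHEJ critical-size formula."""
    rate = params.epsilon * params.nu * params.beta
    if rate <= 0 or N_star <= 0:
        raise ValueError("requires eps*nu*beta > 0 and N_star > 0")
    return 1.0 / (4.0 * N_star * rate**params.m)
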