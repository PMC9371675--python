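"""Hybrid Poisson-Gaussian approximation to multinomial sampling.

Wright-Fisher simulation at population sizes of 1e9 and beyond needs
multinomial draws whose cost does not grow with N and that remain stochastic
for the rare categories where resistance originates. Categories are split at
an expected count of ``threshold`` (default 10): rare categories
(N*x_k <= threshold) are drawn as independent Poisson(N*x_k); the remaining
common categories are drawn jointly from the multivariate Gaussian
approximation to the multinomial, conditioned on the reduced total
N' = N - sum(rare draws), with covariance S_ij = N' x'_i (delta_ij - x'_j).
The Gaussian block is discretized and repaired so the returned vector sums to
N exactly. Small totals (N <= exact cutoff) use numpy's exact multinomial.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hybrid_multinomial"]

_PROB_TOL = 1e-9


def _validate_probs(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("frequency vector must be one-dimensional and non-empty")
    if (x < -_PROB_TOL).any():
        raise ValueError("frequency vector has negative entries")
    total = x.sum()
    if not np.isfinite(total) or abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequency vector sums to {total}, expected 1")
    x = np.clip(x, 0.0, None)
    return x / x.sum()


def _gaussian_block(n_total: int, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integer draw of len(x) common categories summing exactly to n_total."""
    k = x.size
    if k == 1:
        return np.array([n_total], dtype=np.int64)
    # Drop the largest-frequency category: the remaining (k-1)-dim covariance
    # is positive definite (full multinomial covariance has rank k-1).
    drop = int(np.argmax(x))
    keep = np.delete(np.arange(k), drop)
    xk = x[keep]
    mean = n_total * xk
    cov = n_total * (np.diag(xk) - np.outer(xk, xk))
    try:
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal(k - 1)
        draw = mean + chol @ z
    except np.linalg.LinAlgError:  # near-degenerate: fall back to svd method
        draw = rng.multivariate_normal(mean, cov, method="svd")
    counts = np.rint(draw).astype(np.int64)
    np.clip(counts, 0, n_total, out=counts)
    # repair so the block sums exactly to n_total
    deficit = n_total - int(counts.sum())
    out = np.zeros(k, dtype=np.int64)
    out[keep] = counts
    if deficit >= 0:
        out[drop] = deficit
    else:
        out[drop] = 0
        excess = -deficit
        # remove the overshoot from the currently largest counts
        while excess > 0:
            top = int(np.argmax(out))
            take = min(excess, int(out[top]))
            if take == 0:  # pragma: no cover - all zero yet excess>0 impossible
                break
            out[top] -= take
            excess -= take
    return out


def hybrid_multinomial(
    N: int,
    x,
    rng: np.random.Generator,
    threshold: float = 10.0,
    exact_cutoff: int = 1_000_000,
    max_rare_retries: int = 100,
) -> np.ndarray:
    """Draw category counts summing exactly to ``N`` with frequencies ``x``.

    Parameters
    ----------
    N : total number of trials (may far exceed 2**32).
    x : probability vector over categories (must sum to 1).
    rng : numpy random generator.
    threshold : expected-count boundary below which a category is treated as
        rare and drawn as an independent Poisson.
    exact_cutoff : for N at or below this, draw from the exact multinomial.
    max_rare_retries : redraw budget should the independent rare Poisson draws
        ever exceed N in total (astronomically unlikely at threshold 10).

    Returns
    -------
    Integer vector of counts with ``counts.sum() == N``.
    """
    x = _validate_probs(x)
    N = int(N)
    if N < 0:
        raise ValueError(f"N must be non-negative, got {N}")
    if N == 0:
        return np.zeros(x.size, dtype=np.int64)
    if N <= exact_cutoff:
        return rng.multinomial(N, x).astype(np.int64)

    expected = N * x
    rare = expected <= threshold
    counts = np.zeros(x.size, dtype=np.int64)

    if rare.all():
        # no common block to absorb the total constraint; N is small relative
        # to the category count, so the exact sampler is both correct and cheap
        return rng.multinomial(N, x).astype(np.int64)

    for _ in range(max_rare_retries):
        rare_draws = rng.poisson(expected[rare]) if rare.any() else np.empty(0, dtype=np.int64)
        n_rare = int(rare_draws.sum())
        if n_rare <= N:
            break
    else:
        raise RuntimeError(
            "rare-category Poisson draws exceeded the total population size "
            f"in {max_rare_retries} consecutive attempts (N={N})"
        )
    counts[rare] = rare_draws

    n_common = N - n_rare
    x_common = x[~rare]
    counts[~rare] = _gaussian_block(n_common, x_common / x_common.sum(), rng)
    return counts
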