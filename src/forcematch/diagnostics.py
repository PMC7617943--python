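"""Posterior-sample diagnostics and summaries.

Draws are stored as arrays of shape ``(n_chains, n_draws)`` per parameter.
Implements split-chain Gelman-Rubin R-hat, an initial-monotone-sequence
effective sample size, highest-density intervals, the deviance
information criterion, and the 95%-HDI group-difference decision rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "rhat",
    "ess_autocorr",
    "hdi",
    "dic",
    "GroupDifference",
    "group_difference",
]


def rhat(chains) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (m, n).  Each chain is split in half, then
    R-hat = sqrt(((n-1)/n W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance.  Returns NaN (with a
    warning) when total variance is zero.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, x.shape[1] - n :]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        warnings.warn("zero within-chain variance; R-hat undefined", RuntimeWarning)
        return float("nan")
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def _autocorr(x: np.ndarray) -> np.ndarray:
    """Autocorrelation of one chain by FFT, normalized to rho[0] = 1."""
    n = len(x)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]


def ess_autocorr(chains) -> float:
    """Effective sample size from Geyer's initial monotone sequence.

    Averages per-chain autocorrelations, forms paired sums
    Gamma_k = rho_{2k} + rho_{2k+1}, truncates at the first non-positive
    pair and enforces monotone decrease, then
    ESS = m*n / (-1 + 2 * sum Gamma_k).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    rho = np.mean([_autocorr(c) for c in x], axis=0)
    n_pairs = (n - 1) // 2
    tau = 1.0
    prev = np.inf
    s = 0.0
    for k in range(n_pairs):
        g = rho[2 * k] + rho[2 * k + 1]
        if g <= 0:
            break
        g = min(g, prev)
        prev = g
        s += g
    tau = max(-1.0 + 2.0 * s, 1e-12)
    return float(m * n / tau)


def hdi(draws, mass: float = 0.90) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws.

    Scans all contiguous windows of ceil(mass*n) sorted draws; ties are
    broken toward the smallest lower bound.
    """
    a = np.sort(np.asarray(draws, dtype=float).ravel())
    n = a.size
    if n < 10:
        raise ValueError("need >= 10 draws for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(a[0]), float(a[-1])
    widths = a[k - 1 :] - a[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: smallest lower bound
    return float(a[i]), float(a[i + k - 1])


def dic(
    samples: dict[str, np.ndarray],
    loglik,
    pointwise_loglik: np.ndarray | None = None,
    positive: set[str] | frozenset[str] = frozenset(),
) -> tuple[float, float, float]:
    """Deviance information criterion from posterior draws.

    D(theta) = -2 loglik(theta); Dbar is the posterior mean deviance
    (computed from ``pointwise_loglik`` if per-draw log-likelihoods were
    recorded during sampling, else by evaluating ``loglik`` at every
    draw); p_D = Dbar - D(theta_bar) with theta_bar the posterior mean
    taken on the sampling scale (log scale for names in ``positive``).
    Returns (DIC, p_D, Dbar) with DIC = Dbar + p_D.
    """
    names = list(samples)
    if pointwise_loglik is not None:
        ll = np.asarray(pointwise_loglik, dtype=float).ravel()
    else:
        shape = samples[names[0]].shape
        flat = {k: np.asarray(v).ravel() for k, v in samples.items()}
        ndraw = int(np.prod(shape))
        ll = np.array(
            [loglik({k: flat[k][i] for k in names}) for i in range(ndraw)]
        )
    dbar = float(np.mean(-2.0 * ll))
    theta_bar = {}
    for k in names:
        v = np.asarray(samples[k], dtype=float).ravel()
        theta_bar[k] = float(np.exp(np.mean(np.log(v)))) if k in positive else float(
            np.mean(v)
        )
    d_hat = -2.0 * float(loglik(theta_bar))
    if not np.isfinite(d_hat):
        raise ValueError("deviance at the posterior mean is not finite")
    p_d = dbar - d_hat
    return dbar + p_d, p_d, dbar


@dataclass(frozen=True)
class GroupDifference:
    """Posterior difference between two groups with the 95%-HDI decision."""

    md: float
    hdi95: tuple[float, float]
    excludes_zero: bool


def group_difference(
    draws_a, draws_b, mass: float = 0.95, seed: int = 0
) -> GroupDifference:
    """Difference distribution A - B summarized by median and HDI.

    Draw arrays of unequal length are resampled (seeded, with
    replacement) to a common length before paired subtraction.  A zero
    difference is rejected when the 95% HDI excludes zero.
    """
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if a.size != b.size:
        rng = np.random.default_rng(seed)
        n = max(a.size, b.size)
        if a.size != n:
            a = rng.choice(a, size=n, replace=True)
        if b.size != n:
            b = rng.choice(b, size=n, replace=True)
    diff = a - b
    lo, hi = hdi(diff, mass)
    return GroupDifference(
        md=float(np.median(diff)),
        hdi95=(lo, hi),
        excludes_zero=not (lo <= 0.0 <= hi),
    )
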