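"""Convergence and data-augmentation adequacy diagnostics.

R-hat here is the classic two-part potential scale reduction factor of
Gelman & Rubin (between/within-chain variance ratio on the retained draws),
with values near 1 indicating convergence and >= 1.1 triggering further
sampling.  Augmentation adequacy checks that the posterior of total richness
N is not pressed against the artificial ceiling M introduced by padding the
data with all-zero pseudo-species.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["gelman_rubin", "split_rhat", "rhat_table", "augmentation_adequate"]


def gelman_rubin(chains) -> float:
    """Classic potential scale reduction factor.

    Parameters
    ----------
    chains : array-like of shape (n_chains, n_iterations)

    Returns +inf when some chains are constant while others differ (no
    within-chain variance to compare against), and nan when all draws are
    identical (a pinned parameter, not a mixing failure).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_iterations) array")
    m, n = x.shape
    if n < 10:
        raise ValueError("need at least 10 iterations per chain")
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W == 0:
        return np.nan if B_over_n == 0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def split_rhat(chains) -> float:
    """R-hat after splitting each chain in half (detects trending chains)."""
    x = np.asarray(chains, dtype=float)
    half = x.shape[1] // 2
    split = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    return gelman_rubin(split)


def rhat_table(draws) -> pd.DataFrame:
    """R-hat and crude ESS for every scalar parameter of a PosteriorDraws."""
    rows = []
    for name, arr in draws.params.items():
        rows.append(
            {"parameter": name, "rhat": gelman_rubin(arr), "ess": _ess_crude(arr)}
        )
    return pd.DataFrame(rows)


def _ess_crude(chains: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS, pooled over chains."""
    x = np.asarray(chains, dtype=float)
    m, n = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    denom = (xc * xc).sum(axis=1)
    if (denom == 0).all():
        return float(m * n)
    tau = 1.0
    for lag in range(1, n // 2):
        rho = (xc[:, :-lag] * xc[:, lag:]).sum(axis=1) / np.where(denom == 0, 1, denom)
        r = rho.mean()
        if r <= 0.0:
            break
        tau += 2.0 * r
    return float(m * n / tau)


def augmentation_adequate(n_draws, M: int) -> tuple[float, bool]:
    """Posterior mass of N in the top tenth of [min(N draws), M].

    The interval between the lowest sampled N and the ceiling M is divided
    into 10 equal sections; augmentation is satisfactory when the upper
    section holds < 1% of the posterior mass.
    """
    n_draws = np.asarray(n_draws).ravel()
    if n_draws.size == 0:
        raise ValueError("no draws of N provided")
    if (n_draws > M).any():
        raise ValueError("draws of N exceed the augmented ceiling M")
    low = n_draws.min()
    if low == M:
        warnings.warn(
            "posterior of N degenerate at the augmentation ceiling M; adequacy undecidable",
            stacklevel=2,
        )
        return 1.0, False
    edge = low + 0.9 * (M - low)
    mass = float((n_draws > edge).mean())
    return mass, mass < 0.01
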