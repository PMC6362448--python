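"""The three hyperprior regimes used for fitting.

All hyper-means (mu's) share one normal prior N(0, sd); all hyper-standard-
deviations (sigma's) share a uniform prior on (0, U]; the community inclusion
probability Omega gets a Beta(a, b) prior.  Set 1 is the wide common-practice
choice, set 2 narrows the logit-scale means, and set 3 additionally replaces
the uniform Omega prior (which implies a discrete-uniform prior on total
richness N over {0..M}) by Beta(0.001, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PriorSet", "make_prior_set", "log_prior"]


@dataclass(frozen=True)
class PriorSet:
    mu_prior_sd: float
    sigma_support: float  # uniform sigma prior on (0, U]
    omega_beta: tuple[float, float]
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.mu_prior_sd <= 0 or self.sigma_support <= 0:
            raise ValueError("mu_prior_sd and sigma_support must be > 0")
        a, b = self.omega_beta
        if a <= 0 or b <= 0:
            raise ValueError("omega Beta parameters must be > 0")


_SETS = {
    "set1": PriorSet(mu_prior_sd=31.0, sigma_support=5.0, omega_beta=(1.0, 1.0), label="set1"),
    "set2": PriorSet(mu_prior_sd=2.25, sigma_support=5.0, omega_beta=(1.0, 1.0), label="set2"),
    "set3": PriorSet(mu_prior_sd=2.25, sigma_support=5.0, omega_beta=(0.001, 1.0), label="set3"),
}


def make_prior_set(label) -> PriorSet:
    """Return prior regime 'set1'/'set2'/'set3' (integers 1-3 accepted)."""
    if isinstance(label, int):
        label = f"set{label}"
    try:
        return _SETS[label]
    except KeyError:
        raise ValueError(f"unknown prior set {label!r}; choose set1, set2 or set3") from None


def log_prior(state, prior_set: PriorSet) -> float:
    """Joint log prior density of the hyperparameters and Omega.

    ``state`` must expose mu_beta, sigma_beta, mu_alpha, sigma_alpha (arrays)
    and omega (scalar).  Returns -inf when a sigma lies outside its support
    (rejection semantics for Metropolis moves).
    """
    sd = prior_set.mu_prior_sd
    U = prior_set.sigma_support
    sigmas = np.concatenate([np.atleast_1d(state.sigma_beta), np.atleast_1d(state.sigma_alpha)])
    if ((sigmas <= 0) | (sigmas > U)).any():
        return -np.inf
    mus = np.concatenate([np.atleast_1d(state.mu_beta), np.atleast_1d(state.mu_alpha)])
    lp = stats.norm.logpdf(mus, 0.0, sd).sum()
    lp += -len(sigmas) * np.log(U)
    a, b = prior_set.omega_beta
    lp += stats.beta.logpdf(state.omega, a, b)
    return float(lp)
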