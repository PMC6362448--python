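"""Missed-species probabilities and posterior richness summaries.

Under constant per-species parameters, the cumulative probability that a
species with per-visit detection probability p is detected at least once at
an occupied site over J visits is ``p* = 1 - (1 - p)^J``, and the probability
of missing the species entirely (no detection at any of S sites) is

    m = (1 - psi * p*)^S .

Averaging m over the community distributions of (psi, p) gives the expected
fraction of species a survey design misses; averaging (1 - psi)^S gives the
fraction of the community absent from every sampled site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .simulate import ScenarioSpec, draw_detectability_alternative

__all__ = [
    "MissedSpec",
    "RichnessSummary",
    "MCEstimate",
    "cumulative_detection",
    "prob_missed",
    "expected_missed_fraction",
    "expected_absent_fraction",
    "percent",
    "table1",
    "posterior_richness",
    "site_richness",
    "region_richness",
]


@dataclass
class MissedSpec:
    """Point parameters for the missed-species probability."""

    psi: float
    p: float
    S: int
    J: int

    def __post_init__(self) -> None:
        if not (0 <= self.psi <= 1 and 0 <= self.p <= 1):
            raise ValueError("psi and p must lie in [0, 1]")
        if self.S < 1 or self.J < 1:
            raise ValueError("S and J must be >= 1")


class MCEstimate(NamedTuple):
    value: float
    se: float
    n: int


@dataclass
class RichnessSummary:
    """Posterior summary of a species count (equal-tailed 95% interval)."""

    median: float
    ci_low: float
    ci_high: float
    n_detected: int
    augmentation_ok: bool = True
    rhat_max: float = np.nan

    def __post_init__(self) -> None:
        assert self.ci_low <= self.median <= self.ci_high


def cumulative_detection(p, J):
    """p* = 1 - (1-p)^J: chance of >=1 detection at an occupied site."""
    p = np.asarray(p, dtype=float)
    return 1.0 - (1.0 - p) ** J


def prob_missed(psi, p, S, J):
    """m = (1 - psi * p*)^S: no detection at any site, any visit."""
    psi = np.asarray(psi, dtype=float)
    return (1.0 - psi * cumulative_detection(p, J)) ** S


def _draw_psi_p(spec: ScenarioSpec, n_mc: int, rng: np.random.Generator):
    psi = expit(rng.normal(spec.occ_mu, spec.occ_sigma, size=n_mc))
    p = draw_detectability_alternative(spec.det_family, spec.det_params, n_mc, rng)
    return psi, p


def _mc_mean(x: np.ndarray) -> MCEstimate:
    n = x.size
    return MCEstimate(float(x.mean()), float(x.std(ddof=1) / np.sqrt(n)), n)


def _warn_small(n_mc: int) -> None:
    if n_mc < 10_000:
        warnings.warn(
            "n_mc < 10^4: Monte-Carlo error too large to trust printed-precision rounding",
            stacklevel=3,
        )


def expected_missed_fraction(spec: ScenarioSpec, n_mc: int = 1_000_000, seed=None) -> MCEstimate:
    """Expected fraction of community species with no detection anywhere."""
    _warn_small(n_mc)
    rng = np.random.default_rng(seed)
    psi, p = _draw_psi_p(spec, n_mc, rng)
    return _mc_mean(prob_missed(psi, p, spec.S, spec.J))


def expected_absent_fraction(spec: ScenarioSpec, n_mc: int = 1_000_000, seed=None) -> MCEstimate:
    """Expected fraction of community species absent from all S sampled sites."""
    _warn_small(n_mc)
    rng = np.random.default_rng(seed)
    psi = expit(rng.normal(spec.occ_mu, spec.occ_sigma, size=n_mc))
    return _mc_mean((1.0 - psi) ** spec.S)


def percent(x) -> int:
    """Proportion -> integer percent, rounding half away from zero."""
    return int(np.floor(100.0 * x + 0.5))


def table1(
    scenarios: dict[str, dict] | None = None,
    S_values=(25, 50, 150),
    J_values=(2, 4, 6),
    n_mc: int = 1_000_000,
    seed=None,
) -> pd.DataFrame:
    """Expected missed / absent percentages over a survey-design grid.

    Returns a tidy frame with one row per (scenario, S, J): the raw
    proportions, Monte-Carlo standard errors, and integer-percent roundings.
    """
    from .simulate import OCC1, OCC2

    if scenarios is None:
        scenarios = {"Occ1": OCC1, "Occ2": OCC2}
    ss = np.random.SeedSequence(seed)
    rows = []
    for name, occ in scenarios.items():
        for S in S_values:
            spec0 = ScenarioSpec(n_species=100, S=S, J=1, **occ)
            child = ss.spawn(1)[0]
            absent = expected_absent_fraction(spec0, n_mc=n_mc, seed=child)
            for J in J_values:
                spec = ScenarioSpec(n_species=100, S=S, J=J, **occ)
                missed = expected_missed_fraction(spec, n_mc=n_mc, seed=ss.spawn(1)[0])
                rows.append(
                    {
                        "scenario": name, "S": S, "J": J,
                        "missed": missed.value, "missed_se": missed.se,
                        "missed_pct": percent(missed.value),
                        "absent": absent.value, "absent_se": absent.se,
                        "absent_pct": percent(absent.value),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def _lower_median(x: np.ndarray) -> float:
    """Smallest value whose CDF reaches 0.5 (deterministic for counts)."""
    return float(np.quantile(x, 0.5, method="inverted_cdf"))


def posterior_richness(
    n_draws: np.ndarray,
    n_detected: int,
    augmentation_ok: bool = True,
    rhat_max: float = np.nan,
) -> RichnessSummary:
    """Summarize posterior draws of a species count N."""
    n_draws = np.asarray(n_draws).ravel()
    lo, hi = np.quantile(n_draws, [0.025, 0.975], method="inverted_cdf")
    return RichnessSummary(
        median=_lower_median(n_draws),
        ci_low=float(lo),
        ci_high=float(hi),
        n_detected=int(n_detected),
        augmentation_ok=augmentation_ok,
        rhat_max=rhat_max,
    )


def site_richness(draws, mode: str = "expected") -> pd.DataFrame:
    """Per-site posterior richness summaries.

    mode="expected" sums w_k * psi_ik over species within each retained draw
    (species richness a site is expected to hold); mode="conditional" sums
    the latent presence indicators z_ik (richness given the data actually
    observed).  Requires the corresponding latent draws to have been kept.
    """
    if mode == "expected":
        if draws.psi is None or draws.w is None:
            raise ValueError(
                "expected site richness needs psi and w draws; "
                "rerun with save_latent including 'psi' and 'w'"
            )
        # (chains, draws, S, M) * (chains, draws, M) -> per-draw site sums
        vals = np.einsum("cdsm,cdm->cds", draws.psi, draws.w.astype(float))
    elif mode == "conditional":
        if draws.z is None:
            raise ValueError(
                "conditional site richness needs z draws; rerun with save_latent including 'z'"
            )
        vals = draws.z.sum(axis=3).astype(float)
    else:
        raise ValueError("mode must be 'expected' or 'conditional'")
    flat = vals.reshape(-1, vals.shape[-1])
    qs = np.quantile(flat, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {
            "site": np.arange(1, flat.shape[1] + 1),
            "mean": flat.mean(axis=0),
            "median": qs[1],
            "ci_low": qs[0],
            "ci_high": qs[2],
        }
    )


def region_richness(draws, site_subset) -> tuple[np.ndarray, RichnessSummary]:
    """Posterior of the number of species occupying >=1 site of a subset.

    Counts, per retained draw, the species with at least one latent z = 1
    within ``site_subset`` (indices into the site axis).  This restricts the
    richness statement to a defined region instead of the open community N.
    """
    site_subset = np.asarray(site_subset, dtype=int)
    if site_subset.size == 0:
        raise ValueError("site_subset must contain at least one site")
    if draws.z is None:
        raise ValueError("region richness needs z draws; rerun with save_latent including 'z'")
    occ_any = draws.z[:, :, site_subset, :].any(axis=2)  # (chains, draws, M)
    counts = occ_any.sum(axis=2).ravel().astype(int)
    detected_in_subset = int(draws.detected_by_site[site_subset].any(axis=0).sum())
    return counts, posterior_richness(counts, n_detected=detected_in_subset)
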