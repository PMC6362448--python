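"""Synthetic communities and replicated detection/non-detection surveys.

A community of ``n_species`` species gets per-species occupancy and
per-visit detection probabilities drawn from community-level distributions
on the logit scale.  Presence at each of S sites is Bernoulli(psi_k), and
each of J visits to an occupied site detects the species with probability
p_k (no false positives).  The ideal generative process uses logit-normal
distributions for both layers; five alternative detectability families are
available to deliberately violate the normality assumption that the fitted
model makes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import optimize, stats
from scipy.special import expit, logit

from .io import DetectionData

__all__ = [
    "ScenarioSpec",
    "CommunityTruth",
    "OCC1",
    "OCC2",
    "DETECTION_IDEAL",
    "VIOLATION_CATALOGUE",
    "draw_species_params",
    "draw_detectability_alternative",
    "simulate_detections",
    "simulate_dataset",
    "tune_detectability_location",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

DET_FAMILIES = ("logit-normal", "mixture", "heavy-tail", "steep-tail", "skewed")

# Occupancy hyperparameters of the two bundled scenarios: logit(psi_k) ~
# N(-1, 0.3) gives mean occupancy ~0.27 (Occ1); N(-2, 0.6) gives ~0.13 (Occ2).
OCC1 = {"occ_mu": -1.0, "occ_sigma": 0.3}
OCC2 = {"occ_mu": -2.0, "occ_sigma": 0.6}
# Ideal detectability: logit(p_k) ~ N(-2, 1), mean single-visit p ~0.15.
DETECTION_IDEAL = {"mean": -2.0, "sd": 1.0}


@dataclass
class ScenarioSpec:
    """Generative description of one community + sampling scenario."""

    n_species: int
    occ_mu: float
    occ_sigma: float
    S: int
    J: int
    det_family: str = "logit-normal"
    det_params: dict = field(default_factory=lambda: dict(DETECTION_IDEAL))
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        if self.occ_sigma < 0:
            raise ValueError("occ_sigma must be >= 0")
        if self.S < 1 or self.J < 1:
            raise ValueError("S and J must be >= 1")
        if self.det_family not in DET_FAMILIES:
            raise ValueError(
                f"unknown det_family {self.det_family!r}; choose from {DET_FAMILIES}"
            )
        _validate_det_params(self.det_family, self.det_params)


def _validate_det_params(family: str, params: dict) -> None:
    if family == "logit-normal":
        if params.get("sd", 1.0) < 0:
            raise ValueError("logit-normal sd must be >= 0")
    elif family == "mixture":
        w = np.asarray(params["weights"], dtype=float)
        means = np.asarray(params["means"], dtype=float)
        sds = np.asarray(params["sds"], dtype=float)
        if not (len(w) == len(means) == len(sds)):
            raise ValueError("mixture weights/means/sds must have equal length")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if (sds <= 0).any():
            raise ValueError("mixture component sds must be > 0")
    elif family == "heavy-tail":
        if params["df"] <= 0 or params["scale"] <= 0:
            raise ValueError("heavy-tail needs df > 0 and scale > 0")
    elif family == "steep-tail":
        if params["scale"] <= 0 or params["lower"] >= params["upper"]:
            raise ValueError("steep-tail needs scale > 0 and lower < upper")
    elif family == "skewed":
        if params["scale"] <= 0:
            raise ValueError("skewed needs scale > 0")


@dataclass
class CommunityTruth:
    """Ground truth for a simulated community and one realized survey."""

    psi: np.ndarray
    p: np.ndarray
    z_true: np.ndarray | None = None
    present_in_sample: np.ndarray | None = None
    detected: np.ndarray | None = None

    def check(self) -> None:
        if self.z_true is not None:
            assert (self.present_in_sample == self.z_true.any(axis=0)).all()
            # a detected species must be present somewhere in the sample
            assert not np.any(self.detected & ~self.present_in_sample)


def _resolve_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def draw_detectability_alternative(
    family: str, det_params: dict, n: int, seed_or_rng
) -> np.ndarray:
    """Draw n per-visit detection probabilities from an alternative family.

    All families are defined on the logit scale and mapped through the
    inverse logit, so values are strictly inside (0, 1).
    """
    rng = _resolve_rng(seed_or_rng)
    _validate_det_params(family, det_params)
    if family == "logit-normal":
        x = rng.normal(det_params["mean"], det_params["sd"], size=n)
    elif family == "mixture":
        w = np.asarray(det_params["weights"], dtype=float)
        means = np.asarray(det_params["means"], dtype=float)
        sds = np.asarray(det_params["sds"], dtype=float)
        comp = rng.choice(len(w), size=n, p=w)
        x = rng.normal(means[comp], sds[comp])
    elif family == "heavy-tail":
        x = det_params["loc"] + det_params["scale"] * rng.standard_t(
            det_params["df"], size=n
        )
    elif family == "steep-tail":
        a = (det_params["lower"] - det_params["loc"]) / det_params["scale"]
        b = (det_params["upper"] - det_params["loc"]) / det_params["scale"]
        x = stats.truncnorm.rvs(
            a, b, loc=det_params["loc"], scale=det_params["scale"], size=n,
            random_state=rng,
        )
    elif family == "skewed":
        x = stats.skewnorm.rvs(
            det_params["a"], loc=det_params["loc"], scale=det_params["scale"],
            size=n, random_state=rng,
        )
    else:  # pragma: no cover - guarded by _validate_det_params
        raise ValueError(family)
    # keep probabilities strictly inside (0, 1): extreme logit draws would
    # otherwise saturate in floating point
    return np.clip(expit(x), 1e-12, 1.0 - 1e-12)


def draw_species_params(spec: ScenarioSpec, seed_or_rng=None) -> CommunityTruth:
    """Draw per-species occupancy and detection probabilities.

    logit(psi_k) ~ N(occ_mu, occ_sigma); detection from the scenario's
    family (logit-normal under ideal conditions).
    """
    rng = _resolve_rng(spec.seed if seed_or_rng is None else seed_or_rng)
    psi = expit(rng.normal(spec.occ_mu, spec.occ_sigma, size=spec.n_species))
    p = draw_detectability_alternative(spec.det_family, spec.det_params, spec.n_species, rng)
    return CommunityTruth(psi=psi, p=p)


def simulate_detections(
    truth: CommunityTruth, S: int, J: int, seed_or_rng
) -> tuple[DetectionData, CommunityTruth]:
    """Simulate presence and J-visit detection histories at S sites.

    z_ik ~ Bernoulli(psi_k), y_ijk ~ Bernoulli(z_ik * p_k): a species absent
    from a site can never be detected there.
    """
    rng = _resolve_rng(seed_or_rng)
    K = len(truth.psi)
    z = (rng.random((S, K)) < truth.psi).astype(np.uint8)
    y = (rng.random((S, J, K)) < truth.p[None, None, :]).astype(np.uint8)
    y *= z[:, None, :]
    completed = replace(
        truth,
        z_true=z,
        present_in_sample=z.any(axis=0),
        detected=y.any(axis=(0, 1)),
    )
    data = DetectionData(y=y, visit_mask=np.ones((S, J), dtype=bool))
    return data, completed


def simulate_dataset(
    spec: ScenarioSpec, replicate: int = 0
) -> tuple[DetectionData, CommunityTruth]:
    """One replicate dataset with an RNG stream keyed by (scenario seed, replicate)."""
    rng = np.random.default_rng([spec.seed, replicate])
    truth = draw_species_params(spec, rng)
    return simulate_detections(truth, spec.S, spec.J, rng)


# ---------------------------------------------------------------------------
# Assumption-violation catalogue
# ---------------------------------------------------------------------------

#: Qualitative shapes for the five detectability families that break the
#: logit-normal assumption: fatter tails, steeper (truncated) tails, skew,
#: and two bimodal shapes distinguished by whether the first mode sits near
#: or away from zero detection probability.  Location parameters are nominal;
#: use :func:`tune_detectability_location` to hit a target missed fraction.
VIOLATION_CATALOGUE: dict[str, tuple[str, dict]] = {
    "heavy_tail": ("heavy-tail", {"df": 3.0, "loc": -2.0, "scale": 0.8}),
    "steep_tail": (
        "steep-tail",
        {"loc": -2.0, "scale": 1.3, "lower": -3.5, "upper": -0.5},
    ),
    "skewed": ("skewed", {"a": 4.0, "loc": -3.0, "scale": 1.6}),
    "bimodal_near_zero": (
        "mixture",
        {
            "weights": [0.5, 0.5],
            "means": [float(logit(0.03)), float(logit(0.30))],
            "sds": [0.4, 0.4],
        },
    ),
    "bimodal_away_from_zero": (
        "mixture",
        {
            "weights": [0.5, 0.5],
            "means": [float(logit(0.20)), float(logit(0.60))],
            "sds": [0.35, 0.35],
        },
    ),
}


def _shift_location(family: str, params: dict, delta: float) -> dict:
    out = dict(params)
    if family == "logit-normal":
        out["mean"] = params["mean"] + delta
    elif family == "mixture":
        out["means"] = [m + delta for m in params["means"]]
    elif family in ("heavy-tail", "skewed"):
        out["loc"] = params["loc"] + delta
    elif family == "steep-tail":
        out["loc"] = params["loc"] + delta
        out["lower"] = params["lower"] + delta
        out["upper"] = params["upper"] + delta
    return out


def tune_detectability_location(
    family: str,
    det_params: dict,
    occ: dict,
    S: int,
    J: int,
    target_missed: float,
    n_mc: int = 100_000,
    seed: int = 20_190_205,
) -> dict:
    """Shift a family's location to hit a target expected missed fraction.

    Solves for the common logit-scale location shift delta such that the
    expected fraction of species with no detection at any of S sites over J
    visits equals ``target_missed``, by root-finding on a common-random-
    numbers Monte-Carlo estimate (smooth in delta).
    """
    from .richness import expected_missed_fraction

    def f(delta: float) -> float:
        spec = ScenarioSpec(
            n_species=100, S=S, J=J, det_family=family,
            det_params=_shift_location(family, det_params, delta), **occ,
        )
        return expected_missed_fraction(spec, n_mc=n_mc, seed=seed).value - target_missed

    delta = optimize.brentq(f, -8.0, 8.0, xtol=1e-3)
    return _shift_location(family, det_params, delta)


# ---------------------------------------------------------------------------
# Scenario (de)serialization
# ---------------------------------------------------------------------------

def scenario_to_yaml(spec: ScenarioSpec, path) -> None:
    d = {
        "name": spec.name, "n_species": spec.n_species,
        "occ_mu": spec.occ_mu, "occ_sigma": spec.occ_sigma,
        "S": spec.S, "J": spec.J, "det_family": spec.det_family,
        "det_params": spec.det_params, "seed": spec.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def scenario_from_yaml(path) -> ScenarioSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ScenarioSpec(**d)
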