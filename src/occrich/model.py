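"""Augmented multispecies occupancy-detection model and its MCMC sampler.

The model stacks single-species occupancy-detection models: presence
z_ik ~ Bernoulli(w_k * psi_ik), detections y_ijk ~ Bernoulli(z_ik * p_ijk),
with logit-linear predictors whose species-level coefficients are normal
random effects (logit psi_ik = beta_0k + beta_1k X_1i + ..., likewise for
detection).  Total community richness N, including never-detected species,
is inferred by data augmentation: the observed n species are padded with
M - n all-zero "potential species", each carrying a community-membership
indicator w_k ~ Bernoulli(Omega), and N = sum_k w_k.

Sampling is Metropolis-within-Gibbs.  The membership indicators of
undetected species are updated with their presence states z marginalized
out (a collapsed conditional), after which z is refreshed given w; this
avoids the absorbing w=0/z=0 configuration of a naive joint Gibbs scan.
Species-level coefficients use adaptive random-walk Metropolis (adaptation
frozen after burn-in), hyper-means use conjugate normal draws, hyper-scales
use slice sampling under their uniform prior, and Omega is conjugate Beta.

An intercept-only model (the ideal-scenario fits) runs on sufficient
statistics -- per-species occupied-site counts, trial counts and detection
totals -- which keeps a full sweep at O(S*M) regardless of J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .diagnostics import gelman_rubin
from .io import DetectionData
from .priors import PriorSet

__all__ = [
    "AugmentedData",
    "MCMCConfig",
    "ModelState",
    "PosteriorDraws",
    "augment",
    "cond_prob_z",
    "cond_prob_w",
    "gibbs_omega",
    "update_hyperparams",
    "metropolis_logit_bernoulli",
    "run_mcmc",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class AugmentedData:
    """Detection array padded with all-zero pseudo-species.

    y has shape (S, J, M): the first ``n_observed`` species columns carry the
    data, the remaining M - n_observed are identically zero.  X (S, P) and
    V (S, J, Q) are design matrices for the occupancy and detection logits;
    both default to an intercept column.  Covariate columns are expected to
    be standardized (mean 0, variance 1).
    """

    y: np.ndarray
    n_observed: int
    visit_mask: np.ndarray | None = None
    X: np.ndarray | None = None
    V: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary")
        self.y = self.y.astype(np.uint8)
        S, J, M = self.y.shape
        if self.n_observed > M:
            raise ValueError("n_observed cannot exceed the augmented size M")
        if self.y[:, :, self.n_observed :].any():
            raise ValueError("augmented pseudo-species columns must be all zero")
        if self.visit_mask is None:
            self.visit_mask = np.ones((S, J), dtype=bool)
        self.visit_mask = np.asarray(self.visit_mask, dtype=bool)
        if self.X is None:
            self.X = np.ones((S, 1))
        if self.V is None:
            self.V = np.ones((S, J, 1))
        self.X = np.asarray(self.X, dtype=float)
        self.V = np.asarray(self.V, dtype=float)

    @property
    def S(self) -> int:
        return self.y.shape[0]

    @property
    def J(self) -> int:
        return self.y.shape[1]

    @property
    def M(self) -> int:
        return self.y.shape[2]

    @property
    def intercept_only(self) -> bool:
        return self.X.shape[1] == 1 and self.V.shape[2] == 1


def augment(y_observed, n_aug: int, visit_mask=None, X=None, V=None) -> AugmentedData:
    """Pad detection data with ``n_aug`` all-zero potential species.

    Accepts a raw (S, J, n) binary array, a DetectionData, or an existing
    AugmentedData (in which case padding is cumulative and ``n_observed``
    is preserved, so augmenting by 300 then 200 equals augmenting by 500).
    """
    if n_aug < 0:
        raise ValueError("n_aug must be >= 0")
    if isinstance(y_observed, AugmentedData):
        base = y_observed
        y = base.y
        n_obs = base.n_observed
        visit_mask = base.visit_mask if visit_mask is None else visit_mask
        X = base.X if X is None else X
        V = base.V if V is None else V
    elif isinstance(y_observed, DetectionData):
        y = y_observed.y
        n_obs = y_observed.n_species
        visit_mask = y_observed.visit_mask if visit_mask is None else visit_mask
    else:
        y = np.asarray(y_observed)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary")
        n_obs = y.shape[2]
        if n_obs and not y.any(axis=(0, 1)).all():
            warnings.warn(
                "observed input contains all-zero species columns; these are "
                "indistinguishable from augmented pseudo-species and should be "
                "dropped before augmentation",
                stacklevel=2,
            )
    S, J, _ = y.shape
    y_aug = np.concatenate([y, np.zeros((S, J, n_aug), dtype=np.uint8)], axis=2)
    return AugmentedData(y=y_aug, n_observed=n_obs, visit_mask=visit_mask, X=X, V=V)


@dataclass
class MCMCConfig:
    n_chains: int = 3
    n_iter: int = 6000
    n_burn: int = 1500
    thin: int = 3
    max_extra_blocks: int = 3
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.3
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burn >= 0):
            raise ValueError("need n_iter > n_burn >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ModelState:
    """Current values of all latent variables and parameters of one chain."""

    w: np.ndarray            # (M,) bool community membership
    z: np.ndarray            # (S, M) bool presence
    beta: np.ndarray         # (M, P) occupancy coefficients
    alpha: np.ndarray        # (M, Q) detection coefficients
    mu_beta: np.ndarray      # (P,)
    sigma_beta: np.ndarray   # (P,)
    mu_alpha: np.ndarray     # (Q,)
    sigma_alpha: np.ndarray  # (Q,)
    omega: float

    def check(self) -> None:
        assert not np.any(self.z & ~self.w[None, :]), "z=1 requires w=1"
        assert (self.sigma_beta > 0).all() and (self.sigma_alpha > 0).all()


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with thinning/burn-in metadata.

    ``params`` maps scalar parameter names to (n_chains, n_draws) arrays;
    latent draws (w, z, psi, beta, alpha) are kept only on request.
    """

    params: dict[str, np.ndarray]
    config: MCMCConfig
    n_observed: int
    M: int
    S: int
    seeds: list = field(default_factory=list)
    blocks_used: int = 1
    converged: bool = True
    rhat: dict[str, float] = field(default_factory=dict)
    w: np.ndarray | None = None
    z: np.ndarray | None = None
    psi: np.ndarray | None = None
    beta: np.ndarray | None = None
    alpha: np.ndarray | None = None
    detected_by_site: np.ndarray | None = None

    def stacked(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    @property
    def N(self) -> np.ndarray:
        """All retained draws of total richness, chains pooled."""
        return self.stacked("N")

    @property
    def rhat_max(self) -> float:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        if any(np.isinf(v) for v in self.rhat.values()):
            return np.inf
        return max(vals) if vals else np.nan


# ---------------------------------------------------------------------------
# Elementary conditionals (exposed for direct checking)
# ---------------------------------------------------------------------------

def cond_prob_z(psi: float, p_visits, y_visits, w: int) -> float:
    """P(z_ik = 1 | everything else) for one site x species cell.

    Any detection forces presence; a community non-member (w=0) cannot be
    present; otherwise Bayes' rule on the all-zero detection history gives
    psi * prod_j (1-p_ij) / (psi * prod_j (1-p_ij) + 1 - psi).
    """
    y_visits = np.asarray(y_visits)
    p_visits = np.asarray(p_visits, dtype=float)
    if y_visits.any():
        if w == 0:
            raise ValueError("inconsistent state: detections recorded for a non-member")
        return 1.0
    if w == 0:
        return 0.0
    q = np.prod(1.0 - p_visits)
    return float(psi * q / (psi * q + 1.0 - psi))


def cond_prob_w(omega: float, psi_sites, pstar_sites) -> float:
    """P(w_k = 1 | params, all-zero history), presence z marginalized.

    For a species with no detections anywhere,
    P(w=1) = Omega * prod_i (1 - psi_i p*_i) / (same + 1 - Omega),
    where p*_i = 1 - prod_j (1 - p_ij) is the cumulative detection
    probability at site i.  Species with detections have w fixed at 1.
    """
    psi_sites, pstar_sites = np.broadcast_arrays(
        np.atleast_1d(np.asarray(psi_sites, dtype=float)),
        np.atleast_1d(np.asarray(pstar_sites, dtype=float)),
    )
    if omega <= 0.0:
        return 0.0
    if omega >= 1.0:
        return 1.0
    log_tail = np.log1p(-psi_sites * pstar_sites).sum()
    return float(expit(logit(omega) + log_tail))


def gibbs_omega(w, prior_a: float, prior_b: float, rng: np.random.Generator) -> float:
    """Conjugate draw Omega ~ Beta(a + sum w, b + M - sum w)."""
    w = np.asarray(w)
    sw = int(w.sum())
    draw = rng.beta(prior_a + sw, prior_b + w.size - sw)
    return float(np.clip(draw, 1e-300, 1.0 - 1e-12))


def metropolis_logit_bernoulli(cur, successes, trials, mu, sigma, scale, rng):
    """Vectorized random-walk Metropolis for logit-scale Bernoulli intercepts.

    Targets, independently per element, the posterior of b given
    ``successes`` successes in ``trials`` Bernoulli(expit(b)) trials and a
    N(mu, sigma) prior.  Returns (new values, acceptance mask).  A proposal
    with identical log-posterior (e.g. scale 0) is always accepted.
    """
    cur = np.asarray(cur, dtype=float)
    prop = cur + scale * rng.normal(size=cur.shape)

    def lp(b):
        # log expit(b) = -log(1+e^-b); log(1-expit(b)) = -log(1+e^b)
        ll = -(successes * np.logaddexp(0.0, -b) + (trials - successes) * np.logaddexp(0.0, b))
        return ll - 0.5 * ((b - mu) / sigma) ** 2

    diff = lp(prop) - lp(cur)
    # a non-finite proposal log-posterior is rejected outright
    diff = np.where(np.isnan(diff), -np.inf, diff)
    accept = np.log(rng.random(cur.shape)) < diff
    return np.where(accept, prop, cur), accept


def _slice_sample(logf, x0: float, lo: float, hi: float, rng, w: float = 0.25) -> float:
    """Univariate slice sampler with stepping-out on a bounded support."""
    y = logf(x0) + np.log(rng.random())
    L = max(lo, x0 - w * rng.random())
    R = min(hi, L + w)
    for _ in range(100):
        if L <= lo or logf(L) <= y:
            break
        L = max(lo, L - w)
    for _ in range(100):
        if R >= hi or logf(R) <= y:
            break
        R = min(hi, R + w)
    for _ in range(200):
        x = L + (R - L) * rng.random()
        if logf(x) > y:
            return x
        if x < x0:
            L = x
        else:
            R = x
    return x0  # pragma: no cover - shrinkage virtually always terminates


def update_hyperparams(effects, sigma: float, prior: PriorSet, rng) -> tuple[float, float]:
    """Gibbs update of one hyper-mean and hyper-sd pair.

    All M species effects (community members and non-members alike, since
    non-members carry the hyperdistribution as their exact conditional)
    inform the update.  mu is conjugate normal under its N(0, sd) prior;
    sigma is slice-sampled under the uniform prior on (0, U].
    """
    effects = np.asarray(effects, dtype=float)
    M = effects.size
    prec = 1.0 / prior.mu_prior_sd**2 + M / sigma**2
    mean = (effects.sum() / sigma**2) / prec
    mu_new = mean + rng.normal() / np.sqrt(prec)

    ss = float(((effects - mu_new) ** 2).sum())
    U = prior.sigma_support

    def logf(s: float) -> float:
        return -M * np.log(s) - ss / (2.0 * s * s)

    sigma_new = _slice_sample(logf, min(sigma, U), 1e-9, U, rng, w=max(0.05, sigma / 2))
    return float(mu_new), float(sigma_new)


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

class Chain:
    """One MCMC chain over the augmented model.

    Holds the model state and precomputed data summaries; ``step()``
    performs one full Metropolis-within-Gibbs sweep.  With intercept-only
    designs all updates run on per-species sufficient statistics.
    """

    def __init__(
        self,
        data: AugmentedData,
        priors: PriorSet,
        config: MCMCConfig,
        rng: np.random.Generator,
        fixed_psi=None,
        fixed_p=None,
    ) -> None:
        self.data = data
        self.priors = priors
        self.config = config
        self.rng = rng
        S, J, M = data.S, data.J, data.M

        self.D = data.y.any(axis=1)                       # (S, M) any detection
        self.det_total = data.y.sum(axis=(0, 1))          # (M,)
        self.observed = self.det_total > 0
        self.J_i = data.visit_mask.sum(axis=1)            # visits per site
        ju = np.unique(self.J_i)
        self.equal_J = ju.size == 1
        self.fixed = fixed_psi is not None
        if self.fixed:
            self.psi_fixed = np.broadcast_to(np.asarray(fixed_psi, dtype=float), (S, M)).copy()
            p = np.asarray(fixed_p, dtype=float)
            if p.ndim == 1:
                p = np.broadcast_to(p, (S, J, M))
            pm = np.where(data.visit_mask[:, :, None], p, 0.0)
            self.q_fixed = np.prod(1.0 - pm, axis=1)       # (S, M) prod over visits
            self.logtail_fixed = np.log1p(-self.psi_fixed * (1.0 - self.q_fixed)).sum(axis=0)
        self.fast = data.intercept_only and not self.fixed

        # --- initial state (z at observed detections, augmented w = 0) ---
        n_obs = data.n_observed
        w0 = self.observed.copy()
        z0 = self.D.copy()
        P, Q = data.X.shape[1], data.V.shape[2]
        beta = np.zeros((M, P))
        alpha = np.zeros((M, Q))
        if not self.fixed:
            naive_occ = np.clip(self.D.sum(axis=0) / S, 0.05, 0.95)
            trials = (self.J_i[:, None] * self.D).sum(axis=0)
            naive_p = np.clip(
                self.det_total / np.maximum(trials, 1), 0.05, 0.95
            )
            beta[:, 0] = logit(naive_occ)
            alpha[:, 0] = logit(naive_p)
            if n_obs > 0:
                mb0 = float(np.mean(beta[: n_obs, 0]))
                ma0 = float(np.mean(alpha[: n_obs, 0]))
            else:
                mb0, ma0 = 0.0, 0.0
            beta[n_obs:, 0] = mb0
            alpha[n_obs:, 0] = ma0
        U = priors.sigma_support
        self.state = ModelState(
            w=w0,
            z=z0,
            beta=beta,
            alpha=alpha,
            mu_beta=np.full(P, beta[:, 0].mean() if not self.fixed else 0.0),
            sigma_beta=np.full(P, min(1.0, U)),
            mu_alpha=np.full(Q, alpha[:, 0].mean() if not self.fixed else 0.0),
            sigma_alpha=np.full(Q, min(1.0, U)),
            omega=(n_obs + 1.0) / (M + 2.0),
        )
        # proposal scales (per coefficient), adapted during burn-in
        self.scale_beta = np.full(P, 0.5)
        self.scale_alpha = np.full(Q, 0.5)
        self._acc_beta = np.zeros(P)
        self._acc_alpha = np.zeros(Q)
        self._acc_n = 0
        self._batch = 0
        self._sigma_at_bound = 0
        self._sigma_draws = 0
        self._refresh_suffstats()

    # -- likelihood helpers ------------------------------------------------

    def _psi_p(self):
        """Current (psi, p) on the probability scale."""
        st, d = self.state, self.data
        if self.fixed:
            return self.psi_fixed, None
        if self.fast:
            return expit(st.beta[:, 0]), expit(st.alpha[:, 0])
        psi = expit(d.X @ st.beta.T)                      # (S, M)
        p = expit(np.einsum("sjq,mq->sjm", d.V, st.alpha))  # (S, J, M)
        return psi, p

    def _refresh_suffstats(self) -> None:
        z = self.state.z
        self.s_occ = z.sum(axis=0)                        # occupied sites per species
        self.trials_det = self.J_i @ z                    # detection trials per species

    # -- individual updates ------------------------------------------------

    def update_species_effects(self) -> None:
        """RW-Metropolis for members; exact prior draws for non-members."""
        if self.fixed:
            return
        st = self.state
        rng = self.rng
        M = self.data.M
        if self.fast:
            S = self.data.S
            act_b = st.w
            newb, acc = metropolis_logit_bernoulli(
                st.beta[:, 0], self.s_occ, np.full(M, S),
                st.mu_beta[0], st.sigma_beta[0], self.scale_beta[0], rng,
            )
            st.beta[:, 0] = np.where(act_b, newb, st.beta[:, 0])
            st.beta[~act_b, 0] = st.mu_beta[0] + st.sigma_beta[0] * rng.normal(
                size=int((~act_b).sum())
            )
            if act_b.any():
                self._acc_beta[0] += acc[act_b].mean()

            act_a = self.trials_det > 0
            newa, acc = metropolis_logit_bernoulli(
                st.alpha[:, 0], self.det_total, self.trials_det,
                st.mu_alpha[0], st.sigma_alpha[0], self.scale_alpha[0], rng,
            )
            st.alpha[:, 0] = np.where(act_a, newa, st.alpha[:, 0])
            st.alpha[~act_a, 0] = st.mu_alpha[0] + st.sigma_alpha[0] * rng.normal(
                size=int((~act_a).sum())
            )
            if act_a.any():
                self._acc_alpha[0] += acc[act_a].mean()
        else:
            self._update_species_general()
        self._acc_n += 1

    def _occ_loglik(self, beta) -> np.ndarray:
        """Per-species occupancy log-likelihood sum_i z log psi + (1-z) log(1-psi)."""
        eta = self.data.X @ beta.T                        # (S, M)
        z = self.state.z
        return -(np.logaddexp(0.0, -eta) * z + np.logaddexp(0.0, eta) * (~z)).sum(axis=0)

    def _det_loglik(self, alpha) -> np.ndarray:
        """Per-species detection log-likelihood over occupied, conducted visits."""
        eta = np.einsum("sjq,mq->sjm", self.data.V, alpha)  # (S, J, M)
        y = self.data.y
        cells = self.state.z[:, None, :] & self.data.visit_mask[:, :, None]
        ll = -(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y))
        return np.where(cells, ll, 0.0).sum(axis=(0, 1))

    def _update_species_general(self) -> None:
        st, rng = self.state, self.rng
        M = self.data.M
        act_b = st.w
        for pi in range(st.beta.shape[1]):
            prop = st.beta.copy()
            prop[:, pi] += self.scale_beta[pi] * rng.normal(size=M)
            dl = (
                self._occ_loglik(prop) - self._occ_loglik(st.beta)
                - 0.5 * ((prop[:, pi] - st.mu_beta[pi]) / st.sigma_beta[pi]) ** 2
                + 0.5 * ((st.beta[:, pi] - st.mu_beta[pi]) / st.sigma_beta[pi]) ** 2
            )
            dl = np.where(np.isnan(dl), -np.inf, dl)
            acc = (np.log(rng.random(M)) < dl) & act_b
            st.beta[acc, pi] = prop[acc, pi]
            if act_b.any():
                self._acc_beta[pi] += acc[act_b].mean()
        st.beta[~act_b, :] = st.mu_beta + st.sigma_beta * rng.normal(
            size=(int((~act_b).sum()), st.beta.shape[1])
        )

        act_a = self.trials_det > 0
        for qi in range(st.alpha.shape[1]):
            prop = st.alpha.copy()
            prop[:, qi] += self.scale_alpha[qi] * rng.normal(size=M)
            dl = (
                self._det_loglik(prop) - self._det_loglik(st.alpha)
                - 0.5 * ((prop[:, qi] - st.mu_alpha[qi]) / st.sigma_alpha[qi]) ** 2
                + 0.5 * ((st.alpha[:, qi] - st.mu_alpha[qi]) / st.sigma_alpha[qi]) ** 2
            )
            dl = np.where(np.isnan(dl), -np.inf, dl)
            acc = (np.log(rng.random(M)) < dl) & act_a
            st.alpha[acc, qi] = prop[acc, qi]
            if act_a.any():
                self._acc_alpha[qi] += acc[act_a].mean()
        st.alpha[~act_a, :] = st.mu_alpha + st.sigma_alpha * rng.normal(
            size=(int((~act_a).sum()), st.alpha.shape[1])
        )

    def update_hyperparams(self) -> None:
        if self.fixed:
            return
        st = self.state
        U = self.priors.sigma_support
        for pi in range(st.beta.shape[1]):
            st.mu_beta[pi], st.sigma_beta[pi] = update_hyperparams(
                st.beta[:, pi], st.sigma_beta[pi], self.priors, self.rng
            )
        for qi in range(st.alpha.shape[1]):
            st.mu_alpha[qi], st.sigma_alpha[qi] = update_hyperparams(
                st.alpha[:, qi], st.sigma_alpha[qi], self.priors, self.rng
            )
        self._sigma_draws += st.beta.shape[1] + st.alpha.shape[1]
        self._sigma_at_bound += int((st.sigma_beta > 0.99 * U).sum())
        self._sigma_at_bound += int((st.sigma_alpha > 0.99 * U).sum())

    def update_w(self) -> None:
        """Collapsed update of membership for the undetected species."""
        st = self.state
        free = ~self.observed
        if not free.any():
            return
        if self.fixed:
            log_tail = self.logtail_fixed
        elif self.fast:
            psi, p = self._psi_p()
            if self.equal_J:
                J = self.J_i[0]
                log_tail = self.data.S * np.log1p(-psi * (1.0 - (1.0 - p) ** J))
            else:
                ju, counts = np.unique(self.J_i, return_counts=True)
                log_tail = np.zeros(self.data.M)
                for Jv, c in zip(ju, counts):
                    log_tail += c * np.log1p(-psi * (1.0 - (1.0 - p) ** Jv))
        else:
            psi, p = self._psi_p()
            pm = np.where(self.data.visit_mask[:, :, None], p, 0.0)
            q = np.prod(1.0 - pm, axis=1)
            log_tail = np.log1p(-psi * (1.0 - q)).sum(axis=0)
        lw = logit(np.clip(st.omega, 1e-300, 1 - 1e-12)) + log_tail
        draw = self.rng.random(self.data.M) < expit(lw)
        st.w = np.where(free, draw, st.w)

    def update_z(self) -> None:
        """Refresh presence given membership; detections force z = 1."""
        st = self.state
        S, M = self.data.S, self.data.M
        if self.fixed:
            psi, q = self.psi_fixed, self.q_fixed
            r = psi * q / (psi * q + 1.0 - psi)
        elif self.fast:
            psi, p = self._psi_p()
            if self.equal_J:
                q = (1.0 - p) ** self.J_i[0]
            else:
                q = np.exp(np.outer(self.J_i, np.log1p(-p)))
            r = psi * q / (psi * q + 1.0 - psi)
        else:
            psi, p = self._psi_p()
            pm = np.where(self.data.visit_mask[:, :, None], p, 0.0)
            q = np.prod(1.0 - pm, axis=1)
            r = psi * q / (psi * q + 1.0 - psi)
        st.z = self.D | (self.rng.random((S, M)) < r)
        st.z &= st.w[None, :]
        self._refresh_suffstats()

    def update_omega(self) -> None:
        a, b = self.priors.omega_beta
        self.state.omega = gibbs_omega(self.state.w, a, b, self.rng)

    # -- sweeps ------------------------------------------------------------

    def step(self, adapt: bool = False) -> None:
        self.update_species_effects()
        self.update_hyperparams()
        self.update_w()
        self.update_z()
        self.update_omega()
        if adapt and self._acc_n >= self.config.adapt_interval:
            self._adapt()

    def _adapt(self) -> None:
        self._batch += 1
        step = min(0.5, 2.0 / np.sqrt(self._batch))
        for scales, accs in ((self.scale_beta, self._acc_beta), (self.scale_alpha, self._acc_alpha)):
            rate = accs / self._acc_n
            scales *= np.exp(step * (rate - self.config.target_accept))
            np.clip(scales, 1e-3, 20.0, out=scales)
        self._acc_beta[:] = 0.0
        self._acc_alpha[:] = 0.0
        self._acc_n = 0

    def record(self) -> dict[str, float]:
        st = self.state
        out = {"omega": st.omega, "N": float(st.w.sum())}
        if not self.fixed:
            for pi in range(st.beta.shape[1]):
                out[f"mu_beta{pi}"] = st.mu_beta[pi]
                out[f"sigma_beta{pi}"] = st.sigma_beta[pi]
            for qi in range(st.alpha.shape[1]):
                out[f"mu_alpha{qi}"] = st.mu_alpha[qi]
                out[f"sigma_alpha{qi}"] = st.sigma_alpha[qi]
        return out


def _collect_block(
    chains: list[Chain], n_steps: int, thin: int, save_latent
) -> tuple[dict, dict]:
    names = chains[0].record().keys()
    n_keep = n_steps // thin
    params = {k: np.empty((len(chains), n_keep)) for k in names}
    latents: dict[str, list] = {k: [] for k in save_latent}
    for ci, ch in enumerate(chains):
        kept_w, kept_z, kept_psi, kept_beta, kept_alpha = [], [], [], [], []
        idx = 0
        for it in range(n_steps):
            ch.step(adapt=False)
            if (it + 1) % thin == 0:
                rec = ch.record()
                for k in names:
                    params[k][ci, idx] = rec[k]
                idx += 1
                if "w" in save_latent:
                    kept_w.append(ch.state.w.copy())
                if "z" in save_latent:
                    kept_z.append(ch.state.z.copy())
                if "psi" in save_latent:
                    psi, _ = ch._psi_p()
                    psi = np.broadcast_to(psi, (ch.data.S, ch.data.M))
                    kept_psi.append(psi.astype(np.float32).copy())
                if "beta" in save_latent:
                    kept_beta.append(ch.state.beta.copy())
                if "alpha" in save_latent:
                    kept_alpha.append(ch.state.alpha.copy())
        for key, buf in (
            ("w", kept_w), ("z", kept_z), ("psi", kept_psi),
            ("beta", kept_beta), ("alpha", kept_alpha),
        ):
            if key in save_latent:
                latents[key].append(np.stack(buf))
    latents = {k: np.stack(v) for k, v in latents.items()}
    return params, latents


def run_mcmc(
    data: AugmentedData,
    priors: PriorSet,
    config: MCMCConfig,
    save_latent: tuple = (),
    fixed_psi=None,
    fixed_p=None,
) -> PosteriorDraws:
    """Fit the augmented model and return retained posterior draws.

    Chains are initialized with latent presence set to the observed
    detections and all augmented species outside the community (w = 0).
    After burn-in (with proposal-scale adaptation, frozen afterwards), a
    block of post-burn-in draws is collected; if the classic R-hat of any
    monitored scalar is >= the threshold, additional same-sized blocks are
    drawn (earlier ones discarded as extra burn-in) up to
    ``max_extra_blocks``.  A run that still fails the R-hat rule is returned
    with ``converged=False`` rather than silently.

    ``fixed_psi``/``fixed_p`` pin the species parameters (no species-effect
    or hyperparameter updates), leaving a sampler over (w, z, Omega) only.
    """
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_chains)
    chains = [
        Chain(data, priors, config, np.random.default_rng(s), fixed_psi, fixed_p)
        for s in child_seeds
    ]
    for ch in chains:
        for _ in range(config.n_burn):
            ch.step(adapt=True)

    block_len = config.n_iter - config.n_burn
    blocks = 0
    while True:
        params, latents = _collect_block(chains, block_len, config.thin, save_latent)
        blocks += 1
        rhat = {}
        for name, arr in params.items():
            if config.n_chains >= 2 and arr.shape[1] >= 10:
                rhat[name] = gelman_rubin(arr)
        finite = [v for v in rhat.values() if not np.isnan(v)]
        converged = all(v < config.rhat_threshold for v in finite) if finite else True
        if converged or blocks > config.max_extra_blocks:
            break
    if not converged:
        warnings.warn(
            f"R-hat >= {config.rhat_threshold} after {blocks} blocks; "
            "result flagged as unconverged",
            stacklevel=2,
        )
    for ch in chains:
        if ch._sigma_draws and ch._sigma_at_bound / ch._sigma_draws > 0.01:
            warnings.warn(
                "hyper-sd near its uniform prior upper bound in >1% of draws; "
                "the prior support constraint is active",
                stacklevel=2,
            )
            break

    return PosteriorDraws(
        params=params,
        config=config,
        n_observed=data.n_observed,
        M=data.M,
        S=data.S,
        seeds=[s.entropy for s in child_seeds],
        blocks_used=blocks,
        converged=converged,
        rhat=rhat,
        w=latents.get("w"),
        z=latents.get("z"),
        psi=latents.get("psi"),
        beta=latents.get("beta"),
        alpha=latents.get("alpha"),
        detected_by_site=chains[0].D,
    )
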