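"""Independent oracles used by the tests.

Everything here is deliberately written from first principles (enumeration,
quadrature, direct formula transcriptions) and independent of the package's
implementation paths, so agreement is evidence rather than tautology.
"""

import itertools

import numpy as np
from scipy import integrate, stats
from scipy.special import betaln, expit


def enumerate_posterior(y, psi, p, a, b):
    """Brute-force joint posterior over (w, z) with Omega marginalized.

    y: (S, J, M) binary with augmented all-zero columns included; psi, p:
    known per-species probabilities; (a, b): Beta prior on Omega.  Returns
    (P(N = v) dict, P(z_ik = 1) matrix) by exhaustive enumeration of all
    membership vectors w, with the presence states z summed out analytically
    per site (z's are conditionally independent across sites).
    """
    S, J, M = y.shape
    det = y.any(axis=(0, 1))
    weights = {}
    pz_num = np.zeros((S, M))
    p_any_num = np.zeros(M)
    for wconf in itertools.product([0, 1], repeat=M):
        w = np.array(wconf)
        if np.any(det & (w == 0)):
            continue
        lw = betaln(a + w.sum(), b + M - w.sum()) - betaln(a, b)
        ll = 0.0
        pz_given = np.zeros((S, M))
        ok = True
        for k in range(M):
            for i in range(S):
                yk = y[i, :, k]
                if w[k] == 0:
                    if yk.any():
                        ok = False
                        break
                    continue
                l_det = np.prod(p[k] ** yk * (1 - p[k]) ** (1 - yk))
                l_pres = psi[k] * l_det
                l_abs = (1 - psi[k]) * (0.0 if yk.any() else 1.0)
                if l_pres + l_abs == 0:
                    ok = False
                    break
                ll += np.log(l_pres + l_abs)
                pz_given[i, k] = l_pres / (l_pres + l_abs)
            if not ok:
                break
        if ok:
            weights[wconf] = (lw + ll, pz_given)
    logs = np.array([v[0] for v in weights.values()])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_n = {}
    for (wconf, (_, pz_given)), pr in zip(weights.items(), probs):
        p_n[sum(wconf)] = p_n.get(sum(wconf), 0.0) + pr
        pz_num += pr * pz_given
        # given w and params, presence is independent across sites
        p_any_num += pr * np.array(wconf) * (1 - np.prod(1 - pz_given, axis=0))
    return p_n, pz_num, p_any_num


def enumerate_prob_missed(psi, p, S, J):
    """P(no detection anywhere) by enumerating presence/detection outcomes."""
    total = 0.0
    # per site: either absent (prob 1-psi, surely no detection) or present
    # and all J visits miss
    per_site_miss = (1 - psi) + psi * (1 - p) ** J
    for pres in itertools.product([0, 1], repeat=S):
        prob = 1.0
        for z in pres:
            if z:
                prob *= psi * (1 - p) ** J
            else:
                prob *= 1 - psi
        total += prob
    assert np.isclose(total, per_site_miss**S)
    return total


def quad_absent_fraction(mu, sigma, S):
    """E[(1 - psi)^S] under logit(psi) ~ N(mu, sigma) by quadrature."""
    f = lambda x: (1 - expit(x)) ** S * stats.norm.pdf(x, mu, sigma)
    val, _ = integrate.quad(f, mu - 12 * sigma, mu + 12 * sigma, limit=200)
    return val


def quad_missed_fraction(occ_mu, occ_sigma, det_mu, det_sigma, S, J):
    """E[(1 - psi p*)^S] under independent logit-normals by 2-D quadrature."""

    def integrand(v, u):
        psi = expit(u)
        pstar = 1 - (1 - expit(v)) ** J
        return (
            (1 - psi * pstar) ** S
            * stats.norm.pdf(u, occ_mu, occ_sigma)
            * stats.norm.pdf(v, det_mu, det_sigma)
        )

    val, _ = integrate.dblquad(
        integrand,
        occ_mu - 8 * occ_sigma, occ_mu + 8 * occ_sigma,
        det_mu - 8 * det_sigma, det_mu + 8 * det_sigma,
        epsabs=1e-6,
    )
    return val


def reference_psrf(chains):
    """Plain transcription of the two-part potential scale reduction factor."""
    x = np.asarray(chains, dtype=float)
    m, n = x.shape
    chain_means = [np.mean(x[c]) for c in range(m)]
    grand = np.mean(chain_means)
    B = n / (m - 1) * sum((cm - grand) ** 2 for cm in chain_means)
    W = np.mean([np.sum((x[c] - chain_means[c]) ** 2) / (n - 1) for c in range(m)])
    var_hat = (n - 1) / n * W + B / n
    return np.sqrt(var_hat / W)


def grid_hyper_posterior(effects, mu_sd, sigma_upper, mu_grid, sigma_grid):
    """Posterior of (mu, sigma) on a grid, normalized over the grid cells."""
    effects = np.asarray(effects)
    logp = np.empty((len(mu_grid), len(sigma_grid)))
    for i, mu in enumerate(mu_grid):
        for j, sg in enumerate(sigma_grid):
            if sg <= 0 or sg > sigma_upper:
                logp[i, j] = -np.inf
                continue
            logp[i, j] = (
                stats.norm.logpdf(effects, mu, sg).sum()
                + stats.norm.logpdf(mu, 0.0, mu_sd)
            )
    pr = np.exp(logp - logp.max())
    return pr / pr.sum()


def mc_se_indicator(indicator_chains):
    """Monte-Carlo standard error of a mean of autocorrelated 0/1 draws."""
    import arviz as az

    x = np.asarray(indicator_chains, dtype=float)
    ess = float(az.ess(x))
    phat = x.mean()
    return np.sqrt(max(phat * (1 - phat), 1e-12) / max(ess, 1.0))
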