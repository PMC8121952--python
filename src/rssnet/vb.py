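"""Variational inference for the network-induced spike-and-slab model.

The observed data enter through the summary-statistic likelihood

    betahat ~ N(S R S^{-1} beta, S R S),        S = diag(s),

with R the banded LD matrix from a reference panel.  The prior on each
SNP effect is the network-induced spike-and-slab

    beta_j ~ pi_j N(0, sigma_j^2) + (1 - pi_j) delta_0,
    pi_j = 1 / (1 + 10^{-(theta0 + a_j theta)}),
    sigma_j^2 = sigma0^2 + sigma^2 * s2sum_j,

where a_j flags SNPs near network genes/REs and s2sum_j = sum_g w_jg^2
carries the quadratic network weights (the slab arises by marginalizing
i.i.d. N(0, sigma^2) per-gene-path effects).  The free-parameter pair
(eta, rho) maps to (sigma0^2, sigma^2): eta is roughly the proportion of
phenotypic variance explained by all SNPs and rho the share of genetic
variance flowing through the network annotation.

Inference is mean-field coordinate ascent over
q(beta) = prod_j [alpha_j N(nu_j, tau_j^2) + (1 - alpha_j) delta_0],
run independently at each point of a hyper-parameter grid; the evidence
lower bound (ELBO) at each point approximates its log marginal
likelihood and feeds the enrichment Bayes factors downstream.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import scipy.linalg
from scipy.special import logsumexp, xlogy

from .datatypes import (GwasSummary, HyperGrid, LDMatrix, NetworkAnnotation,
                        ValidationError, VariationalFit)
from . import _kernels

logger = logging.getLogger("rssnet")

LN10 = np.log(10.0)


def map_hyperparams(eta: float, rho: float, pi: np.ndarray, se: np.ndarray,
                    n: np.ndarray, s2sum: np.ndarray) -> tuple[float, float]:
    """Map (eta, rho) to (sigma0^2, sigma^2).

    sigma0^2 = eta (1-rho) / sum_j pi_j / (n_j s_j^2)
    sigma^2  = eta rho / sum_j pi_j s2sum_j / (n_j s_j^2)

    Since n s_j^2 approximates the phenotype-to-genotype variance ratio,
    the mapping keeps beta on the trait scale independent of sample
    size.  A zero sigma^2 denominator (annotation with no weights) with
    rho > 0 yields sigma^2 = 0 with a warning.
    """
    if not (0 <= eta <= 1 and 0 <= rho <= 1):
        raise ValidationError("eta and rho must lie in [0, 1]")
    n = np.broadcast_to(np.atleast_1d(n).astype(float), pi.shape)
    base = pi / (n * se ** 2)
    d0 = base.sum()
    sigma0_sq = eta * (1 - rho) / d0 if d0 > 0 else 0.0
    d1 = (base * s2sum).sum()
    if d1 > 0:
        sigma_sq = eta * rho / d1
    else:
        sigma_sq = 0.0
        if eta * rho > 0:
            logger.warning("map_hyperparams: no network weights; sigma^2 "
                           "forced to 0 despite rho > 0")
    return sigma0_sq, sigma_sq


def prior_moments(theta0: float, theta: float, a: np.ndarray,
                  sigma0_sq: float, sigma_sq: float,
                  s2sum: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP prior parameters (pi_j, sigma_j^2)."""
    a = np.asarray(a, dtype=float)
    pi = 1.0 / (1.0 + 10.0 ** (-(theta0 + a * theta)))
    sigma2j = sigma0_sq + sigma_sq * np.asarray(s2sum, dtype=float)
    return pi, sigma2j


def likelihood_normalizer(gwas: GwasSummary, ld: LDMatrix) -> float:
    """Log normalizing constant of the likelihood at beta = 0:
    log N(betahat; 0, S R S).

    Requires the banded R to be positive definite (banded Cholesky).
    This term is shared by every grid point for the same data, so it
    cancels in Bayes factors; it is included so the ELBO is a genuine
    lower bound on the log marginal likelihood.
    """
    p = len(gwas)
    try:
        cb = scipy.linalg.cholesky_banded(ld.ab, lower=True)
    except scipy.linalg.LinAlgError as e:
        raise ValidationError(f"banded LD matrix not positive definite: {e}")
    logdet_r = 2.0 * np.sum(np.log(cb[0]))
    z = gwas.betahat / gwas.se
    quad = z @ scipy.linalg.cho_solve_banded((cb, True), z)
    return -0.5 * (p * np.log(2 * np.pi) + 2 * np.sum(np.log(gwas.se))
                   + logdet_r + quad)


def compute_tau(se: np.ndarray, sigma2j: np.ndarray) -> np.ndarray:
    """tau_j = s_j sigma_j / sqrt(s_j^2 + sigma_j^2)."""
    sigma = np.sqrt(np.maximum(sigma2j, 0.0))
    return se * sigma / np.sqrt(se ** 2 + sigma2j)


def lower_bound(alpha, nu, tau, gwas: GwasSummary, ld: LDMatrix,
                pi, sigma2j, const: float = 0.0) -> float:
    """ELBO = E_q[log likelihood] - KL(q || prior), in natural log.

    ``const`` is the output of :func:`likelihood_normalizer` (pass 0 to
    work on the shared-constant-dropped scale; differences between grid
    points on the same data are unaffected).
    """
    se = gwas.se
    m = alpha * nu
    t = m / se
    rt = ld.matvec(t.copy())
    tau2 = tau ** 2
    e_b2 = alpha * (nu ** 2 + tau2)
    fit_part = (m * gwas.betahat / se ** 2).sum() \
        - 0.5 * (t @ rt) - 0.5 * ((e_b2 - m ** 2) / se ** 2).sum()
    # KL of each spike-and-slab mixture against its prior
    kl_disc = (xlogy(alpha, alpha) - xlogy(alpha, pi)
               + xlogy(1 - alpha, 1 - alpha) - xlogy(1 - alpha, 1 - pi))
    ok = sigma2j > 0
    kl_slab = np.zeros_like(alpha)
    kl_slab[ok] = alpha[ok] * (
        0.5 * np.log(sigma2j[ok] / tau2[ok])
        + (tau2[ok] + nu[ok] ** 2) / (2 * sigma2j[ok]) - 0.5)
    return const + fit_part - kl_disc.sum() - kl_slab.sum()


def coordinate_ascent(gwas: GwasSummary, ld: LDMatrix, pi: np.ndarray,
                      sigma2j: np.ndarray, init_nu=None, init_alpha=None,
                      tol: float = 1e-4, max_iter: int = 300,
                      seed: int = 0, const: float = 0.0,
                      track_elbo: bool = False) -> VariationalFit:
    """Box-style mean-field coordinate ascent for one grid point.

    Updates per SNP j:
        nu_j    = tau_j^2 (betahat_j / s_j^2
                  - sum_{i != j} r_ij alpha_i nu_i / (s_i s_j))
        odds(alpha_j) = odds(pi_j) * (tau_j / sigma_j)
                  * exp(nu_j^2 / (2 tau_j^2))
    with alternating forward/backward sweep order.  Converged when both
    max_j |d alpha_j| < tol and max_j |d (alpha_j nu_j)| < tol.  Random
    initialization (alpha ~ U(0.01, 0.99), nu ~ N(0, sigma_j^2)) unless
    a warm start is supplied.  SNPs with sigma_j = 0 are pinned to the
    spike (alpha_j = nu_j = 0).
    """
    p = len(gwas)
    se = gwas.se
    pi = np.asarray(pi, dtype=float)
    sigma2j = np.asarray(sigma2j, dtype=float)
    tau = compute_tau(se, sigma2j)
    tau2 = tau ** 2
    if init_alpha is None or init_nu is None:
        rng = np.random.default_rng(seed)
        alpha = rng.uniform(0.01, 0.99, size=p)
        nu = rng.normal(0.0, np.sqrt(np.maximum(sigma2j, 0.0)), size=p)
    else:
        alpha = np.array(init_alpha, dtype=float)
        nu = np.array(init_nu, dtype=float)
    dead = sigma2j <= 0
    alpha[dead] = 0.0
    nu[dead] = 0.0
    # natural-log prior odds; pi in (0,1) by construction
    logit_pi = np.log(pi) - np.log1p(-pi)
    t = alpha * nu / se
    q = _kernels.band_matvec(ld.ab, t)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_da, max_dm = _kernels.sweep(
            ld.ab, gwas.betahat, se, logit_pi, sigma2j, tau, tau2,
            alpha, nu, t, q, it % 2 == 0)
        if track_elbo:
            trace.append(lower_bound(alpha, nu, tau, gwas, ld, pi, sigma2j,
                                     const))
        if max_da < tol and max_dm < tol:
            converged = True
            break
    elbo = lower_bound(alpha, nu, tau, gwas, ld, pi, sigma2j, const)
    fit = VariationalFit(alpha=alpha, nu=nu, tau=tau, elbo=elbo,
                         n_iter=it, converged=converged)
    fit.elbo_trace = trace
    if not converged:
        logger.warning("coordinate ascent did not converge in %d sweeps",
                       max_iter)
    return fit


def fit_grid(gwas: GwasSummary, ld: LDMatrix, ann: NetworkAnnotation,
             grid: HyperGrid, seed: int = 0, warm_start: bool = True,
             tol: float = 1e-4, max_iter: int = 300,
             const: float = None) -> list[VariationalFit]:
    """Fit every hyper-grid point; returns fits in grid order.

    Points are visited sorted by (eta, rho, theta0, theta); each point
    warm-starts from the previously fit point (the first is cold-started
    from ``seed``), which mitigates local optima at modest cost.
    Deterministic given the seed.
    """
    if len(grid) == 0:
        raise ValidationError("empty hyper-parameter grid")
    if const is None:
        const = likelihood_normalizer(gwas, ld)
    pts = grid.points
    order = pts.sort_values(["eta", "rho", "theta0", "theta"],
                            kind="mergesort").index.to_numpy()
    fits: dict[int, VariationalFit] = {}
    prev = None
    for h in order:
        theta0, theta, eta, rho = (pts.loc[h, "theta0"], pts.loc[h, "theta"],
                                   pts.loc[h, "eta"], pts.loc[h, "rho"])
        pi0, _ = prior_moments(theta0, theta, ann.a, 0.0, 0.0, ann.s2sum)
        s0sq, ssq = map_hyperparams(eta, rho, pi0, gwas.se, gwas.n, ann.s2sum)
        pi, sigma2j = prior_moments(theta0, theta, ann.a, s0sq, ssq, ann.s2sum)
        kwargs = {}
        if warm_start and prev is not None:
            kwargs = {"init_alpha": prev.alpha, "init_nu": prev.nu}
        fit = coordinate_ascent(gwas, ld, pi, sigma2j, tol=tol,
                                max_iter=max_iter, seed=seed, const=const,
                                **kwargs)
        fit.theta0, fit.theta, fit.eta, fit.rho = (float(theta0), float(theta),
                                                   float(eta), float(rho))
        fits[h] = fit
        prev = fit
    return [fits[h] for h in range(len(pts))]


def exact_posterior_oracle(gwas: GwasSummary, r_dense: np.ndarray,
                           pi: np.ndarray, sigma2j: np.ndarray,
                           const_included: bool = True):
    """Exact posterior by enumerating all 2^p spike/slab configurations.

    For each configuration gamma the marginal of betahat is Gaussian,
    N(0, SRS + A_gamma D_gamma A_gamma') with A = S R S^{-1}; evidences
    combine with the prior mixture weights.  Returns (exact alpha,
    log evidence).  Refuses p > 12.
    """
    p = len(gwas)
    if p > 12:
        raise ValidationError("exact enumeration limited to p <= 12")
    se = gwas.se
    srs = (se[:, None] * r_dense * se[None, :])
    a_mat = (se[:, None] * r_dense / se[None, :])
    log_pi = np.log(pi)
    log_1mpi = np.log1p(-pi)
    log_terms = np.empty(2 ** p)
    member = np.zeros((2 ** p, p), dtype=bool)
    bh = gwas.betahat
    for k, gamma in enumerate(itertools.product([0, 1], repeat=p)):
        g = np.array(gamma, dtype=bool)
        member[k] = g
        cov = srs.copy()
        if g.any():
            ag = a_mat[:, g]
            cov += (ag * sigma2j[g]) @ ag.T
        sign, logdet = np.linalg.slogdet(cov)
        sol = np.linalg.solve(cov, bh)
        loglik = -0.5 * (p * np.log(2 * np.pi) + logdet + bh @ sol)
        log_prior = log_pi[g].sum() + log_1mpi[~g].sum()
        log_terms[k] = loglik + log_prior
    log_ev = logsumexp(log_terms)
    w = np.exp(log_terms - log_ev)
    alpha_exact = w @ member
    if not const_included:
        log_ev -= likelihood_normalizer(
            gwas, LDMatrix.from_dense(r_dense, p - 1))
    return alpha_exact, log_ev
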