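"""Numba inner loops for the coordinate-ascent updates.

The sweep maintains t_j = alpha_j * nu_j / s_j and q = R @ t so that the
residual sum in the nu-update,
sum_{i != j} r_ij alpha_i nu_i / (s_i s_j) = (q_j - t_j) / s_j,
costs O(bandwidth) per SNP instead of O(p).
"""

import numpy as np
from numba import njit

MAX_EXP = 700.0


@njit(cache=True)
def sweep(ab, betahat, se, logit_pi, sigma2j, tau, tau2,
          alpha, nu, t, q, reverse):
    """One coordinate sweep over all SNPs (in place).

    ab: (bw+1, p) lower banded LD storage; logit_pi: natural-log prior
    odds; sigma2j: per-SNP slab variances; tau/tau2: per-SNP conditional
    posterior sd and variance.  Returns (max |d alpha|, max |d alpha*nu|).
    """
    p = betahat.shape[0]
    bw = ab.shape[0] - 1
    max_da = 0.0
    max_dm = 0.0
    for idx in range(p):
        j = p - 1 - idx if reverse else idx
        old_a = alpha[j]
        old_m = alpha[j] * nu[j]
        if sigma2j[j] <= 0.0:
            # degenerate slab: point mass at zero
            new_a = 0.0
            new_nu = 0.0
        else:
            resid = betahat[j] / (se[j] * se[j]) - (q[j] - t[j]) / se[j]
            new_nu = tau2[j] * resid
            z = logit_pi[j] + np.log(tau[j] / np.sqrt(sigma2j[j])) \
                + new_nu * new_nu / (2.0 * tau2[j])
            if z > MAX_EXP:
                z = MAX_EXP
            elif z < -MAX_EXP:
                z = -MAX_EXP
            new_a = 1.0 / (1.0 + np.exp(-z))
        new_m = new_a * new_nu
        d = new_m / se[j] - t[j]
        if d != 0.0:
            lo = j - bw if j - bw > 0 else 0
            hi = j + bw if j + bw < p - 1 else p - 1
            for i in range(lo, j):
                q[i] += ab[j - i, i] * d
            for i in range(j + 1, hi + 1):
                q[i] += ab[i - j, j] * d
            q[j] += ab[0, j] * d
            t[j] += d
        alpha[j] = new_a
        nu[j] = new_nu
        da = abs(new_a - old_a)
        dm = abs(new_m - old_m)
        if da > max_da:
            max_da = da
        if dm > max_dm:
            max_dm = dm
    return max_da, max_dm


@njit(cache=True)
def ar1_blocks(eps, rho, block_size):
    """AR(1) latent Gaussian within consecutive blocks (in place).

    eps: (m, p) standard normals; correlation restarts at every block
    boundary, so blocks are exactly independent.
    """
    m, p = eps.shape
    c = np.sqrt(1.0 - rho * rho)
    for i in range(m):
        for j in range(1, p):
            if j % block_size != 0:
                eps[i, j] = rho * eps[i, j - 1] + c * eps[i, j]


@njit(cache=True)
def band_matvec(ab, x):
    """R @ x for lower banded storage ab."""
    p = x.shape[0]
    bw = ab.shape[0] - 1
    y = np.zeros(p)
    for j in range(p):
        y[j] += ab[0, j] * x[j]
        hi = bw if j + bw < p else p - 1 - j
        for k in range(1, hi + 1):
            y[j + k] += ab[k, j] * x[j]
            y[j] += ab[k, j] * x[j + k]
    return y
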