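"""Numba-compiled single-site Gibbs sweeps over marker effects.

Each sweep maintains the residual vector e = y - mu - X beta in place, so a
marker update costs two length-n BLAS-1 passes.  All random numbers are drawn
outside (one vector per sweep from a seeded numpy Generator) and passed in,
which keeps the chains fully deterministic given the seed.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_normal(Xt, xx, e, beta, var_beta, sigma2_e, z):
    """One Gibbs sweep with independent normal priors beta_j ~ N(0, var_beta[j])."""
    p, n = Xt.shape
    for j in range(p):
        xj = Xt[j]
        bj = beta[j]
        rhs = np.dot(xj, e) + xx[j] * bj
        v = 1.0 / (xx[j] / sigma2_e + 1.0 / var_beta[j])
        m = v * rhs / sigma2_e
        bn = m + np.sqrt(v) * z[j]
        d = bj - bn
        if d != 0.0:
            for i in range(n):
                e[i] += xj[i] * d
        beta[j] = bn


@njit(cache=True)
def sweep_point_mass(Xt, xx, e, gamma, incl, sigma2_g, sigma2_e, log_odds_pi, z, u):
    """One sweep with the point-mass mixture gamma_j ~ pi N(0, s2) + (1-pi) d0.

    The inclusion indicator is drawn from its conditional with gamma_j
    integrated out (log Bayes factor 0.5 log(v/s2) + m^2 / 2v).  Returns the
    number of markers currently in the slab.
    """
    p, n = Xt.shape
    n_in = 0
    for j in range(p):
        xj = Xt[j]
        gj = gamma[j]
        rhs = np.dot(xj, e) + xx[j] * gj
        v = 1.0 / (xx[j] / sigma2_e + 1.0 / sigma2_g)
        m = v * rhs / sigma2_e
        lo = log_odds_pi + 0.5 * np.log(v / sigma2_g) + 0.5 * m * m / v
        if np.log(u[j] / (1.0 - u[j])) < lo:
            gn = m + np.sqrt(v) * z[j]
            incl[j] = 1
            n_in += 1
        else:
            gn = 0.0
            incl[j] = 0
        d = gj - gn
        if d != 0.0:
            for i in range(n):
                e[i] += xj[i] * d
        gamma[j] = gn
    return n_in


@njit(cache=True)
def sweep_two_normal(Xt, xx, e, beta, incl, s2_slab, s2_spike, sigma2_e,
                     log_odds_pi, z, u):
    """One sweep with the two-normal mixture (George & McCulloch).

    The indicator is drawn given the current beta_j (ratio of the two normal
    prior densities), then beta_j is refreshed under the selected variance.
    """
    p, n = Xt.shape
    n_slab = 0
    for j in range(p):
        bj = beta[j]
        lo = (log_odds_pi
              + 0.5 * bj * bj * (1.0 / s2_spike - 1.0 / s2_slab)
              + 0.5 * np.log(s2_spike / s2_slab))
        if np.log(u[j] / (1.0 - u[j])) < lo:
            var = s2_slab
            incl[j] = 1
            n_slab += 1
        else:
            var = s2_spike
            incl[j] = 0
        xj = Xt[j]
        rhs = np.dot(xj, e) + xx[j] * bj
        v = 1.0 / (xx[j] / sigma2_e + 1.0 / var)
        m = v * rhs / sigma2_e
        bn = m + np.sqrt(v) * z[j]
        d = bj - bn
        if d != 0.0:
            for i in range(n):
                e[i] += xj[i] * d
        beta[j] = bn
    return n_slab
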