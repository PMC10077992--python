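"""Independent brute-force oracles for the model density functions.

These re-derive the generative quantities with scalar loops and textbook
density formulas (math.lgamma etc.), deliberately sharing no code with the
package's vectorized implementations.
"""

import math

import numpy as np


def oracle_kernel(ws, wd, nu1, nu2, h1, h2):
    a = math.exp(-((nu1 - ws) ** 2) / (2.0 * h1))
    b = math.exp(-(math.sin((nu2 - wd) * math.pi / 360.0) ** 2) / (2.0 * h2))
    return a * b


def oracle_mu(state, wind):
    """Model mean by explicit per-cell loops."""
    P, K, T = state.P, state.K, state.T
    mu = np.zeros((P, T))
    for t in range(T):
        xi = []
        for k in range(K - 1):
            w = oracle_kernel(wind.ws[t], wind.wd[t], state.nu1[k], state.nu2[k],
                              state.h1[k], state.h2[k])
            xi.append(w * state.eta[k, t])
        xi.append(1.0)
        s = []
        for k in range(K):
            prod = 1.0
            for l in range(k):
                prod *= 1.0 - xi[l]
            s.append(xi[k] * prod)
        for p in range(P):
            mu[p, t] = sum(state.lam[p, k] * s[k] * state.c[t] for k in range(K))
    return mu


def _norm_logpdf(x, m, sd):
    return -0.5 * math.log(2.0 * math.pi) - math.log(sd) - (x - m) ** 2 / (2.0 * sd ** 2)


def _gamma_logpdf(x, shape, rate):
    return (shape * math.log(rate) - math.lgamma(shape)
            + (shape - 1.0) * math.log(x) - rate * x)


def oracle_loglik(state, data, wind):
    mu = oracle_mu(state, wind)
    total = 0.0
    for p in range(state.P):
        for t in range(state.T):
            if not data.missing_mask[p, t]:
                total += _norm_logpdf(math.log(data.values[p, t]),
                                      math.log(mu[p, t]), state.sigma[p])
    return total


def oracle_logprior(state, config, wind):
    P, K = state.P, state.K
    J = K - 1
    nu1_upper = config.nu1_upper if config.nu1_upper is not None else max(wind.ws)
    lp = _norm_logpdf(state.mu_c, config.prior_mu_c[0], config.prior_mu_c[1])
    lp += _gamma_logpdf(state.sigma_c, *config.prior_sigma_c)
    for p in range(P):
        lp += _gamma_logpdf(state.sigma[p] ** 2, *config.prior_sigma_p_sq)
    a = config.prior_lambda
    for k in range(K):
        lp += math.lgamma(P * a) - P * math.lgamma(a)
        for p in range(P):
            lp += (a - 1.0) * math.log(state.lam[p, k])
    lp += _gamma_logpdf(state.alpha, *config.prior_alpha)
    for k in range(J):
        for t in range(state.T):
            # Beta(1, alpha) density
            lp += math.log(state.alpha) + (state.alpha - 1.0) * math.log(
                1.0 - state.eta[k, t])
    for k in range(J):
        for h in (state.h1[k], state.h2[k]):
            lp += _gamma_logpdf(1.0 / h, *config.prior_inv_h) - 2.0 * math.log(h)
        lp += -math.log(nu1_upper) - math.log(360.0)
    for t in range(state.T):
        lp += _norm_logpdf(math.log(state.c[t]), state.mu_c, state.sigma_c)
    return lp
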