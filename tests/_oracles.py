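"""Independent brute-force implementations used as test oracles.

These deliberately use plain loops over quadrature nodes, mastery profiles
and items, sharing no code with the vectorized likelihood engines.
"""

import itertools

import numpy as np
from scipy.special import expit

from lgcdm import QuadratureRule


def brute_person_loglik(spec, item, attr, y, z=0.0):
    """Enumeration-based marginal log-likelihood for one person."""
    g = QuadratureRule.gauss_hermite(spec.quadrature)
    K = spec.qmatrix.n_attributes
    J = spec.qmatrix.n_items
    q = spec.qmatrix.entries
    T = y.shape[0]
    tc = spec.time_coding.codes

    def item_lik(alpha, t):
        out = 1.0
        for j in range(J):
            if not np.isfinite(y[t, j]):
                continue
            eta = int(all(alpha[k] >= q[j, k] for k in range(K)))
            p = expit(item.f[j] + item.d[j] * eta)
            out *= p if y[t, j] == 1 else 1.0 - p
        return out

    if spec.family.startswith("lg_"):
        total = 0.0
        for iu, u in enumerate(g.nodes):
            for iv, v in enumerate(g.nodes):
                w = g.weights[iu] * g.weights[iv]
                prod_t = 1.0
                for t in range(T):
                    pk = []
                    for k in range(K):
                        a = (
                            attr.b[k] + attr.h[k] * z + attr.mu0
                            + (attr.sigma0 + attr.h0 * z) * u
                            + (attr.mu1 + (attr.sigma1 + attr.h1 * z) * v) * tc[t]
                        )
                        if attr.eps_sd > 0:
                            pk.append(
                                sum(
                                    we * expit(a + attr.eps_sd * xe)
                                    for xe, we in zip(g.nodes, g.weights)
                                )
                            )
                        else:
                            pk.append(expit(a))
                    s = 0.0
                    for alpha in itertools.product([0, 1], repeat=K):
                        pa = np.prod(
                            [pk[k] if alpha[k] else 1 - pk[k] for k in range(K)]
                        )
                        s += pa * item_lik(alpha, t)
                    prod_t *= s
                total += w * prod_t
        return float(np.log(total))

    # stacked RDINA: one profile per person across all occasions
    total = 0.0
    for alpha in itertools.product([0, 1], repeat=K):
        pa = 1.0
        for k in range(K):
            p = expit(attr.b[k] + attr.h[k] * z)
            pa *= p if alpha[k] else 1.0 - p
        lik = 1.0
        for t in range(T):
            lik *= item_lik(alpha, t)
        total += pa * lik
    return float(np.log(total))


def brute_rdina_posterior(spec, item, attr, y, z=0.0):
    """Bayes-rule posterior P(alpha_k = 1 | y) for the stacked RDINA model."""
    K = spec.qmatrix.n_attributes
    q = spec.qmatrix.entries
    J = spec.qmatrix.n_items
    T = y.shape[0]
    num = np.zeros(K)
    den = 0.0
    for alpha in itertools.product([0, 1], repeat=K):
        pa = 1.0
        for k in range(K):
            p = expit(attr.b[k] + attr.h[k] * z)
            pa *= p if alpha[k] else 1.0 - p
        lik = 1.0
        for t in range(T):
            for j in range(J):
                if not np.isfinite(y[t, j]):
                    continue
                eta = int(all(alpha[k] >= q[j, k] for k in range(K)))
                pj = expit(item.f[j] + item.d[j] * eta)
                lik *= pj if y[t, j] == 1 else 1.0 - pj
        den += pa * lik
        num += pa * lik * np.array(alpha)
    return num / den
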