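"""Independent, deliberately naive reference implementations used as oracles.

Everything here is written directly from the textbook formulas with explicit
double loops or brute-force integration, independent of the package's
vectorized code paths.
"""

import numpy as np


def naive_morans_i(y, w):
    """Global Moran's I by explicit double loop."""
    n = len(y)
    ybar = sum(y) / n
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i][j] * (y[i] - ybar) * (y[j] - ybar)
            s0 += w[i][j]
    den = sum((yi - ybar) ** 2 for yi in y)
    return (n / s0) * num / den


def naive_gi_star(y, w_binary):
    """Getis-Ord Gi* z-scores, self-included weights, explicit loops."""
    n = len(y)
    ybar = sum(y) / n
    s = (sum(yi * yi for yi in y) / n - ybar * ybar) ** 0.5
    out = []
    for i in range(n):
        wi = [w_binary[i][j] for j in range(n)]
        wi[i] = 1.0
        sw = sum(wi)
        sw2 = sum(v * v for v in wi)
        num = sum(wi[j] * y[j] for j in range(n)) - ybar * sw
        den = s * ((n * sw2 - sw * sw) / (n - 1)) ** 0.5
        out.append(num / den if den != 0 else float("nan"))
    return out


def naive_local_moran(y, w_row):
    """Local Moran I_i on sample-sd standardized values, explicit loops."""
    n = len(y)
    ybar = sum(y) / n
    s = (sum((yi - ybar) ** 2 for yi in y) / (n - 1)) ** 0.5
    z = [(yi - ybar) / s for yi in y]
    return [z[i] * sum(w_row[i][j] * z[j] for j in range(n)) for i in range(n)]


def brute_force_cluster_loglik(eta1, eta2, psi, cells, sigma,
                               lim=8.0, n_grid=400):
    """2-D trapezoid integration of one cluster's marginal likelihood.

    eta1/eta2/cells are per-record; cells index (00, 01, 10, 11).
    """
    from bivlogit.dale import cell_probabilities

    g = np.linspace(-lim, lim, n_grid)
    b1, b2 = np.meshgrid(g, g)
    si = np.linalg.inv(sigma)
    logprior = (-0.5 * (si[0, 0] * b1 ** 2 + 2 * si[0, 1] * b1 * b2
                        + si[1, 1] * b2 ** 2)
                - np.log(2 * np.pi) - 0.5 * np.log(np.linalg.det(sigma)))
    tot = np.zeros_like(b1)
    for e1, e2, c in zip(eta1, eta2, cells):
        probs = cell_probabilities(e1 + b1.ravel(), e2 + b2.ravel(),
                                   np.log(psi) * np.ones(b1.size))
        tot += np.log(probs[:, c]).reshape(b1.shape)
    integrand = np.exp(tot + logprior)
    return float(np.log(np.trapezoid(np.trapezoid(integrand, g, axis=1), g)))


def random_spatial_instance(rng, n_max=30):
    """A random symmetric connected-ish weight structure and a rate vector."""
    n = int(rng.integers(5, n_max + 1))
    a = np.zeros((n, n))
    # random symmetric adjacency, then force a ring so no islands
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.25:
                a[i, j] = a[j, i] = 1.0
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1.0
    y = rng.random(n)
    return y, a
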