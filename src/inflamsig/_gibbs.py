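"""Numba kernel for the threshold-model Bayesian LASSO Gibbs sampler.

The augmented sampler alternates:

1. liabilities l_i ~ N(eta_i, 1) truncated to (0, inf) for cases and
   (-inf, 0] for controls (residual variance 1 and threshold 0 are fixed for
   identification);
2. each regression coefficient from its univariate normal full conditional in
   a single-site (Gauss-Seidel) scan -- unpenalized covariate effects beta
   first, then SNP effects g with per-SNP prior variance tau2_j;
3. 1/tau2_j ~ inverse-Gaussian(mean sqrt(lambda2)/|g_j|, shape lambda2);
4. lambda2 ~ Gamma(shape p + a, rate b + sum_j tau2_j / 2) (optional; a fixed
   lambda2 makes the marginal prior on each g_j exactly double-exponential).

Truncated-normal draws use the inverse CDF with a tail-safe exponential
rejection fallback for extreme means.
"""

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _phi_cdf(x):
    return 0.5 * (1.0 + math.erf(x / SQRT2))


@njit(cache=True)
def _ndtri(p):
    """Standard normal quantile (Acklam's rational approximation + one
    Halley refinement step; ~1e-15 relative accuracy)."""
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    a = (-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
         1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00)
    b = (-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
         6.680131188771972e+01, -1.328068155288572e+01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
         -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00)
    d = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
         3.754408661907416e+00)
    plow = 0.02425
    if p < plow:
        q = math.sqrt(-2.0 * math.log(p))
        x = ((((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5])
             / ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0))
    elif p <= 1.0 - plow:
        q = p - 0.5
        r = q * q
        x = ((((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * q
             / (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r + 1.0))
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -((((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5])
              / ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0))
    # Halley refinement
    e = _phi_cdf(x) - p
    u = e * math.sqrt(2.0 * math.pi) * math.exp(x * x / 2.0)
    x = x - u / (1.0 + x * u / 2.0)
    return x


@njit(cache=True)
def _rtnorm_lower(mu):
    """Draw from N(mu, 1) truncated to (0, inf)."""
    a = -mu  # standard-normal lower bound
    if a < 4.0:
        p0 = _phi_cdf(a)
        u = np.random.random()
        q = p0 + u * (1.0 - p0)
        if q >= 1.0:
            q = 1.0 - 1e-16
        return mu + _ndtri(q)
    # far-tail fallback: Robert's exponential rejection above a
    alpha = (a + math.sqrt(a * a + 4.0)) / 2.0
    while True:
        z = a + np.random.exponential(1.0 / alpha)
        rho = math.exp(-((z - alpha) ** 2) / 2.0)
        if np.random.random() <= rho:
            return mu + z


@njit(cache=True)
def _rinvgauss(mu, lam):
    """Inverse-Gaussian(mu, lam) via Michael-Schucany-Haas."""
    v = np.random.standard_normal()
    y = v * v
    x = (mu + mu * mu * y / (2.0 * lam)
         - mu / (2.0 * lam) * math.sqrt(4.0 * mu * lam * y + mu * mu * y * y))
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def gibbs_kernel(W, X, y, n_iter, burn_in, thin, hyper_a, hyper_b,
                 lambda2_init, sample_lambda2, store_liabilities, seed):
    """Run the sampler; returns post-burn-in chains.

    Returns (beta_chain, g_chain, lambda2_chain, mu_l_chain, l_chain,
    trunc_ok, bad_iter).  ``bad_iter`` >= 0 flags a non-finite state at that
    iteration (the caller raises).  ``l_chain`` has shape (0, 0) unless
    ``store_liabilities``.
    """
    np.random.seed(seed)
    n, q = W.shape
    p = X.shape[1]
    wss = np.empty(q)
    for c in range(q):
        s = 0.0
        for i in range(n):
            s += W[i, c] * W[i, c]
        wss[c] = s
    xss = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xss[j] = s

    beta = np.zeros(q)
    g = np.zeros(p)
    tau2 = np.ones(p)
    lambda2 = lambda2_init
    l = np.empty(n)
    r = np.empty(n)
    for i in range(n):
        if y[i] == 1:
            l[i] = _rtnorm_lower(0.0)
        else:
            l[i] = -_rtnorm_lower(0.0)
        r[i] = l[i]  # eta starts at 0

    n_keep = (n_iter - burn_in + thin - 1) // thin
    beta_chain = np.empty((n_keep, q))
    g_chain = np.empty((n_keep, p))
    lambda2_chain = np.empty(n_keep)
    mu_l_chain = np.empty(n_keep)
    if store_liabilities:
        l_chain = np.empty((n_keep, n))
    else:
        l_chain = np.empty((0, 0))
    trunc_ok = True
    bad_iter = -1
    keep = 0

    for it in range(n_iter):
        # (1) liabilities
        for i in range(n):
            eta_i = l[i] - r[i]
            if y[i] == 1:
                l[i] = _rtnorm_lower(eta_i)
            else:
                l[i] = -_rtnorm_lower(-eta_i)
            r[i] = l[i] - eta_i
        # (2) coefficients, single-site scan: beta (flat prior) then g
        for c in range(q):
            old = beta[c]
            ztr = 0.0
            for i in range(n):
                ztr += W[i, c] * r[i]
            ztr += wss[c] * old
            v = 1.0 / wss[c]
            new = v * ztr + math.sqrt(v) * np.random.standard_normal()
            diff = new - old
            beta[c] = new
            for i in range(n):
                r[i] -= W[i, c] * diff
        for j in range(p):
            old = g[j]
            ztr = 0.0
            for i in range(n):
                ztr += X[i, j] * r[i]
            ztr += xss[j] * old
            v = 1.0 / (xss[j] + 1.0 / tau2[j])
            new = v * ztr + math.sqrt(v) * np.random.standard_normal()
            diff = new - old
            g[j] = new
            for i in range(n):
                r[i] -= X[i, j] * diff
        # (3) prior variances
        tau_sum = 0.0
        sqrt_l2 = math.sqrt(lambda2)
        for j in range(p):
            gj = abs(g[j])
            if gj < 1e-10:
                gj = 1e-10  # guard: inverse-Gaussian mean diverges at g = 0
            inv_tau = _rinvgauss(sqrt_l2 / gj, lambda2)
            tau2[j] = 1.0 / inv_tau
            tau_sum += tau2[j]
        # (4) shrinkage hyperparameter
        if sample_lambda2:
            lambda2 = np.random.gamma(p + hyper_a, 1.0 / (hyper_b + tau_sum / 2.0))

        if it >= burn_in and (it - burn_in) % thin == 0:
            mu = 0.0
            finite = True
            for i in range(n):
                eta_i = l[i] - r[i]
                mu += eta_i
                if not math.isfinite(l[i]):
                    finite = False
                if y[i] == 1 and l[i] <= 0.0:
                    trunc_ok = False
                if y[i] == 0 and l[i] > 0.0:
                    trunc_ok = False
            mu /= n
            if not (finite and math.isfinite(mu) and math.isfinite(lambda2)):
                bad_iter = it
                break
            for c in range(q):
                beta_chain[keep, c] = beta[c]
            for j in range(p):
                g_chain[keep, j] = g[j]
            lambda2_chain[keep] = lambda2
            mu_l_chain[keep] = mu
            if store_liabilities:
                for i in range(n):
                    l_chain[keep, i] = l[i]
            keep += 1

    return beta_chain, g_chain, lambda2_chain, mu_l_chain, l_chain, trunc_ok, bad_iter
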