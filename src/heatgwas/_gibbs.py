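"""Single-site Gibbs sampler kernel for Bayes-C / Bayes-Cpi whole-genome regression.

Model: y = X beta + Z u + e, with flat priors on the fixed effects beta,
marker effects u_j that are zero with probability pi and otherwise
N(0, sigma2_u) with a variance common to all included markers, and
e ~ N(0, sigma2_e I).  sigma2_u and sigma2_e carry scaled-inverse-chi-square
priors; pi is either fixed (Bayes-C) or given a uniform prior and sampled
from its Beta full conditional (Bayes-Cpi).

Each marker's (indicator, effect) pair is updated jointly from the marginal
likelihood with the effect integrated out, in a fresh random order every
iteration.  The kernel maintains the residual vector incrementally and is
resumable: it mutates ``u`` and ``beta`` in place and returns the final
variance/pi state, so chains can be extended block-wise.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# kernel return status codes
OK = 0
FAILED_NONFINITE = 1


@njit(cache=True)
def run_chain(
    Z, y, X,
    u, beta,
    s2u, s2e, pi,
    n_iter, burn_in, thin,
    estimate_pi, fix_variances,
    nu_u, scale_u_base, max_incl_frac, nu_e, scale_e,
    seed,
    out_s2u, out_s2e, out_pi, out_gv, out_h2,
    out_u, out_delta, out_beta, pi_trace,
):  # pragma: no cover - exercised via the python wrapper
    np.random.seed(seed)
    n, m = Z.shape
    p = X.shape[1]

    zsq = np.empty(m)
    for j in range(m):
        zsq[j] = Z[:, j] @ Z[:, j]
    xsq = np.empty(p)
    for l in range(p):
        xsq[l] = X[:, l] @ X[:, l]

    e = y - X @ beta - Z @ u
    delta = np.zeros(m, dtype=np.uint8)
    for j in range(m):
        if u[j] != 0.0:
            delta[j] = 1

    # Per-marker prior scale: the genomic-variance prior is spread over the
    # markers expected to be included, tracking the current pi but never over
    # more than the prior expectation (max_incl_frac) — the floor on the scale
    # keeps sigma2_u from collapsing when a chain transiently over-includes.
    min_frac = 1.0 / m
    frac = 1.0 - pi
    if frac > max_incl_frac:
        frac = max_incl_frac
    if frac < min_frac:
        frac = min_frac
    scale_u = scale_u_base / frac

    s = 0  # saved-state counter
    for it in range(1, n_iter + 1):
        # --- fixed effects, coordinate-wise with flat priors ---
        for l in range(p):
            if xsq[l] <= 0.0:
                continue
            old = beta[l]
            e += X[:, l] * old
            r = X[:, l] @ e
            mean = r / xsq[l]
            beta[l] = mean + np.random.normal() * np.sqrt(s2e / xsq[l])
            e -= X[:, l] * beta[l]

        # --- marker effects: joint (indicator, effect) update ---
        perm = np.random.permutation(m)
        k = 0
        ssq_u = 0.0
        for idx in range(m):
            j = perm[idx]
            c = zsq[j]
            if c <= 0.0:
                u[j] = 0.0
                delta[j] = 0
                continue
            if u[j] != 0.0:
                e += Z[:, j] * u[j]
            r = Z[:, j] @ e
            if pi >= 1.0:
                include = False
            elif pi <= 0.0:
                include = True
            else:
                v0 = c * s2e
                v1 = c * c * s2u + c * s2e
                log_odds = (
                    np.log(1.0 - pi) - np.log(pi)
                    + 0.5 * (np.log(v0) - np.log(v1))
                    + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
                )
                if log_odds > 35.0:
                    include = True
                elif log_odds < -35.0:
                    include = False
                else:
                    include = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))
            if include:
                lhs = c + s2e / s2u
                mean = r / lhs
                u[j] = mean + np.random.normal() * np.sqrt(s2e / lhs)
                e -= Z[:, j] * u[j]
                delta[j] = 1
                k += 1
                ssq_u += u[j] * u[j]
            else:
                u[j] = 0.0
                delta[j] = 0

        # --- variance components: scaled-inverse-chi-square full conditionals ---
        if not fix_variances:
            s2u = (ssq_u + nu_u * scale_u) / np.random.chisquare(nu_u + k)
            sse = e @ e
            s2e = (sse + nu_e * scale_e) / np.random.chisquare(nu_e + n)
            if not (np.isfinite(s2u) and np.isfinite(s2e)) or s2e <= 0.0 or s2u <= 0.0:
                return FAILED_NONFINITE, it, s, s2u, s2e, pi

        # --- pi: Beta full conditional under a uniform prior (Bayes-Cpi) ---
        if estimate_pi:
            pi = np.random.beta(m - k + 1, k + 1)
            frac = 1.0 - pi
            if frac > max_incl_frac:
                frac = max_incl_frac
            if frac < min_frac:
                frac = min_frac
            scale_u = scale_u_base / frac
        pi_trace[it - 1] = pi

        # --- save thinned post-burn-in states ---
        t = it - burn_in
        if t > 0 and t % thin == 0 and s < out_s2u.shape[0]:
            g = Z @ u  # current genomic values
            gmean = g.mean()
            gv = ((g - gmean) @ (g - gmean)) / (n - 1)
            out_s2u[s] = s2u
            out_s2e[s] = s2e
            out_pi[s] = pi
            out_gv[s] = gv
            out_h2[s] = gv / (gv + s2e) if gv + s2e > 0.0 else 0.0
            for j in range(m):
                out_u[s, j] = u[j]
                out_delta[s, j] = delta[j]
            for l in range(p):
                out_beta[s, l] = beta[l]
            s += 1

    return OK, n_iter, s, s2u, s2e, pi
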