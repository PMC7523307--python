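"""Compiled Gibbs-sampler kernels for the multilevel VAR(1).

Per-person work (missing-cell imputation by forward-filter backward-sampling,
conjugate draws of the person lag matrix and latent mean) runs inside numba
so study-scale panels fit in seconds.  All randomness enters through
pre-generated standard-normal arrays, so reproducibility is governed by the
caller's numpy Generator.

Layout conventions
------------------
* ``Y``: (n_persons, T_max, p) with trailing padding; ``lengths`` gives each
  person's span.  ``obs``: boolean mask of originally observed cells.
* Person parameter vector theta has 49 lag entries in row-major order
  (``theta[p*a + c] = phi[a, c]``, the effect of item c at t-1 on item a at
  t) followed by the 7 latent means.
"""

from __future__ import annotations

import numpy as np
from numba import njit

JITTER = 1e-9


@njit(cache=True)
def _stationary_cov(phi, sigma):
    """Solve V = phi V phi' + sigma via the 49x49 vectorised system.

    Falls back to an inflated innovation covariance when the solve is
    unusable (near-unit-root person draw).
    """
    p = phi.shape[0]
    pp = p * p
    M = np.empty((pp, pp))
    for a in range(p):
        for c in range(p):
            for d in range(p):
                for e in range(p):
                    val = -phi[a, d] * phi[c, e]
                    if a == d and c == e:
                        val += 1.0
                    M[p * a + c, p * d + e] = val
    vecs = sigma.copy().reshape(pp)
    v = np.linalg.solve(M, vecs)
    V = v.reshape((p, p))
    ok = True
    for a in range(p):
        if not np.isfinite(V[a, a]) or V[a, a] <= 0.0:
            ok = False
    if not ok:
        V = 10.0 * sigma
    return 0.5 * (V + V.T)


@njit(cache=True)
def _chol_sample(prec, h, noise):
    """Sample N(prec^-1 h, prec^-1) given std-normal ``noise``."""
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, h)
    dev = np.linalg.solve(L.T, noise)
    return mean + dev


@njit(cache=True)
def _ffbs_person(y, obs, T, phi, mu, sigma, v0, noise):
    """Impute missing cells of one person's series in place.

    State z_t = y_t - mu follows the VAR(1); observed components condition
    the filter exactly (no measurement noise).  ``noise`` is (T, p) standard
    normals, consumed per slot for the missing components.
    """
    p = phi.shape[0]
    m = np.zeros((T, p))
    Pf = np.zeros((T, p, p))
    obs_idx = np.empty(p, np.int64)
    mis_idx = np.empty(p, np.int64)

    # ---- forward filter
    for t in range(T):
        if t == 0:
            mpred = np.zeros(p)
            Ppred = v0.copy()
        else:
            mpred = phi @ m[t - 1]
            Ppred = phi @ Pf[t - 1] @ phi.T + sigma
        no = 0
        for j in range(p):
            if obs[t, j]:
                obs_idx[no] = j
                no += 1
        if no == 0:
            m[t] = mpred
            Pf[t] = Ppred
        elif no == p:
            for j in range(p):
                m[t, j] = y[t, j] - mu[j]
            # Pf stays zero
        else:
            Poo = np.empty((no, no))
            for a in range(no):
                for b in range(no):
                    Poo[a, b] = Ppred[obs_idx[a], obs_idx[b]]
                Poo[a, a] += JITTER
            innov = np.empty(no)
            for a in range(no):
                j = obs_idx[a]
                innov[a] = (y[t, j] - mu[j]) - mpred[j]
            Pio = np.empty((p, no))
            for r in range(p):
                for a in range(no):
                    Pio[r, a] = Ppred[r, obs_idx[a]]
            K = Pio @ np.linalg.inv(Poo)
            mnew = mpred + K @ innov
            Pnew = Ppred - K @ Pio.T
            Pnew = 0.5 * (Pnew + Pnew.T)
            # clamp observed rows/cols exactly
            for a in range(no):
                j = obs_idx[a]
                mnew[j] = y[t, j] - mu[j]
                for r in range(p):
                    Pnew[j, r] = 0.0
                    Pnew[r, j] = 0.0
            m[t] = mnew
            Pf[t] = Pnew

    # ---- backward sample
    z = np.empty((T, p))
    for t in range(T - 1, -1, -1):
        if t == T - 1:
            cmean = m[t].copy()
            ccov = Pf[t].copy()
        else:
            C = Pf[t] @ phi.T
            Spred = phi @ Pf[t] @ phi.T + sigma
            G = C @ np.linalg.inv(Spred)
            cmean = m[t] + G @ (z[t + 1] - phi @ m[t])
            ccov = Pf[t] - G @ C.T
            ccov = 0.5 * (ccov + ccov.T)
        nm = 0
        for j in range(p):
            if obs[t, j]:
                z[t, j] = y[t, j] - mu[j]
            else:
                mis_idx[nm] = j
                nm += 1
        if nm > 0:
            Cm = np.empty((nm, nm))
            for a in range(nm):
                for b in range(nm):
                    Cm[a, b] = ccov[mis_idx[a], mis_idx[b]]
                Cm[a, a] += JITTER
            L = np.linalg.cholesky(Cm)
            draw = L @ noise[t, :nm]
            for a in range(nm):
                j = mis_idx[a]
                z[t, j] = cmean[j] + draw[a]
                y[t, j] = mu[j] + z[t, j]
    return y


@njit(cache=True)
def _draw_phi(z, sigma_inv, tau_phi_inv, prior_phi, noise):
    """Conjugate draw of the person lag matrix (row-major vectorisation).

    z: (T, p) latent-centred series; prior is entrywise Normal with mean
    ``prior_phi`` and precision ``tau_phi_inv`` (length p*p, row-major).
    """
    T, p = z.shape
    pp = p * p
    X = z[: T - 1]
    Z = z[1:]
    Sxx = X.T @ X
    Szx = Z.T @ X
    H = sigma_inv @ Szx
    prec = np.empty((pp, pp))
    for a in range(p):
        for c in range(p):
            for d in range(p):
                for e in range(p):
                    prec[p * a + c, p * d + e] = sigma_inv[a, d] * Sxx[c, e]
    h = np.empty(pp)
    for a in range(p):
        for c in range(p):
            k = p * a + c
            prec[k, k] += tau_phi_inv[k]
            h[k] = H[a, c] + prior_phi[a, c] * tau_phi_inv[k]
    b = _chol_sample(prec, h, noise)
    return b.reshape((p, p)).copy()


@njit(cache=True)
def _draw_mu(y, T, phi, sigma_inv, tau_mu_inv, prior_mu, noise):
    """Conjugate draw of the person latent mean given phi and the data."""
    p = phi.shape[0]
    A = np.eye(p) - phi
    csum = np.zeros(p)
    for t in range(1, T):
        csum += y[t] - phi @ y[t - 1]
    As = A.T @ sigma_inv
    prec = (T - 1) * (As @ A)
    h = As @ csum
    for j in range(p):
        prec[j, j] += tau_mu_inv[j]
        h[j] += prior_mu[j] * tau_mu_inv[j]
    return _chol_sample(prec, h, noise)


@njit(cache=True)
def person_pass(Y, obs, lengths, has_missing, phi_all, mu_all, sigma,
                prior_mean, tau2, noise_z, noise_phi, noise_mu):
    """One Gibbs sweep over persons; updates Y, phi_all, mu_all in place.

    Returns the pooled innovation scatter matrix and transition count for
    the innovation-covariance update.
    """
    n, _, p = Y.shape
    pp = p * p
    sigma_inv = np.linalg.inv(sigma)
    tau_inv = 1.0 / tau2
    S = np.zeros((p, p))
    n_trans = 0
    for i in range(n):
        T = lengths[i]
        phi_i = phi_all[i]
        mu_i = mu_all[i]
        # 1. impute missing cells
        if has_missing[i]:
            v0 = _stationary_cov(phi_i, sigma)
            _ffbs_person(Y[i], obs[i], T, phi_i, mu_i, sigma, v0, noise_z[i])
        # 2. person lag matrix
        z = Y[i, :T] - mu_i
        prior_phi = prior_mean[i, :pp].reshape((p, p)).copy()
        phi_i = _draw_phi(z, sigma_inv, tau_inv[:pp], prior_phi, noise_phi[i])
        phi_all[i] = phi_i
        # 3. person mean
        mu_i = _draw_mu(Y[i, :T], T, phi_i, sigma_inv, tau_inv[pp:],
                        prior_mean[i, pp:], noise_mu[i])
        mu_all[i] = mu_i
        # 4. innovation residuals
        z = Y[i, :T] - mu_i
        for t in range(1, T):
            e = z[t] - phi_i @ z[t - 1]
            S += np.outer(e, e)
        n_trans += T - 1
    return S, n_trans
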