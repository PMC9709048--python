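"""Chain-vectorized MCMC machinery for the many-to-many mixed stock model.

The model (J rookeries, M mixed stocks, H haplotypes, optional UNK sink):

    f[j]   ~ Dirichlet(alpha_f)             rookery haplotype frequencies
    d[j]   ~ Dirichlet(alpha_d)             destinations over M stocks (+ UNK)
    theta[i, j] = W[i, j] * d[j, i] / sum_j' W[i, j'] * d[j', i]
    X[j]   ~ Multinomial(n_j, f[j])         rookery samples
    Y[i]   ~ Multinomial(n_i, q[i]),        q[i] = sum_j theta[i, j] * f[j]

where W[i, j] is S[j] (base mode) or S[j] * P[i, j] (distance-weighted mode).
Each mixed-stock individual is augmented with its latent source rookery,
which makes the f-update conjugate (Gibbs) and reduces the d-update to a
low-dimensional Metropolis step per rookery on additive-log-ratio
coordinates.  All chains advance together through vectorized array ops.

The distance-prior variant drops d entirely and puts Dirichlet(kappa * P[i])
priors directly on each theta[i]; there every update is conjugate.
"""

from __future__ import annotations

import numpy as np

# Additive-log-ratio coordinates are restricted to this box; the posterior
# places negligible mass outside it and the bound keeps softmax/log exact.
_LOGIT_BOUND = 30.0
_TARGET_ACCEPT = 0.35


def multinomial_rows(rng: np.random.Generator, n, p) -> np.ndarray:
    """Vectorized multinomial sampling via conditional binomials.

    ``n`` broadcasts against ``p[..., 0]``; ``p`` rows must sum to 1.
    """
    p = np.asarray(p, dtype=float)
    out = np.zeros(p.shape, dtype=np.int64)
    rem_n = np.broadcast_to(np.asarray(n, dtype=np.int64), p.shape[:-1]).copy()
    rem_p = np.ones(p.shape[:-1])
    for j in range(p.shape[-1] - 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            pj = np.where(rem_p > 1e-300, p[..., j] / rem_p, 0.0)
        np.clip(pj, 0.0, 1.0, out=pj)
        draw = rng.binomial(rem_n, pj)
        out[..., j] = draw
        rem_n -= draw
        rem_p = np.maximum(rem_p - p[..., j], 0.0)
    out[..., -1] = rem_n
    return out


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draws along the last axis of ``alpha`` (element-wise gamma)."""
    g = rng.standard_gamma(alpha)
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=-1, keepdims=True)


def _softmax_with_ref(u: np.ndarray) -> np.ndarray:
    """Map free coordinates u (..., K-1) to a K-simplex (last entry is the reference)."""
    full = np.concatenate([u, np.zeros(u.shape[:-1] + (1,))], axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def _alr(d: np.ndarray) -> np.ndarray:
    """Additive log-ratio transform relative to the last component."""
    return np.log(d[..., :-1]) - np.log(d[..., -1:])


def _theta_from_delta(delta: np.ndarray, W: np.ndarray) -> np.ndarray:
    """theta[c, i, j] from destinations delta[c, j, m] and weights W[i, j]."""
    M = W.shape[0]
    num = W[None, :, :] * np.swapaxes(delta[:, :, :M], 1, 2)
    return num / num.sum(axis=2, keepdims=True)


def run_many_to_many(
    X: np.ndarray,
    Y: np.ndarray,
    weights: np.ndarray,
    alpha_f: np.ndarray,
    alpha_d: np.ndarray,
    *,
    n_chains: int,
    n_iter: int,
    n_burnin: int,
    thin: int = 1,
    seed: int = 0,
) -> dict:
    """Run the augmented Gibbs/Metropolis sampler for base or distance-weighted mode.

    ``weights`` is the (M, J) matrix W[i, j]; ``alpha_d`` has length M (+1 when
    an UNK destination is modelled).  Returns post-burn-in draws of f, delta
    and theta plus per-rookery acceptance rates.
    """
    J, H = X.shape
    M = Y.shape[0]
    Mp = alpha_d.shape[0]
    C = n_chains
    n_free = Mp - 1

    # Random starting points from the priors, one seeded stream per chain.
    f = np.empty((C, J, H))
    delta = np.empty((C, J, Mp))
    for c in range(C):
        rng_c = np.random.default_rng(seed + c)
        f[c] = _dirichlet(rng_c, np.broadcast_to(alpha_f, (J, H)).astype(float))
        delta[c] = _dirichlet(rng_c, np.broadcast_to(alpha_d, (J, Mp)).astype(float))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A]))

    # Active mixed-stock cells (site, haplotype) with observed individuals.
    ii, hh = np.nonzero(Y)
    K = ii.size
    y_k = Y[ii, hh].astype(np.int64)
    onehot_h = np.zeros((K, H))
    onehot_h[np.arange(K), hh] = 1.0
    onehot_i = np.zeros((K, M))
    onehot_i[np.arange(K), ii] = 1.0

    step = np.full((C, J), 0.5)
    accept_count = np.zeros((C, J))

    T = (n_iter - n_burnin + thin - 1) // thin
    f_draws = np.empty((C, T, J, H))
    d_draws = np.empty((C, T, J, Mp))
    t_draws = np.empty((C, T, M, J))
    kept = 0

    alpha_fJ = np.broadcast_to(alpha_f, (J, H)).astype(float)

    u = _alr(np.clip(delta, 1e-12, None))
    np.clip(u, -_LOGIT_BOUND, _LOGIT_BOUND, out=u)
    delta = _softmax_with_ref(u)

    for t in range(n_iter):
        theta = _theta_from_delta(delta, weights)

        # --- latent source assignments Z for every observed mixed-stock cell
        if K:
            w = theta[:, ii, :] * np.swapaxes(f, 1, 2)[:, hh, :]  # (C, K, J)
            w = w / w.sum(axis=2, keepdims=True)
            Z = multinomial_rows(rng, y_k[None, :], w)
            A = np.einsum("ckj,kh->cjh", Z, onehot_h)
            N = np.einsum("ckj,km->cmj", Z, onehot_i)
        else:
            A = np.zeros((C, J, H))
            N = np.zeros((C, M, J))

        # --- conjugate update of rookery haplotype frequencies
        f = _dirichlet(rng, alpha_fJ[None] + X[None] + A)

        # --- Metropolis update of each rookery's destination simplex
        if n_free > 0:
            log_theta = np.log(theta)
            ll_cur = np.einsum("cmj,cmj->c", N, log_theta)
            for j in range(J):
                u_j = u[:, j, :]
                prop = u_j + step[:, j, None] * rng.standard_normal((C, n_free))
                in_box = np.all(np.abs(prop) <= _LOGIT_BOUND, axis=1)
                delta_prop_j = _softmax_with_ref(prop)
                delta_prop = delta.copy()
                delta_prop[:, j, :] = delta_prop_j
                theta_prop = _theta_from_delta(delta_prop, weights)
                ll_prop = np.einsum("cmj,cmj->c", N, np.log(theta_prop))
                prior_cur = np.einsum("m,cm->c", alpha_d, np.log(delta[:, j, :]))
                prior_prop = np.einsum("m,cm->c", alpha_d, np.log(delta_prop_j))
                log_ratio = (ll_prop + prior_prop) - (ll_cur + prior_cur)
                acc = in_box & (np.log(rng.uniform(size=C)) < log_ratio)
                u[acc, j, :] = prop[acc]
                delta[acc, j, :] = delta_prop_j[acc]
                theta = np.where(acc[:, None, None], theta_prop, theta)
                ll_cur = np.where(acc, ll_prop, ll_cur)
                accept_count[:, j] += acc
                if t < n_burnin:
                    step[:, j] *= np.exp(0.05 * (acc.astype(float) - _TARGET_ACCEPT))

        if t >= n_burnin and (t - n_burnin) % thin == 0:
            f_draws[:, kept] = f
            d_draws[:, kept] = delta
            t_draws[:, kept] = _theta_from_delta(delta, weights)
            kept += 1

    return {
        "f": f_draws[:, :kept],
        "delta": d_draws[:, :kept],
        "theta": t_draws[:, :kept],
        "accept_rate": accept_count / max(n_iter, 1),
    }


def run_distance_prior(
    X: np.ndarray,
    Y: np.ndarray,
    P: np.ndarray,
    kappa: float,
    alpha_f: np.ndarray,
    *,
    n_chains: int,
    n_iter: int,
    n_burnin: int,
    thin: int = 1,
    seed: int = 0,
) -> dict:
    """Fully conjugate Gibbs sampler for the distances-as-priors variant.

    Mixed-stock-centric contributions theta[i] get Dirichlet(kappa * P[i])
    priors directly; there is no destination parameter and no UNK sink.
    """
    J, H = X.shape
    M = Y.shape[0]
    C = n_chains

    alpha_theta = kappa * P  # (M, J)
    f = np.empty((C, J, H))
    theta = np.empty((C, M, J))
    for c in range(C):
        rng_c = np.random.default_rng(seed + c)
        f[c] = _dirichlet(rng_c, np.broadcast_to(alpha_f, (J, H)).astype(float))
        theta[c] = _dirichlet(rng_c, alpha_theta)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B]))

    ii, hh = np.nonzero(Y)
    K = ii.size
    y_k = Y[ii, hh].astype(np.int64)
    onehot_h = np.zeros((K, H))
    onehot_h[np.arange(K), hh] = 1.0
    onehot_i = np.zeros((K, M))
    onehot_i[np.arange(K), ii] = 1.0

    alpha_fJ = np.broadcast_to(alpha_f, (J, H)).astype(float)
    T = (n_iter - n_burnin + thin - 1) // thin
    f_draws = np.empty((C, T, J, H))
    t_draws = np.empty((C, T, M, J))
    kept = 0

    for t in range(n_iter):
        if K:
            w = theta[:, ii, :] * np.swapaxes(f, 1, 2)[:, hh, :]
            w = w / w.sum(axis=2, keepdims=True)
            Z = multinomial_rows(rng, y_k[None, :], w)
            A = np.einsum("ckj,kh->cjh", Z, onehot_h)
            N = np.einsum("ckj,km->cmj", Z, onehot_i)
        else:
            A = np.zeros((C, J, H))
            N = np.zeros((C, M, J))
        f = _dirichlet(rng, alpha_fJ[None] + X[None] + A)
        theta = _dirichlet(rng, alpha_theta[None] + N)
        if t >= n_burnin and (t - n_burnin) % thin == 0:
            f_draws[:, kept] = f
            t_draws[:, kept] = theta
            kept += 1

    return {"f": f_draws[:, :kept], "delta": None, "theta": t_draws[:, :kept], "accept_rate": None}
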