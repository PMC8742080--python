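"""Gibbs-sampling building blocks for the censored latent-Gaussian model.

The latent matrix W (n×S) follows row-wise MVN(B'x_i, Σ) restricted by the
observation rule: for continuous abundance (CA, tobit) an observed y > 0
pins the latent value exactly (w = y) while y = 0 constrains w ≤ 0; for
presence/absence (PA, probit) w > 0 iff y = 1.  The three conditional
updates below (latent states, coefficients, residual covariance) are
conjugate and exact.

All truncated-normal draws use the inverse-CDF method with a tail-safe
fallback, so chains are reproducible from a seed and never produce NaN in
extreme tails.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

__all__ = [
    "mvn_deviance",
    "censor_to_observed",
    "sample_latent",
    "gibbs_update_latent",
    "sample_coefficients",
    "sample_covariance",
    "truncated_normal_below",
    "truncated_normal_above",
    "SamplerError",
]

_TINY = 1e-300


class SamplerError(RuntimeError):
    """Raised when a Gibbs update cannot be performed (non-PD covariance,
    rank-deficient design, divergent state)."""


def mvn_deviance(W, M, sigma_cho, logdet):
    """-2 log p(W | M, Σ) for row-wise MVN, via a Cholesky solve.

    ``sigma_cho`` is the (c, lower) pair from ``cho_factor`` and
    ``logdet`` the log-determinant of Σ.
    """
    n, S = W.shape
    R = W - M
    quad = float(np.sum(R * cho_solve(sigma_cho, R.T).T))
    return n * (S * np.log(2.0 * np.pi) + logdet) + quad


def censor_to_observed(w: np.ndarray, kind: str) -> np.ndarray:
    """Map latent values to the observation scale.

    CA: y = w where w > 0 else 0 (tobit censoring).
    PA: y = 1 where w > 0 else 0 (probit threshold).
    """
    w = np.asarray(w, dtype=float)
    if kind == "CA":
        return np.where(w > 0.0, w, 0.0)
    if kind == "PA":
        return (w > 0.0).astype(float)
    raise ValueError(f"unknown response kind {kind!r}")


def truncated_normal_below(mean, sd, bound, rng) -> np.ndarray:
    """Vectorized draw from N(mean, sd²) truncated to (-inf, bound]."""
    mean = np.asarray(mean, dtype=float)
    a = (bound - mean) / sd
    u = rng.random(mean.shape)
    p = ndtr(a)
    z = ndtri(np.clip(u * p, _TINY, 1.0 - 1e-16))
    # extreme lower tail: inverse-CDF of the asymptotic tail law
    bad = p <= _TINY
    if np.any(bad):
        m = -a[bad]
        z[bad] = -np.sqrt(m * m - 2.0 * np.log1p(-u[bad]))
    return mean + sd * np.minimum(z, a)


def truncated_normal_above(mean, sd, bound, rng) -> np.ndarray:
    """Vectorized draw from N(mean, sd²) truncated to [bound, inf)."""
    return -truncated_normal_below(-np.asarray(mean, dtype=float), sd, -bound, rng)


def _conditional_coefs(sigma: np.ndarray):
    """Per-species regression of one latent column on the others.

    Returns (coefs, cond_sd): coefs[s] is the length-(S-1) vector c with
    E[w_s | w_-s] = mu_s + c'(w_-s - mu_-s); cond_sd[s] the residual sd.
    """
    S = sigma.shape[0]
    if S == 1:
        if sigma[0, 0] <= 0:
            raise SamplerError("residual covariance is not positive definite")
        return np.empty((1, 0)), np.sqrt(np.array([sigma[0, 0]]))
    coefs = np.empty((S, S - 1))
    cond_var = np.empty(S)
    idx = np.arange(S)
    for s in range(S):
        keep = idx != s
        sub = sigma[np.ix_(keep, keep)]
        cross = sigma[keep, s]
        try:
            c = cho_solve(cho_factor(sub, lower=True), cross)
        except np.linalg.LinAlgError as e:  # pragma: no cover - guarded upstream
            raise SamplerError("residual covariance is not positive definite") from e
        coefs[s] = c
        cond_var[s] = sigma[s, s] - cross @ c
    if np.any(cond_var <= 0):
        raise SamplerError("residual covariance is not positive definite")
    return coefs, np.sqrt(cond_var)


def gibbs_update_latent(w, y, mu, sigma, kind, rng, coefs=None, cond_sd=None):
    """One full Gibbs sweep over species columns of the latent matrix.

    Operates in place on ``w``.  For each species in fixed order the
    censored entries are redrawn from the univariate conditional (given
    all other current latent values in the row) truncated to the region
    consistent with the observation.  CA entries with y > 0 are never
    touched — they are fixed at y.
    """
    n, S = w.shape
    if coefs is None:
        coefs, cond_sd = _conditional_coefs(sigma)
    idx = np.arange(S)
    for s in range(S):
        keep = idx != s
        cmean = mu[:, s] + (w[:, keep] - mu[:, keep]) @ coefs[s]
        if kind == "CA":
            mask = y[:, s] <= 0.0
            if np.any(mask):
                w[mask, s] = truncated_normal_below(cmean[mask], cond_sd[s], 0.0, rng)
        else:  # PA: every entry is latent
            pos = y[:, s] > 0.0
            neg = ~pos
            if np.any(pos):
                w[pos, s] = truncated_normal_above(cmean[pos], cond_sd[s], 0.0, rng)
            if np.any(neg):
                w[neg, s] = truncated_normal_below(cmean[neg], cond_sd[s], 0.0, rng)
    return w


def initialize_latent(y: np.ndarray, kind: str) -> np.ndarray:
    """Feasible starting state: y for positive CA entries, -0.5 in the
    censored region; ±0.5 by label for PA."""
    if kind == "CA":
        return np.where(y > 0.0, y, -0.5)
    return np.where(y > 0.0, 0.5, -0.5)


def sample_latent(y, X, B, sigma, rng, kind="CA", w0=None, sweeps=1):
    """Draw a latent matrix consistent with observations y.

    Convenience wrapper around :func:`gibbs_update_latent`; ``sweeps``
    full scans are applied starting from ``w0`` (default: the feasible
    initialization).  With ``sweeps=1`` and a current Gibbs state as
    ``w0`` this is exactly the sampler's latent step.
    """
    sigma = np.asarray(sigma, dtype=float)
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as e:
        raise SamplerError("sigma is not positive definite") from e
    y = np.asarray(y, dtype=float)
    mu = np.asarray(X, dtype=float) @ B
    w = initialize_latent(y, kind) if w0 is None else np.array(w0, dtype=float)
    coefs, cond_sd = _conditional_coefs(sigma)
    for _ in range(sweeps):
        gibbs_update_latent(w, y, mu, sigma, kind, rng, coefs, cond_sd)
    return w


def sample_coefficients(W, X, sigma, rng, xtx_cho=None, xtw=None):
    """One draw of B from its matrix-normal full conditional (flat prior).

    Mean (X'X)⁻¹X'W, row covariance (X'X)⁻¹, column covariance Σ.
    """
    X = np.asarray(X, dtype=float)
    if xtx_cho is None:
        xtx = X.T @ X
        try:
            xtx_cho = cho_factor(xtx, lower=True)
        except np.linalg.LinAlgError:
            _raise_rank_deficient(X)
    if xtw is None:
        xtw = X.T @ W
    bhat = cho_solve(xtx_cho, xtw)
    Q, S = bhat.shape
    # row-covariance factor: (X'X)^{-1} = L^{-T} L^{-1} with L = chol(X'X)
    L = np.tril(xtx_cho[0])
    A = solve_triangular(L, np.eye(Q), lower=True).T  # A A' = (X'X)^{-1}
    C = cholesky(sigma, lower=True)
    Z = rng.standard_normal((Q, S))
    return bhat + A @ Z @ C.T


def _raise_rank_deficient(X):
    # name (near-)collinear columns via the diagonal of R in a QR factorization
    _, R = np.linalg.qr(X)
    d = np.abs(np.diag(R))
    bad = np.where(d < 1e-8 * max(d.max(), 1.0))[0].tolist()
    raise SamplerError(f"design matrix is rank deficient; collinear column indices: {bad}")


def sample_covariance(W, X, B, rng, nu0=None, psi0=None):
    """One inverse-Wishart draw of Σ from its full conditional.

    Prior IW(ν₀, Ψ₀), default ν₀ = S + 2, Ψ₀ = I.  Posterior shape
    ν₀ + n, scale Ψ₀ + (W − XB)'(W − XB).
    """
    W = np.asarray(W, dtype=float)
    n, S = W.shape
    if nu0 is None:
        nu0 = S + 2
    if psi0 is None:
        psi0 = np.eye(S)
    if n + nu0 <= S + 1:
        raise SamplerError(
            f"too few observations (n={n}) for a proper IW posterior with S={S}"
        )
    resid = W - np.asarray(X, dtype=float) @ B
    scale = psi0 + resid.T @ resid
    scale = 0.5 * (scale + scale.T)
    draw = invwishart.rvs(df=nu0 + n, scale=scale, random_state=rng)
    return np.atleast_2d(draw)
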