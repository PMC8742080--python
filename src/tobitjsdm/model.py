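"""The joint species distribution model and its Gibbs-sampling ``fit``.

``JointSpeciesModel`` pairs an n×S response matrix (CPUE with exact zeros,
or presence/absence) with an n×Q design matrix.  Species share a single
residual covariance Σ, so the model is a multivariate tobit (CA) or
multivariate probit (PA) on a latent Gaussian matrix W:

    w_i | x_i ~ MVN(B' x_i, Σ),   y_is = w_is · 1[w_is > 0]   (CA)
                                  y_is = 1[w_is > 0]          (PA)

``fit`` runs the three-block Gibbs sampler (latent states, coefficients,
residual covariance) and returns a :class:`~tobitjsdm.results.GibbsResults`
carrying the post-burn-in draws, derived quantities (residual correlation
R, community sensitivity f, environmental covariance E) and prediction
methods.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .formula import DesignMatrix, ModelSpec, build_design
from .results import GibbsResults
from .sampler import (
    SamplerError,
    _conditional_coefs,
    _raise_rank_deficient,
    gibbs_update_latent,
    initialize_latent,
    mvn_deviance,
    sample_coefficients,
    sample_covariance,
)

__all__ = ["JointSpeciesModel"]

logger = logging.getLogger("tobitjsdm")


class JointSpeciesModel:
    """Multivariate tobit/probit model for a species community.

    Parameters
    ----------
    y : (n, S) array
        Response matrix.  CA: nonnegative CPUE (kg/tow) with exact
        zeros.  PA: 0/1 presence flags.
    design : DesignMatrix
        Expanded covariates (see :func:`tobitjsdm.formula.build_design`).
    species : sequence of str, optional
        Species names (defaults to s0..s{S-1}).

    Raises
    ------
    ValueError
        On invariant violations, including a species column that is zero
        in every tow — such species carry no information for B or Σ and
        should be removed beforehand with
        :func:`tobitjsdm.io.filter_species`.
    """

    def __init__(self, y, design: DesignMatrix, species=None):
        y = np.asarray(y, dtype=float)
        if y.ndim != 2:
            raise ValueError("y must be a 2-D (tows × species) matrix")
        if y.shape[0] != design.n:
            raise ValueError(
                f"response has {y.shape[0]} rows but design has {design.n}"
            )
        kind = design.spec.response_kind
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if kind == "CA" and np.any(y < 0):
            raise ValueError("CA response must be nonnegative (CPUE kg/tow)")
        if kind == "PA" and not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("PA response must be binary 0/1")
        dead = np.where(~np.any(y > 0, axis=0))[0]
        if dead.size:
            raise ValueError(
                f"species column(s) {dead.tolist()} are all-zero; "
                "apply tobitjsdm.io.filter_species before fitting"
            )
        self.y = y
        self.design = design
        self.kind = kind
        self.species = (
            list(species) if species is not None else [f"s{i}" for i in range(y.shape[1])]
        )
        if len(self.species) != y.shape[1]:
            raise ValueError("species names do not match response columns")

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, spec: ModelSpec, species) -> "JointSpeciesModel":
        """Build model from a survey table: covariates expanded per
        ``spec``, responses taken from the named species columns."""
        missing = [s for s in species if s not in table.columns]
        if missing:
            raise ValueError(f"species column(s) missing from table: {missing}")
        design = build_design(table, spec)
        y = table[list(species)].to_numpy(dtype=float)
        if spec.response_kind == "PA":
            y = (y > 0).astype(float)
        return cls(y, design, species=species)

    @property
    def n(self):
        return self.y.shape[0]

    @property
    def n_species(self):
        return self.y.shape[1]

    # ------------------------------------------------------------------
    def fit(
        self,
        n_iter: int = 20_000,
        burnin: int = 8_000,
        seed: int = 0,
        nu0: int | None = None,
        psi0: np.ndarray | None = None,
        thin: int = 1,
        n_latent_snapshots: int = 3,
        log_every: int = 500,
    ) -> GibbsResults:
        """Run the Gibbs sampler.

        Defaults mirror a full production run (20,000 iterations with
        8,000 burn-in); shorter chains are appropriate for model
        screening.  The sampler cycles latent states → coefficients →
        residual covariance.  For PA responses each *stored* draw is
        rescaled to a correlation matrix, with B rescaled compatibly
        (parameter expansion); the raw unidentified draws drive the
        chain.

        Returns
        -------
        GibbsResults
        """
        if not (n_iter > burnin >= 0):
            raise ValueError("need n_iter > burnin >= 0")
        X = self.design.values
        n, S = self.y.shape
        Q = X.shape[1]
        if nu0 is None:
            nu0 = S + 2
        if psi0 is None:
            psi0 = np.eye(S)
        rng = np.random.default_rng(np.random.SeedSequence(seed))

        xtx = X.T @ X
        try:
            xtx_cho = cho_factor(xtx, lower=True)
        except np.linalg.LinAlgError:
            _raise_rank_deficient(X)

        w = initialize_latent(self.y, self.kind)
        B = cho_solve(xtx_cho, X.T @ w)
        sigma = np.eye(S)

        m_keep = len(range(burnin, n_iter)[::thin])
        B_draws = np.empty((m_keep, Q, S))
        sigma_draws = np.empty((m_keep, S, S))
        deviance = np.empty(m_keep)
        W_sum = np.zeros((n, S))
        B_sum = np.zeros((Q, S))
        sigma_sum = np.zeros((S, S))
        snap_at = set(
            np.linspace(0, m_keep - 1, num=min(n_latent_snapshots, m_keep), dtype=int).tolist()
        ) if m_keep else set()
        snapshots = []

        k = 0
        for t in range(n_iter):
            mu = X @ B
            coefs, cond_sd = _conditional_coefs(sigma)
            gibbs_update_latent(w, self.y, mu, sigma, self.kind, rng, coefs, cond_sd)
            B = sample_coefficients(w, X, sigma, rng, xtx_cho=xtx_cho, xtw=X.T @ w)
            sigma = sample_covariance(w, X, B, rng, nu0=nu0, psi0=psi0)
            if not (np.all(np.isfinite(B)) and np.all(np.isfinite(sigma)) and np.all(np.isfinite(w))):
                raise SamplerError(f"divergent chain state at iteration {t}")
            if log_every and (t + 1) % log_every == 0:
                cho = cho_factor(sigma, lower=True)
                logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
                ll = -0.5 * mvn_deviance(w, X @ B, cho, logdet)
                logger.info("iteration %d/%d  complete-data loglik %.2f", t + 1, n_iter, ll)
            if t >= burnin and (t - burnin) % thin == 0:
                cho = cho_factor(sigma, lower=True)
                logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
                deviance[k] = mvn_deviance(w, X @ B, cho, logdet)
                W_sum += w
                B_sum += B
                sigma_sum += sigma
                if self.kind == "PA":
                    d = np.sqrt(np.diag(sigma))
                    sigma_draws[k] = sigma / np.outer(d, d)
                    B_draws[k] = B / d[np.newaxis, :]
                else:
                    sigma_draws[k] = sigma
                    B_draws[k] = B
                if k in snap_at:
                    snapshots.append((t, w.copy()))
                k += 1

        return GibbsResults(
            model=self,
            B_draws=B_draws,
            sigma_draws=sigma_draws,
            burnin=burnin,
            n_iter=n_iter,
            thin=thin,
            seed=seed,
            deviance_draws=deviance,
            W_mean=W_sum / max(m_keep, 1),
            B_mean_raw=B_sum / max(m_keep, 1),
            sigma_mean_raw=sigma_sum / max(m_keep, 1),
            latent_snapshots=snapshots,
            W_last=w.copy(),
        )
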