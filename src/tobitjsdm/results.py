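"""Posterior results: summaries, derived matrices and prediction.

Derived quantities
------------------
R : residual correlation, R_ss' = Σ_ss'/√(Σ_ss Σ_s's') — species
    co-dependence left over after the environmental mean structure.
f : community sensitivity, f = diag(B Σ⁻¹ B'), one nonnegative value per
    design column measuring how much the whole community responds to
    that predictor.
E : environmental covariance, E = B'VB with V the predictor covariance —
    species similarity induced by shared environmental responses.

Prediction draws w̃ ~ MVN(B'x̃, Σ) per retained posterior draw, censored
to the observation scale; conditional prediction partitions the MVN over
species so that observed abundances of some species inform others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import ndtr

from .formula import ModelSpec
from .sampler import censor_to_observed, mvn_deviance, truncated_normal_above, truncated_normal_below

__all__ = [
    "GibbsResults",
    "Predictions",
    "correlation_matrix",
    "predictor_covariance",
    "sensitivity",
    "environmental_covariance",
    "mvn_conditional",
]


def correlation_matrix(sigma: np.ndarray) -> np.ndarray:
    """Correlation matrix associated with a PD covariance."""
    sigma = np.asarray(sigma, dtype=float)
    d = np.diag(sigma)
    if np.any(d <= 0):
        raise ValueError("covariance has a nonpositive diagonal entry")
    s = np.sqrt(d)
    return sigma / np.outer(s, s)


def predictor_covariance(X, intercept_col: int = 0) -> np.ndarray:
    """Sample covariance V of the design columns with the intercept
    row/column zeroed (an intercept does not vary)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows for a sample covariance")
    V = np.cov(X, rowvar=False, ddof=1)
    V = np.atleast_2d(V)
    V[intercept_col, :] = 0.0
    V[:, intercept_col] = 0.0
    return V


def sensitivity(B: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Community sensitivity f = diag(B Σ⁻¹ B'); length Q, entries ≥ 0."""
    B = np.asarray(B, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if B.shape[1] != sigma.shape[0]:
        raise ValueError(
            f"B has {B.shape[1]} species columns but sigma is {sigma.shape[0]}×{sigma.shape[1]}"
        )
    cho = cho_factor(sigma, lower=True)
    return np.einsum("qs,qs->q", B, cho_solve(cho, B.T).T)


def environmental_covariance(B: np.ndarray, V: np.ndarray) -> np.ndarray:
    """E = B'VB: S×S species similarity from shared environmental response."""
    B = np.asarray(B, dtype=float)
    V = np.asarray(V, dtype=float)
    if B.shape[0] != V.shape[0]:
        raise ValueError(f"B has {B.shape[0]} rows but V is {V.shape[0]}×{V.shape[1]}")
    E = B.T @ V @ B
    return 0.5 * (E + E.T)


def mvn_conditional(mu, sigma, cond_idx, target_idx, w_cond):
    """Mean and covariance of targets given conditioned coordinates.

    mean = μ_T + Σ_TC Σ_CC⁻¹ (w_C − μ_C);  cov = Σ_TT − Σ_TC Σ_CC⁻¹ Σ_CT.
    ``w_cond`` may be a vector or an (n, |C|) matrix (means returned
    rowwise).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    cond_idx = list(cond_idx)
    target_idx = list(target_idx)
    if not cond_idx:
        mu_t = mu[..., target_idx]
        return mu_t, sigma[np.ix_(target_idx, target_idx)]
    s_cc = sigma[np.ix_(cond_idx, cond_idx)]
    s_tc = sigma[np.ix_(target_idx, cond_idx)]
    s_tt = sigma[np.ix_(target_idx, target_idx)]
    cho = cho_factor(s_cc, lower=True)
    gain = cho_solve(cho, s_tc.T).T  # Σ_TC Σ_CC⁻¹
    dev = np.asarray(w_cond, dtype=float) - mu[..., cond_idx]
    mean = mu[..., target_idx] + dev @ gain.T
    cov = s_tt - gain @ s_tc.T
    return mean, 0.5 * (cov + cov.T)


@dataclass
class Predictions:
    """Posterior-predictive summary on the observation scale."""

    species: list
    mean: np.ndarray          # (n, S_t)
    intervals: dict           # level -> (lo, hi) arrays (n, S_t)
    n_draws: int

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.mean, columns=self.species)
        for level, (lo, hi) in sorted(self.intervals.items()):
            pct = int(round(level * 100))
            for j, sp in enumerate(self.species):
                out[f"{sp}_lo{pct}"] = lo[:, j]
                out[f"{sp}_hi{pct}"] = hi[:, j]
        return out


@dataclass
class GibbsResults:
    """Post-burn-in Gibbs draws and everything derived from them."""

    B_draws: np.ndarray          # (M, Q, S), PA draws already identified
    sigma_draws: np.ndarray      # (M, S, S)
    burnin: int
    n_iter: int
    thin: int
    seed: int
    deviance_draws: np.ndarray   # complete-data deviance per retained draw
    W_mean: np.ndarray | None = None
    B_mean_raw: np.ndarray | None = None
    sigma_mean_raw: np.ndarray | None = None
    latent_snapshots: list = field(default_factory=list)
    W_last: np.ndarray | None = None
    model: object | None = None
    species: list | None = None
    column_names: list | None = None
    spec: ModelSpec | None = None
    standardization_params: dict | None = None

    def __post_init__(self):
        if self.model is not None:
            self.species = list(self.model.species)
            self.column_names = list(self.model.design.column_names)
            self.spec = self.model.design.spec
            self.standardization_params = dict(self.model.design.standardization_params)

    # basic posterior summaries ---------------------------------------
    @property
    def n_draws(self) -> int:
        return self.B_draws.shape[0]

    @property
    def kind(self) -> str:
        return self.spec.response_kind

    @property
    def B_mean(self) -> np.ndarray:
        return self.B_draws.mean(axis=0)

    @property
    def sigma_mean(self) -> np.ndarray:
        return self.sigma_draws.mean(axis=0)

    @property
    def R_draws(self) -> np.ndarray:
        d = np.sqrt(np.einsum("mss->ms", self.sigma_draws))
        return self.sigma_draws / (d[:, :, None] * d[:, None, :])

    @property
    def R_mean(self) -> np.ndarray:
        return self.R_draws.mean(axis=0)

    def credible_intervals(self, level: float = 0.95):
        """(lo, hi) arrays of shape (Q, S) for the central interval."""
        alpha = (1.0 - level) / 2.0
        lo = np.quantile(self.B_draws, alpha, axis=0)
        hi = np.quantile(self.B_draws, 1.0 - alpha, axis=0)
        return lo, hi

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Term × species coefficient table with posterior mean, sd,
        central interval and a does-not-cross-zero significance flag."""
        lo, hi = self.credible_intervals(level)
        mean = self.B_mean
        sd = self.B_draws.std(axis=0, ddof=1)
        rows = []
        for qi, term in enumerate(self.column_names):
            for sj, sp in enumerate(self.species):
                rows.append(
                    {
                        "term": term,
                        "species": sp,
                        "mean": mean[qi, sj],
                        "sd": sd[qi, sj],
                        "lo": lo[qi, sj],
                        "hi": hi[qi, sj],
                        "significant": bool(lo[qi, sj] > 0 or hi[qi, sj] < 0),
                    }
                )
        return pd.DataFrame(rows)

    def ess(self) -> pd.DataFrame:
        """Effective sample size per coefficient (bulk ESS)."""
        import arviz as az

        Q, S = self.B_draws.shape[1:]
        out = np.empty((Q, S))
        for q in range(Q):
            for s in range(S):
                out[q, s] = float(az.ess(self.B_draws[None, :, q, s]))
        return pd.DataFrame(out, index=self.column_names, columns=self.species)

    # derived matrices -------------------------------------------------
    def sensitivity_draws(self) -> np.ndarray:
        """(M, Q) posterior draws of f = diag(B Σ⁻¹ B')."""
        out = np.empty((self.n_draws, self.B_draws.shape[1]))
        for m in range(self.n_draws):
            out[m] = sensitivity(self.B_draws[m], self.sigma_draws[m])
        return out

    def sensitivity_summary(self) -> pd.DataFrame:
        f = self.sensitivity_draws()
        return pd.DataFrame(
            {
                "term": self.column_names,
                "median": np.median(f, axis=0),
                "lo90": np.quantile(f, 0.05, axis=0),
                "hi90": np.quantile(f, 0.95, axis=0),
            }
        )

    def environmental_covariance(self, V: np.ndarray | None = None) -> np.ndarray:
        """Posterior-mean E = B'VB; V defaults to the training-design
        predictor covariance."""
        if V is None:
            V = predictor_covariance(self.model.design.values)
        acc = np.zeros((len(self.species), len(self.species)))
        for m in range(self.n_draws):
            acc += environmental_covariance(self.B_draws[m], V)
        return acc / self.n_draws

    # model comparison -------------------------------------------------
    def dic(self) -> dict:
        """Complete-data (conditional) DIC: D̄ + p_D, with p_D = D̄ − D(θ̄)
        and D(θ̄) the deviance at the posterior means of (W, B, Σ)."""
        if self.n_draws < 50:
            raise ValueError(
                f"DIC requires at least 50 retained draws, have {self.n_draws}"
            )
        dbar = float(np.mean(self.deviance_draws))
        cho = cho_factor(self.sigma_mean_raw, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        dhat = mvn_deviance(
            self.W_mean, self.model.design.values @ self.B_mean_raw, cho, logdet
        )
        pd_eff = dbar - dhat
        return {"dic": dbar + pd_eff, "dbar": dbar, "pd": pd_eff}

    # prediction -------------------------------------------------------
    def predictive_mean(self, X_new=None, n_draws: int | None = None) -> np.ndarray:
        """Exact posterior-predictive mean on the observation scale.

        Uses the closed form of the censored-normal mean per draw —
        CA: E[y] = μΦ(μ/σ) + σφ(μ/σ); PA: P(y=1) = Φ(μ/σ) — averaged
        over retained draws, so no Monte-Carlo noise enters the point
        prediction.  Interval summaries still come from
        :meth:`predict`.
        """
        from scipy.stats import norm

        X = self._resolve_design(X_new)
        idx = self._draw_indices(n_draws)
        acc = np.zeros((X.shape[0], len(self.species)))
        for m in idx:
            mu = X @ self.B_draws[m]
            s = np.sqrt(np.diag(self.sigma_draws[m]))
            z = mu / s
            if self.kind == "CA":
                acc += mu * ndtr(z) + s * norm.pdf(z)
            else:
                acc += ndtr(z)
        return acc / len(idx)

    def _draw_indices(self, n_draws):
        m = self.n_draws
        if n_draws is None or n_draws >= m:
            return np.arange(m)
        return np.unique(np.linspace(0, m - 1, num=n_draws, dtype=int))

    def predict(
        self,
        X_new=None,
        seed: int = 0,
        n_draws: int | None = 200,
        levels=(0.90, 0.95),
    ) -> Predictions:
        """Posterior-predictive mean and central intervals per species.

        ``X_new`` is a DesignMatrix built with the *training*
        standardization parameters (or a raw array on the training
        scale); defaults to the training design (in-sample prediction).
        """
        return self.conditional_predict(
            X_new, conditioned={}, targets=list(self.species), seed=seed,
            n_draws=n_draws, levels=levels,
        )

    def conditional_predict(
        self,
        X_new=None,
        conditioned: dict | None = None,
        targets=None,
        seed: int = 0,
        n_draws: int | None = 200,
        levels=(0.90, 0.95),
        cond_sweeps: int = 3,
    ) -> Predictions:
        """Predict target species given observed values of others.

        Per retained draw the conditioned species' latent values are
        fixed at y where CA y > 0 and sampled from the censored region
        otherwise; targets are then drawn from the MVN conditional and
        censored to the observation scale.  With ``conditioned={}`` this
        reduces exactly to marginal prediction.
        """
        conditioned = conditioned or {}
        if targets is None:
            targets = [s for s in self.species if s not in conditioned]
        unknown = (set(conditioned) | set(targets)) - set(self.species)
        if unknown:
            raise ValueError(f"unknown species name(s): {sorted(unknown)}")
        overlap = set(conditioned) & set(targets)
        if overlap:
            raise ValueError(f"species cannot be both conditioned and target: {sorted(overlap)}")

        X = self._resolve_design(X_new)
        n = X.shape[0]
        c_idx = [self.species.index(s) for s in conditioned]
        t_idx = [self.species.index(s) for s in targets]
        y_c = (
            np.column_stack([np.broadcast_to(np.asarray(conditioned[s], dtype=float), (n,)) for s in conditioned])
            if c_idx else np.empty((n, 0))
        )

        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), int(seed)]))
        idx = self._draw_indices(n_draws)
        draws = np.empty((len(idx), n, len(t_idx)))
        for j, m in enumerate(idx):
            B = self.B_draws[m]
            sigma = self.sigma_draws[m]
            mu = X @ B
            if c_idx:
                w_c = self._latent_conditioned(y_c, mu[:, c_idx], sigma[np.ix_(c_idx, c_idx)], rng, cond_sweeps)
                mean_t, cov_t = mvn_conditional(mu, sigma, c_idx, t_idx, w_c)
            else:
                mean_t = mu[:, t_idx]
                cov_t = sigma[np.ix_(t_idx, t_idx)]
            L = cholesky(cov_t, lower=True)
            w_t = mean_t + rng.standard_normal((n, len(t_idx))) @ L.T
            draws[j] = censor_to_observed(w_t, self.kind)

        intervals = {}
        for level in levels:
            alpha = (1.0 - level) / 2.0
            intervals[level] = (
                np.quantile(draws, alpha, axis=0),
                np.quantile(draws, 1.0 - alpha, axis=0),
            )
        return Predictions(
            species=list(targets), mean=draws.mean(axis=0), intervals=intervals,
            n_draws=len(idx),
        )

    def _latent_conditioned(self, y_c, mu_c, sigma_cc, rng, sweeps):
        """Latent values for conditioned species: fixed at y for positive
        CA observations, censored-region draws otherwise (short Gibbs
        scan within the conditioned block)."""
        if self.kind == "CA":
            w = np.where(y_c > 0, y_c, -0.5)
        else:
            w = np.where(y_c > 0, 0.5, -0.5)
        if y_c.shape[1] == 1:
            sd = np.sqrt(sigma_cc[0, 0])
            if self.kind == "CA":
                mask = y_c[:, 0] <= 0
                if mask.any():
                    w[mask, 0] = truncated_normal_below(mu_c[mask, 0], sd, 0.0, rng)
            else:
                pos = y_c[:, 0] > 0
                if pos.any():
                    w[pos, 0] = truncated_normal_above(mu_c[pos, 0], sd, 0.0, rng)
                if (~pos).any():
                    w[~pos, 0] = truncated_normal_below(mu_c[~pos, 0], sd, 0.0, rng)
            return w
        from .sampler import gibbs_update_latent

        for _ in range(sweeps):
            gibbs_update_latent(w, y_c, mu_c, sigma_cc, self.kind, rng)
        return w

    def _resolve_design(self, X_new):
        if X_new is None:
            if self.model is None:
                raise ValueError("no training design available; pass X_new")
            return self.model.design.values
        if hasattr(X_new, "values") and hasattr(X_new, "standardization_params"):
            if (
                self.standardization_params
                and X_new.standardization_params != self.standardization_params
            ):
                raise ValueError(
                    "design was not built with the training standardization "
                    "parameters; rebuild with build_design(..., params=...)"
                )
            return X_new.values
        return np.asarray(X_new, dtype=float)

    # persistence ------------------------------------------------------
    def save(self, path_prefix: str):
        """Write draws to ``<prefix>.npz`` and metadata to ``<prefix>.json``."""
        np.savez_compressed(
            f"{path_prefix}.npz",
            B_draws=self.B_draws,
            sigma_draws=self.sigma_draws,
            deviance_draws=self.deviance_draws,
        )
        meta = {
            "species": self.species,
            "column_names": self.column_names,
            "burnin": self.burnin,
            "n_iter": self.n_iter,
            "thin": self.thin,
            "seed": self.seed,
            "spec": self.spec.to_dict() if self.spec is not None else None,
            "standardization_params": self.standardization_params,
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "GibbsResults":
        arrays = np.load(f"{path_prefix}.npz")
        with open(f"{path_prefix}.json") as fh:
            meta = json.load(fh)
        spec = ModelSpec.from_dict(meta["spec"]) if meta.get("spec") else None
        return cls(
            B_draws=arrays["B_draws"],
            sigma_draws=arrays["sigma_draws"],
            deviance_draws=arrays["deviance_draws"],
            burnin=meta["burnin"],
            n_iter=meta["n_iter"],
            thin=meta["thin"],
            seed=meta["seed"],
            species=meta["species"],
            column_names=meta["column_names"],
            spec=spec,
            standardization_params={
                k: tuple(v) for k, v in (meta["standardization_params"] or {}).items()
            },
        )

    def export_summary_csv(self, path: str, level: float = 0.95):
        self.summary(level).to_csv(path, index=False)
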