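"""Prediction metrics and residual diagnostics.

All metrics operate on the observation scale (CPUE in kg/tow, presence
probabilities in [0, 1]) and accept predictions from any model, so an
external single-species baseline can be scored through the identical
code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score
from statsmodels.tsa.stattools import pacf as _sm_pacf

__all__ = [
    "rmspe",
    "r_squared",
    "auc",
    "mean_precision",
    "aggregate_by_kmeans",
    "variance_partition",
    "significance_table",
    "abs_correlation_difference",
    "residual_semivariogram",
    "residual_pacf",
    "metrics_report",
]


def _paired(pred, obs):
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    if pred.size == 0:
        raise ValueError("empty input")
    return pred, obs


def rmspe(pred, obs) -> float:
    """Root mean squared prediction error, in the units of the data."""
    pred, obs = _paired(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def r_squared(pred, obs) -> float:
    """1 − Σ(pred − obs)² / Σ(obs − mean(obs))²; may be negative."""
    pred, obs = _paired(pred, obs)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observations are constant; R² undefined")
    return 1.0 - float(np.sum((pred - obs) ** 2)) / ss_tot


def auc(scores, labels) -> float:
    """Area under the ROC curve (tie-corrected Mann–Whitney statistic)."""
    scores, labels = _paired(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels.astype(int), scores))


def mean_precision(scores, labels, step: float = 0.01) -> float:
    """Mean precision over the threshold grid {0, step, …, 1}.

    Precision at threshold t is TP/(TP+FP) among scores ≥ t; thresholds
    where nothing is predicted present are skipped (0/0 undefined).
    """
    scores, labels = _paired(scores, labels)
    pos = labels > 0
    if not pos.any():
        raise ValueError("mean precision requires at least one positive label")
    thresholds = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    vals = []
    for t in thresholds:
        predicted = scores >= t
        npred = predicted.sum()
        if npred == 0:
            continue
        vals.append(float((predicted & pos).sum()) / npred)
    return float(np.mean(vals))


def aggregate_by_kmeans(pred, obs, X, k: int, seed: int = 0, max_retries: int = 3) -> pd.DataFrame:
    """Cluster tows by their (standardized) predictors and average
    predictions and observations within clusters.

    Aggregation is mean-preserving: the size-weighted grand means of the
    returned cluster means equal the input grand means.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float).T).T
    obs = np.atleast_2d(np.asarray(obs, dtype=float).T).T
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        labels = np.arange(n)
        k_eff = n
    else:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=0)) / sd
        for attempt in range(max_retries):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt)
            labels = km.fit_predict(Z)
            if len(np.unique(labels)) == k:
                break
        else:
            raise RuntimeError(f"k-means produced an empty cluster after {max_retries} retries")
        k_eff = k
    rows = []
    for c in range(k_eff):
        mask = labels == c
        rows.append(
            {"cluster": c, "size": int(mask.sum()),
             **{f"pred{j}": pred[mask, j].mean() for j in range(pred.shape[1])},
             **{f"obs{j}": obs[mask, j].mean() for j in range(obs.shape[1])}}
        )
    return pd.DataFrame(rows)


def variance_partition(results, X=None) -> pd.DataFrame:
    """Per species: total variance Var_i(μ_is) + Σ_ss and the fraction
    contributed by the mean structure (posterior means over draws)."""
    if X is None:
        X = results.model.design.values
    X = np.asarray(X, dtype=float)
    M = results.n_draws
    S = len(results.species)
    total = np.zeros(S)
    frac = np.zeros(S)
    for m in range(M):
        mu = X @ results.B_draws[m]
        v_mean = mu.var(axis=0, ddof=0)
        v_res = np.diag(results.sigma_draws[m])
        tot = v_mean + v_res
        total += tot
        frac += v_mean / tot
    return pd.DataFrame(
        {"species": results.species, "total_variance": total / M,
         "fraction_from_mean": frac / M}
    )


def significance_table(results, level: float = 0.95) -> pd.DataFrame:
    """Term × species flags: True iff the central credible interval of
    the coefficient excludes zero."""
    summ = results.summary(level)
    return summ.pivot(index="term", columns="species", values="significant")


def abs_correlation_difference(R_pa, R_cpue, species=None) -> np.ndarray:
    """|R_PA| − |R_CPUE| elementwise; shows where the occurrence and
    abundance models disagree about residual co-dependence."""
    if isinstance(R_pa, pd.DataFrame) and isinstance(R_cpue, pd.DataFrame):
        if list(R_pa.columns) != list(R_cpue.columns):
            raise ValueError("species order differs between the two matrices")
        R_pa, R_cpue = R_pa.to_numpy(), R_cpue.to_numpy()
    R_pa = np.asarray(R_pa, dtype=float)
    R_cpue = np.asarray(R_cpue, dtype=float)
    if R_pa.shape != R_cpue.shape:
        raise ValueError("matrices must have identical shape and species order")
    out = np.abs(R_pa) - np.abs(R_cpue)
    np.fill_diagonal(out, 0.0)
    return 0.5 * (out + out.T)


_EARTH_RADIUS_KM = 6371.0088


def _haversine_pairs(lat, lon):
    """Condensed upper-triangle great-circle distances in km."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    i, j = np.triu_indices(len(phi), k=1)
    dphi = phi[j] - phi[i]
    dlam = lam[j] - lam[i]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi[i]) * np.cos(phi[j]) * np.sin(dlam / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1))), i, j


def residual_semivariogram(residuals, lat, lon, bin_edges=None, n_bins: int = 10) -> pd.DataFrame:
    """Empirical semivariogram γ(h) = (1/2|N(h)|) Σ (r_i − r_j)² over
    great-circle distance bins; empty bins reported as NaN.

    Default bins: ``n_bins`` equal-width bins up to the median pairwise
    distance.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 2:
        raise ValueError("need at least two points")
    d, i, j = _haversine_pairs(lat, lon)
    if bin_edges is None:
        bin_edges = np.linspace(0.0, np.median(d), n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    sq = 0.5 * (residuals[i] - residuals[j]) ** 2
    which = np.digitize(d, bin_edges) - 1
    rows = []
    for b in range(len(bin_edges) - 1):
        mask = which == b
        rows.append(
            {"bin_lo": bin_edges[b], "bin_hi": bin_edges[b + 1],
             "n_pairs": int(mask.sum()),
             "gamma": float(sq[mask].mean()) if mask.any() else np.nan}
        )
    return pd.DataFrame(rows)


def residual_pacf(series, max_lag: int) -> np.ndarray:
    """Partial autocorrelations (Durbin–Levinson on sample ACF) for lags
    0..max_lag; lag 0 is 1 by convention."""
    series = np.asarray(series, dtype=float)
    if series.size <= max_lag + 1:
        raise ValueError(
            f"series of length {series.size} too short for max_lag={max_lag}"
        )
    return _sm_pacf(series, nlags=max_lag, method="ywm")


def metrics_report(pred, obs, kind: str = "CA", species=None) -> pd.DataFrame:
    """Per-species metric table.

    CA: RMSPE (kg/tow) and R².  PA: AUC and mean precision (scores are
    predicted presence probabilities).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.ndim == 1:
        pred = pred[:, None]
        obs = obs[:, None]
    S = pred.shape[1]
    species = list(species) if species is not None else [f"s{j}" for j in range(S)]
    rows = []
    for j in range(S):
        row = {"species": species[j], "n": pred.shape[0]}
        if kind == "CA":
            row["rmspe"] = rmspe(pred[:, j], obs[:, j])
            row["r2"] = r_squared(pred[:, j], obs[:, j])
        else:
            row["auc"] = auc(pred[:, j], obs[:, j])
            row["mean_precision"] = mean_precision(pred[:, j], obs[:, j])
        rows.append(row)
    return pd.DataFrame(rows)
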