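"""End-to-end validation experiments on synthetic surveys.

Each experiment generates data with known truth, runs the full pipeline
(fit, predict, select) and measures recovery.  They are used both by the
test suite and by ``scripts/acceptance.py``; all randomness flows from
the single ``seed`` argument.

Problem sizes are deliberately moderate (hundreds to a few thousand
tows, 5-10 species, short screening chains) so a complete validation run
finishes on one CPU in minutes; the quantities checked — interval
coverage, oracle agreement, selection recovery — are calibration
properties that do not require production-scale chains.
"""

from __future__ import annotations

import numpy as np

from .formula import ModelSpec, build_design, continuous, intercept
from .model import JointSpeciesModel
from .results import GibbsResults
from .selection import enumerate_model_grid, select_by_grid, select_by_inverse_prediction
from .synthetic import (
    SyntheticTruth,
    default_structure,
    generate_community,
    generate_covariates,
    random_correlation,
)

__all__ = [
    "oracle_equivalence_experiment",
    "parameter_recovery_experiment",
    "halfnormal_prediction_check",
    "grid_selection_experiment",
    "pruning_selection_experiment",
]


def _four_covariate_spec(kind="CA") -> ModelSpec:
    return ModelSpec(kind, [intercept(), continuous("BT"), continuous("depth"),
                            continuous("BSAL"), continuous("SST")])


def oracle_equivalence_experiment(seed: int = 0, n: int = 1000, S: int = 5,
                                  n_iter: int = 1500, burnin: int = 500) -> dict:
    """Uncensored CA data: the posterior mean of B must match ordinary
    least squares (the flat-prior conjugate answer) within MC error.

    Returns the largest |posterior mean − OLS| in units of the posterior
    sd, and the fraction of entries within 3 sd.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    spec = ModelSpec("CA", [intercept(), continuous("BT"), continuous("depth"),
                            continuous("BSAL")])  # Q = 4
    covs = generate_covariates(n, default_structure(), seed=seed)
    X = build_design(covs, spec)
    Q = X.q
    B = rng.normal(0.0, 0.5, (Q, S))
    B[0] = 12.0  # large intercept: every latent value stays positive
    sigma = random_correlation(S, rng)
    L = np.linalg.cholesky(sigma)
    y = X.values @ B + rng.standard_normal((n, S)) @ L.T
    assert np.all(y > 0), "construction must leave no censored entries"
    model = JointSpeciesModel(y, X)
    res = model.fit(n_iter=n_iter, burnin=burnin, seed=seed, log_every=0)
    ols = np.linalg.lstsq(X.values, y, rcond=None)[0]
    sd = res.B_draws.std(axis=0, ddof=1)
    z = np.abs(res.B_mean - ols) / sd
    return {"max_z": float(z.max()), "frac_within_3sd": float(np.mean(z < 3.0)),
            "n": n, "n_params": int(Q * S)}


def parameter_recovery_experiment(seed: int = 0, n_replicates: int = 5,
                                  n: int = 2000, S: int = 10,
                                  n_iter: int = 4000, burnin: int = 1000) -> dict:
    """Tobit parameter recovery under heavy zero inflation.

    Generates ``n_replicates`` surveys from random truths (Q = 5 design),
    fits each, and pools 95% credible-interval coverage of the true β
    and of the true residual-correlation off-diagonals, plus the
    Frobenius relative error of the posterior-mean R per replicate.
    """
    spec = _four_covariate_spec()
    beta_hits = beta_total = 0
    r_hits = r_total = 0
    frob = []
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, 22, rep]).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(rep_seed)
        covs = generate_covariates(n, default_structure(), seed=rep_seed)
        X = build_design(covs, spec)
        B = rng.normal(0.0, 0.5, (X.q, S))
        B[0] = rng.uniform(-1.0, 0.5, S)
        sigma = random_correlation(S, rng)
        truth = SyntheticTruth(spec=spec, B=B, sigma=sigma,
                               species=[f"sp{j:02d}" for j in range(S)],
                               structure=default_structure(), seed=rep_seed)
        table = generate_community(truth, covs, seed=rep_seed)
        model = JointSpeciesModel.from_dataframe(table, spec, truth.species)
        res = model.fit(n_iter=n_iter, burnin=burnin, seed=rep_seed, log_every=0)
        lo, hi = res.credible_intervals(0.95)
        beta_hits += int(np.sum((lo <= B) & (B <= hi)))
        beta_total += B.size
        R_draws = res.R_draws
        r_lo = np.quantile(R_draws, 0.025, axis=0)
        r_hi = np.quantile(R_draws, 0.975, axis=0)
        iu = np.triu_indices(S, 1)
        R_true = truth.R
        r_hits += int(np.sum((r_lo[iu] <= R_true[iu]) & (R_true[iu] <= r_hi[iu])))
        r_total += len(iu[0])
        frob.append(float(np.linalg.norm(res.R_mean - R_true) / np.linalg.norm(R_true)))
    return {
        "beta_coverage": beta_hits / beta_total,
        "r_coverage": r_hits / r_total,
        "r_frob_rel_err": frob,
        "n_replicates": n_replicates,
        "n": n,
        "n_beta_intervals": beta_total,
    }


def halfnormal_prediction_check(seed: int = 0, n_rows: int = 400,
                                n_draws: int = 400) -> dict:
    """With B = 0 and Σ = I the censored predictive mean per species is
    E[max(Z, 0)] = 1/√(2π); returns the MC estimate and its standard
    error."""
    S, M = 4, 300
    res = GibbsResults(
        B_draws=np.zeros((M, 1, S)), sigma_draws=np.tile(np.eye(S), (M, 1, 1)),
        burnin=0, n_iter=M, thin=1, seed=seed, deviance_draws=np.zeros(M),
        species=[f"s{j}" for j in range(S)], column_names=["intercept"],
        spec=ModelSpec("CA", [intercept()]), standardization_params={},
    )
    X = np.ones((n_rows, 1))
    pred = res.predict(X, seed=seed, n_draws=n_draws, levels=())
    est = float(pred.mean.mean())
    # MC standard error of the pooled mean of censored draws
    var_half = 0.5 - 1.0 / (2.0 * np.pi)
    se = float(np.sqrt(var_half / (n_rows * S * min(n_draws, M))))
    return {"estimate": est, "expected": float(1.0 / np.sqrt(2.0 * np.pi)), "se": se}


def _selection_truth(seed: int, S: int, include_bsal: bool):
    """Truth on the 4-covariate spec; BSAL's effect is real or exactly
    zero depending on the scenario."""
    rng = np.random.default_rng(seed)
    spec = _four_covariate_spec()
    covs_probe = generate_covariates(8, default_structure(), seed=0)
    Q = build_design(covs_probe, spec).q
    B = np.zeros((Q, S))
    B[0] = rng.uniform(-0.8, 0.3, S)
    B[1] = rng.normal(0.7, 0.1, S) * np.sign(rng.standard_normal(S))   # BT
    B[2] = rng.normal(-0.5, 0.1, S)                                    # depth
    B[4] = rng.normal(0.6, 0.1, S) * np.sign(rng.standard_normal(S))   # SST
    if include_bsal:
        B[3] = rng.normal(0.5, 0.1, S) * np.sign(rng.standard_normal(S))
    sigma = random_correlation(S, rng)
    truth = SyntheticTruth(spec=spec, B=B, sigma=sigma,
                           species=[f"sp{j:02d}" for j in range(S)],
                           structure=default_structure(), seed=seed)
    return truth


def grid_selection_experiment(seed: int = 0, n_replicates: int = 20,
                              n: int = 600, S: int = 10,
                              n_iter: int = 1000, burnin: int = 400) -> dict:
    """All-subsets grid over {SST, BSAL} on top of a forced core; data
    generated from the candidate containing both.  Candidates missing a
    real covariate lose at the DIC stage and at out-of-sample R², so
    the workflow should recover the generating candidate."""
    want = tuple(sorted(["intercept", "BT", "depth", "SST", "BSAL"]))
    wins = 0
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, 33, rep]).generate_state(1)[0] % (2**31))
        truth = _selection_truth(rep_seed, S, include_bsal=True)
        covs = generate_covariates(n, default_structure(), seed=rep_seed)
        table = generate_community(truth, covs, seed=rep_seed)
        grid = enumerate_model_grid(
            [intercept(), continuous("BT"), continuous("depth")],
            [continuous("SST"), continuous("BSAL")], "CA",
        )
        report = select_by_grid(grid, table, truth.species, seed=rep_seed,
                                n_iter=n_iter, burnin=burnin, shortlist_size=2)
        wins += tuple(sorted(report.chosen.term_names())) == want
    return {"recovery_rate": wins / n_replicates, "n_replicates": n_replicates,
            "grid_size": 4, "chance_rate": 0.25}


def pruning_selection_experiment(seed: int = 0, n_replicates: int = 20,
                                 n: int = 600, S: int = 10,
                                 n_iter: int = 1000, burnin: int = 300) -> dict:
    """Sensitivity + inverse-prediction pruning from a saturated model
    containing one covariate with exactly zero effect (BSAL); recovery
    means the final spec equals the generating one."""
    want = tuple(sorted(["intercept", "BT", "depth", "SST"]))
    wins = 0
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, 44, rep]).generate_state(1)[0] % (2**31))
        truth = _selection_truth(rep_seed, S, include_bsal=False)
        covs = generate_covariates(n, default_structure(), seed=rep_seed)
        table = generate_community(truth, covs, seed=rep_seed)
        report = select_by_inverse_prediction(
            table, truth.species, truth.spec, seed=rep_seed,
            n_iter=n_iter, burnin=burnin, n_inverse_draws=25, max_rows=300,
        )
        wins += tuple(sorted(report.chosen.term_names())) == want
    return {"recovery_rate": wins / n_replicates, "n_replicates": n_replicates,
            "saturated_terms": 5, "chance_rate": 1.0 / 16.0}
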