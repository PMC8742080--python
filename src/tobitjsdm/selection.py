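"""Variable selection: exhaustive DIC/out-of-sample grids and the
sensitivity + inverse-prediction pruning loop.

Two workflows:

(A) *Pruning loop* — fit a saturated model, compute the community
    sensitivity posterior and the inverse-prediction score of each
    covariate, drop terms that are both insensitive and poorly
    inverse-predicted (interactions before their main effects), refit;
    repeat until stable.

(B) *Exhaustive grid* — enumerate all subsets of the optional terms on
    top of a forced core (2^|optional| candidates), fit each with a
    short chain on a 70/30 train split, shortlist by lowest in-sample
    DIC, and choose among the shortlist by out-of-sample R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .evaluation import r_squared
from .formula import ModelSpec
from .inverse import inverse_predict
from .model import JointSpeciesModel

__all__ = [
    "ModelGrid",
    "SelectionReport",
    "enumerate_model_grid",
    "train_test_split",
    "dic",
    "select_by_grid",
    "select_by_inverse_prediction",
]


@dataclass
class ModelGrid:
    """All-subsets candidate grid over optional terms."""

    forced: list          # Term objects always included
    optional: list        # Term objects toggled on/off
    response_kind: str
    subsets: list = field(default_factory=list)     # tuples of optional-term names
    candidates: list = field(default_factory=list)  # ModelSpec per subset

    def __len__(self):
        return len(self.candidates)


def enumerate_model_grid(forced, optional, response_kind: str = "CA",
                         standardize: bool = True) -> ModelGrid:
    """Enumerate every subset of ``optional`` appended to ``forced``.

    The candidate count is exactly 2^|optional|.  When a subset includes
    an interaction whose main effect is itself optional and not in the
    subset, the main effect is added when the spec is materialized
    (model hierarchy), so every candidate is a valid spec.
    """
    forced_names = {t.name for t in forced}
    optional_names = {t.name for t in optional}
    overlap = forced_names & optional_names
    if overlap:
        raise ValueError(f"terms cannot be both forced and optional: {sorted(overlap)}")
    by_name = {t.name: t for t in list(forced) + list(optional)}
    grid = ModelGrid(list(forced), list(optional), response_kind)
    opt_names = [t.name for t in optional]
    for r in range(len(opt_names) + 1):
        for subset in combinations(opt_names, r):
            terms = list(forced) + [by_name[n] for n in subset]
            # hierarchy completion for interactions
            present = {t.name for t in terms}
            for t in list(terms):
                if t.kind == "interaction":
                    for p in t.parents:
                        if p not in present:
                            terms.append(by_name[p])
                            present.add(p)
            grid.subsets.append(subset)
            grid.candidates.append(ModelSpec(response_kind, terms, standardize))
    return grid


def train_test_split(n: int, train_fraction: float = 0.7, seed: int = 0):
    """Disjoint, exhaustive, seed-reproducible index split.

    The train size is round(fraction·n) with half-up rounding, so a
    70/30 split of 5,935 gives 4,155/1,780 and of 5,217 gives
    3,652/1,565.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(train_fraction * n + 0.5))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def dic(results) -> float:
    """Complete-data DIC of a fitted model (D̄ + p_D)."""
    return results.dic()["dic"]


@dataclass
class SelectionReport:
    """Outcome of a selection workflow."""

    table: pd.DataFrame                 # one row per candidate / round
    chosen: ModelSpec | None
    shortlist: list = field(default_factory=list)
    history: list = field(default_factory=list)  # workflow-A round details

    @property
    def chosen_terms(self):
        return sorted(self.chosen.term_names()) if self.chosen else None


def _fit_candidate(spec, table, species, n_iter, burnin, seed):
    model = JointSpeciesModel.from_dataframe(table, spec, species)
    return model, model.fit(n_iter=n_iter, burnin=burnin, seed=seed, log_every=0)


def select_by_grid(
    grid: ModelGrid,
    table: pd.DataFrame,
    species,
    shortlist_size: int = 10,
    seed: int = 0,
    n_iter: int = 1000,
    burnin: int = 400,
    train_fraction: float = 0.7,
    direction: str = "highest",
    n_pred_draws: int = 100,
) -> SelectionReport:
    """Workflow B: all-candidates DIC screen, then out-of-sample R².

    Every candidate is fitted with a short chain on the training split
    and scored by in-sample DIC; the ``shortlist_size`` lowest-DIC
    candidates are re-scored by pooled out-of-sample R² on the held-out
    split, and the best (``direction='highest'``; 'lowest' available)
    wins.  Candidate fit failures are recorded, not fatal.
    """
    if len(grid) == 0:
        raise ValueError("empty model grid")
    n = len(table)
    train_idx, test_idx = train_test_split(n, train_fraction, seed)
    train = table.iloc[train_idx].reset_index(drop=True)
    test = table.iloc[test_idx].reset_index(drop=True)
    rows = []
    fits = {}
    for ci, spec in enumerate(grid.candidates):
        try:
            model, res = _fit_candidate(spec, train, species, n_iter, burnin, seed)
            fits[ci] = (model, res)
            rows.append({"candidate": ci, "terms": "+".join(sorted(spec.term_names())),
                         "dic": res.dic()["dic"], "error": None})
        except Exception as e:  # noqa: BLE001 - recorded per candidate
            rows.append({"candidate": ci, "terms": "+".join(sorted(spec.term_names())),
                         "dic": np.nan, "error": str(e)})
    report = pd.DataFrame(rows)
    ok = report.dropna(subset=["dic"]).sort_values("dic")
    shortlist = ok["candidate"].head(shortlist_size).tolist()
    oos = {}
    for ci in shortlist:
        model, res = fits[ci]
        from .formula import build_design

        X_test = build_design(test, grid.candidates[ci],
                              params=model.design.standardization_params)
        pred_mean = res.predictive_mean(X_test, n_draws=n_pred_draws)
        y_test = test[list(species)].to_numpy(dtype=float)
        if grid.response_kind == "PA":
            y_test = (y_test > 0).astype(float)
        oos[ci] = r_squared(pred_mean.ravel(), y_test.ravel())
    report["oos_r2"] = report["candidate"].map(oos)
    if direction == "highest":
        chosen_ci = max(oos, key=oos.get) if oos else None
    else:
        chosen_ci = min(oos, key=oos.get) if oos else None
    chosen = grid.candidates[chosen_ci] if chosen_ci is not None else None
    return SelectionReport(table=report, chosen=chosen, shortlist=shortlist)


def _term_sensitivity_medians(results) -> dict:
    """Median posterior sensitivity per term (summing f over the design
    columns a factor/interaction term spans), intercept excluded."""
    f = results.sensitivity_draws()  # (M, Q)
    out = {}
    for t in results.spec.terms:
        if t.kind == "intercept":
            continue
        cols = [j for j, name in enumerate(results.column_names)
                if results.model.design.column_terms[j].name == t.name]
        out[t.name] = float(np.median(f[:, cols].sum(axis=1)))
    return out


def select_by_inverse_prediction(
    table: pd.DataFrame,
    species,
    saturated_spec: ModelSpec,
    seed: int = 0,
    n_iter: int = 5000,
    burnin: int = 800,
    max_rounds: int = 5,
    sensitivity_fraction: float = 0.1,
    r2_floor: float = 0.1,
    accuracy_margin: float = 0.05,
    n_inverse_draws: int = 30,
    max_rows: int = 400,
) -> SelectionReport:
    """Workflow A: iterative sensitivity + inverse-prediction pruning.

    Each round fits the current spec, computes term-level sensitivity
    medians and per-covariate inverse-prediction scores, and drops every
    term whose sensitivity median falls below ``sensitivity_fraction``
    of the largest term's *and* whose covariate the community cannot
    predict back (continuous R² < ``r2_floor``; factor accuracy below
    chance + ``accuracy_margin``).  Interactions are dropped before
    their main effects: a main effect survives while any retained
    interaction references it.  Stops when a round drops nothing.
    """
    spec = saturated_spec
    history = []
    rows = []
    chosen_results = None
    for rnd in range(max_rounds):
        model, res = _fit_candidate(spec, table, species, n_iter, burnin, seed + rnd)
        chosen_results = res
        sens = _term_sensitivity_medians(res)
        top = max(sens.values()) if sens else 0.0
        inv = inverse_predict(res, table, seed=seed + rnd, n_draws=n_inverse_draws,
                              max_rows=max_rows)
        score_table = inv.scores(table)
        scores = dict(zip(score_table["covariate"], score_table["score"]))
        in_use = {p for t in spec.interaction_terms for p in t.parents}
        drops = []
        for t in spec.terms:
            if t.kind == "intercept":
                continue
            low_sens = sens[t.name] < sensitivity_fraction * top
            if t.kind == "interaction":
                if low_sens:
                    drops.append(t.name)
            elif t.kind == "continuous":
                if t.name in in_use:
                    continue  # interaction must go first
                if low_sens and scores.get(t.name, 0.0) < r2_floor:
                    drops.append(t.name)
            else:  # factor
                chance = 1.0 / len(t.levels)
                if low_sens and scores.get(t.name, 0.0) < chance + accuracy_margin:
                    drops.append(t.name)
        history.append({"round": rnd, "terms": spec.term_names(),
                        "sensitivity": sens, "scores": scores, "dropped": drops})
        rows.append({"round": rnd, "n_terms": len(spec.terms),
                     "dropped": "+".join(drops) if drops else ""})
        if not drops:
            break
        spec = spec.drop(drops)
    return SelectionReport(table=pd.DataFrame(rows), chosen=spec,
                           shortlist=[], history=history)
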