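"""Model terms and design-matrix construction.

A model is declared as an ordered list of :class:`Term` objects — an
intercept, continuous covariates, factors (dummy-coded against a named
baseline level) and pairwise interactions.  Continuous covariates are
standardized (mean 0, sd 1) *before* interaction columns are formed, and
the standardization parameters are stored so that new data (prediction,
inversion) is mapped onto exactly the training scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Term",
    "ModelSpec",
    "DesignMatrix",
    "build_design",
    "intercept",
    "continuous",
    "factor",
    "interaction",
    "DesignError",
]


class DesignError(ValueError):
    """Raised for invalid model specifications or unusable covariate data."""


@dataclass(frozen=True)
class Term:
    """One additive term of the mean structure.

    Parameters
    ----------
    kind : {"intercept", "continuous", "factor", "interaction"}
    name : str
        Covariate/factor name; for interactions ``"a:b"``.
    parents : tuple of str
        For interactions, the two constituent main-effect names
        (continuous×continuous or continuous×factor).
    levels : tuple of str
        For factors, the declared levels; the first is the baseline and
        is omitted from the design matrix.
    """

    kind: str
    name: str
    parents: tuple = ()
    levels: tuple = ()

    def __post_init__(self):
        if self.kind not in ("intercept", "continuous", "factor", "interaction"):
            raise DesignError(f"unknown term kind {self.kind!r}")
        if self.kind == "interaction" and len(self.parents) != 2:
            raise DesignError("interaction requires exactly two parent terms")
        if self.kind == "factor" and len(self.levels) < 2:
            raise DesignError(f"factor {self.name!r} needs at least two levels")


def intercept() -> Term:
    return Term("intercept", "intercept")


def continuous(name: str) -> Term:
    return Term("continuous", name)


def factor(name: str, levels) -> Term:
    """Factor term; ``levels[0]`` is the baseline and gets no column."""
    return Term("factor", name, levels=tuple(levels))


def interaction(a: str, b: str) -> Term:
    return Term("interaction", f"{a}:{b}", parents=(a, b))


@dataclass
class ModelSpec:
    """Mean-structure declaration for one response matrix.

    response_kind is ``"CA"`` (continuous abundance, tobit) or ``"PA"``
    (presence/absence, probit).
    """

    response_kind: str
    terms: list
    standardize: bool = True

    def __post_init__(self):
        if self.response_kind not in ("CA", "PA"):
            raise DesignError(f"response_kind must be 'CA' or 'PA', got {self.response_kind!r}")
        n_icpt = sum(t.kind == "intercept" for t in self.terms)
        if n_icpt != 1:
            raise DesignError(f"spec must contain exactly one intercept term, found {n_icpt}")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise DesignError("duplicate terms in spec")
        main = {t.name for t in self.terms if t.kind in ("continuous", "factor")}
        for t in self.terms:
            if t.kind == "interaction":
                for p in t.parents:
                    if p not in main:
                        raise DesignError(
                            f"interaction {t.name!r} requires main effect {p!r} in the spec"
                        )

    # convenience views -------------------------------------------------
    @property
    def continuous_names(self):
        return [t.name for t in self.terms if t.kind == "continuous"]

    @property
    def factor_terms(self):
        return [t for t in self.terms if t.kind == "factor"]

    @property
    def interaction_terms(self):
        return [t for t in self.terms if t.kind == "interaction"]

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise DesignError(f"term {name!r} not in spec")

    def drop(self, names) -> "ModelSpec":
        """New spec without the named terms (interactions referencing a
        dropped main effect are dropped too)."""
        names = set(names)
        kept = [t for t in self.terms if t.name not in names]
        kept = [
            t for t in kept
            if not (t.kind == "interaction" and names.intersection(t.parents))
        ]
        if not any(t.kind == "intercept" for t in kept):
            raise DesignError("cannot drop the intercept")
        return ModelSpec(self.response_kind, kept, self.standardize)

    def term_names(self):
        return [t.name for t in self.terms]

    # serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "response_kind": self.response_kind,
            "standardize": self.standardize,
            "terms": [
                {
                    "kind": t.kind,
                    "name": t.name,
                    "parents": list(t.parents),
                    "levels": list(t.levels),
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        terms = [
            Term(t["kind"], t["name"], tuple(t.get("parents", ())), tuple(t.get("levels", ())))
            for t in d["terms"]
        ]
        return cls(d["response_kind"], terms, d.get("standardize", True))


@dataclass
class DesignMatrix:
    """n×Q design with per-column term bookkeeping.

    ``standardization_params`` maps covariate name -> (mean, sd) on the
    training data; reused verbatim when expanding new data.
    """

    values: np.ndarray
    column_names: list
    column_terms: list  # Term per column (factors/interactions repeat)
    spec: ModelSpec
    standardization_params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def columns_for(self, term_name: str):
        """Indices of the design columns belonging to one term."""
        return [j for j, t in enumerate(self.column_terms) if t.name == term_name]


def _standardize(x: np.ndarray, name: str, params: dict | None, store: dict):
    if params is not None:
        mean, sd = params[name]
    else:
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=0))
        if sd == 0.0:
            raise DesignError(f"covariate {name!r} has zero variance; cannot standardize")
    store[name] = (mean, sd)
    return (x - mean) / sd


def build_design(table: pd.DataFrame, spec: ModelSpec, params: dict | None = None) -> DesignMatrix:
    """Expand a survey table into the n×Q design matrix.

    Parameters
    ----------
    table : DataFrame with one row per tow and the covariates named in
        ``spec`` as columns.
    spec : ModelSpec
    params : optional standardization parameters from a training design;
        pass ``DesignMatrix.standardization_params`` to place new data
        on the training scale.

    Raises
    ------
    DesignError
        If a covariate is missing, has zero variance under
        standardization, or a factor column contains a level not
        declared in the spec.
    """
    n = len(table)
    store: dict = {}
    std_cols: dict = {}
    for name in spec.continuous_names:
        if name not in table.columns:
            raise DesignError(f"missing covariate {name!r} in table")
        x = np.asarray(table[name], dtype=float)
        if not np.all(np.isfinite(x)):
            raise DesignError(f"non-finite values in covariate {name!r}")
        std_cols[name] = _standardize(x, name, params, store) if spec.standardize else x

    # factor dummies keyed (factor, level)
    factor_cols: dict = {}
    for ft in spec.factor_terms:
        if ft.name not in table.columns:
            raise DesignError(f"missing factor {ft.name!r} in table")
        obs = table[ft.name].astype(str).to_numpy()
        unseen = set(obs) - set(ft.levels)
        if unseen:
            raise DesignError(
                f"factor {ft.name!r} contains level(s) {sorted(unseen)} not declared in spec"
            )
        for lev in ft.levels[1:]:
            factor_cols[(ft.name, lev)] = (obs == lev).astype(float)

    cols, names, terms = [], [], []
    for t in spec.terms:
        if t.kind == "intercept":
            cols.append(np.ones(n))
            names.append("intercept")
            terms.append(t)
        elif t.kind == "continuous":
            cols.append(std_cols[t.name])
            names.append(t.name)
            terms.append(t)
        elif t.kind == "factor":
            for lev in t.levels[1:]:
                cols.append(factor_cols[(t.name, lev)])
                names.append(f"{t.name}[{lev}]")
                terms.append(t)
        else:  # interaction
            a, b = t.parents
            a_term = spec.term(a)
            b_term = spec.term(b)
            if a_term.kind == "factor" and b_term.kind == "factor":
                raise DesignError(f"factor×factor interaction {t.name!r} not supported")
            if b_term.kind == "factor":
                a_term, b_term = b_term, a_term  # put factor first
                a, b = b, a
            if a_term.kind == "factor":
                for lev in a_term.levels[1:]:
                    cols.append(factor_cols[(a, lev)] * std_cols[b])
                    names.append(f"{a}[{lev}]:{b}")
                    terms.append(t)
            else:
                cols.append(std_cols[a] * std_cols[b])
                names.append(t.name)
                terms.append(t)
    values = np.column_stack(cols)
    return DesignMatrix(values, names, terms, spec, store)
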