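import numpy as np
import pandas as pd
import pytest

from tobitjsdm.formula import ModelSpec, continuous, factor, intercept, interaction
from tobitjsdm.model import JointSpeciesModel
from tobitjsdm.synthetic import (
    SyntheticTruth,
    default_structure,
    generate_community,
    generate_covariates,
    random_correlation,
)


def small_spec(kind="CA"):
    """Compact mean structure with a factor and an interaction."""
    return ModelSpec(
        kind,
        [
            intercept(),
            continuous("BT"),
            continuous("depth"),
            factor("subregion", ("GoM", "SNE")),
            interaction("depth", "BT"),
        ],
    )


def make_strong_truth(S=5, seed=0, kind="CA", slope=0.7):
    """Truth with clearly nonzero covariate effects for recovery tests."""
    rng = np.random.default_rng(seed)
    spec = small_spec(kind)
    Q = 5  # intercept, BT, depth, subregion[SNE], depth:BT
    B = rng.normal(0.0, slope, size=(Q, S))
    B[0] = rng.uniform(-0.6, 0.4, S)
    sigma = random_correlation(S, rng)
    return SyntheticTruth(
        spec=spec, B=B, sigma=sigma, species=[f"sp{j:02d}" for j in range(S)],
        structure=default_structure(), seed=seed,
    )


@pytest.fixture(scope="session")
def ca_fit():
    """A moderately sized fitted CA model shared across tests."""
    truth = make_strong_truth(S=5, seed=11)
    covs = generate_covariates(600, truth.structure, seed=11)
    table = generate_community(truth, covs, seed=11)
    model = JointSpeciesModel.from_dataframe(table, truth.spec, truth.species)
    results = model.fit(n_iter=900, burnin=300, seed=7, log_every=0)
    return {"truth": truth, "table": table, "model": model, "results": results}


@pytest.fixture(scope="session")
def pa_fit():
    truth = make_strong_truth(S=4, seed=21, kind="PA", slope=0.6)
    covs = generate_covariates(500, truth.structure, seed=21)
    table = generate_community(truth, covs, seed=21)
    model = JointSpeciesModel.from_dataframe(table, truth.spec, truth.species)
    results = model.fit(n_iter=700, burnin=250, seed=9, log_every=0)
    return {"truth": truth, "table": table, "model": model, "results": results}


@pytest.fixture()
def toy_table():
    return pd.DataFrame(
        {
            "BT": [10.0, 12.0, 14.0],
            "depth": [50.0, 100.0, 150.0],
            "subregion": ["GoM", "SNE", "GoM"],
            "sp00": [1.0, 0.0, 2.5],
            "sp01": [0.0, 0.3, 0.0],
        }
    )
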