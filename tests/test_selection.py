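"""Model grids, split arithmetic, DIC behavior and selection workflows."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tobitjsdm.formula import ModelSpec, continuous, factor, intercept, interaction
from tobitjsdm.model import JointSpeciesModel
from tobitjsdm.selection import (
    enumerate_model_grid,
    select_by_grid,
    select_by_inverse_prediction,
    train_test_split,
)
from tobitjsdm.synthetic import generate_community, generate_covariates

from conftest import make_strong_truth


class TestGridEnumeration:
    def test_ten_optional_terms_give_1024_candidates(self):
        forced = [intercept(), continuous("BT"), continuous("BSAL"), continuous("SST"),
                  continuous("SSAL"), continuous("chla"), continuous("depth")]
        optional = [continuous("SEDSIZE"), factor("subregion", ("GoM", "SNE")),
                    factor("position", ("low", "mid", "high")),
                    factor("seabedform", ("flat", "slope")),
                    interaction("depth", "SEDSIZE"), interaction("depth", "BT"),
                    interaction("depth", "BSAL"), interaction("depth", "SST"),
                    interaction("depth", "SSAL"), interaction("depth", "chla")]
        grid = enumerate_model_grid(forced, optional)
        assert len(grid) == 1024

    def test_no_optional_terms_single_candidate(self):
        grid = enumerate_model_grid([intercept(), continuous("BT")], [])
        assert len(grid) == 1
        assert grid.candidates[0].term_names() == ["intercept", "BT"]

    def test_two_optional_terms_explicit_listing(self):
        grid = enumerate_model_grid(
            [intercept(), continuous("BT")], [continuous("SST"), continuous("BSAL")]
        )
        assert sorted(grid.subsets) == [(), ("SST",), ("SST", "BSAL"), ("BSAL",)] or \
            sorted(map(sorted, grid.subsets)) == [[], ["BSAL"], ["BSAL", "SST"], ["SST"]]
        assert len(grid) == 4

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="forced and optional"):
            enumerate_model_grid([intercept(), continuous("BT")], [continuous("BT")])

    def test_interaction_subset_completed_to_valid_spec(self):
        grid = enumerate_model_grid(
            [intercept(), continuous("depth")],
            [continuous("SEDSIZE"), interaction("depth", "SEDSIZE")],
        )
        assert len(grid) == 4
        for spec in grid.candidates:
            if "depth:SEDSIZE" in spec.term_names():
                assert "SEDSIZE" in spec.term_names()

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 6))
    def test_count_is_power_of_two(self, k):
        optional = [continuous(f"c{i}") for i in range(k)]
        grid = enumerate_model_grid([intercept(), continuous("BT")], optional)
        assert len(grid) == 2**k


class TestTrainTestSplit:
    @pytest.mark.parametrize(
        "n,train,test",
        [(5217, 3652, 1565), (5935, 4155, 1780), (10, 7, 3)],
    )
    def test_seventy_thirty_arithmetic(self, n, train, test):
        tr, te = train_test_split(n, 0.7, seed=0)
        assert len(tr) == train and len(te) == test

    def test_even_split_disjoint_exhaustive(self):
        tr, te = train_test_split(10, 0.5, seed=1)
        assert len(tr) == len(te) == 5
        assert set(tr).isdisjoint(te)
        assert sorted(np.concatenate([tr, te])) == list(range(10))

    def test_reproducible_by_seed(self):
        a = train_test_split(100, 0.7, seed=3)
        b = train_test_split(100, 0.7, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        c = train_test_split(100, 0.7, seed=4)
        assert not np.array_equal(a[0], c[0])

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            train_test_split(10, 1.0)


class TestDIC:
    def test_too_few_draws_rejected(self, ca_fit):
        import copy

        res = copy.copy(ca_fit["results"])
        res.B_draws = res.B_draws[:20]
        res.sigma_draws = res.sigma_draws[:20]
        res.deviance_draws = res.deviance_draws[:20]
        with pytest.raises(ValueError, match="50"):
            res.dic()

    def test_effective_parameters_positive(self, ca_fit):
        assert ca_fit["results"].dic()["pd"] > 0

    def test_dic_stable_under_draw_doubling(self):
        truth = make_strong_truth(S=4, seed=55)
        covs = generate_covariates(400, truth.structure, seed=55)
        table = generate_community(truth, covs, seed=55)
        m = JointSpeciesModel.from_dataframe(table, truth.spec, truth.species)
        short = m.fit(n_iter=700, burnin=400, seed=1, log_every=0).dic()["dic"]
        long = m.fit(n_iter=1000, burnin=400, seed=1, log_every=0).dic()["dic"]
        assert abs(short - long) / abs(long) < 0.01

    def test_superfluous_term_rarely_lowers_dic_much(self):
        """Data from the smaller of two nested specs: the larger model's
        DIC should not systematically beat the smaller's."""
        wins = 0
        reps = 8
        for rep in range(reps):
            truth = make_strong_truth(S=4, seed=70 + rep)
            covs = generate_covariates(400, truth.structure, seed=70 + rep)
            # an extra pure-noise covariate available to the bigger spec
            rng = np.random.default_rng(1000 + rep)
            covs["noise"] = rng.normal(0, 1, len(covs))
            table = generate_community(truth, covs, seed=70 + rep)
            small = truth.spec
            big = ModelSpec("CA", small.terms + [continuous("noise")])
            m_small = JointSpeciesModel.from_dataframe(table, small, truth.species)
            m_big = JointSpeciesModel.from_dataframe(table, big, truth.species)
            d_small = m_small.fit(n_iter=700, burnin=300, seed=rep, log_every=0).dic()["dic"]
            d_big = m_big.fit(n_iter=700, burnin=300, seed=rep, log_every=0).dic()["dic"]
            wins += d_big < d_small - 5.0  # a decisive spurious win
        assert wins <= reps // 2


class TestWorkflows:
    def test_grid_report_invariants(self):
        truth = make_strong_truth(S=4, seed=90)
        covs = generate_covariates(300, truth.structure, seed=90)
        table = generate_community(truth, covs, seed=90)
        grid = enumerate_model_grid(
            [intercept(), continuous("BT"), continuous("depth"),
             factor("subregion", ("GoM", "SNE")), interaction("depth", "BT")],
            [continuous("SST")],
        )
        report = select_by_grid(grid, table, truth.species, seed=0,
                                n_iter=300, burnin=120)
        assert len(report.table) == 2
        assert set(report.shortlist) <= set(range(len(grid)))
        chosen_terms = sorted(report.chosen.term_names())
        assert any(sorted(c.term_names()) == chosen_terms
                   for i, c in enumerate(grid.candidates) if i in report.shortlist)

    def test_shortlist_larger_than_grid_keeps_all(self):
        truth = make_strong_truth(S=3, seed=91)
        covs = generate_covariates(250, truth.structure, seed=91)
        table = generate_community(truth, covs, seed=91)
        grid = enumerate_model_grid(
            [intercept(), continuous("BT"), continuous("depth"),
             factor("subregion", ("GoM", "SNE")), interaction("depth", "BT")], []
        )
        report = select_by_grid(grid, table, truth.species, seed=0,
                                n_iter=300, burnin=120, shortlist_size=10)
        assert report.shortlist == list(range(len(grid)))

    def test_pruning_drops_interaction_before_main_effect(self):
        """When depth:BT and BT are both useless, the first round may
        only drop the interaction; BT survives until no interaction
        references it."""
        truth = make_strong_truth(S=5, seed=92, slope=0.8)
        # zero out BT and its interaction: both truly useless
        truth.B[1] = 0.0
        truth.B[4] = 0.0
        covs = generate_covariates(500, truth.structure, seed=92)
        table = generate_community(truth, covs, seed=92)
        report = select_by_inverse_prediction(
            table, truth.species, truth.spec, seed=0, n_iter=500, burnin=200,
            n_inverse_draws=15, max_rows=200,
        )
        for round_info in report.history:
            if "BT" in round_info["dropped"]:
                # by the time BT goes, no interaction with BT remains
                remaining = set(round_info["terms"]) - set(round_info["dropped"])
                assert "depth:BT" not in remaining
        assert "intercept" in report.chosen.term_names()

    def test_all_informative_terms_yield_no_drops(self):
        truth = make_strong_truth(S=5, seed=93, slope=0.9)
        covs = generate_covariates(500, truth.structure, seed=93)
        table = generate_community(truth, covs, seed=93)
        report = select_by_inverse_prediction(
            table, truth.species, truth.spec, seed=0, n_iter=500, burnin=200,
            n_inverse_draws=15, max_rows=200,
        )
        assert len(report.history) == 1
        assert report.history[0]["dropped"] == []
        assert report.chosen.term_names() == truth.spec.term_names()
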