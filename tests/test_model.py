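"""Choice probabilities, the pair likelihood, and maximum-likelihood fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bws
from bws.data import ChoiceDataset, ChoiceRecord
from bws.model import SeparationError

# the three-item worked example: utilities on the logit scale for
# good knowledge (0.695), idea of self-care (0.107), minor illness (-0.083)
G3 = np.array([0.695, 0.107, -0.083])

utilities_strategy = st.lists(
    st.floats(-3, 3, allow_nan=False), min_size=7, max_size=7).map(np.array)


def brute_force_loglike(dataset, utilities):
    """Independent oracle: enumerate every ordered pair with plain math."""
    total = 0.0
    for rec in dataset.records:
        blk = dataset.design.blocks[rec.block_id - 1]
        u = {i: utilities[i] for i in blk}
        z = sum(math.exp(u[a] - u[b]) for a in blk for b in blk if a != b)
        a = dataset.design.item_set.index(rec.best)
        b = dataset.design.item_set.index(rec.worst)
        total += math.log(math.exp(u[a] - u[b]) / z)
    return total


class TestProbabilities:
    def test_uniform_best_when_utilities_equal(self):
        p = bws.best_prob(np.zeros(9), list(range(7)))
        assert np.allclose(p, 1 / 7)

    def test_two_item_equal_utilities(self):
        assert np.allclose(bws.best_prob(np.array([0.3, 0.3]), [0, 1]), 0.5)

    def test_three_item_worked_example_best(self):
        np.testing.assert_allclose(bws.best_prob(G3, [0, 1, 2]),
                                   [0.4963, 0.2757, 0.2280], atol=2e-4)

    def test_three_item_worked_example_worst(self):
        np.testing.assert_allclose(bws.worst_prob(G3, [0, 1, 2]),
                                   [0.2009, 0.3617, 0.4374], atol=2e-4)

    def test_three_item_worked_example_pair(self):
        p = bws.maxdiff_pair_prob(G3, [0, 1, 2])
        assert len(p) == 6
        assert p[(0, 2)] == pytest.approx(0.3098, abs=2e-4)

    def test_uniform_pairs_seven_items(self):
        p = bws.maxdiff_pair_prob(np.zeros(7), list(range(7)))
        assert len(p) == 42
        assert np.allclose(list(p.values()), 1 / 42)

    def test_block_too_small(self):
        with pytest.raises(ValueError):
            bws.best_prob(np.zeros(3), [0])
        with pytest.raises(ValueError):
            bws.maxdiff_pair_prob(np.zeros(3), [0, 1])

    @settings(derandomize=True, max_examples=50)
    @given(g=utilities_strategy)
    def test_normalisation_and_translation_invariance(self, g):
        blk = [0, 2, 3, 5, 6]
        for fn in (bws.best_prob, bws.worst_prob):
            p = fn(g, blk)
            assert np.isclose(p.sum(), 1.0)
            assert np.allclose(p, fn(g + 4.2, blk), atol=1e-9)
        pp = bws.maxdiff_pair_prob(g, blk)
        assert np.isclose(sum(pp.values()), 1.0)
        pp_shift = bws.maxdiff_pair_prob(g + 4.2, blk)
        assert np.allclose(list(pp.values()), list(pp_shift.values()), atol=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(g=utilities_strategy)
    def test_two_item_reversal_identity(self, g):
        """Q_{a,b}(a) = R_{a,b}(b): best of a equals worst of b."""
        q = bws.best_prob(g, [1, 4])
        r = bws.worst_prob(g, [1, 4])
        assert q[0] == pytest.approx(r[1], abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(g=utilities_strategy)
    def test_pair_odds_identity(self, g):
        """p(a,b)/p(b,a) = exp(2*(g_a - g_b))."""
        p = bws.maxdiff_pair_prob(g, [0, 1, 2, 3])
        assert p[(0, 3)] / p[(3, 0)] == pytest.approx(
            math.exp(2 * (g[0] - g[3])), rel=1e-9)


class TestLogLikelihood:
    def test_zero_utilities_closed_form(self, study_fixture):
        _, dataset, _ = study_fixture
        ll = bws.log_likelihood(dataset, np.zeros(15))
        assert ll == pytest.approx(dataset.n_tasks * math.log(1 / 42))

    def test_matches_brute_force_oracle(self, fano_design, study_fixture):
        rng = np.random.default_rng(7)
        design, dataset, _ = study_fixture
        small = ChoiceDataset(design, dataset.records[:25])
        g15 = rng.normal(0, 0.7, 15)
        assert bws.log_likelihood(small, g15) == pytest.approx(
            brute_force_loglike(small, g15), abs=1e-10)

        # k = 3 blocks
        cfg = bws.SimulationConfig(fano_design, rng.normal(0, 0.7, 7),
                                   n_respondents=5, seed=3)
        ds3 = bws.simulate_responses(cfg)
        g7 = rng.normal(0, 0.7, 7)
        assert bws.log_likelihood(ds3, g7) == pytest.approx(
            brute_force_loglike(ds3, g7), abs=1e-10)

        # k = 4: a single block holding all four items
        items4 = bws.ItemSet(list("abcd"))
        d4 = bws.BWSDesign(items4, [(0, 1, 2, 3)])
        ds4 = bws.simulate_responses(bws.SimulationConfig(
            d4, rng.normal(0, 0.7, 4), n_respondents=9, seed=4))
        g4 = rng.normal(0, 0.7, 4)
        assert bws.log_likelihood(ds4, g4) == pytest.approx(
            brute_force_loglike(ds4, g4), abs=1e-10)

    def test_model_loglike_agrees_with_functional_form(self, study_fixture):
        _, dataset, truth = study_fixture
        m = bws.MaxDiffModel(dataset)
        theta = truth[:-1]  # truth is sum-to-zero already
        assert m.loglike(theta) == pytest.approx(
            bws.log_likelihood(dataset, truth), abs=1e-8)


class TestFit:
    def test_df_and_identification(self, study_fit):
        assert study_fit.df_model == 14
        assert study_fit.utilities.sum() == pytest.approx(0.0, abs=1e-10)
        assert study_fit.converged

    def test_score_vanishes_at_optimum(self, study_fit):
        grad = study_fit.model.score(study_fit.params)
        assert np.linalg.norm(grad, np.inf) <= 1e-8

    def test_recovers_generating_utilities(self, study_fixture, study_fit):
        _, _, truth = study_fixture
        assert np.abs(study_fit.utilities - truth).max() < 0.15

    def test_fit_statistics_definitions(self, study_fit):
        res = study_fit
        assert res.lr_chisq == pytest.approx(2 * (res.llf - res.llnull))
        assert res.aic == pytest.approx(-2 * res.llf + 2 * 14)
        assert res.bic == pytest.approx(-2 * res.llf + 14 * math.log(4500))
        assert res.aicc > res.aic
        assert res.llf <= 0 and res.lr_chisq > 0

    def test_covariance_psd_and_ci_order(self, study_fit):
        eigvals = np.linalg.eigvalsh(study_fit.cov_utilities)
        assert eigvals.min() > -1e-12
        ci = study_fit.conf_int()
        assert np.all(ci[:, 0] < ci[:, 1])

    def test_consistency_error_shrinks_with_sample_size(self, study_design):
        truth = bws.reference_utilities()
        mae = {}
        for n in (50, 1000):
            ds = bws.simulate_responses(bws.SimulationConfig(
                study_design, truth, n_respondents=n, seed=11))
            res = bws.fit_maxdiff(ds)
            mae[n] = np.abs(res.utilities - truth).mean()
        assert mae[1000] < mae[50]

    def test_separation_reported_with_item(self, fano_design):
        # item 'item0' chosen best in every block that shows it
        labels = fano_design.item_set.items
        records = []
        for j in range(fano_design.b):
            blk = fano_design.block_labels(j)
            if labels[0] in blk:
                worst = next(x for x in blk if x != labels[0])
                records.append(ChoiceRecord("R1", j + 1, labels[0], worst))
            else:
                records.append(ChoiceRecord("R1", j + 1, blk[0], blk[1]))
        with pytest.raises(SeparationError, match="item0"):
            bws.MaxDiffModel(ChoiceDataset(fano_design, records))

    def test_never_chosen_item_reported(self, fano_design):
        lbl = fano_design.block_labels(0)
        ds = ChoiceDataset(fano_design, [ChoiceRecord("R1", 1, lbl[0], lbl[1])])
        with pytest.raises(SeparationError):
            bws.MaxDiffModel(ds)

    def test_summary_mentions_fit_stats(self, study_fit):
        text = study_fit.summary()
        assert "L-R chi-square" in text and "AIC" in text and "BIC" in text
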