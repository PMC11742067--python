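"""Purity MLE, skewness adjustment, Fisher information, cell fractions."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import skew as scipy_skew

from cpgformer.deconvolve import (
    CellFractionEstimator,
    PurityEstimator,
    adjust_estimate,
    cell_fractions,
    fisher_information,
    invert_posteriors,
    purity_mle,
    reconstruct_methylation,
    region_purities,
    skewness_g1,
)
from cpgformer.pipelines import calibrated_posterior_table
from cpgformer.simulate import MethylomeSimulator, SimConfig
from cpgformer.types import PosteriorTable


def _table(posteriors, priors=(0.5, 0.5), regions=None):
    posteriors = np.asarray(posteriors, dtype=float)
    n = len(posteriors)
    frame = pd.DataFrame({
        "read_id": [f"r{i}" for i in range(n)],
        "region_index": np.zeros(n, dtype=int) if regions is None
        else np.asarray(regions),
        "Tumour": posteriors[:, 0],
        "Normal": posteriors[:, 1],
    })
    return PosteriorTable(frame, ["Tumour", "Normal"], list(priors))


class TestInvertPosteriors:
    def test_bayes_arithmetic(self):
        table = _table([[0.8, 0.2]])
        scores = invert_posteriors(table, normalise=False)
        assert scores[0, 0] == pytest.approx(1.6)

    def test_uniform_priors_proportional_to_posteriors(self):
        table = _table([[0.7, 0.3], [0.2, 0.8]])
        scores = invert_posteriors(table, normalise=False)
        np.testing.assert_allclose(scores, 2 * table.posteriors)

    def test_zero_prior_rejected(self):
        table = _table([[0.5, 0.5]])
        table.priors = np.array([0.0, 1.0])
        with pytest.raises(ValueError, match="priors"):
            invert_posteriors(table)


class TestPurityMle:
    def test_certain_posteriors_recover_read_share(self):
        scores = np.array([[1.0, 0.0]] * 30 + [[0.0, 1.0]] * 70)
        delta, flat = purity_mle(scores)
        assert delta == pytest.approx(0.3, abs=1e-9)
        assert not flat

    def test_two_opposite_reads_give_half(self):
        # L(d) proportional to d(1-d), maximised at 0.5
        delta, _ = purity_mle(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert delta == pytest.approx(0.5)

    def test_flat_likelihood_flagged_and_tie_to_zero(self):
        delta, flat = purity_mle(np.array([[1.0, 1.0]] * 5))
        assert delta == 0.0 and flat

    def test_per_read_scaling_invariance(self, rng):
        scores = rng.uniform(0.01, 1.0, size=(40, 2))
        base, _ = purity_mle(scores)
        scaled = scores * rng.uniform(0.5, 10.0, size=(40, 1))
        again, _ = purity_mle(scaled)
        assert base == pytest.approx(again, abs=1e-12)

    def test_matches_dense_optimiser_on_calibrated_posteriors(self):
        """Grid argmax within 2 grid steps of a continuous optimiser."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            table, _ = calibrated_posterior_table(0.35, 10, 50, rng,
                                                  sharpness=1.0)
            scores = invert_posteriors(table)
            delta, _ = purity_mle(scores, grid_step=1e-4)
            s_t, s_n = scores[:, 0], scores[:, 1]

            def nll(d):
                return -np.log(d * s_t + (1 - d) * s_n).sum()

            res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                  options={"xatol": 1e-10})
            assert abs(delta - res.x) <= 2e-4

    def test_swap_equivariance_exact(self, rng):
        table, _ = calibrated_posterior_table(0.22, 5, 40, rng)
        scores = invert_posteriors(table)
        d, _ = purity_mle(scores, grid_step=1e-3)
        d_swapped, _ = purity_mle(scores[:, ::-1], grid_step=1e-3)
        assert d_swapped == pytest.approx(1.0 - d, abs=1e-12)

    def test_all_zero_rows_dropped(self, caplog):
        scores = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with caplog.at_level("WARNING"):
            delta, _ = purity_mle(scores, grid_step=1e-3)
        assert "all-zero" in caplog.text
        assert delta == pytest.approx(2 / 3, abs=1e-3)


class TestRegionPurities:
    def test_per_region_certain_shares(self):
        post = [[1, 0]] * 2 + [[0, 1]] * 8 + [[1, 0]] * 4 + [[0, 1]] * 6
        regions = [0] * 10 + [1] * 10
        table = _table(post, regions=regions)
        ids, deltas = region_purities(invert_posteriors(table),
                                      table.region_index)
        np.testing.assert_allclose(deltas, [0.2, 0.4], atol=1e-9)

    def test_pooled_close_to_region_mean_for_homogeneous_regions(self, rng):
        table, _ = calibrated_posterior_table(0.3, 8, 200, rng, sharpness=0.3)
        scores = invert_posteriors(table)
        pooled, _ = purity_mle(scores, grid_step=1e-3)
        _, deltas = region_purities(scores, table.region_index,
                                    grid_step=1e-3)
        assert abs(pooled - deltas.mean()) < 0.02


class TestSkewness:
    def test_hand_values(self):
        assert skewness_g1([0, 0, 1]) == pytest.approx(np.sqrt(3), abs=1e-12)
        assert skewness_g1([1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_odd_symmetry(self, rng):
        x = rng.normal(size=25)
        assert skewness_g1(-x) == pytest.approx(-skewness_g1(x), abs=1e-12)

    def test_matches_scipy_bias_corrected(self, rng):
        for _ in range(5):
            x = rng.normal(size=rng.integers(3, 50))
            assert skewness_g1(x) == pytest.approx(
                scipy_skew(x, bias=False), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            skewness_g1([1, 2])
        with pytest.raises(ValueError):
            skewness_g1([2, 2, 2])


class TestAdjustEstimate:
    def test_symmetric_input_keeps_identity_mapping(self):
        deltas = np.linspace(0.2, 0.8, 7)
        W, adjusted, info = adjust_estimate(deltas)
        np.testing.assert_allclose(W, 1.0, atol=1e-2)
        assert adjusted == pytest.approx(deltas.mean(), abs=1e-3)

    def test_skew_magnitude_never_increases(self, rng):
        for _ in range(5):
            deltas = np.clip(rng.beta(0.5, 3.0, size=20), 1e-4, 1.0)
            _, _, info = adjust_estimate(deltas)
            assert abs(info["g1_after"]) <= abs(info["g1_before"]) + 1e-9

    def test_mapped_purities_stay_in_unit_interval(self, rng):
        deltas = np.clip(rng.beta(2.0, 0.4, size=30), 0.0, 1.0)
        W, adjusted, _ = adjust_estimate(deltas)
        mapped = W * deltas
        assert (mapped >= -1e-12).all() and (mapped <= 1 + 1e-9).all()
        assert adjusted == pytest.approx(mapped.mean())

    def test_all_equal_returns_identity(self):
        W, adjusted, info = adjust_estimate(np.full(5, 0.4))
        np.testing.assert_array_equal(W, 1.0)
        assert adjusted == pytest.approx(0.4)
        assert info["g1_before"] is None

    def test_needs_three_regions(self):
        with pytest.raises(ValueError):
            adjust_estimate(np.array([0.1, 0.9]))


class TestFisherInformation:
    def test_uninformative_scores_zero(self):
        scores = np.ones((10, 2))
        assert fisher_information(scores, 0.3) == 0.0

    def test_matches_finite_difference_oracle(self, rng):
        """Var over reads of d/d-delta log l_i, via central differences."""
        scores = rng.uniform(0.05, 1.0, size=(25, 2))
        delta, h = 0.4, 1e-7

        def per_read_loglik(d):
            return np.log(d * scores[:, 0] + (1 - d) * scores[:, 1])

        s_num = (per_read_loglik(delta + h) - per_read_loglik(delta - h)) / (2 * h)
        expected = np.var(s_num, ddof=1)
        assert fisher_information(scores, delta) == pytest.approx(
            expected, abs=1e-6)

    def test_sharper_posteriors_give_larger_information(self, rng):
        soft, _ = calibrated_posterior_table(0.3, 5, 200, rng, sharpness=5.0)
        sharp, _ = calibrated_posterior_table(0.3, 5, 200, rng, sharpness=0.2)
        fi_soft = fisher_information(invert_posteriors(soft), 0.3)
        fi_sharp = fisher_information(invert_posteriors(sharp), 0.3)
        assert fi_sharp > fi_soft

    def test_delta_domain(self):
        with pytest.raises(ValueError):
            fisher_information(np.ones((3, 2)), 0.0)


class TestCellFractions:
    def test_certain_two_class_split(self):
        post = [[1 - 1e-12, 1e-12]] * 30 + [[1e-12, 1 - 1e-12]] * 70
        table = _table(post, priors=(0.5, 0.5))
        res = cell_fractions(table, grid_step=1e-3)
        np.testing.assert_allclose(res.fractions, [0.3, 0.7], atol=1e-2)

    def test_absent_class_gets_zero(self):
        names = ["a", "b", "c"]
        frame = pd.DataFrame({
            "read_id": ["r0", "r1"], "region_index": [0, 0],
            "a": [0.9, 0.8], "b": [0.05, 0.1], "c": [0.05, 0.1],
        })
        table = PosteriorTable(frame, names, [1 / 3] * 3)
        res = cell_fractions(table, grid_step=1e-3)
        assert res.fractions[names.index("b")] == 0.0
        assert res.fractions.sum() == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        frame = pd.DataFrame(columns=["read_id", "region_index",
                                      "Tumour", "Normal"])
        table = PosteriorTable(frame, ["Tumour", "Normal"], [0.5, 0.5])
        with pytest.raises(ValueError, match="empty"):
            cell_fractions(table)


class TestReconstructMethylation:
    def test_fully_methylated_class(self, small_pools):
        reads = small_pools["Tumour"][:6]
        # overwrite calls: every CpG methylated
        for r in reads:
            r.cpg_calls = [(o, True) for o, _ in r.cpg_calls]
        out = reconstruct_methylation(reads, ["Tumour"] * 6)
        assert np.allclose(out["Tumour"].dropna(), 1.0)

    def test_missing_class_is_nan_not_zero(self, small_pools):
        reads = small_pools["Tumour"][:3]
        out = reconstruct_methylation(reads, ["Tumour"] * 3,
                                      cell_types=["Tumour", "Normal"])
        assert out["Normal"].isna().all()

    def test_recovers_generative_levels_under_perfect_labels(self):
        """Per-class reconstruction beats the pooled bulk level (a1_b5)."""
        cfg = SimConfig(alpha=1.0, n_regions=12, coverage=40, seed=21)
        sim = MethylomeSimulator(cfg)
        pools = sim.simulate()
        reads = pools["Tumour"] + pools["Normal"]
        labels = [r.cell_label for r in reads]
        recon = reconstruct_methylation(reads, labels)
        truth_t = np.array([sr.probs["Tumour"].mean()
                            for sr in sim.sim_regions])
        bulk = np.array([
            np.nanmean([r.mean_methylation() for r in reads
                        if r.region_index == k])
            for k in range(cfg.n_regions)
        ])
        err_class = np.abs(recon["Tumour"].to_numpy() - truth_t).mean()
        err_bulk = np.abs(bulk - truth_t).mean()
        corr_class = np.corrcoef(recon["Tumour"], truth_t)[0, 1]
        corr_bulk = np.corrcoef(bulk, truth_t)[0, 1]
        assert err_class < err_bulk
        assert corr_class > corr_bulk


class TestEstimatorApi:
    def test_purity_estimator_attributes(self, rng):
        table, real = calibrated_posterior_table(0.25, 8, 50, rng)
        est = PurityEstimator(grid_step=1e-3).fit(table)
        assert 0 <= est.delta_ <= 1
        assert len(est.region_deltas_) == 8
        assert len(est.fisher_information_) == 8
        assert est.result_.adjusted_delta == est.adjusted_delta_
        assert abs(est.estimate_ - real) < 0.2

    def test_sklearn_param_round_trip(self):
        from sklearn.base import clone

        for est in (PurityEstimator(adjust=False, grid_step=1e-3),
                    CellFractionEstimator(grid_step=1e-2)):
            cloned = clone(est)
            assert cloned.get_params() == est.get_params()

    def test_requires_two_cell_types(self, rng):
        frame = pd.DataFrame({"read_id": ["r0"], "region_index": [0],
                              "a": [0.2], "b": [0.5], "c": [0.3]})
        table = PosteriorTable(frame, ["a", "b", "c"], [1 / 3] * 3)
        with pytest.raises(ValueError, match="two cell types"):
            PurityEstimator().fit(table)
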