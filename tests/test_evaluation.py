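"""Metrics, ROC families, sparsification, calibration and OOD perturbations."""
import numpy as np
import pytest

from ecglyte.discretization import BinaryTaskPair
from ecglyte.evaluation import (
    binary_auroc_pair,
    calibration_curve,
    cumulative_roc,
    perturb_mask,
    perturb_noise,
    regression_metrics,
    sparsification,
    stratified_metrics,
    uncertainty_error_correlation,
)


def mann_whitney_auroc(scores, labels):
    """Brute-force U-statistic AUROC (ties counted half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRegressionMetrics:
    def test_perfect_predictions(self, rng):
        y = rng.normal(size=30)
        rep = regression_metrics(y, y)
        assert (rep.mse, rep.mae) == (0.0, 0.0)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)

    def test_constant_predictions_degenerate(self, rng):
        y = rng.normal(size=50)
        with pytest.warns(UserWarning):
            rep = regression_metrics(np.full(50, y.mean()), y)
        assert rep.mse == pytest.approx(y.var())
        assert np.isnan(rep.pearson_r) and np.isnan(rep.spearman_rho)

    def test_matches_brute_force_formulas(self):
        preds = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 2.0, 4.0, 3.0])
        rep = regression_metrics(preds, y)
        assert rep.mse == pytest.approx(np.mean((preds - y) ** 2), abs=1e-12)
        assert rep.mae == pytest.approx(np.mean(np.abs(preds - y)), abs=1e-12)
        # Pearson by its definition
        r = np.sum((preds - preds.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((preds - preds.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert rep.pearson_r == pytest.approx(r, abs=1e-12)
        # Spearman via midranks: y ranks = (1.5, 1.5, 4, 3)
        ranks_p = np.array([1.0, 2.0, 3.0, 4.0])
        ranks_y = np.array([1.5, 1.5, 4.0, 3.0])
        rho = np.corrcoef(ranks_p, ranks_y)[0, 1]
        assert rep.spearman_rho == pytest.approx(rho, abs=1e-12)


class TestStratifiedMetrics:
    def test_single_stratum_equals_global(self, rng):
        y = rng.normal(4, 0.5, 100)
        preds = y + rng.normal(0, 0.2, 100)
        ages = np.full(100, 25.0)
        sexes = np.array(["male"] * 100)
        out = stratified_metrics(preds, y, ages, sexes)
        rep = regression_metrics(preds, y)
        assert out["age"]["18-29"]["mae_normalized"] == pytest.approx(rep.mae / y.std())
        assert out["age"]["18-29"]["n"] == 100
        assert out["age"]["30-39"]["n"] == 0

    def test_target_sd_tracks_spread_by_decade(self, rng):
        ages = np.concatenate([np.full(500, 25.0), np.full(500, 85.0)])
        y = np.concatenate([rng.normal(4, 0.2, 500), rng.normal(4, 0.8, 500)])
        out = stratified_metrics(y, y, ages, np.array(["male"] * 1000))
        assert out["age"]["80+"]["target_sd"] > out["age"]["18-29"]["target_sd"]

    def test_identical_sex_subcohorts_have_equal_mae(self, rng):
        y = rng.normal(4, 0.5, 200)
        preds = y + rng.normal(0, 0.3, 200)
        sexes = np.array(["male", "female"] * 100)
        out = stratified_metrics(np.tile(preds, 2), np.tile(y, 2),
                                 np.full(400, 50.0), np.tile(sexes, 2))
        a = out["sex"]["male"]["mae_normalized"]
        b = out["sex"]["female"]["mae_normalized"]
        assert a == pytest.approx(b, rel=0.2)


class TestROCFamilies:
    def test_perfectly_ordered_scores(self):
        classes = np.repeat([1, 2, 3, 4], 25)
        probs = np.zeros((100, 4))
        probs[np.arange(100), classes - 1] = 1.0
        fam = cumulative_roc(probs, classes, 4, "classification")
        assert fam.aurocs == [1.0, 1.0, 1.0]
        assert fam.aumroc == 1.0

    def test_random_scores_near_half(self, rng):
        classes = rng.integers(1, 5, 2000)
        probs = rng.dirichlet(np.ones(4), size=2000)
        fam = cumulative_roc(probs, classes, 4, "classification")
        assert all(abs(a - 0.5) < 0.05 for a in fam.aurocs)

    def test_binary_case_matches_u_statistic(self, rng):
        classes = rng.integers(1, 3, 200)
        p2 = rng.uniform(size=200)
        probs = np.stack([1 - p2, p2], axis=1)
        fam = cumulative_roc(probs, classes, 2, "classification")
        oracle = mann_whitney_auroc(1 - p2, (classes == 1).astype(int))
        assert fam.aurocs[0] == pytest.approx(oracle, abs=1e-12)

    def test_ordinal_orientation(self, rng):
        """Low threshold probabilities mean low classes."""
        classes = np.repeat([1, 2, 3], 30)
        p = np.stack([(classes > 1) * 0.9 + 0.05, (classes > 2) * 0.9 + 0.05], axis=1)
        fam = cumulative_roc(p, classes, 3, "ordinal")
        assert fam.aurocs == [1.0, 1.0]

    def test_degenerate_event_reported_nan(self):
        classes = np.full(50, 2)
        probs = np.tile([0.5, 0.5], (50, 1))
        fam = cumulative_roc(probs, classes, 2, "classification")
        assert np.isnan(fam.aurocs[0])


class TestBinaryPair:
    PAIR = BinaryTaskPair(3.5, 5.5)

    def test_separated_scores_reach_one(self):
        y = np.array([3.0, 3.2, 4.0, 4.5, 5.8, 6.0])
        hypo_scores = -y  # lower value -> higher hypo risk
        hyper_scores = y
        out = binary_auroc_pair(hypo_scores, hyper_scores, y, self.PAIR)
        assert out["hypo_auroc"] == 1.0 and out["hyper_auroc"] == 1.0
        assert out["average"] == 1.0

    def test_score_flip_complements_auroc(self, rng):
        y = rng.normal(4.5, 1.0, 300)
        s = y + rng.normal(0, 0.5, 300)
        a = binary_auroc_pair(-s, s, y, self.PAIR)
        b = binary_auroc_pair(s, -s, y, self.PAIR)
        assert a["hypo_auroc"] == pytest.approx(1 - b["hypo_auroc"], abs=1e-12)

    def test_matches_u_statistic_oracle(self, rng):
        y = rng.normal(4.5, 1.0, 150)
        s = rng.uniform(size=150)
        out = binary_auroc_pair(s, s, y, self.PAIR)
        assert out["hyper_auroc"] == pytest.approx(
            mann_whitney_auroc(s, self.PAIR.hyper_labels(y)), abs=1e-12
        )


class TestSparsification:
    def test_oracle_uncertainty_monotone_non_increasing(self, rng):
        err = np.abs(rng.normal(size=500))
        res = sparsification(err, err)
        assert np.all(np.diff(res.mae) <= 1e-12)

    def test_uninformative_uncertainty_flat(self, rng):
        err = np.abs(rng.normal(size=4000))
        unc = rng.uniform(size=4000)  # independent of error
        res = sparsification(err, unc, fractions=np.arange(0, 0.9, 0.1))
        assert np.abs(res.mae - res.mae[0]).max() < 4 * err.std() / np.sqrt(400)

    def test_zero_fraction_is_full_mae(self, rng):
        err = np.abs(rng.normal(size=100))
        res = sparsification(err, rng.uniform(size=100), fractions=[0.0, 0.5])
        assert res.mae[0] == pytest.approx(err.mean(), abs=1e-12)


class TestCalibration:
    def test_self_consistent_gaussians_cover_nominally(self, rng):
        n = 20000
        mu = rng.normal(4, 0.5, n)
        var = rng.uniform(0.05, 0.3, n)
        y = rng.normal(mu, np.sqrt(var))
        out = calibration_curve(mu, var, y)
        for q, cov in zip(out["nominal"], out["empirical"]):
            assert abs(cov - q) < 4 * np.sqrt(q * (1 - q) / n) + 0.005

    def test_vanishing_variance_loses_coverage(self, rng):
        y = rng.normal(size=200)
        out = calibration_curve(y + 0.5, np.full(200, 1e-12), y)
        assert np.all(out["empirical"] == 0.0)

    def test_huge_variance_covers_everything(self, rng):
        y = rng.normal(size=200)
        out = calibration_curve(y + 0.5, np.full(200, 1e12), y)
        assert np.all(out["empirical"] == 1.0)


class TestUncertaintyErrorCorrelation:
    def test_proportional_uncertainty_perfect_correlation(self, rng):
        se = rng.uniform(size=100) ** 2
        out = uncertainty_error_correlation({"aleatoric": 3.0 * se}, se)
        assert out["aleatoric"] == pytest.approx(1.0)

    def test_independent_uncertainty_near_zero(self, rng):
        se = rng.uniform(size=5000)
        out = uncertainty_error_correlation({"u": rng.uniform(size=5000)}, se)
        assert abs(out["u"]) < 0.05

    def test_constant_uncertainty_reported_missing(self, rng):
        with pytest.warns(UserWarning):
            out = uncertainty_error_correlation({"u": np.ones(50)}, rng.uniform(size=50))
        assert np.isnan(out["u"])

    def test_combination_sums_estimates(self, rng):
        se = rng.uniform(size=200)
        a = 0.5 * se + rng.normal(0, 0.1, 200)
        b = 0.5 * se + rng.normal(0, 0.1, 200)
        out = uncertainty_error_correlation(
            {"a": a, "b": b}, se, combinations=[("a", "b")]
        )
        expected = np.corrcoef(a + b, se)[0, 1]
        assert out["a+b"] == pytest.approx(expected, abs=1e-12)


class TestPerturbations:
    def test_noise_power_matches_snr(self, rng):
        X = rng.standard_normal((4, 8, 512)).astype(np.float32)
        out = perturb_noise(X, snr=10.0, seed=0)
        for i in range(4):
            p_sig = np.mean(X[i].astype(float) ** 2)
            p_noise = np.mean((out[i] - X[i]).astype(float) ** 2)
            assert abs(p_sig / p_noise - 10.0) / 10.0 < 0.15  # finite-sample sd

    def test_snr_one_equal_power(self, rng):
        X = rng.standard_normal((2, 8, 4096)).astype(np.float32)
        out = perturb_noise(X, snr=1.0, seed=1)
        p_sig = np.mean(X.astype(float) ** 2)
        p_noise = np.mean((out - X).astype(float) ** 2)
        assert abs(p_noise / p_sig - 1.0) < 0.05

    def test_huge_snr_is_nearly_identity(self, rng):
        X = rng.standard_normal((2, 8, 256)).astype(np.float32)
        out = perturb_noise(X, snr=1e12, seed=0)
        assert np.abs(out - X).max() < 1e-4

    def test_padding_tail_preserved(self, rng):
        X = rng.standard_normal((2, 8, 256)).astype(np.float32)
        X[:, :, 200:] = 0.0
        out = perturb_noise(X, snr=1.0, seed=0)
        assert np.all(out[:, :, 200:] == 0)

    def test_mask_zero_proportion_is_identity(self, rng):
        X = rng.standard_normal((3, 8, 128)).astype(np.float32)
        assert np.array_equal(perturb_mask(X, 0.0, seed=0), X)

    def test_mask_full_proportion_zeroes_trace(self, rng):
        X = rng.standard_normal((3, 8, 128)).astype(np.float32)
        assert np.all(perturb_mask(X, 1.0, seed=0) == 0)

    @pytest.mark.parametrize("mode", ["contiguous", "scattered"])
    def test_mask_count_exact(self, rng, mode):
        X = rng.uniform(0.5, 1.0, (2, 8, 4096)).astype(np.float32)  # no zeros
        out = perturb_mask(X, 0.25, seed=3, mode=mode)
        for i in range(2):
            for lead in range(8):
                assert np.sum(out[i, lead] == 0) == 1024


class TestOODReport:
    def test_identical_conditions_identical_rows(self, rng):
        from ecglyte.models import BackboneConfig, ModelState, TrainConfig, build_network
        from ecglyte.preprocessing import ArrayDataset, NormalizationParams
        from ecglyte.uncertainty import Ensemble, fit_laplace
        from ecglyte.evaluation import ood_report
        import json

        flat = BackboneConfig(kind="flatten", input_shape=(1, 6))
        net = build_network(flat, [1, 1], seed=0)
        member = ModelState(task="gaussian", backbone=flat, head_dims=[1, 1],
                            params=net.get_state(),
                            normalization=NormalizationParams(4.0, 0.5),
                            train_config=TrainConfig(seed=0))
        X = rng.standard_normal((20, 1, 6)).astype(np.float32)
        y = rng.normal(4, 0.5, 20)
        ds = ArrayDataset(X, y, np.arange(20).astype(str), np.arange(20).astype(str),
                          np.full(20, 50.0), np.array(["male"] * 20))
        ens = Ensemble([member, member])
        posts = [fit_laplace(member, ds, prior_precision=1.0, observation_variance=1.0)] * 2
        rep = ood_report(ens, posts, {"a": X, "b": X.copy()}, y)
        assert rep["a"] == rep["b"]
        json.dumps(rep)  # schema is JSON-serializable
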