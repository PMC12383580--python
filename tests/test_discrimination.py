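import numpy as np
import pandas as pd
import pytest

from cardiogrs import discrimination as disc
from cardiogrs import grs_engine, phenotyping
from cardiogrs.discrimination import (
    AUCReport,
    BalanceSpec,
    auc_single_predictor,
    concordance,
    cv_bootstrap_auc,
    cv_mean_auc,
    downsample_balance,
    gaussian_age_match,
)
from cardiogrs.synthetic_cohort import emulate_study


def _frame(n_pos, n_neg, rng, shift=0.0):
    y = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
    x = rng.standard_normal(n_pos + n_neg) + shift * y
    return pd.DataFrame({"x": x, "y": y, "age": rng.normal(40, 10, len(y))})


class TestDownsample:
    def test_majority_subsampled_to_minority_size(self, rng):
        df = _frame(30, 100, rng)
        out = downsample_balance(df, "y", 0)
        assert (out["y"].sum(), (~out["y"]).sum()) == (30, 30)

    def test_already_balanced_unchanged(self, rng):
        df = _frame(40, 40, rng)
        out = downsample_balance(df, "y", 0)
        assert len(out) == 80 and out["y"].sum() == 40

    def test_different_seeds_give_different_subsets_of_equal_size(self, rng):
        df = _frame(30, 200, rng)
        a = downsample_balance(df, "y", 1)
        b = downsample_balance(df, "y", 2)
        assert len(a) == len(b) == 60
        assert set(a.index) != set(b.index)

    def test_empty_class_rejected(self, rng):
        df = _frame(10, 0, rng)
        with pytest.raises(ValueError):
            downsample_balance(df, "y", 0)


class TestGaussianAgeMatch:
    def test_target_ages_pulled_toward_reference_gaussian(self, rng):
        # target class wide enough to cover the reference age range, so the
        # weighted draw can actually realize the reference Gaussian
        df = pd.DataFrame({
            "cls": ["ref"] * 2000 + ["tgt"] * 20000,
            "age": np.r_[rng.normal(30, 5, 2000), rng.normal(50, 15, 20000)],
        })
        out = gaussian_age_match(df, "cls", "tgt", "ref", 0)
        resampled = out[out["cls"] == "tgt"]
        assert len(resampled) == 2000
        assert 27 <= resampled["age"].mean() <= 33
        assert resampled["age"].std() == pytest.approx(5, rel=0.2)

    def test_identical_distributions_behave_like_random_subsample(self, rng):
        df = pd.DataFrame({
            "cls": ["ref"] * 2000 + ["tgt"] * 3000,
            "age": rng.normal(40, 8, 5000),
        })
        out = gaussian_age_match(df, "cls", "tgt", "ref", 0)
        resampled = out[out["cls"] == "tgt"]
        se = 8 / np.sqrt(len(resampled))
        assert abs(resampled["age"].mean() - 40) < 2 * se + abs(
            df.loc[df.cls == "tgt", "age"].mean() - 40
        )

    def test_support_mismatch_emits_warning(self, rng):
        df = pd.DataFrame({
            "cls": ["ref"] * 500 + ["tgt"] * 800,
            "age": np.r_[rng.normal(25, 4, 500), rng.normal(70, 3, 800)],
        })
        with pytest.warns(UserWarning, match="incomplete age overlap"):
            gaussian_age_match(df, "cls", "tgt", "ref", 0)

    def test_small_classes_rejected(self, rng):
        df = pd.DataFrame({"cls": ["ref"] * 10 + ["tgt"] * 40,
                           "age": rng.normal(40, 5, 50)})
        with pytest.raises(ValueError, match=">= 30"):
            gaussian_age_match(df, "cls", "tgt", "ref", 0)


class TestSinglePredictorAUC:
    def test_perfect_separation_scores_one(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x > 0.5
        assert auc_single_predictor(x, y) == pytest.approx(1.0)

    def test_constant_predictor_scores_half_by_tie_convention(self):
        y = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        assert auc_single_predictor(np.ones(20), y) == 0.5

    def test_concordance_count_example(self):
        # cases at x in {2,4}, controls at {1,3}: 3 of 4 pairs concordant
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([False, True, False, True])
        assert auc_single_predictor(x, y) == pytest.approx(0.75)
        assert concordance(x, y) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_single_predictor([1.0, 2.0], [True, True])

    def test_logistic_auc_equals_mann_whitney_concordance(self, rng):
        """Oracle equivalence on random small datasets (midrank ties)."""
        for _ in range(100):
            n = int(rng.integers(8, 40))
            x = rng.integers(0, 6, n).astype(float)  # ties on purpose
            y = rng.random(n) < 0.5
            if y.all() or not y.any() or np.ptp(x) == 0:
                continue
            auc = auc_single_predictor(x, y)
            conc = concordance(x, y)
            cov = np.mean(x * y) - x.mean() * y.mean()
            if cov > 0:
                assert auc == pytest.approx(conc, abs=1e-9)
            elif cov < 0:
                assert auc == pytest.approx(1 - conc, abs=1e-9)


class TestCVBootstrap:
    def test_same_seed_reproduces_report_exactly(self, rng):
        df = _frame(150, 150, rng, shift=0.8)
        a = cv_bootstrap_auc(df, "x", "y", n_folds=5, n_boot=50, seed=3)
        b = cv_bootstrap_auc(df, "x", "y", n_folds=5, n_boot=50, seed=3)
        assert a == b

    def test_strong_signal_lower_ci_clears_chance(self, rng):
        df = _frame(1000, 1000, rng, shift=1.5)  # true AUC ~ 0.85
        rep = cv_bootstrap_auc(df, "x", "y", n_folds=10, n_boot=200, seed=0)
        assert rep.ci_low > 0.5
        assert 0.78 < rep.auc < 0.92

    def test_orientation_handles_negative_predictors(self, rng):
        df = _frame(500, 500, rng, shift=1.5)
        df["neg"] = -df["x"]
        rep = cv_bootstrap_auc(df, "neg", "y", n_folds=5, n_boot=30, seed=0)
        assert rep.auc > 0.75  # oriented by the fitted slope sign

    def test_too_few_class_members_for_folds_rejected(self, rng):
        df = _frame(4, 100, rng)
        with pytest.raises(ValueError, match="stratify"):
            cv_mean_auc(df["x"].to_numpy(), df["y"].to_numpy(), 10,
                        np.random.default_rng(0))

    def test_fold_resampling_alternative_gives_consistent_point_estimate(self, rng):
        df = _frame(300, 300, rng, shift=1.0)
        a = cv_bootstrap_auc(df, "x", "y", n_folds=10, n_boot=100, seed=1)
        b = cv_bootstrap_auc(df, "x", "y", n_folds=10, n_boot=100, seed=1,
                             boot_method="resample_folds")
        assert b.auc == pytest.approx(a.auc, abs=0.05)
        assert b.ci_low <= b.auc <= b.ci_high

    def test_report_invariants_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            AUCReport("x", "y", 0.7, 0.8, 0.9, 10, 100, "none", 0, 100)


class TestStudyRecovery:
    def test_grs_discriminates_cvd_weakly_and_age_dominates(self, panel18):
        """On replicate study cohorts, the GRS AUC for CVD sits in the
        modest 0.50-0.57 band and age is the stronger predictor."""
        hits = 0
        reps = 25
        for s in range(reps):
            cohort = emulate_study(seed=200 + s)
            pheno = phenotyping.classify_cohort(cohort.phenotypes)
            grs = grs_engine.score_cohort(cohort.genotypes, panel18)
            df = pheno.join(grs, how="inner")
            balanced = downsample_balance(df, "cvd", seed=s)
            rng_ = np.random.default_rng(s)
            y = balanced["cvd"].to_numpy(bool)
            auc_grs = cv_mean_auc(balanced["scaled"].to_numpy(float), y, 10, rng_)
            auc_age = cv_mean_auc(balanced["age"].to_numpy(float), y, 10, rng_)
            hits += (0.50 <= auc_grs <= 0.57) and (auc_age > auc_grs)
        assert hits >= 0.9 * reps
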