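"""Elastic-net hemoglobin model, ratio saturation model, bundle round-trip."""

import math

import numpy as np
import pandas as pd
import pytest

from hemotrans import (
    CalibrationBundle,
    FeatureVector,
    SO2Model,
    fit_hgb_model,
    fit_so2_model,
    predict_hgb,
    predict_so2,
    split_calibration_validation,
)
from hemotrans.calibration import HgbModel, predict_hgb_many
from hemotrans.errors import (
    FoldError,
    InsufficientDataError,
    InsufficientStructureError,
    NotFittedError,
    ParameterError,
)
from hemotrans.preprocessing import feature_matrix


def random_features(n, seed):
    """Well-spread feature vectors from log-intensity ranges seen in operation."""
    rng = np.random.default_rng(seed)
    feats = []
    for _ in range(n):
        ln680 = rng.uniform(2.0, 8.0)
        ln850 = rng.uniform(1.5, 6.0)
        feats.append(FeatureVector.from_scaled(math.exp(ln680), math.exp(ln850)))
    return feats


class TestSplit:
    def test_disjoint_exhaustive_stratified(self):
        samples = pd.DataFrame(
            {"sample_id": range(1, 87), "day_id": [d % 7 + 1 for d in range(86)]}
        )
        cal, val = split_calibration_validation(samples, fraction=0.5, seed=7)
        assert not set(cal) & set(val)
        assert sorted(cal + val) == list(range(1, 87))
        for day in range(1, 8):
            ids = set(samples[samples["day_id"] == day]["sample_id"])
            assert ids & set(cal) and ids & set(val)

    def test_forced_two_by_two(self):
        samples = pd.DataFrame({"sample_id": [1, 2, 3, 4], "day_id": [1, 1, 2, 2]})
        cal, val = split_calibration_validation(samples, fraction=0.5, seed=0)
        assert len(cal) == len(val) == 2
        assert len({1, 2} & set(cal)) == 1 and len({3, 4} & set(cal)) == 1

    def test_seeding_contract(self):
        samples = pd.DataFrame(
            {"sample_id": range(40), "day_id": [d % 5 + 1 for d in range(40)]}
        )
        assert split_calibration_validation(samples, seed=3) == split_calibration_validation(
            samples, seed=3
        )
        assert split_calibration_validation(samples, seed=3) != split_calibration_validation(
            samples, seed=4
        )

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_domain(self, fraction):
        samples = pd.DataFrame({"sample_id": [1, 2], "day_id": [1, 1]})
        with pytest.raises(ParameterError):
            split_calibration_validation(samples, fraction=fraction)

    def test_day_with_single_sample_rejected(self):
        samples = pd.DataFrame({"sample_id": [1, 2, 3], "day_id": [1, 1, 2]})
        with pytest.raises(InsufficientDataError):
            split_calibration_validation(samples)


class TestHgbModel:
    def test_unpenalized_fit_matches_normal_equations(self):
        """lam=0 must agree with the closed-form least squares solution."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(15, 51))
            X = np.column_stack([rng.normal(size=(n, 8)), np.ones(n)])
            y = rng.normal(size=n)
            model = fit_hgb_model(
                X, y, lambda_grid=[0.0], mixing_grid=[0.5], seed=seed
            )
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(model.coeffs, beta, rtol=1e-8, atol=1e-10)

    def test_recovers_exact_sparse_target(self):
        feats = random_features(40, seed=1)
        R = np.array([f.ratio for f in feats])
        y = 2.0 * R + 5.0
        model = fit_hgb_model(
            feats, y, lambda_grid=[0.0, 1e-3, 1e-1], mixing_grid=[0.5], seed=0
        )
        assert model.penalty_lambda == 0.0
        expected = np.zeros(9)
        expected[5], expected[8] = 2.0, 5.0
        np.testing.assert_allclose(model.coeffs, expected, atol=1e-6)

    def test_large_penalty_collapses_to_intercept(self):
        feats = random_features(30, seed=2)
        y = np.random.default_rng(0).uniform(6, 14, 30)
        model = fit_hgb_model(feats, y, lambda_grid=[1e6], mixing_grid=[0.5])
        np.testing.assert_allclose(model.coeffs[:8], 0.0, atol=1e-12)
        assert model.coeffs[8] == pytest.approx(float(np.mean(y)))

    def test_seeded_selection_is_deterministic(self):
        feats = random_features(30, seed=3)
        y = np.array([f.ratio for f in feats]) * 3 + np.random.default_rng(1).normal(
            0, 0.1, 30
        )
        m1 = fit_hgb_model(feats, y, seed=11)
        m2 = fit_hgb_model(feats, y, seed=11)
        assert (m1.penalty_lambda, m1.mixing) == (m2.penalty_lambda, m2.mixing)
        assert m1.coeffs == m2.coeffs

    def test_penalty_path_shrinks_coefficients(self):
        """Shrinkage along the penalty ladder at fixed mixing.

        On the (collinear) feature library the guaranteed quantity is the
        elastic-net penalty value mix*L1 + (1-mix)/2*L2 of the standardized
        coefficients; on a well-conditioned design the plain L1 norm itself
        is also non-increasing.
        """
        mix = 0.5
        ladder = np.logspace(-4, 1, 12)

        feats = random_features(60, seed=4)
        X = feature_matrix(feats)
        y = X[:, 3] * 1.5 - X[:, 5] * 2.0 + 4.0
        penalties = []
        for lam in ladder:
            m = fit_hgb_model(feats, y, lambda_grid=[lam], mixing_grid=[mix])
            w = np.asarray(m.coeffs[:8]) * np.asarray(m.feature_scales)
            penalties.append(mix * np.abs(w).sum() + (1 - mix) / 2 * np.sum(w ** 2))
        assert all(b <= a + 1e-9 for a, b in zip(penalties, penalties[1:]))

        rng = np.random.default_rng(8)
        Xo = np.column_stack([rng.normal(size=(50, 8)), np.ones(50)])
        yo = Xo[:, 0] - 2 * Xo[:, 4] + rng.normal(0, 0.2, 50)
        l1 = []
        for lam in ladder:
            m = fit_hgb_model(Xo, yo, lambda_grid=[lam], mixing_grid=[mix])
            w = np.asarray(m.coeffs[:8]) * np.asarray(m.feature_scales)
            l1.append(np.abs(w).sum())
        assert all(b <= a + 1e-9 for a, b in zip(l1, l1[1:]))

    def test_too_few_samples_for_folds(self):
        feats = random_features(4, seed=5)
        with pytest.raises(FoldError):
            fit_hgb_model(feats, [8, 9, 10, 11], cv_folds=5)

    def test_predict_examples(self):
        intercept_only = HgbModel(
            coeffs=[0] * 8 + [12.0], penalty_lambda=0, mixing=0.5, cv_folds=5,
            feature_means=[0] * 8, feature_scales=[1] * 8,
        )
        f = random_features(1, seed=6)[0]
        assert predict_hgb(f, intercept_only) == pytest.approx(12.0)

        ratio_only = HgbModel(
            coeffs=[0, 0, 0, 0, 0, 1.0, 0, 0, 0], penalty_lambda=0, mixing=0.5,
            cv_folds=5, feature_means=[0] * 8, feature_scales=[1] * 8,
        )
        f2 = FeatureVector.from_scaled(math.exp(2.0), math.e)  # ratio 2
        assert predict_hgb(f2, ratio_only) == pytest.approx(2.0)

        ones = HgbModel(
            coeffs=[1.0] * 9, penalty_lambda=0, mixing=0.5, cv_folds=5,
            feature_means=[0] * 8, feature_scales=[1] * 8,
        )
        assert predict_hgb(np.array([4, 1, 4, 2, 1, 2, 2, 4, 1.0]), ones) == pytest.approx(21.0)

    def test_unfitted_model_rejected(self):
        with pytest.raises(NotFittedError):
            predict_hgb(random_features(1, seed=0)[0], None)


def design_with_ratio(ratios):
    X = np.zeros((len(ratios), 9))
    X[:, 5] = ratios
    X[:, 8] = 1.0
    return X


class TestSO2Model:
    def test_exact_linear_structure_recovered(self):
        rows, so2, hgb = [], [], []
        for h in range(6, 15):
            for r in (0.8, 1.0, 1.2, 1.4):
                rows.append(r)
                so2.append((2.0 * h) * r + (3.0 * h + 1.0))
                hgb.append(float(h))
        model = fit_so2_model(design_with_ratio(rows), so2, hgb)
        assert model.m_alpha == pytest.approx(2.0, abs=1e-9)
        assert model.b_alpha == pytest.approx(0.0, abs=1e-9)
        assert model.m_beta == pytest.approx(3.0, abs=1e-9)
        assert model.b_beta == pytest.approx(1.0, abs=1e-9)
        assert all(f.r2 == pytest.approx(1.0) for f in model.bin_fits)
        assert [f.hgb_center for f in model.bin_fits] == list(range(6, 15))

    def test_half_gdl_ties_assigned_to_lower_center(self):
        hgb = [6.5] * 4 + [7.4] * 4
        rows = [0.8, 1.0, 1.2, 1.4] * 2
        so2 = [50, 60, 70, 80] * 2
        model = fit_so2_model(design_with_ratio(rows), so2, hgb)
        assert [f.hgb_center for f in model.bin_fits] == [6, 7]

    def test_single_bin_insufficient(self):
        rows = [0.8, 1.0, 1.2, 1.4]
        so2 = [50, 60, 70, 80]
        with pytest.raises(InsufficientStructureError):
            fit_so2_model(design_with_ratio(rows), so2, [10.0] * 4)

    def test_predict_examples(self):
        passthrough = SO2Model(m_alpha=0, b_alpha=100, m_beta=0, b_beta=0)
        assert predict_so2(0.5, 10.0, passthrough) == (50.0, False)

        clamp = SO2Model(m_alpha=0, b_alpha=100, m_beta=0, b_beta=70)
        value, clamped = predict_so2(0.5, 10.0, clamp)
        assert value == 100.0 and clamped

        hand = SO2Model(m_alpha=2, b_alpha=0, m_beta=3, b_beta=1)
        assert predict_so2(2.0, 10.0, hand) == (pytest.approx(71.0), False)

    def test_unfitted_model_rejected(self):
        with pytest.raises(NotFittedError):
            predict_so2(1.0, 10.0, None)


class TestBundle:
    def test_json_round_trip_lossless(self, tmp_path, default_study):
        bundle = default_study.bundle
        again = CalibrationBundle.from_dict(bundle.to_dict())
        assert again == bundle
        path = tmp_path / "bundle.json"
        bundle.save(path)
        assert CalibrationBundle.load(path) == bundle

    def test_bundle_shape(self, default_study):
        bundle = default_study.bundle
        assert len(bundle.hgb_model.coeffs) == 9
        assert len(bundle.scalings) == 2
        assert {"m_alpha", "b_alpha", "m_beta", "b_beta"} <= set(
            vars(bundle.so2_model)
        )


class TestEndToEndRecovery:
    def test_noiseless_hgb_recovery(self, noiseless_study):
        """With noise off, held-out hemoglobin error collapses to numerics."""
        m = noiseless_study.predictions.merge(noiseless_study.bloodgas, on="sample_id")
        val = m[m["sample_id"].isin(noiseless_study.val_ids)]
        rmse = float(np.sqrt(((val["hgb_pred_gdl"] - val["hgb_gdl"]) ** 2).mean()))
        assert rmse <= 0.1

    def test_noiseless_bins_stay_linear(self, noiseless_study):
        assert all(f.r2 >= 0.99 for f in noiseless_study.bundle.so2_model.bin_fits)

    def test_predictions_use_estimated_hgb_for_correction(self, noiseless_study):
        bundle = noiseless_study.bundle
        so2m = bundle.so2_model
        from hemotrans.pipeline import features_for_windows

        feats = features_for_windows(noiseless_study.windows, bundle.scalings)
        hgb = predict_hgb_many(feats, bundle.hgb_model)
        expected = [predict_so2(f, h, so2m)[0] for f, h in zip(feats, hgb)]
        np.testing.assert_allclose(
            noiseless_study.predictions["so2_pred_pct"], expected, rtol=0, atol=1e-12
        )
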