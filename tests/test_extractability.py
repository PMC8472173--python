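"""Tests for concentration arithmetic, stepwise regression and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from caulirheo.extractability import (
    dry_to_wet,
    fit_mra,
    fold_change,
    join_tables,
    pca_supplementary,
)
from caulirheo.synthetic_data import GeneratorConfig, gen_study_dataset


class TestConcentrationArithmetic:
    def test_identity_fold_change(self):
        assert fold_change(745.2, 745.2) == 1.00

    def test_rounded_to_two_decimals(self):
        assert fold_change(1.0, 3.0) == 0.33

    def test_zero_fresh_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)

    def test_dry_to_wet_examples(self):
        assert dry_to_wet(1000.0, 90.0) == pytest.approx(100.0)
        assert dry_to_wet(745.2, 92.8) == pytest.approx(53.65, abs=0.01)
        assert dry_to_wet(500.0, 0.0) == pytest.approx(500.0)

    def test_out_of_range_water_rejected(self):
        with pytest.raises(ValueError):
            dry_to_wet(100.0, 100.0)

    @given(
        fresh=st.floats(1.0, 1e4),
        cooked=st.floats(1.0, 1e4),
        w_fresh=st.floats(0.0, 99.0),
        w_cooked=st.floats(0.0, 99.0),
    )
    def test_wet_basis_fold_change_composes(self, fresh, cooked, w_fresh, w_cooked):
        wet_ratio = dry_to_wet(cooked, w_cooked) / dry_to_wet(fresh, w_fresh)
        dm_ratio = (1 - w_cooked / 100) / (1 - w_fresh / 100)
        assert wet_ratio == pytest.approx((cooked / fresh) * dm_ratio, rel=1e-9)


def _synthetic_regression_table(n=200, noise_cv=0.0, seed=0, decouple=False):
    rng = np.random.default_rng(seed)
    era = rng.uniform(20.0, 95.0, n)
    epr = rng.uniform(600.0, 2500.0, n)
    y = 50.0 - 30.0 * era + (0.0 if decouple else 1.5) * epr
    if noise_cv > 0:
        y = y * (1 + rng.normal(0, noise_cv, n))
    return pd.DataFrame({"ERA": era, "EPR": epr, "TotSte": y})


class TestMRA:
    def test_exact_recovery_without_noise(self):
        model = fit_mra(_synthetic_regression_table(), "TotSte", split_seed=0)
        assert set(model.predictors) == {"ERA", "EPR"}
        assert model.coefficients["const"] == pytest.approx(50.0, abs=1e-6)
        assert model.coefficients["ERA"] == pytest.approx(-30.0, abs=1e-8)
        assert model.coefficients["EPR"] == pytest.approx(1.5, abs=1e-8)
        assert model.validation_r2 == pytest.approx(1.0)
        assert model.validation_mare == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery_within_two_standard_errors(self):
        table = _synthetic_regression_table(n=200, noise_cv=0.05, seed=1)
        model = fit_mra(table, "TotSte", split_seed=1)
        truth = {"const": 50.0, "ERA": -30.0, "EPR": 1.5}
        for name, true_val in truth.items():
            if name in model.coefficients and name != "const":
                err = abs(model.coefficients[name] - true_val)
                assert err <= 2 * model.standard_errors[name]

    def test_independent_predictor_mostly_excluded(self):
        kept = 0
        for seed in range(100):
            table = _synthetic_regression_table(n=60, noise_cv=0.05, seed=seed, decouple=True)
            model = fit_mra(table, "TotSte", split_seed=seed)
            kept += "EPR" in model.predictors
        assert kept <= 10  # type-I control of the stepwise entry test

    def test_validation_rows_never_influence_coefficients(self):
        table = _synthetic_regression_table(n=100, noise_cv=0.05, seed=3)
        ref = fit_mra(table, "TotSte", split_seed=7)
        # permute the responses of the held-out rows only; coefficients must not move
        from sklearn.model_selection import train_test_split

        cal, val = train_test_split(table, test_size=0.3, random_state=7)
        permuted = table.copy()
        rng = np.random.default_rng(0)
        permuted.loc[val.index, "TotSte"] = rng.permutation(val["TotSte"].to_numpy())
        alt = fit_mra(permuted, "TotSte", split_seed=7)
        assert alt.coefficients == ref.coefficients

    def test_deterministic_under_split_seed(self):
        table = _synthetic_regression_table(n=80, noise_cv=0.05, seed=5)
        a = fit_mra(table, "TotSte", split_seed=11)
        b = fit_mra(table, "TotSte", split_seed=11)
        assert a.coefficients == b.coefficients

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_mra(_synthetic_regression_table(n=8), "TotSte")


class TestStudyRoundTrip:
    def test_noiseless_study_recovers_link_exactly(self):
        cfg = GeneratorConfig(seed=3, noise_cv_descriptor=0.0, noise_cv_chemistry=0.0)
        study = gen_study_dataset(cfg)
        joined = join_tables(study.specimens, study.descriptors)
        a, b_era, b_epr = study.truth["link"]["TotSte"]
        model = fit_mra(joined, "TotSte", split_seed=0)
        assert model.coefficients["const"] == pytest.approx(a, rel=1e-9)
        assert model.coefficients["ERA"] == pytest.approx(b_era, rel=1e-9)
        assert model.coefficients["EPR"] == pytest.approx(b_epr, rel=1e-9)


def _pca_table(n=60, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(n)
    return pd.DataFrame(
        {
            "a": base,
            "b": 2.0 * base + 1.0,  # perfectly correlated with a
            "c": rng.standard_normal(n),
            "d": rng.standard_normal(n),
            "a_copy": base,
        }
    )


class TestPCA:
    def test_eigenvalues_sum_to_active_count_and_nonincreasing(self):
        res = pca_supplementary(_pca_table(), ("a", "b", "c", "d"))
        assert res.eigenvalues.sum() == pytest.approx(4.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_scores_centered_and_components_orthonormal(self):
        res = pca_supplementary(_pca_table(), ("a", "b", "c", "d"))
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-12)
        gram = res.components.T @ res.components
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_supplementary_duplicate_gets_active_loadings(self):
        res = pca_supplementary(_pca_table(), ("a", "b", "c", "d"), ("a_copy",))
        assert np.allclose(
            res.supplementary.loc["a_copy"].to_numpy(),
            res.loadings.loc["a"].to_numpy(),
            atol=1e-8,
        )

    def test_perfectly_correlated_pair_share_leading_loading_magnitude(self):
        res = pca_supplementary(_pca_table(), ("a", "b", "c", "d"))
        assert abs(res.loadings.loc["a", "PC1"]) == pytest.approx(
            abs(res.loadings.loc["b", "PC1"]), abs=1e-10
        )

    def test_constant_column_rejected_by_name(self):
        table = _pca_table()
        table["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            pca_supplementary(table, ("a", "b", "flat"))
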