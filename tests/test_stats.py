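"""Chamber comparisons and the random-intercept mixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import chamberflux as cf
from chamberflux.stats import (
    LMESpec,
    fit_metabolic_lme,
    residual_diagnostics,
    select_model,
)


class TestCompareChambers:
    def test_identical_vectors_paired(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = cf.compare_chambers(x, x, design="paired")
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.mean_diff == 0.0

    def test_paired_recovers_constant_shift(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 2, size=12)
        res = cf.compare_chambers(x + 1.5, x, design="paired")
        assert res.mean_diff == pytest.approx(1.5)

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(42)
        rejections = []
        for shift in (0.0, 0.5, 1.5):
            hits = 0
            for _ in range(300):
                a = rng.normal(0, 1, 15)
                b = rng.normal(shift, 1, 15)
                if cf.compare_chambers(a, b).p < 0.05:
                    hits += 1
            rejections.append(hits / 300)
        assert rejections[0] < rejections[1] < rejections[2]

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="two observations"):
            cf.compare_chambers([1.0], [2.0, 3.0])

    def test_paired_requires_matched_lengths(self):
        with pytest.raises(ValueError, match="matched"):
            cf.compare_chambers([1, 2, 3], [1, 2], design="paired")


def _simulate_mixed(alpha, betas, day_sd, resid_sd, n_per_cell, n_days, rng):
    """Small generative draw: cell mean + day intercept + residual."""
    species = list(betas)
    rows = []
    for day in range(n_days):
        b = rng.normal(0, day_sd)
        for sp in species:
            for _ in range(n_per_cell):
                rows.append(
                    {"species": sp, "day": day,
                     "value": alpha + betas[sp] + b + rng.normal(0, resid_sd)}
                )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_noiseless_fixed_effects_recovered_exactly(self):
        rng = np.random.default_rng(1)
        data = _simulate_mixed(5.0, {"a": 0.0, "b": 2.0, "c": -1.0},
                             day_sd=0.0, resid_sd=0.0, n_per_cell=4, n_days=3,
                             rng=rng)
        res = fit_metabolic_lme(
            data, LMESpec(response="value", fixed=("species",), group="day",
                          reference={"species": "a"})
        )
        assert res.params.iloc[0] == pytest.approx(5.0, abs=1e-6)
        labels = {n: v for n, v in res.params.items()}
        b_term = [n for n in labels if n.endswith("[T.b]")][0]
        c_term = [n for n in labels if n.endswith("[T.c]")][0]
        assert labels[b_term] == pytest.approx(2.0, abs=1e-6)
        assert labels[c_term] == pytest.approx(-1.0, abs=1e-6)

    def test_reference_rotation_leaves_fitted_values_unchanged(self):
        rng = np.random.default_rng(2)
        data = _simulate_mixed(3.0, {"a": 0.0, "b": 1.0, "c": 2.0},
                             day_sd=0.3, resid_sd=0.5, n_per_cell=5, n_days=4,
                             rng=rng)
        fits = {}
        for ref in ("a", "b"):
            res = fit_metabolic_lme(
                data, LMESpec(response="value", fixed=("species",), group="day",
                              reference={"species": ref})
            )
            fits[ref] = np.asarray(res.fittedvalues)
        assert np.allclose(fits["a"], fits["b"], atol=1e-5)

    def test_zero_noise_degenerates_to_least_squares_oracle(self):
        """With no day or residual variance the fit equals the normal equations."""
        rng = np.random.default_rng(3)
        data = _simulate_mixed(1.0, {"a": 0.0, "b": 4.0},
                             day_sd=0.0, resid_sd=0.0, n_per_cell=3, n_days=2,
                             rng=rng)
        X = np.column_stack(
            [np.ones(len(data)), (data["species"] == "b").astype(float)]
        )
        beta_ols, *_ = np.linalg.lstsq(X, data["value"].to_numpy(), rcond=None)
        res = fit_metabolic_lme(
            data, LMESpec(response="value", fixed=("species",), group="day",
                          reference={"species": "a"})
        )
        assert np.allclose(res.params.to_numpy(), beta_ols, atol=1e-6)

    def test_single_day_refused(self):
        rng = np.random.default_rng(4)
        data = _simulate_mixed(1.0, {"a": 0.0, "b": 1.0}, 0.0, 0.1, 4, 1, rng)
        with pytest.raises(ValueError, match="2 levels"):
            fit_metabolic_lme(
                data, LMESpec(response="value", fixed=("species",), group="day")
            )

    def test_constant_factor_refused(self):
        rng = np.random.default_rng(5)
        data = _simulate_mixed(1.0, {"a": 0.0}, 0.0, 0.1, 4, 3, rng)
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_metabolic_lme(
                data, LMESpec(response="value", fixed=("species",), group="day")
            )

    def test_incomplete_rows_dropped_with_report(self):
        rng = np.random.default_rng(6)
        data = _simulate_mixed(1.0, {"a": 0.0, "b": 1.0}, 0.1, 0.3, 4, 3, rng)
        data.loc[0, "value"] = np.nan
        with pytest.warns(UserWarning, match="incomplete"):
            res = fit_metabolic_lme(
                data, LMESpec(response="value", fixed=("species",), group="day")
            )
        assert res.n_obs == len(data) - 1

    def test_variance_components_nonnegative_and_residual_identity(self):
        rng = np.random.default_rng(7)
        data = _simulate_mixed(2.0, {"a": 0.0, "b": 1.0}, 0.4, 0.6, 5, 5, rng)
        res = fit_metabolic_lme(
            data, LMESpec(response="value", fixed=("species",), group="day")
        )
        assert res.group_var >= 0
        assert res.resid_var >= 0
        recon = np.asarray(res.fittedvalues) + np.asarray(res.residuals)
        assert np.allclose(recon, data["value"].to_numpy())


class TestModelSelection:
    def test_equal_models_give_zero_lr(self):
        rng = np.random.default_rng(8)
        data = _simulate_mixed(1.0, {"a": 0.0, "b": 1.0}, 0.2, 0.4, 5, 4, rng)
        spec = LMESpec(response="value", fixed=("species",), group="day")
        res = select_model(data, spec, spec)
        assert res.lr == pytest.approx(0.0, abs=1e-6)
        assert res.df == 0
        assert res.p == 1.0

    def test_non_nested_pair_rejected(self):
        full = LMESpec(response="value", fixed=("species",), group="day")
        reduced = LMESpec(response="value", fixed=("site",), group="day")
        with pytest.raises(ValueError, match="nested"):
            select_model(pd.DataFrame(), full, reduced)

    def test_null_lr_behaves_like_chi_square(self):
        """Under a true null extra factor, LR ~ chi2(1) to Monte-Carlo accuracy."""
        rng = np.random.default_rng(9)
        lrs = []
        for _ in range(200):
            data = _simulate_mixed(1.0, {"a": 0.0, "b": 1.0}, 0.3, 0.5, 3, 5, rng)
            # a second factor with no effect
            data["site"] = rng.permutation(
                np.tile(["n", "s"], len(data) // 2)
            )
            full = LMESpec(response="value", fixed=("species", "site"), group="day")
            reduced = LMESpec(response="value", fixed=("species",), group="day")
            lrs.append(select_model(data, full, reduced).lr)
        lrs = np.asarray(lrs)
        # mean of chi2(1) is 1; upper tail mass near nominal
        assert lrs.mean() == pytest.approx(1.0, abs=0.35)
        tail = (lrs > sps.chi2.ppf(0.95, 1)).mean()
        assert 0.01 <= tail <= 0.12

    def test_detects_a_real_effect(self):
        rng = np.random.default_rng(10)
        data = _simulate_mixed(1.0, {"a": 0.0, "b": 3.0}, 0.2, 0.4, 5, 5, rng)
        full = LMESpec(response="value", fixed=("species",), group="day")
        reduced_data = data.assign(dummy="x")
        # intercept-only reduced model: drop the species factor
        reduced = LMESpec(response="value", fixed=(), group="day")
        res = select_model(data, full, reduced)
        assert res.p < 1e-4


class TestDiagnostics:
    def test_advisory_table_shape(self):
        rng = np.random.default_rng(11)
        data = _simulate_mixed(1.0, {"a": 0.0, "b": 1.0}, 0.2, 0.4, 5, 4, rng)
        res = fit_metabolic_lme(
            data, LMESpec(response="value", fixed=("species",), group="day")
        )
        diag = residual_diagnostics(res, data)
        assert {"check", "statistic", "p"} <= set(diag.columns)
        assert (diag["check"] == "shapiro_wilk_residuals").any()
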