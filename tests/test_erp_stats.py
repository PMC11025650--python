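"""Mixed-model estimation, nested comparison, and FDR correction.

The bespoke profiled-likelihood solver is cross-checked against statsmodels
MixedLM (ML, variance-components formulation) as an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sgn400 import (ErpGeneratorSpec, assemble_trials, compare_models,
                    draw_predictors, fdr_correct, fit_mixed_model,
                    generate_erp_trials)
from sgn400.erp_stats import (FixedEffect, MixedModelResult,
                              fit_mixed_model_statsmodels)


@pytest.fixture(scope="module")
def small_trials():
    spec = ErpGeneratorSpec(n_subjects=8, n_words=40, seed=3)
    erp, latents = generate_erp_trials(spec)
    trials, _ = assemble_trials(erp, latents["predictors"], standardize=False)
    return trials


class TestAssembleTrials:
    def test_su_negated_before_standardization(self):
        erp = pd.DataFrame({"subject": ["s0", "s0"], "word": ["w0", "w1"],
                            "n400": [1.0, 2.0], "baseline": [0.1, -0.1]})
        pred = pd.DataFrame({"word": ["w0", "w1"], "su": [0.3, 0.6]})
        trials, _ = assemble_trials(erp, pred, standardize=False)
        assert trials["su"].tolist() == [-0.3, -0.6]

    def test_zscoring(self):
        erp = pd.DataFrame({"subject": ["s0"] * 4, "word": list("abcd"),
                            "n400": [1.0, 2, 3, 4], "baseline": [0.1, 2, -3, 1]})
        pred = pd.DataFrame({"word": list("abcd"), "su": [0.1, 0.4, 0.2, 0.9],
                             "surprisal": [1.0, 3, 2, 5]})
        trials, meta = assemble_trials(erp, pred, standardize=True)
        for col in ("su", "surprisal", "baseline"):
            assert abs(trials[col].mean()) < 1e-9
            assert abs(trials[col].std(ddof=0) - 1) < 1e-9
        assert meta["standardized"]

    def test_unmatched_rows_dropped_and_counted(self, caplog):
        erp = pd.DataFrame({"subject": ["s0"] * 3, "word": ["a", "b", "zz"],
                            "n400": [1.0, 2, 3], "baseline": [0.0, 0, 0]})
        pred = pd.DataFrame({"word": ["a", "b"], "su": [0.1, 0.2]})
        trials, meta = assemble_trials(erp, pred)
        assert len(trials) == 2
        assert meta["n_dropped"] == 1

    def test_no_matches_is_error(self):
        erp = pd.DataFrame({"subject": ["s0"], "word": ["zz"],
                            "n400": [1.0], "baseline": [0.0]})
        pred = pd.DataFrame({"word": ["a"], "su": [0.1]})
        with pytest.raises(ValueError):
            assemble_trials(erp, pred)


class TestFitMixedModel:
    def test_noise_free_recovery_is_exact(self):
        spec = ErpGeneratorSpec(n_subjects=5, n_words=30, sd_subject=0,
                                sd_subject_slope_su=0, sd_word=0, sd_resid=0,
                                seed=2)
        erp, latents = generate_erp_trials(spec)
        trials, _ = assemble_trials(erp, latents["predictors"])
        res = fit_mixed_model(trials, fixed=("su", "surprisal"), random_slopes=())
        assert abs(res.fixed["baseline"].beta - spec.beta_baseline) <= 1e-6
        assert abs(res.fixed["su"].beta - spec.beta_su) <= 1e-6
        assert abs(res.fixed["surprisal"].beta - spec.beta_surprisal) <= 1e-6

    def test_agrees_with_statsmodels_oracle(self, small_trials):
        ours = fit_mixed_model(small_trials, fixed=("su", "surprisal"),
                               random_slopes=("su",))
        sm = fit_mixed_model_statsmodels(small_trials, fixed=("su", "surprisal"),
                                         random_slopes=("su",))
        assert abs(ours.llf - sm.llf) < 1e-3
        sm_betas = dict(zip(sm.model.exog_names, sm.fe_params))
        assert abs(ours.fixed["intercept"].beta - sm_betas["Intercept"]) < 1e-4
        for name in ("baseline", "su", "surprisal"):
            assert abs(ours.fixed[name].beta - sm_betas[name]) < 1e-4

    def test_constant_predictor_raises_named_error(self, small_trials):
        trials = small_trials.copy()
        trials["su"] = 1.0
        with pytest.raises(ValueError, match="su"):
            fit_mixed_model(trials, fixed=("su",), random_slopes=())

    def test_too_few_levels_rejected(self, small_trials):
        one_subj = small_trials[small_trials["subject"] == "s0"]
        with pytest.raises(ValueError):
            fit_mixed_model(one_subj, fixed=("su",))

    def test_aic_loglik_identity(self, small_trials):
        res = fit_mixed_model(small_trials, fixed=("su",), random_slopes=())
        assert np.isclose(res.aic, 2 * res.n_params - 2 * res.llf)

    def test_random_effect_variances_nonnegative(self, small_trials):
        res = fit_mixed_model(small_trials, fixed=("su",), random_slopes=("su",))
        assert all(v >= 0 for v in res.re_var.values())
        assert set(res.re_var) == {"subject", "word", "subject_slope:su"}


def _dummy_result(llf, k, n=100, fixed=("su",)):
    return MixedModelResult(
        fixed={name: FixedEffect(0.0, 1.0, 0.0, 1.0) for name in fixed},
        llf=llf, aic=2 * k - 2 * llf, n_params=k, n_obs=n, sigma2=1.0,
        re_var={}, converged=True, fallback=None)


class TestCompareModels:
    def test_equal_loglik_one_extra_parameter(self):
        m0 = _dummy_result(-50.0, 5, fixed=("su",))
        m1 = _dummy_result(-50.0, 6, fixed=("su", "surprisal"))
        cmp = compare_models(m0, m1)
        assert cmp.chi2 == 0.0
        assert cmp.p == 1.0
        assert np.isclose(cmp.delta_aic, -2.0)

    def test_chi2_clipped_at_zero(self):
        m0 = _dummy_result(-49.0, 5)
        m1 = _dummy_result(-49.5, 6, fixed=("su", "surprisal"))
        assert compare_models(m0, m1).chi2 == 0.0

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_models(_dummy_result(-50.0, 5, n=99),
                           _dummy_result(-50.0, 6, n=100,
                                         fixed=("su", "surprisal")))

    def test_non_nested_rejected(self):
        m0 = _dummy_result(-50.0, 5, fixed=("surprisal",))
        m1 = _dummy_result(-50.0, 6, fixed=("su",))
        with pytest.raises(ValueError):
            compare_models(m0, m1)


def _bh_oracle(p, alpha):
    """Exhaustive Benjamini-Hochberg step-up on a small vector."""
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestFdr:
    def test_hand_worked_example(self):
        p = [0.01, 0.02, 0.03, 0.04]
        _, reject = fdr_correct(p, alpha=0.05)
        assert reject.all()

    def test_single_p_reduces_to_raw_threshold(self):
        _, reject = fdr_correct([0.04], alpha=0.05)
        assert reject.all()

    def test_all_half_none_rejected(self):
        _, reject = fdr_correct([0.5] * 6, alpha=0.05)
        assert not reject.any()

    def test_empty_input(self):
        p_adj, reject = fdr_correct([])
        assert p_adj.size == 0 and reject.size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.sampled_from([0.01, 0.05, 0.1]))
    @settings(max_examples=150, deadline=None)
    def test_matches_step_up_oracle(self, pvals, alpha):
        p = np.array(pvals)
        _, reject = fdr_correct(p, alpha=alpha)
        np.testing.assert_array_equal(reject, _bh_oracle(p, alpha))
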