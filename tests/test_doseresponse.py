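"""4PL fitting, EC50/EF50 extraction, F-test comparison, fold sensitivity."""

import numpy as np
import pytest

from asipipe import (
    DoseResponseDataset,
    DoseResponseTruth,
    compare_ec50_f_test,
    ec50,
    fit_4pl,
    fit_flow_response,
    fold_sensitivity,
    four_pl,
    generate_dose_response,
    round_to_1_significant,
)

TRUE = dict(bottom=0.5, top=0.75, ec50=17.0, hill=1.0)


def _noise_free(n_per_dose=5, **kw):
    truth = DoseResponseTruth(noise_sd=0.0, n_cells_per_dose=n_per_dose,
                              **{**TRUE, **kw})
    return generate_dose_response(truth)


class TestFit4PL:
    def test_noise_free_parameter_recovery(self):
        fit = fit_4pl(_noise_free())
        for name in ("bottom", "top", "ec50", "hill"):
            assert getattr(fit, name) == pytest.approx(TRUE[name], rel=1e-3)
        assert fit.converged
        assert fit.dof == fit.n_obs - 4

    def test_linear_and_log_parameterizations_agree(self):
        ds = _noise_free()
        a = fit_4pl(ds, parameterization="log")
        b = fit_4pl(ds, parameterization="linear")
        assert b.ec50 == pytest.approx(a.ec50, rel=1e-6)

    def test_flat_data_flagged_unidentifiable(self):
        ds = DoseResponseDataset(dose=np.repeat([0, 1, 10, 100], 5),
                                 response=np.full(20, 0.5))
        fit = fit_4pl(ds)
        assert not fit.converged
        assert fit.top == pytest.approx(fit.bottom)

    def test_too_few_distinct_doses_rejected(self):
        ds = DoseResponseDataset(dose=np.repeat([0, 1, 10], 5),
                                 response=np.linspace(0.5, 0.7, 15))
        with pytest.raises(ValueError, match="distinct doses"):
            fit_4pl(ds)

    def test_noisy_ec50_within_twenty_percent(self):
        truth = DoseResponseTruth(noise_sd=0.02, n_cells_per_dose=100, seed=5,
                                  **TRUE)
        fit = fit_4pl(generate_dose_response(truth))
        assert abs(fit.ec50 - TRUE["ec50"]) / TRUE["ec50"] < 0.2

    def test_ec50_bias_small_at_assay_design(self):
        # 8 doses, ~100 cells/dose: mean fitted EC50 within 10% of truth
        fits = []
        for seed in range(200):
            truth = DoseResponseTruth(noise_sd=0.03, n_cells_per_dose=100,
                                      seed=seed, **TRUE)
            fits.append(fit_4pl(generate_dose_response(truth)).ec50)
        bias = abs(np.mean(fits) - TRUE["ec50"]) / TRUE["ec50"]
        assert bias < 0.10


class TestEc50Extraction:
    def test_midpoint_identity(self):
        fit = fit_4pl(_noise_free())
        assert four_pl(fit.ec50, fit.bottom, fit.top, fit.ec50, fit.hill) == \
            pytest.approx(0.5 * (fit.top + fit.bottom))
        assert ec50(fit) == fit.ec50

    def test_symmetry_for_unit_hill(self):
        b, t, e = 0.5, 0.75, 17.0
        for x in (2.0, 5.0, 13.0):
            left = four_pl(e * x, b, t, e, 1.0) - b
            right = t - four_pl(e / x, b, t, e, 1.0)
            assert left == pytest.approx(right)

    def test_unconverged_fit_rejected(self):
        ds = DoseResponseDataset(dose=np.repeat([0, 1, 10, 100], 5),
                                 response=np.full(20, 0.5))
        with pytest.raises(ValueError, match="unconverged"):
            ec50(fit_4pl(ds))


class TestFlowResponse:
    # shear-stress magnitudes spanning the assayed range (dyn/cm^2)
    SS_GRID = (0.0, 0.05, 0.4, 2.0, 4.0, 19.0, 40.0)

    def test_ef50_recovered_noise_free(self):
        truth = DoseResponseTruth(bottom=0.50, top=0.62, ec50=2.8, hill=2.0,
                                  doses=self.SS_GRID, noise_sd=0.0,
                                  n_cells_per_dose=20, axis="shear")
        fit = fit_flow_response(generate_dose_response(truth))
        assert fit.ef50 == pytest.approx(2.8, rel=1e-3)
        assert fit.axis == "shear"

    def test_saturation_at_high_shear(self):
        truth = DoseResponseTruth(bottom=0.50, top=0.62, ec50=2.8, hill=2.0,
                                  doses=self.SS_GRID, noise_sd=0.0,
                                  n_cells_per_dose=20, axis="shear")
        fit = fit_flow_response(generate_dose_response(truth))
        for ss in (19.0, 40.0):
            assert fit.predict(ss) == pytest.approx(fit.top, abs=0.01)

    def test_flat_flow_data_flagged(self):
        ds = DoseResponseDataset(dose=np.repeat(self.SS_GRID, 3),
                                 response=np.full(21, 0.5), axis="shear")
        assert not fit_flow_response(ds).converged


class TestFTest:
    def _pair(self, ec50_b, noise, seed):
        d1 = generate_dose_response(DoseResponseTruth(
            noise_sd=noise, n_cells_per_dose=50, seed=seed, condition="a", **TRUE))
        kw = {**TRUE, "ec50": ec50_b}
        d2 = generate_dose_response(DoseResponseTruth(
            noise_sd=noise, n_cells_per_dose=50, seed=seed + 10_000,
            condition="b", **kw))
        return d1, d2

    def test_self_comparison_f_zero(self):
        d1, _ = self._pair(17.0, 0.02, 1)
        twin = DoseResponseDataset(d1.dose.copy(), d1.response.copy(), "a2")
        with pytest.warns(UserWarning, match="identical"):
            cmp = compare_ec50_f_test([d1, twin])
        assert cmp.f_stat == pytest.approx(0.0, abs=1e-6)
        assert cmp.p_value == pytest.approx(1.0, abs=1e-6)

    def test_thirtyfold_separation_detected(self):
        d1, d2 = self._pair(510.0, 0.01, 2)
        cmp = compare_ec50_f_test([d1, d2])
        assert cmp.p_value < 1e-4

    def test_nested_inequality_and_dof(self):
        for seed in range(5):
            d1, d2 = self._pair(30.0, 0.05, seed)
            cmp = compare_ec50_f_test([d1, d2])
            assert cmp.sse_null >= cmp.sse_alt
            assert cmp.f_stat >= 0
            assert cmp.df_num == 1
            assert cmp.df_den == d1.n_obs + d2.n_obs - 8

    def test_null_rejection_rate_near_alpha(self):
        # quick null calibration; the full 500-replicate version runs in the
        # acceptance suite
        rejections = sum(
            compare_ec50_f_test(self._pair(17.0, 0.03, seed)).p_value < 0.05
            for seed in range(60)
        )
        assert rejections <= 9  # binomial(60, 0.05) upper tail

    def test_single_dataset_rejected(self):
        d1, _ = self._pair(17.0, 0.02, 3)
        with pytest.raises(ValueError):
            compare_ec50_f_test([d1])


class TestFoldSensitivity:
    def test_static_vs_flow_worked_example(self):
        # static EC50s 17 (plate) and 41 (device) pg/mL vs flow 0.5-0.7 pg/mL
        fs = fold_sensitivity([17.0, 41.0], [0.5, 0.6, 0.7])
        assert fs.fold == pytest.approx(29.0 / 0.6)
        assert fs.fold_rounded == 50.0

    def test_identical_lists_give_unity(self):
        assert fold_sensitivity([10.0], [10.0]).fold == 1.0
        assert fold_sensitivity([3.0, 5.0], [3.0, 5.0]).fold == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fold_sensitivity([], [1.0])
        with pytest.raises(ValueError):
            fold_sensitivity([1.0], [-2.0])

    @pytest.mark.parametrize("x,expected", [
        (48.33, 50.0), (0.063, 0.06), (123.0, 100.0), (2.8, 3.0),
    ])
    def test_one_significant_figure(self, x, expected):
        assert round_to_1_significant(x) == expected
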