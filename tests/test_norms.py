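"""Normative model fitting and deviation analysis."""

import datetime as dt

import numpy as np
import pytest
from scipy import stats

import perimetry as pm
from perimetry.norms import NormativeError


def _flat_cohort(grid, n=30, value=30.0, age_effect=0.0, noise=0.0,
                 seed=0):
    """Cohort with identical spatial structure at every location."""
    rng = np.random.default_rng(seed)
    fields = []
    for k in range(n):
        age = 20 + 60 * k / (n - 1)
        sens = np.full(len(grid), value + age_effect * (age - 45))
        sens = sens + rng.normal(0, noise, size=len(grid))
        sens[grid.blind_spot_mask] = np.nan
        fields.append(pm.VisualField(
            f"S{k}", "OD", dt.date(2000, 1, 1), age, 300, 0, 0, 0,
            grid.name, np.round(sens, 2)))
    return fields


class TestFit:
    def test_age_slope_recovery(self, cohort, cohort_spec, norm_model):
        """Fitted age slopes cover the generating slope in >= 90% of the
        per-location OLS 95% confidence intervals."""
        fields, _ = cohort
        ages = np.array([f.age for f in fields])
        m = len(fields)
        sxx = np.sum((ages - ages.mean()) ** 2)
        se = norm_model.residual_sd / np.sqrt(sxx)
        tcrit = stats.t.ppf(0.975, m - 2)
        truth = -cohort_spec.age_slope
        ok = np.abs(norm_model.slopes - truth) <= tcrit * se
        covered = np.mean(ok[~norm_model.blind_spot_mask])
        assert covered >= 0.90

    def test_zero_noise_cohort_degenerate_cutoffs(self, grid24):
        model = pm.fit_normative_model(_flat_cohort(grid24))
        nb = ~model.blind_spot_mask
        assert np.allclose(model.residual_sd[nb], 0.0, atol=1e-10)
        assert np.allclose(model.td_cutoffs[:, nb], 0.0, atol=1e-10)
        assert np.allclose(model.slopes[nb], 0.0, atol=1e-12)

    def test_smooth_equals_pointwise_on_homogeneous_cohort(self, grid24):
        cohort = _flat_cohort(grid24, n=40, noise=1.0, seed=3)
        pw = pm.fit_normative_model(cohort, method="pointwise")
        sm = pm.fit_normative_model(cohort, method="smooth")
        nb = ~pw.blind_spot_mask
        # smoothing averages neighbors; on a spatially exchangeable cohort
        # it only tightens dispersion around the common value
        assert np.allclose(sm.residual_sd[nb].mean(),
                           pw.residual_sd[nb].mean(), rtol=0.05)
        assert np.std(sm.td_cutoffs[3, nb]) <= np.std(pw.td_cutoffs[3, nb])

    def test_cutoffs_monotone(self, norm_model):
        nb = ~norm_model.blind_spot_mask
        assert np.all(np.diff(norm_model.td_cutoffs[:, nb], axis=0)
                      >= -1e-12)
        assert np.all(np.diff(norm_model.pd_cutoffs[:, nb], axis=0)
                      >= -1e-12)

    def test_md_weights_normalized(self, norm_model):
        nb = ~norm_model.blind_spot_mask
        w = norm_model.md_weights
        assert w[~nb].sum() == 0
        assert w[nb].sum() == pytest.approx(1.0, abs=1e-9)

    def test_validation_errors(self, grid24, cohort):
        fields, _ = cohort
        with pytest.raises(NormativeError, match=">= 20"):
            pm.fit_normative_model(fields[:10])
        dup = fields[:19] + [fields[0]]
        with pytest.raises(NormativeError, match="duplicated"):
            pm.fit_normative_model(dup + fields[19:20])
        young = [f for f in fields if f.age < 35][:25]
        if len(young) >= 20:
            with pytest.raises(NormativeError, match="span"):
                pm.fit_normative_model(young)

    def test_json_round_trip(self, norm_model, tmp_path):
        path = tmp_path / "model.json"
        norm_model.to_json(path)
        back = pm.NormativeModel.from_json(path)
        np.testing.assert_allclose(back.slopes, norm_model.slopes)
        np.testing.assert_allclose(back.td_cutoffs, norm_model.td_cutoffs)
        assert back.grid_name == norm_model.grid_name


class TestDeviations:
    def _field(self, model, sens, age=50.0):
        return pm.VisualField("x", "OD", dt.date(2020, 1, 1), age, 300,
                              0, 0, 0, model.grid_name, sens)

    def test_td_zero_at_expected(self, norm_model):
        f = self._field(norm_model, norm_model.expected(50.0))
        td = pm.total_deviation(f, norm_model)
        nb = ~norm_model.blind_spot_mask
        assert np.allclose(td[nb], 0.0, atol=1e-12)
        assert np.isnan(td[~nb]).all()

    def test_td_subtraction_and_equivariance(self, norm_model):
        base = norm_model.expected(60.0)
        f1 = self._field(norm_model, base - 8.0, age=60)
        td1 = pm.total_deviation(f1, norm_model)
        nb = ~norm_model.blind_spot_mask
        assert np.allclose(td1[nb], -8.0)
        f2 = self._field(norm_model, base - 8.0 + 3.0, age=60)
        td2 = pm.total_deviation(f2, norm_model)
        assert np.allclose(td2[nb] - td1[nb], 3.0)

    def test_grid_mismatch(self, norm_model):
        f = pm.VisualField("x", "OD", dt.date(2020, 1, 1), 50, 300, 0, 0,
                           0, "24-2-mirrored", np.zeros(54))
        with pytest.raises(NormativeError, match="grid"):
            pm.total_deviation(f, norm_model)

    def test_probability_categories(self):
        cutoffs = np.array([[-8.0], [-6.0], [-4.0], [-2.0]])
        cat = lambda v: pm.deviation_probability(np.array([v]), cutoffs)[0]
        assert cat(-9.0) == "<0.5%"
        assert cat(-5.0) == "<2%"
        assert cat(-2.0) == "normal"  # strict inequality at the cutoff
        assert cat(0.0) == "normal"
        values = np.linspace(-10, 2, 121)
        order = {lbl: k for k, lbl in enumerate(
            ("<0.5%", "<1%", "<2%", "<5%", "normal"))}
        ranks = [order[cat(v)] for v in values]
        assert ranks == sorted(ranks)  # monotone in the value

    def test_pattern_deviation_constant_td(self, norm_model):
        td = np.where(norm_model.blind_spot_mask, np.nan, -3.0)
        pd, gh = pm.pattern_deviation(td, norm_model)
        assert gh == -3.0
        assert np.allclose(pd[~norm_model.blind_spot_mask], 0.0)

    def test_pattern_deviation_translation_invariant(self, norm_model,
                                                     rng):
        nb = ~norm_model.blind_spot_mask
        td = np.where(nb, rng.normal(-2, 3, size=54), np.nan)
        pd1, _ = pm.pattern_deviation(td, norm_model)
        pd2, _ = pm.pattern_deviation(td + 5.0, norm_model)
        assert np.allclose(pd1[nb], pd2[nb])

    def test_pattern_deviation_isolates_focal_loss(self, norm_model):
        td = np.where(norm_model.blind_spot_mask, np.nan, 0.0)
        i = int(np.flatnonzero(~norm_model.blind_spot_mask)[10])
        td[i] = -15.0
        pd, gh = pm.pattern_deviation(td, norm_model)
        assert gh == 0.0
        assert pd[i] == pytest.approx(-15.0)

    def test_mean_deviation_linear(self, norm_model, rng):
        nb = ~norm_model.blind_spot_mask
        td0 = np.where(nb, 0.0, np.nan)
        assert pm.mean_deviation(td0, norm_model) == 0.0
        td = np.where(nb, rng.normal(size=54), np.nan)
        md1 = pm.mean_deviation(td, norm_model)
        md2 = pm.mean_deviation(2 * td + 1, norm_model)
        assert md2 == pytest.approx(2 * md1 + 1)

    def test_uniform_weight_example(self, grid24):
        cohort = _flat_cohort(grid24, n=30, noise=1.0, seed=5)
        model = pm.fit_normative_model(cohort, uniform_weights=True)
        nb = ~model.blind_spot_mask
        td = np.full(54, np.nan)
        idx = np.flatnonzero(nb)
        td[idx] = 0.0
        td[idx[0]], td[idx[1]] = -2.0, -4.0
        md = pm.mean_deviation(td, model)
        assert md == pytest.approx((-2.0 - 4.0) / nb.sum())

    def test_analyze_field_consistency(self, norm_model, cohort_spec):
        f = pm.synth_healthy_field(cohort_spec, age=55.0, rng=77)
        dev = pm.analyze_field(f, norm_model)
        nb = ~norm_model.blind_spot_mask
        assert np.isfinite(dev.td[nb]).all()
        assert dev.md == pytest.approx(
            pm.mean_deviation(dev.td, norm_model))
        assert len(dev.td_category) == 54
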