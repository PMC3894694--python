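"""Screening statistics: Z'-factor, AUC, 4PL dose-response, onset."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpiscreen.stats import (
    aggregate_wells,
    detect_onset,
    fit_dose_response,
    timelapse_auc,
    z_prime,
)
from qpiscreen.synth import DoseModel, PlateDesign, WellSpec


class TestZPrime:
    def test_closed_form_example(self):
        # 1 - 3*(5+5)/|100-50| = 0.4, from groups with those exact stats
        pos = np.array([95.0, 100.0, 105.0])  # mean 100, sd 5
        neg = np.array([45.0, 50.0, 55.0])  # mean 50, sd 5
        zr = z_prime(pos, neg)
        assert zr.z_prime == pytest.approx(0.4)

    def test_zero_noise_limit_is_exactly_one(self):
        zr = z_prime(np.array([7.0, 7.0, 7.0]), np.array([3.0, 3.0, 3.0]))
        assert zr.z_prime == 1.0

    def test_identical_groups_flagged_undefined(self):
        zr = z_prime(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert not zr.valid
        assert np.isnan(zr.z_prime)

    def test_needs_two_wells_per_group(self):
        with pytest.raises(ValueError):
            z_prime(np.array([1.0]), np.array([2.0, 3.0]))

    @settings(max_examples=250, deadline=None)
    @given(
        mu_p=st.floats(-1e3, 1e3),
        mu_n=st.floats(-1e3, 1e3),
        sd_p=st.floats(0, 100),
        sd_n=st.floats(0, 100),
        data=st.data(),
    )
    def test_matches_independent_closed_form(self, mu_p, mu_n, sd_p, sd_n, data):
        # construct groups with exactly the requested mean/SD, then compare
        # against a direct evaluation of 1 - 3(sd_p+sd_n)/|mu_p-mu_n|
        if abs(mu_p - mu_n) < 1e-6:
            return
        base = np.array([-1.0, 0.0, 1.0]) / np.array([-1.0, 0.0, 1.0]).std(ddof=1)
        pos = mu_p + sd_p * base
        neg = mu_n + sd_n * base
        expected = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
        zr = z_prime(pos, neg)
        assert zr.z_prime == pytest.approx(expected, abs=1e-9, rel=1e-9)
        assert zr.z_prime <= 1.0

    def test_doubling_spread_strictly_decreases_z(self):
        rng = np.random.default_rng(0)
        pos = 100 + rng.normal(0, 2, 12)
        neg = 50 + rng.normal(0, 2, 12)
        narrow = z_prime(pos, neg).z_prime
        wide = z_prime(
            100 + 2 * (pos - 100), 50 + 2 * (neg - 50)
        ).z_prime
        assert wide < narrow


class TestAggregateWells:
    def _design(self):
        wells = [
            WellSpec("A01", "hela", "doxorubicin", 30.0, 0),
            WellSpec("A02", "hela", "doxorubicin", 0.0, 0),
        ]
        return PlateDesign(wells, fields_per_well=4, field_size=(64, 64))

    def test_well_mean_of_four_fields(self):
        df = pd.DataFrame(
            {
                "well": ["A01"] * 4 + ["A02"],
                "field": [0, 1, 2, 3, 0],
                "average_opd": [1.0, 2.0, 3.0, 4.0, 7.0],
            }
        )
        out = aggregate_wells(df, self._design())
        a01 = out.loc[out.well == "A01"].iloc[0]
        assert a01["average_opd"] == pytest.approx(2.5)
        assert a01["n_fields"] == 4
        # single-field well: the mean is that field
        assert out.loc[out.well == "A02", "average_opd"].iloc[0] == 7.0

    def test_orphan_field_raises_with_well_id(self):
        df = pd.DataFrame({"well": ["Z99"], "average_opd": [1.0]})
        with pytest.raises(ValueError, match="Z99"):
            aggregate_wells(df, self._design())


class TestTimelapseAuc:
    def test_constant_series(self):
        t = np.linspace(0, 24, 145)
        assert timelapse_auc(t, np.full(145, 3.0)) == pytest.approx(72.0)

    def test_linear_ramp(self):
        t = np.linspace(0, 24, 145)
        assert timelapse_auc(t, t / 24.0) == pytest.approx(12.0)

    def test_baseline_subtraction_zeroes_flat_series(self):
        t = np.linspace(0, 24, 25)
        auc = timelapse_auc(t, np.full(25, 5.0), baseline_subtract=True)
        assert auc == 0.0

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            timelapse_auc(np.array([0.0, 2.0, 1.0]), np.zeros(3))
        with pytest.raises(ValueError):
            timelapse_auc(np.array([1.0]), np.array([1.0]))


class TestFitDoseResponse:
    DOSES = np.array([0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0])

    def test_noise_free_recovery(self):
        true = DoseModel(0.2, 1.4, 10.0, 1.3)
        r = np.asarray(true.response(self.DOSES))
        fit = fit_dose_response(self.DOSES, r, vehicle_response=0.2)
        assert fit.converged
        assert fit.bottom == pytest.approx(0.2, abs=1e-3)
        assert fit.top == pytest.approx(1.4, rel=1e-3)
        assert fit.ec50_um == pytest.approx(10.0, rel=1e-3)
        assert fit.hill == pytest.approx(1.3, rel=1e-3)

    def test_flat_responses_flagged_nonconvergent(self):
        fit = fit_dose_response(self.DOSES, np.full(8, 0.5))
        assert not fit.converged
        assert np.isnan(fit.ec50_um)

    def test_response_scaling_equivariance(self):
        true = DoseModel(0.0, 1.0, 10.0, 1.0)
        r = np.asarray(true.response(self.DOSES))
        f1 = fit_dose_response(self.DOSES, r, 0.0)
        f2 = fit_dose_response(self.DOSES, 2 * r, 0.0)
        assert f2.top == pytest.approx(2 * f1.top, rel=1e-6)
        assert f2.bottom == pytest.approx(2 * f1.bottom, abs=1e-6)
        assert f2.ec50_um == pytest.approx(f1.ec50_um, rel=1e-6)

    def test_nonpositive_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response(np.array([0.0, 1.0]), np.array([0.1, 0.9]))

    def test_median_ec50_error_under_well_level_noise(self):
        # 100 seeded screens at the well-level noise scale of the synthetic
        # plates (~4% of the response span)
        rng = np.random.default_rng(7)
        errors = []
        for k in range(100):
            true = DoseModel(
                0.0, 1.0, float(10 ** rng.uniform(0, 1.5)),
                float(rng.uniform(0.8, 2.0)),
            )
            noisy = np.asarray(true.response(self.DOSES)) + rng.normal(
                0, 0.04, self.DOSES.size
            )
            fit = fit_dose_response(
                self.DOSES, noisy, float(rng.normal(0, 0.04)), seed=k
            )
            if fit.converged:
                errors.append(abs(fit.ec50_um - true.ec50_um) / true.ec50_um)
        assert len(errors) >= 95
        assert np.median(errors) < 0.10

    def test_summary_mentions_parameters(self):
        true = DoseModel(0.0, 1.0, 10.0, 1.0)
        fit = fit_dose_response(
            self.DOSES, np.asarray(true.response(self.DOSES)), 0.0
        )
        text = fit.summary()
        assert "EC50" in text and "hill" in text


class TestDetectOnset:
    def _series(self, onset_h, step=1.0, noise_sd=0.01, seed=0, duration=8.0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, duration + 1e-9, 1 / 6)  # 10-min sampling
        v = rng.normal(0, noise_sd, t.size)
        v[t >= onset_h] += step
        return t, v

    def test_clean_step_recovered_within_one_frame(self):
        t, v = self._series(onset_h=4.0, step=0.1, noise_sd=0.01)
        onset = detect_onset(t, v, baseline_window_h=2.0)
        assert onset == pytest.approx(4.0, abs=1 / 6 + 1e-9)

    def test_flat_series_returns_none(self):
        t, v = self._series(onset_h=100.0)
        assert detect_onset(t, v, baseline_window_h=2.0) is None

    def test_deviation_at_first_candidate_point(self):
        # response already present at the first post-baseline frame
        t = np.arange(0, 4 + 1e-9, 1 / 6)
        v = np.where(t <= 1.0, 0.0, 5.0) + np.sin(t) * 1e-6
        onset = detect_onset(t, v, baseline_window_h=1.0, k_sd=3.0)
        assert onset == pytest.approx(t[t > 1.0][0])

    def test_decreasing_direction(self):
        t, v = self._series(onset_h=3.0, step=-0.5)
        onset = detect_onset(t, v, baseline_window_h=1.5, direction="decrease")
        assert onset == pytest.approx(3.0, abs=1 / 6 + 1e-9)

    def test_zero_variance_baseline_uses_absolute_tolerance(self):
        t = np.arange(0, 6 + 1e-9, 1 / 6)
        v = np.where(t >= 2.0, 1.0, 0.0)
        onset = detect_onset(t, v, baseline_window_h=1.0, abs_tol=0.5)
        assert onset == pytest.approx(2.0)

    def test_transient_blip_shorter_than_m_is_ignored(self):
        t = np.arange(0, 6 + 1e-9, 1 / 6)
        rng = np.random.default_rng(1)
        v = rng.normal(0, 0.01, t.size)
        v[20] += 1.0  # single-frame excursion
        assert detect_onset(t, v, baseline_window_h=2.0, m_consecutive=3) is None
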