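"""Latency extraction, quartile summaries, Weibull fits, hazard classes."""

import math

import numpy as np
import pytest
from scipy import stats

from pvsignal.event_dictionary import PtSet
from pvsignal.srs_store import filter_suspected
from pvsignal.synthetic_srs import DEFAULT_DIG_PTS, default_config, generate
from pvsignal.time_to_onset import (
    HazardClass,
    WeibullFit,
    classify_hazard,
    compute_durations,
    fit_weibull,
    summarize_times,
)

from conftest import make_db

ILEUS = PtSet("ileus", ("Ileus",))


def _one_report_db(start, onset, involvement="suspected"):
    return make_db(
        demo_rows=[{"report_id": "R1", "sex": "", "age_band": "", "reporting_year": ""}],
        drug_rows=[{"report_id": "R1", "drug_name": "loperamide", "involvement": involvement,
                    "route": "", "start_date": start, "end_date": ""}],
        reac_rows=[{"report_id": "R1", "pt_name": "Ileus", "onset_date": onset, "outcome": ""}],
    )


class TestComputeDurations:
    def test_calendar_arithmetic(self):
        ds = compute_durations(_one_report_db("20200101", "20200103"), ["loperamide"], ILEUS)
        assert len(ds) == 1 and ds.durations[0].days == 2

    def test_onset_before_start_excluded_and_tallied(self):
        ds = compute_durations(_one_report_db("20200110", "20200103"), ["loperamide"], ILEUS)
        assert len(ds) == 0 and ds.exclusions["negative"] == 1

    @pytest.mark.parametrize("start,onset", [("202001", "20200103"), ("20200101", "2020"), ("", "20200103")])
    def test_incomplete_dates_excluded_and_tallied(self, start, onset):
        ds = compute_durations(_one_report_db(start, onset), ["loperamide"], ILEUS)
        assert len(ds) == 0 and ds.exclusions["incomplete_date"] == 1

    def test_window_boundary(self):
        inside = compute_durations(_one_report_db("20200101", "20200331"), ["loperamide"], ILEUS)
        assert len(inside) == 1 and inside.durations[0].days == 90
        beyond = compute_durations(_one_report_db("20200101", "20200401"), ["loperamide"], ILEUS)
        assert len(beyond) == 0 and beyond.exclusions["beyond_window"] == 1

    def test_earliest_start_of_duplicated_drug_row_is_anchor(self):
        db = make_db(
            demo_rows=[{"report_id": "R1", "sex": "", "age_band": "", "reporting_year": ""}],
            drug_rows=[
                {"report_id": "R1", "drug_name": "loperamide", "involvement": "suspected",
                 "route": "", "start_date": "20200110", "end_date": ""},
                {"report_id": "R1", "drug_name": "loperamide", "involvement": "suspected",
                 "route": "", "start_date": "20200101", "end_date": ""},
            ],
            reac_rows=[{"report_id": "R1", "pt_name": "Ileus", "onset_date": "20200111", "outcome": ""}],
        )
        ds = compute_durations(db, ["loperamide"], ILEUS)
        assert [d.days for d in ds.durations] == [10]

    def test_non_suspected_rows_ignored(self):
        ds = compute_durations(_one_report_db("20200101", "20200103", involvement="concomitant"),
                               ["loperamide"], ILEUS)
        assert len(ds) == 0

    def test_retained_count_matches_generator_bookkeeping(self):
        cfg = default_config(seed=13, n_reports=20_000)
        db, truth = generate(cfg)
        sus = filter_suspected(db)
        dig = PtSet("dig", DEFAULT_DIG_PTS)
        for spec in cfg.drugs:
            ds = compute_durations(sus, [spec.name], dig)
            assert len(ds) == truth.complete_in_window[spec.name]


class TestSummarizeTimes:
    def test_singleton(self):
        s = summarize_times([2])
        assert (s.median, s.q1, s.q3) == (2.0, 2.0, 2.0)

    def test_all_zero_latencies(self):
        s = summarize_times([0] * 145)
        assert (s.median, s.q1, s.q3) == (0.0, 0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_times([])

    def test_matches_hand_coded_type7_interpolation(self):
        """Oracle: direct linear interpolation between order statistics."""
        rng = np.random.default_rng(8)

        def type7(x, p):
            x = np.sort(x)
            h = (len(x) - 1) * p
            lo = int(math.floor(h))
            hi = min(lo + 1, len(x) - 1)
            return x[lo] + (h - lo) * (x[hi] - x[lo])

        for _ in range(50):
            x = rng.integers(0, 91, size=rng.integers(1, 200)).astype(float)
            s = summarize_times(x)
            assert s.q1 == pytest.approx(type7(x, 0.25))
            assert s.median == pytest.approx(type7(x, 0.50))
            assert s.q3 == pytest.approx(type7(x, 0.75))


class TestFitWeibull:
    def test_exponential_submodel_scale_is_sample_mean(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(20.0, size=2_000)
        f = fit_weibull(x, fix_shape=1.0)
        assert f.scale_alpha == pytest.approx(float(np.mean(x)), rel=1e-9)

    def test_point_estimates_match_scipy_mle(self):
        rng = np.random.default_rng(2)
        x = 20 * rng.weibull(1.5, size=500)
        f = fit_weibull(x)
        shape, _, scale = stats.weibull_min.fit(x, floc=0)
        assert f.shape_beta == pytest.approx(shape, rel=1e-4)
        assert f.scale_alpha == pytest.approx(scale, rel=1e-4)

    def test_known_truth_recovery_with_ci_coverage(self):
        rng = np.random.default_rng(3)
        x = 20 * rng.weibull(1.5, size=1_000)
        f = fit_weibull(x)
        assert f.converged
        assert abs(f.shape_beta - 1.5) / 1.5 < 0.05
        assert f.beta_ci[0] <= 1.5 <= f.beta_ci[1]
        assert f.alpha_ci[0] <= 20 <= f.alpha_ci[1]

    @pytest.mark.parametrize("data", [[5, 7], [4.0] * 10, []])
    def test_degenerate_inputs_not_fitted(self, data):
        f = fit_weibull(data)
        assert not f.converged and f.scale_alpha is None

    def test_zero_days_shifted_not_dropped(self):
        f = fit_weibull([0, 0, 1, 2, 3, 5, 8])
        assert f.converged and f.n == 7

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        x = 10 * rng.weibull(1.2, size=400) + 1  # keep off the zero-shift
        f1, f2 = fit_weibull(x), fit_weibull(3.0 * x)
        assert f2.scale_alpha == pytest.approx(3.0 * f1.scale_alpha, rel=1e-5)
        assert f2.shape_beta == pytest.approx(f1.shape_beta, rel=1e-5)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        x = 15 * rng.weibull(1.8, size=200)
        f = fit_weibull(x, ci_method="bootstrap", n_boot=200, seed=0)
        assert f.converged
        assert f.beta_ci[0] < f.shape_beta < f.beta_ci[1]
        # deterministic under the same seed
        g = fit_weibull(x, ci_method="bootstrap", n_boot=200, seed=0)
        assert f.beta_ci == g.beta_ci


class TestClassifyHazard:
    @pytest.mark.parametrize(
        "ci,expected",
        [
            ((1.1, 1.4), HazardClass.INCREASING),
            ((0.9, 1.3), HazardClass.CONSTANT_COMPATIBLE),
            ((0.4, 0.8), HazardClass.DECREASING),
        ],
    )
    def test_ci_rule(self, ci, expected):
        fit = WeibullFit(n=50, converged=True, scale_alpha=10.0, alpha_ci=(8, 12),
                         shape_beta=sum(ci) / 2, beta_ci=ci)
        assert classify_hazard(fit) == expected

    def test_unconverged_rejected(self):
        with pytest.raises(ValueError):
            classify_hazard(WeibullFit(n=2, converged=False))
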