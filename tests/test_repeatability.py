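import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefrugosity.errors import (
    AlignmentError,
    InsufficientReplicationError,
    ParameterError,
    UndefinedStatisticError,
)
from reefrugosity.repeatability import (
    SurveySet,
    group_errors,
    quadrat_summaries,
    site_report,
    summarize_quadrat,
    survey_bias,
)


def make_set(matrix, groups=None, site="site"):
    """SurveySet from a quadrat-by-survey array."""
    matrix = np.asarray(matrix, dtype=float)
    nq, ns = matrix.shape
    groups = groups or ["multi_day"] * ns
    rows = []
    for i in range(ns):
        for j in range(nq):
            rows.append({"survey_id": f"s{i}", "quadrat_id": j, "sr": matrix[j, i]})
    manifest = pd.DataFrame(
        {"survey_id": [f"s{i}" for i in range(ns)], "group": groups}
    )
    return SurveySet(site, pd.DataFrame(rows), manifest)


class TestSummarizeQuadrat:
    def test_constant_surveys(self):
        s = summarize_quadrat([1.30, 1.30, 1.30, 1.30])
        assert s.mu == pytest.approx(1.30)
        assert s.sigma == 0.0

    def test_hand_computed_sigma(self):
        # deltas (+-0.01, +-0.02): sigma = sqrt(0.001/4) = sqrt(0.00025)
        vals = np.array([0.01, -0.01, 0.02, -0.02]) + 1.5
        s = summarize_quadrat(vals)
        assert s.mu == pytest.approx(1.5)
        assert s.sigma == pytest.approx(np.sqrt(0.00025), rel=1e-12)
        assert s.deltas.sum() == pytest.approx(0.0, abs=1e-15)

    def test_matches_population_sd_oracle(self, rng):
        for _ in range(20):
            vals = rng.normal(1.5, 0.1, 4)
            s = summarize_quadrat(vals)
            # independent oracle: direct population sd formula
            mu = sum(vals) / len(vals)
            oracle = (sum((v - mu) ** 2 for v in vals) / len(vals)) ** 0.5
            assert s.sigma == pytest.approx(oracle, rel=1e-12)

    def test_unbiased_flag(self):
        vals = [1.0, 1.1, 1.2, 1.3]
        pop = summarize_quadrat(vals).sigma
        unb = summarize_quadrat(vals, unbiased=True).sigma
        assert unb == pytest.approx(pop * np.sqrt(4 / 3), rel=1e-12)

    def test_single_survey_raises(self):
        with pytest.raises(InsufficientReplicationError):
            summarize_quadrat([1.2])


class TestSurveyBias:
    def test_identical_surveys_zero_bias(self):
        m = np.tile(np.linspace(1.1, 1.9, 5)[:, None], (1, 4))
        biases = survey_bias(make_set(m))
        assert all(b.b == pytest.approx(0.0, abs=1e-15) for b in biases)

    def test_uniform_offset_closed_form(self):
        # one of 4 surveys uniformly +0.05: its bias is 0.05*(3/4), others -0.05/4
        m = np.tile(np.linspace(1.1, 1.9, 6)[:, None], (1, 4))
        m[:, 0] += 0.05
        biases = survey_bias(make_set(m))
        assert biases[0].b == pytest.approx(0.05 * 3 / 4, rel=1e-12)
        for b in biases[1:]:
            assert b.b == pytest.approx(-0.05 / 4, rel=1e-12)

    def test_biases_sum_to_zero(self, rng):
        m = rng.normal(1.5, 0.2, (30, 4))
        biases = survey_bias(make_set(m))
        assert sum(b.b for b in biases) == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery(self, rng):
        # injected per-survey biases ~ N(0, 0.03^2), 50 quadrats, noise 0.01:
        # recovery error bounded by ~2 SE = 2 * 0.01 / sqrt(50) < 0.004
        true_sr = rng.uniform(1.2, 2.0, 50)
        B = rng.normal(0, 0.03, 4)
        m = true_sr[:, None] + B[None, :] + rng.normal(0, 0.01, (50, 4))
        biases = survey_bias(make_set(m))
        centred = B - B.mean()
        for b, t in zip(biases, centred):
            assert b.b == pytest.approx(t, abs=0.004)

    def test_mismatched_quadrats_complete_case(self, caplog):
        df = pd.DataFrame(
            {
                "survey_id": ["a", "a", "b"],
                "quadrat_id": [0, 1, 0],
                "sr": [1.2, 1.4, 1.25],
            }
        )
        manifest = pd.DataFrame(
            {"survey_id": ["a", "b"], "group": ["multi_day", "multi_day"]}
        )
        sset = SurveySet("s", df, manifest)
        biases = survey_bias(sset)  # quadrat 1 dropped, quadrat 0 kept
        assert len(biases) == 2
        assert biases[0].b == pytest.approx(-0.025, abs=1e-12)


class TestGroupErrors:
    def test_groups_are_independent(self, rng):
        m_single = np.tile([[1.5]], (10, 2))  # identical -> sigma 0
        m_multi = 1.5 + rng.normal(0, 0.05, (10, 2))
        m = np.hstack([m_single, m_multi])
        sset = make_set(m, groups=["single_day"] * 2 + ["multi_day"] * 2)
        s_single = group_errors(sset, "single_day")
        s_multi = group_errors(sset, "multi_day")
        assert np.all(s_single["sigma"] == 0)
        assert s_multi["sigma"].mean() > 0

    def test_noisier_group_has_larger_sigma(self, rng):
        base = rng.uniform(1.2, 2.0, 40)
        m = np.hstack(
            [
                base[:, None] + rng.normal(0, 0.01, (40, 4)),
                base[:, None] + rng.normal(0, 0.05, (40, 4)),
            ]
        )
        sset = make_set(m, groups=["single_day"] * 4 + ["multi_day"] * 4)
        assert (
            group_errors(sset, "single_day")["sigma"].mean()
            < group_errors(sset, "multi_day")["sigma"].mean()
        )

    def test_missing_group_raises(self):
        sset = make_set(np.ones((4, 2)) * 1.3, groups=["multi_day"] * 2)
        with pytest.raises(InsufficientReplicationError):
            group_errors(sset, "single_day")

    def test_unknown_group_label_rejected(self):
        sset = make_set(np.ones((4, 2)))
        with pytest.raises(ParameterError):
            group_errors(sset, "weekly")


class TestSiteReport:
    def test_zero_noise_zero_percent(self):
        m = np.tile(np.linspace(1.1, 1.6, 8)[:, None], (1, 4))
        rep = site_report(make_set(m))
        assert rep.sigma_pct_of_range == 0.0
        assert rep.bias_pct_of_range == 0.0

    def test_percent_arithmetic(self):
        # mean sigma 0.05 over range 0.5 -> 10%
        m = np.array([[1.0, 1.0], [1.5, 1.5]])
        sset = make_set(m)
        rep = site_report(sset)
        assert rep.sr_range == pytest.approx(0.5)
        # direct check of the formula on a constructed report
        assert rep.sigma_pct_of_range == pytest.approx(
            100 * rep.mean_sigma / rep.sr_range
        )

    def test_zero_range_raises(self):
        m = np.ones((5, 3)) * 1.4
        with pytest.raises(UndefinedStatisticError):
            site_report(make_set(m))

    def test_report_matches_simulation_expectation(self, rng):
        # noise sd 0.02 on true SR spanning [1.1, 2.0]: expected sigma_pct
        # ~ 100 * E[sigma_hat] / range; check within Monte Carlo slack
        true_sr = np.linspace(1.1, 2.0, 60)
        m = true_sr[:, None] + rng.normal(0, 0.02, (60, 4))
        rep = site_report(make_set(m))
        c4 = np.sqrt(2 / 4) * 1.0 / 0.8862269255  # E[sigma_hat]/sigma, N=4
        expected = 100 * 0.02 * c4 / (rep.sr_range)
        assert rep.sigma_pct_of_range == pytest.approx(expected, rel=0.25)


class TestInvariants:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_centering_and_shift_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(1.5, 0.1, (12, 4))
        sset = make_set(m)
        summ = quadrat_summaries(sset)
        biases = np.array([b.b for b in survey_bias(sset)])
        assert abs(biases.sum()) < 1e-12
        # sigma invariant / bias equivariant under adding a constant to one survey
        m2 = m.copy()
        m2[:, 2] += 0.25
        sset2 = make_set(m2)
        summ2 = quadrat_summaries(sset2)
        biases2 = np.array([b.b for b in survey_bias(sset2)])
        # adding a constant to a survey changes each quadrat's deltas, so sigma
        # changes; but adding a constant to EVERY survey leaves sigma fixed
        m3 = m + 0.25
        summ3 = quadrat_summaries(make_set(m3))
        np.testing.assert_allclose(summ3["sigma"], summ["sigma"], atol=1e-12)
        # bias equivariance: survey 2's bias gains 0.25 * (1 - 1/4)
        assert biases2[2] - biases[2] == pytest.approx(0.25 * 3 / 4, rel=1e-9)

    def test_duplicate_measurement_rejected(self):
        df = pd.DataFrame(
            {"survey_id": ["a", "a"], "quadrat_id": [0, 0], "sr": [1.0, 1.1]}
        )
        manifest = pd.DataFrame({"survey_id": ["a"], "group": ["multi_day"]})
        with pytest.raises(AlignmentError):
            SurveySet("s", df, manifest).wide()
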