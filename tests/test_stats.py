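"""Survival and count statistics: product-limit oracle, log-rank by
hand, Cox cross-checks, exact Mann-Whitney enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import bcellhcc as bc
from bcellhcc.errors import (DegenerateInputError,
                             MonotoneLikelihoodError)
from bcellhcc.records import SurvivalRecord


def _recs(times, events, group=None):
    return [SurvivalRecord(f"p{i}", float(t), int(e), group)
            for i, (t, e) in enumerate(zip(times, events))]


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        curve = bc.km_estimate(_recs([1, 2, 3], [1, 1, 1]))
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert list(curve.at_risk) == [3, 2, 1]

    def test_all_censored_flat_at_one(self):
        curve = bc.km_estimate(_recs([1, 2, 3], [0, 0, 0]))
        assert np.allclose(curve.survival, 1.0)

    def test_mixed_case_matches_longhand_table(self):
        # t=1 death (n=6), t=2 censor, t=3 death (n=4), t=4 death (n=3),
        # t=5 censor, t=6 death (n=1)
        curve = bc.km_estimate(_recs([1, 2, 3, 4, 5, 6],
                                     [1, 0, 1, 1, 0, 1]))
        expected = [5 / 6, 5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 2 / 3,
                    5 / 12, 0.0]
        assert np.allclose(curve.survival, expected)
        assert list(curve.events) == [1, 0, 1, 1, 0, 1]

    def test_censor_free_closed_form(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=25)
        curve = bc.km_estimate(_recs(times, np.ones(25)))
        n = 25
        assert np.allclose(curve.survival,
                           [(n - i) / n for i in range(1, n + 1)])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        e[0] = 1
        curve = bc.km_estimate(_recs(t, e))
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            bc.km_estimate([])


def longhand_logrank(a, b):
    """Independent O/E/V tabulation over distinct event times."""
    times = sorted({r.time_months for r in a + b if r.event})
    O = E = V = 0.0
    for u in times:
        n1 = sum(r.time_months >= u for r in a)
        n2 = sum(r.time_months >= u for r in b)
        d1 = sum(r.time_months == u and r.event for r in a)
        d2 = sum(r.time_months == u and r.event for r in b)
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        a = _recs([1, 3, 5, 7], [1, 0, 1, 1])
        chi2, p = bc.logrank_test(a, list(a))
        assert chi2 < 1e-12
        assert p > 0.999

    def test_matches_longhand_tabulation(self):
        a = _recs([2, 4, 6, 8, 10], [1, 1, 0, 1, 1])
        b = _recs([1, 3, 5, 7, 9], [1, 0, 1, 1, 1])
        chi2, _ = bc.logrank_test(a, b)
        assert np.isclose(chi2, longhand_logrank(a, b), rtol=1e-10)

    def test_power_at_strong_hazard_ratio(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(3000 + s)
            a = _recs(rng.exponential(30, 200), np.ones(200))
            b = _recs(rng.exponential(10, 200), np.ones(200))
            _, p = bc.logrank_test(a, b)
            hits += p < 0.001
        assert hits >= 99

    def test_zero_events_rejected(self):
        with pytest.raises(DegenerateInputError):
            bc.logrank_test(_recs([1, 2], [0, 0]), _recs([3], [0]))


class TestCoxHR:
    def _sim(self, seed, n=242, hr=1.5):
        rng = np.random.default_rng(seed)
        x = rng.random(n) < 0.5
        haz = 0.0116 * np.where(x, hr, 1.0)
        t = rng.exponential(1 / haz)
        e = (t <= 96).astype(int)
        return [SurvivalRecord(f"p{i}", float(min(t[i], 96)), int(e[i]),
                               "low" if x[i] else "high")
                for i in range(n)]

    def test_matches_lifelines(self):
        recs = self._sim(42)
        est = bc.cox_hr(recs, exposed="low")
        df = pd.DataFrame({"t": [r.time_months for r in recs],
                           "e": [r.event for r in recs],
                           "x": [1.0 if r.group == "low" else 0.0
                                 for r in recs]})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.isclose(est.hr, np.exp(cph.params_["x"]), atol=1e-6)
        assert np.isclose(est.log_hr_se, cph.standard_errors_["x"],
                          atol=1e-6)
        ci = cph.confidence_intervals_
        assert np.isclose(est.ci_low, np.exp(ci.iloc[0, 0]), atol=1e-6)

    def test_null_labels_center_on_one(self):
        hrs = [bc.cox_hr(self._sim(4000 + s, hr=1.0), exposed="low").hr
               for s in range(60)]
        log_mean = np.mean(np.log(hrs))
        se = np.std(np.log(hrs), ddof=1) / np.sqrt(60)
        assert abs(log_mean) < 3 * se + 0.02

    def test_efron_equals_breslow_without_ties(self):
        recs = self._sim(7)
        e = bc.cox_hr(recs, exposed="low", ties="efron")
        b = bc.cox_hr(recs, exposed="low", ties="breslow")
        assert abs(e.hr - b.hr) < 1e-10

    def test_tied_data_efron_matches_lifelines(self):
        rng = np.random.default_rng(11)
        t = rng.integers(1, 15, 80).astype(float)  # heavy ties
        x = rng.random(80) < 0.5
        e = rng.random(80) < 0.8
        recs = [SurvivalRecord(f"p{i}", t[i], int(e[i]),
                               "low" if x[i] else "high")
                for i in range(80)]
        est = bc.cox_hr(recs, exposed="low")
        df = pd.DataFrame({"t": t, "e": e.astype(int),
                           "x": x.astype(float)})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.isclose(est.hr, np.exp(cph.params_["x"]), atol=1e-6)

    def test_group_without_events_is_monotone(self):
        recs = _recs([1, 2, 3, 4], [1, 1, 0, 0])
        recs = [SurvivalRecord(r.patient_id, r.time_months, r.event,
                               "low" if i < 2 else "high")
                for i, r in enumerate(recs)]
        with pytest.raises(MonotoneLikelihoodError):
            bc.cox_hr(recs, exposed="low")

    def test_ci_brackets_estimate(self):
        est = bc.cox_hr(self._sim(13), exposed="low")
        assert 0 < est.ci_low <= est.hr <= est.ci_high


class TestDescriptives:
    def test_mean_sem_small(self):
        mean, sem, n = bc.mean_sem([1, 2, 3])
        assert mean == 2.0
        assert np.isclose(sem, 1 / np.sqrt(3))
        assert n == 3

    def test_sem_of_constants_is_zero_and_n1_flagged(self):
        assert bc.mean_sem([4, 4, 4])[1] == 0.0
        mean, sem, n = bc.mean_sem([7.0])
        assert mean == 7.0 and sem is None and n == 1

    def test_mean_sem_matches_bruteforce_on_cohort(self, ihc_cohort):
        vals = [r.mean_count for r in ihc_cohort.records
                if r.marker == "CD20" and r.region == "Im"]
        mean, sem, n = bc.mean_sem(vals)
        v = np.asarray(vals)
        assert n == 119
        assert np.isclose(mean, v.sum() / len(v))
        sd = np.sqrt(((v - v.mean()) ** 2).sum() / (len(v) - 1))
        assert np.isclose(sem, sd / np.sqrt(len(v)))


class TestSplitHighLow:
    def test_mean_split(self):
        ga = bc.split_high_low({"a": 1, "b": 2, "c": 3, "d": 10})
        assert ga.ids("high") == ["d"]
        assert set(ga.ids("low")) == {"a", "b", "c"}

    def test_value_at_mean_goes_low(self):
        ga = bc.split_high_low({"a": 0, "b": 2, "c": 4})  # mean 2
        assert ga.labels["b"] == "low"

    def test_groups_bracket_overall_mean(self):
        rng = np.random.default_rng(12)
        vals = {f"p{i}": float(v)
                for i, v in enumerate(rng.gamma(2, 10, 50))}
        ga = bc.split_high_low(vals)
        overall = np.mean(list(vals.values()))
        hi = np.mean([vals[p] for p in ga.ids("high")])
        lo = np.mean([vals[p] for p in ga.ids("low")])
        assert lo < overall < hi

    def test_constant_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            bc.split_high_low({"a": 5, "b": 5})


def enumeration_mwu(a, b):
    """Exact two-sided Mann-Whitney by full enumeration of rank splits."""
    na, nb = len(a), len(b)
    n = na + nb
    allv = list(a) + list(b)
    order = sorted(range(n), key=lambda i: allv[i])
    ranks = [0] * n
    for r, i in enumerate(order):
        ranks[i] = r + 1
    u_obs = sum(ranks[:na]) - na * (na + 1) / 2
    us = np.array([sum(c) - na * (na + 1) / 2
                   for c in itertools.combinations(range(1, n + 1), na)])
    p = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
    return u_obs, p


class TestMannWhitney:
    def test_complete_separation_gives_minimal_u(self):
        u, _ = bc.mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0

    def test_identical_samples_not_significant(self):
        vals = list(np.arange(30.0))
        _, p = bc.mann_whitney(vals, vals)
        assert p >= 0.99

    @pytest.mark.parametrize("na,nb", [(na, nb) for na in range(1, 6)
                                       for nb in range(1, 6)])
    def test_exact_branch_equals_enumeration(self, na, nb):
        rng = np.random.default_rng(10 * na + nb)
        for _ in range(8):
            a = list(rng.normal(size=na))
            b = list(rng.normal(size=nb))
            u, p = bc.mann_whitney(a, b)
            u_o, p_o = enumeration_mwu(a, b)
            assert u == u_o
            assert abs(p - p_o) < 1e-12


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 4.0, 8.0]
        assert np.isclose(bc.pearson_correlation(x, x)[0], 1.0)
        assert np.isclose(
            bc.pearson_correlation(x, [-v for v in x])[0], -1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=(2, 40))
        r, _ = bc.pearson_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        assert abs(r - (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))) < 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            bc.pearson_correlation([1, 1, 1], [1, 2, 3])


class TestIHCRegionAnalysis:
    def test_report_structure_and_margin_dominance(self, ihc_cohort):
        report = bc.ihc_region_analysis(ihc_cohort.records,
                                        ihc_cohort.survival)
        assert report.n_patients == 119
        for marker in ("CD20", "CD79a"):
            means = {r: report.summary[marker][r][0]
                     for r in ("Tu", "Im", "Sd")}
            assert means["Im"] > means["Sd"] > means["Tu"]
            for pair in (("Im", "Tu"), ("Im", "Sd")):
                assert report.comparisons[marker][pair][1] < 0.001

    def test_positivity_tracks_infiltration(self, ihc_cohort):
        report = bc.ihc_region_analysis(ihc_cohort.records,
                                        ihc_cohort.survival)
        for ig in ("kappa", "igm"):
            for region in ("Tu", "Im"):
                block = report.positivity[ig][region]
                assert block["frac_positive_high"] > \
                    block["frac_positive_low"]

    def test_positivity_null_link_shows_no_difference(
            self, default_ihc_config):
        import dataclasses
        cfg = dataclasses.replace(
            default_ihc_config,
            positivity_link={"p_high": {"Tu": .4, "Im": .4, "Sd": .4},
                             "p_low": {"Tu": .4, "Im": .4, "Sd": .4}})
        ps = []
        for seed in range(40):
            coh = bc.generate_ihc_cohort(cfg, 6000 + seed)
            rep = bc.ihc_region_analysis(coh.records, coh.survival)
            ps.append(rep.positivity["kappa"]["Im"]["p"])
        # under the null, small p-values appear at their nominal rate
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_incomplete_patients_are_excluded(self, ihc_cohort):
        records = [r for r in ihc_cohort.records
                   if not (r.patient_id == "R001" and r.region == "Sd")]
        report = bc.ihc_region_analysis(records, ihc_cohort.survival)
        assert report.n_patients == 118
        assert report.excluded_patients == ["R001"]
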