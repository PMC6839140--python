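import numpy as np
import pytest

from methcap.methio import BetaMatrix, SurvivalTable, ValidationError
from methcap.survival import (
    fit_cox_univariate,
    km_curve,
    prognostic_scores,
    site_directions,
    stratify_and_test,
)
from methcap.synthetic_cohort import CohortConfig, generate_cohort


def logrank_bruteforce(time, event, group):
    """Classical logrank observed-minus-expected over risk sets (no-ties form:
    hypergeometric variance reduces to n1*n0/n^2 when d=1)."""
    time, event, group = map(np.asarray, (time, event, group))
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    from scipy.stats import chi2

    stat = o_minus_e**2 / var
    return stat, float(chi2.sf(stat, 1))


def _table(time, event, ids=None):
    ids = ids or [f"s{i}" for i in range(len(time))]
    return SurvivalTable(ids, np.asarray(time, float), np.asarray(event))


class TestKaplanMeier:
    def test_no_events_flat_one(self):
        t = _table([10, 20, 30], [0, 0, 0])
        (curve,) = km_curve(t)
        assert np.all(curve.survival == 1.0)
        assert curve.at(25) == 1.0

    def test_single_event_drops_by_one_over_n(self):
        t = _table([5, 10, 15, 20], [1, 0, 0, 0])
        (curve,) = km_curve(t)
        assert curve.at(4.9) == 1.0
        assert curve.at(5) == pytest.approx(3 / 4)

    def test_hand_computed_six_sample_table(self):
        """times 2,4+,6,8,10,12 (4 censored): product-limit by hand.

        t=2:  6 at risk, 1 event -> S = 5/6
        t=6:  4 at risk, 1 event -> S = 5/6 * 3/4
        t=8:  3 at risk, 1 event -> S = 5/6 * 3/4 * 2/3
        t=10: 2 at risk, 1 event -> S = ... * 1/2
        t=12: 1 at risk, 1 event -> S = 0
        """
        t = _table([2, 4, 6, 8, 10, 12], [1, 0, 1, 1, 1, 1])
        (curve,) = km_curve(t)
        assert curve.at(2) == pytest.approx(5 / 6)
        assert curve.at(6) == pytest.approx(5 / 6 * 3 / 4)
        assert curve.at(8) == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert curve.at(10) == pytest.approx(5 / 6 * 3 / 4 * 2 / 3 * 1 / 2)
        assert curve.at(12) == pytest.approx(0.0)

    def test_nonincreasing_and_one_at_zero(self, rng):
        t = _table(rng.uniform(1, 100, 30), rng.integers(0, 2, 30))
        (curve,) = km_curve(t)
        assert curve.survival[0] == 1.0 and curve.times[0] == 0.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_grouped_curves(self):
        t = _table([5, 10, 15, 20], [1, 1, 1, 1])
        group = {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}
        curves = km_curve(t, group)
        assert [c.group for c in curves] == ["a", "b"]

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        time = rng.uniform(1, 100, 50)
        event = rng.integers(0, 2, 50)
        (curve,) = km_curve(_table(time, event))
        kmf = KaplanMeierFitter().fit(time, event)
        for t in np.unique(time[event == 1]):
            assert curve.at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )


class TestCox:
    def test_identical_groups_null(self):
        # mirrored survival in both groups -> score at 0 vanishes, hr = 1
        time = [3, 5, 8, 13, 3, 5, 8, 13]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        res = fit_cox_univariate(x, _table(time, event))
        assert res.hr == pytest.approx(1.0, abs=1e-6)
        assert res.score_statistic == pytest.approx(0.0, abs=1e-10)

    def test_logrank_matches_bruteforce_12_sample_toy(self):
        time = [1, 3, 4, 6, 7, 9, 2, 5, 8, 10, 11, 12]
        event = [1, 1, 0, 1, 1, 1, 1, 0, 1, 1, 0, 1]
        x = np.array([1] * 6 + [0] * 6, float)
        res = fit_cox_univariate(x, _table(time, event))
        stat, p = logrank_bruteforce(time, event, x)
        assert res.score_statistic == pytest.approx(stat, rel=1e-10)
        assert res.logrank_p == pytest.approx(p, rel=1e-10)

    def test_matches_lifelines_estimate(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        # untied times: lifelines defaults to Efron, which equals Breslow
        # only in the absence of tied event times
        n = 80
        x = rng.binomial(1, 0.5, n).astype(float)
        time = rng.exponential(50 / np.exp(0.6 * x)) + 0.1
        event = rng.binomial(1, 0.7, n)
        res = fit_cox_univariate(x, _table(time, event))
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": time, "E": event, "x": x}), "T", "E"
        )
        # lifelines' Newton stops at a looser tolerance than our |score|<1e-8
        assert res.log_hr == pytest.approx(float(cph.params_["x"]), abs=5e-4)
        assert res.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-3)

    def test_parameter_recovery_three_seeds(self):
        for seed in range(3):
            r = np.random.default_rng(seed)
            n = 400
            x = r.binomial(1, 0.5, n).astype(float)
            time = r.exponential(60 / np.exp(0.7 * x))
            cens = r.uniform(0, 150, n)
            event = (time <= cens).astype(int)
            obs = np.minimum(time, cens) + 1e-6
            res = fit_cox_univariate(x, _table(obs, event))
            assert abs(res.log_hr - 0.7) < 3 * res.se

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError, match="events"):
            fit_cox_univariate(np.array([0.0, 1.0]), _table([1, 2], [0, 0]))

    def test_monotone_likelihood_flagged(self):
        # events perfectly ordered by covariate -> separation
        time = [1, 2, 3, 10, 11, 12]
        event = [1, 1, 1, 1, 1, 1]
        x = np.array([1, 1, 1, 0, 0, 0], float)
        res = fit_cox_univariate(x, _table(time, event))
        assert res.boundary
        assert abs(res.log_hr) <= 15.0


class TestSiteDirections:
    def _cohort(self):
        return generate_cohort(
            CohortConfig(
                n_samples_per_subtype=(50, 50, 50),
                n_probes=60,
                n_planted_tn=10,
                n_planted_luminal_only=0,
                n_prognostic=10,
                hazard_log_hr=1.2,
                censor_rate=0.3,
                seed=21,
            )
        )

    def test_high_hazard_site_favorable_low(self):
        c = self._cohort()
        sub = c.betas.select_probes(c.truth.prognostic_probes)
        dirs = site_directions(sub, c.clinical, alpha=0.01)
        # planted unfavorable state is 'high' methylation at every site
        frac_low = np.mean([d.favorable_state == "low" for d in dirs])
        assert frac_low >= 0.9

    def test_zero_variance_site_skipped(self, rng):
        vals = rng.uniform(0.2, 0.8, (3, 20))
        vals[1] = 0.5
        bm = BetaMatrix(["a", "b", "c"], [f"s{i}" for i in range(20)], vals)
        clin = _table(rng.uniform(1, 100, 20), np.ones(20, int), bm.sample_ids)
        dirs = site_directions(bm, clin)
        assert [d.probe_id for d in dirs] == ["a", "c"]

    def test_preconditions(self, rng):
        bm = BetaMatrix(["a"], [f"s{i}" for i in range(5)], rng.uniform(0.2, 0.8, (1, 5)))
        clin = _table([1, 2, 3, 4, 5], [1, 1, 1, 1, 1], bm.sample_ids)
        with pytest.raises(ValidationError):
            site_directions(bm, clin)


class TestPrognosticScores:
    def _dirs_and_matrix(self, rng, n_sites=4, n_samples=20):
        from methcap.survival import SiteDirection

        vals = rng.uniform(0.1, 0.9, (n_sites, n_samples))
        bm = BetaMatrix(
            [f"p{i}" for i in range(n_sites)],
            [f"s{j}" for j in range(n_samples)],
            vals,
        )
        dirs = [
            SiteDirection(f"p{i}", "low" if i % 2 else "high", 1.5, 0.001, True)
            for i in range(n_sites)
        ]
        return bm, dirs

    def test_all_favorable_scores_one(self, rng):
        from methcap.survival import SiteDirection

        vals = np.vstack([np.linspace(0.1, 0.9, 10)] * 3)
        bm = BetaMatrix(["a", "b", "c"], [f"s{j}" for j in range(10)], vals)
        dirs = [SiteDirection(p, "high", 0.5, 0.001, True) for p in "abc"]
        scores = prognostic_scores(bm, dirs)
        # top-half samples are 'high' (favorable) at every site
        by_id = {s.sample_id: s.score for s in scores}
        assert by_id["s9"] == 1.0
        assert by_id["s0"] == 0.0

    def test_three_of_four(self, rng):
        bm, dirs = self._dirs_and_matrix(rng)
        scores = prognostic_scores(bm, dirs)
        for s in scores:
            assert s.n_sites_used == 4
            assert s.score in {0.0, 0.25, 0.5, 0.75, 1.0}

    def test_invariant_to_site_order(self, rng):
        bm, dirs = self._dirs_and_matrix(rng)
        a = prognostic_scores(bm, dirs)
        b = prognostic_scores(bm, list(reversed(dirs)))
        assert [s.score for s in a] == [s.score for s in b]

    def test_only_significant_filter(self, rng):
        bm, dirs = self._dirs_and_matrix(rng)
        dirs[0].significant = False
        scores = prognostic_scores(bm, dirs, use_only_significant=True)
        assert scores[0].n_sites_used == 3

    def test_empty_direction_set_rejected(self, rng):
        bm, dirs = self._dirs_and_matrix(rng)
        for d in dirs:
            d.significant = False
        with pytest.raises(ValidationError):
            prognostic_scores(bm, dirs, use_only_significant=True)


class TestStratifyAndTest:
    def test_two_samples_one_per_group(self):
        from methcap.survival import PrognosticScore

        scores = [PrognosticScore("s0", 0.2, 4), PrognosticScore("s1", 0.8, 4)]
        clin = _table([10, 50], [1, 1])
        group, p, hr = stratify_and_test(scores, clin)
        assert set(group.values()) == {"low", "high"}

    def test_all_equal_scores_rejected(self):
        from methcap.survival import PrognosticScore

        scores = [PrognosticScore(f"s{i}", 0.5, 4) for i in range(4)]
        clin = _table([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValidationError):
            stratify_and_test(scores, clin)

    def test_null_no_spurious_separation(self):
        """Scores independent of survival: p not systematically small."""
        from methcap.survival import PrognosticScore

        ps = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            n = 60
            clin = _table(r.uniform(1, 100, n), r.binomial(1, 0.7, n))
            scores = [PrognosticScore(s, float(r.random()), 5) for s in clin.sample_ids]
            _, p, _ = stratify_and_test(scores, clin)
            ps.append(p)
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_planted_cohort_stratifies(self, planted_cohort):
        c = planted_cohort
        sub = c.betas.select_probes(c.truth.prognostic_probes)
        dirs = site_directions(sub, c.clinical, alpha=0.01)
        scores = prognostic_scores(sub, dirs, use_only_significant=any(d.significant for d in dirs))
        _, p, hr = stratify_and_test(scores, c.clinical)
        assert p < 0.01
        assert hr > 1.0  # low score (mostly unfavorable states) has higher hazard
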