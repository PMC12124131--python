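"""Onset analyses (log-rank, Firth Cox, onset summaries) and cohort
construction (sex rebalancing, pathogenic-carrier exclusion)."""

import numpy as np
import pandas as pd
import pytest

from rvcollapse.cohort import exclude_flagged_carriers, rebalance_controls
from rvcollapse.firth import cox_firth, _cox_penalized_ll
from rvcollapse.stats import ContingencyTable, fisher_two_sided, odds_ratio_ci
from rvcollapse.survival import km_curve, logrank, onset_summary


def logrank_hand_oracle(groups):
    """Observed-minus-expected log-rank statistic computed from first
    principles (no censoring support needed for the toy data used here)."""
    all_times = sorted({t for ts, _ in groups.values() for t in ts})
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n_total = sum((np.asarray(ts) >= t).sum() for ts, _ in groups.values())
        d_total = sum(
            ((np.asarray(ts) == t) & np.asarray(es, dtype=bool)).sum()
            for ts, es in groups.values()
        )
        ts1, es1 = list(groups.values())[0]
        n1 = (np.asarray(ts1) >= t).sum()
        d1 = ((np.asarray(ts1) == t) & np.asarray(es1, dtype=bool)).sum()
        e1 = d_total * n1 / n_total
        o_minus_e += d1 - e1
        if n_total > 1:
            var += (
                d_total * (n1 / n_total) * (1 - n1 / n_total)
                * (n_total - d_total) / (n_total - 1)
            )
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        g = {
            "a": ([1.0, 2.0, 3.0], [True, True, True]),
            "b": ([1.0, 2.0, 3.0], [True, True, True]),
        }
        res = logrank(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        g = {
            "a": ([1.0, 2.0, 3.0], [True] * 3),
            "b": ([4.0, 5.0, 6.0], [True] * 3),
        }
        res = logrank(g)
        assert res.statistic == pytest.approx(logrank_hand_oracle(g), rel=1e-9)
        assert res.n_events == 6

    def test_doubling_sample_increases_statistic(self):
        g1 = {
            "a": ([1.0, 2.0, 5.0], [True] * 3),
            "b": ([3.0, 6.0, 7.0], [True] * 3),
        }
        g2 = {k: (list(t) * 2, list(e) * 2) for k, (t, e) in g1.items()}
        assert logrank(g2).statistic > logrank(g1).statistic

    def test_errors(self):
        with pytest.raises(ValueError):
            logrank({"a": ([1.0], [True])})
        with pytest.raises(ValueError):
            logrank({"a": ([1.0], [False]), "b": ([2.0], [False])})


class TestOnsetSummary:
    def test_five_values(self):
        med, (q25, q75) = onset_summary([64, 59, 75, 66, 70])
        assert med == 66

    def test_single_value_degenerate(self):
        med, (q25, q75) = onset_summary([70.0])
        assert med == q25 == q75 == 70.0

    def test_weibull_median_recovery(self):
        """Weibull(shape 5, scale 70/ln2^(1/5)) has median 70; the summary
        recovers it within Monte-Carlo error."""
        shape, target = 5.0, 70.0
        scale = target / np.log(2) ** (1 / shape)
        rng = np.random.default_rng(77)
        draws = scale * rng.weibull(shape, 4000)
        med, _ = onset_summary(draws)
        assert med == pytest.approx(target, abs=0.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            onset_summary([])


class TestCoxFirth:
    def test_monotone_likelihood_finite(self):
        """Covariate carried only by censored subjects: ordinary Cox has a
        monotone likelihood; the penalised estimate stays finite."""
        times = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        events = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])
        fit, summary = cox_firth(times, events, x[:, None])
        assert np.isfinite(summary.hr) and summary.hr > 0
        assert np.isfinite(fit.ci_low["x1"])

    def test_matches_grid_oracle_small(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(1.0, 12).round(3)
        events = np.ones(12, dtype=bool)
        x = (np.arange(12) % 2).astype(float)
        fit, _ = cox_firth(times, events, x[:, None])
        grid = np.linspace(-4, 4, 8001)
        lls = [_cox_penalized_ll(np.array([b]), times, events, x[:, None]) for b in grid]
        b_star = grid[int(np.argmax(lls))]
        assert fit.coefficients["x1"] == pytest.approx(b_star, abs=1e-3)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(14)
        n = 400
        times = rng.exponential(1.0, n)
        events = rng.random(n) < 0.8
        x = rng.binomial(1, 0.5, n).astype(float)
        _, summary = cox_firth(times, events, x[:, None])
        assert abs(np.log(summary.hr)) < 0.3
        assert summary.p > 0.01

    def test_approaches_unpenalized_cox(self):
        """With growing n the penalty is negligible (lifelines cross-check;
        continuous times, so Efron and Breslow tie handling coincide)."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 600
        x = rng.binomial(1, 0.5, n).astype(float)
        times = rng.exponential(np.exp(-0.7 * x))
        events = np.ones(n, dtype=bool)
        fit, _ = cox_firth(times, events, x[:, None])
        df = pd.DataFrame({"t": times, "e": events.astype(int), "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.coefficients["x1"] == pytest.approx(cph.params_["x"], abs=0.02)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_firth([1.0, 2.0], [False, False], np.ones((2, 1)))


class TestRebalance:
    def _samples(self, cm, cf, km, kf):
        rows = (
            [("case", "male")] * cm + [("case", "female")] * cf
            + [("control", "male")] * km + [("control", "female")] * kf
        )
        df = pd.DataFrame(rows, columns=["phenotype", "sex"])
        df.insert(0, "sample_id", [f"s{i}" for i in range(len(df))])
        return df

    def test_odds_matching_arithmetic(self):
        # cases 63M/37F vs controls 500M/500F -> retain 500M and 294F
        samples = self._samples(63, 37, 500, 500)
        assert fisher_two_sided(ContingencyTable(63, 37, 500, 500)) < 0.05
        kept = rebalance_controls(samples, seed=3)
        ctrl = kept[kept["phenotype"] == "control"]
        assert (ctrl["sex"] == "male").sum() == 500
        assert (ctrl["sex"] == "female").sum() == 294
        assert (kept["phenotype"] == "case").sum() == 100

    def test_post_condition_balanced(self):
        samples = self._samples(63, 37, 500, 500)
        kept = rebalance_controls(samples, seed=3)
        ctrl = kept[kept["phenotype"] == "control"]
        km, kf = (ctrl["sex"] == "male").sum(), (ctrl["sex"] == "female").sum()
        # odds matched to nearest integer
        assert kf == round(km * 37 / 63)

    def test_identity_when_not_significant(self):
        samples = self._samples(50, 50, 500, 500)
        kept = rebalance_controls(samples, seed=1)
        pd.testing.assert_frame_equal(kept, samples)

    def test_deterministic_given_seed(self):
        samples = self._samples(63, 37, 500, 500)
        a = rebalance_controls(samples, seed=11)
        b = rebalance_controls(samples, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_impossible_target_rejected(self):
        samples = self._samples(10, 2, 0, 50)
        with pytest.raises(ValueError):
            rebalance_controls(samples, seed=0)


class TestExclusion:
    def test_no_flags_identity(self):
        samples = pd.DataFrame(
            {"sample_id": ["a", "b"], "phenotype": ["case", "control"]}
        )
        calls = pd.DataFrame(columns=["sample_id", "variant_key", "zygosity"])
        kept, report = exclude_flagged_carriers(samples, calls, {})
        pd.testing.assert_frame_equal(kept, samples)

    def test_flagged_carrier_removed(self):
        samples = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "phenotype": ["case", "control", "control"]}
        )
        calls = pd.DataFrame(
            [("a", "gba1-v", "het"), ("b", "other", "het")],
            columns=["sample_id", "variant_key", "zygosity"],
        )
        kept, report = exclude_flagged_carriers(samples, calls, {"clinvar": {"gba1-v"}})
        assert list(kept["sample_id"]) == ["b", "c"]
        row = report[report["criterion"] == "any"].iloc[0]
        assert row["cases_removed"] == 1 and row["controls_removed"] == 0

    def test_published_exclusion_statistics(self):
        """A cohort built to mimic the pathogenic-carrier exclusion (3,702 ->
        3,301 cases; 233,378 -> 217,556 controls; target-gene carriers 9 -> 9
        and 54 -> 49) reproduces the published post-exclusion statistics."""
        n_case, n_ctrl = 3702, 233378
        samples = pd.DataFrame(
            {
                "sample_id": [f"p{i}" for i in range(n_case + n_ctrl)],
                "phenotype": ["case"] * n_case + ["control"] * n_ctrl,
            }
        )
        # target-gene carriers: 9 cases, 54 controls (5 of which also carry a
        # flagged variant); flagged non-target carriers fill the remainder
        rows = [(f"p{i}", "itsn1-v", "het") for i in range(9)]
        rows += [(f"p{n_case + i}", "itsn1-v", "het") for i in range(54)]
        rows += [(f"p{n_case + i}", "flag-v", "het") for i in range(5)]  # overlap
        rows += [(f"p{9 + i}", "flag-v", "het") for i in range(401)]  # cases
        rows += [(f"p{n_case + 54 + i}", "flag-v", "het") for i in range(15822 - 5)]
        calls = pd.DataFrame(rows, columns=["sample_id", "variant_key", "zygosity"])
        kept, report = exclude_flagged_carriers(samples, calls, {"flagged": {"flag-v"}})
        n_case_kept = (kept["phenotype"] == "case").sum()
        n_ctrl_kept = (kept["phenotype"] == "control").sum()
        assert n_case_kept == 3301 and n_ctrl_kept == 217556
        carriers = kept[kept["sample_id"].isin(
            set(calls.loc[calls["variant_key"] == "itsn1-v", "sample_id"])
        )]
        a = (carriers["phenotype"] == "case").sum()
        c = (carriers["phenotype"] == "control").sum()
        assert (a, c) == (9, 49)
        t = ContingencyTable(a, n_case_kept - a, c, n_ctrl_kept - c)
        assert float(f"{fisher_two_sided(t):.1e}") == pytest.approx(2.0e-7)
        or_, _, _, _ = odds_ratio_ci(t)
        assert round(or_, 2) == 12.14


def test_km_curve_monotone(small_cohort):
    cases = small_cohort["samples"].query("phenotype == 'case'")
    curve = km_curve(cases["age_at_event"], cases["event"] == "diagnosed")
    assert (curve["survival"].diff().dropna() <= 1e-12).all()
    assert curve["survival"].iloc[0] == pytest.approx(1.0)
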