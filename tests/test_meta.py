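"""Stratified exact CMH, inflation estimation, and power analysis."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from rvcollapse.meta import (
    PowerSpec,
    StratifiedTables,
    cmh_exact,
    estimate_lambda,
    permute_and_refit,
    power_fisher,
    required_n,
)
from rvcollapse.simulate import itsn1_strata
from rvcollapse.stats import ContingencyTable, fisher_two_sided, odds_ratio_ci


def cmh_enumeration_oracle(tables) -> float:
    """Exact integer-arithmetic enumeration over the joint conditional table
    space (independent of the log-space convolution implementation)."""
    supports = []
    for t in tables:
        r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
        xs = range(max(0, c1 - r2), min(r1, c1) + 1)
        supports.append([(x, comb(r1, x) * comb(r2, c1 - x)) for x in xs])
    dist: dict[int, int] = {0: 1}
    for sup in supports:
        new: dict[int, int] = {}
        for s, w in dist.items():
            for x, wx in sup:
                new[s + x] = new.get(s + x, 0) + w * wx
        dist = new
    s_obs = sum(t.a for t in tables)
    w_obs = dist[s_obs]
    total = sum(dist.values())
    return sum(w for w in dist.values() if w <= w_obs * (1 + 1e-7)) / total


class TestCMH:
    def test_single_stratum_reduces_to_fisher(self):
        for counts in [(3, 7, 2, 12), (9, 3693, 54, 233324), (1, 5, 4, 4)]:
            t = ContingencyTable(*counts)
            p, or_mh, _ = cmh_exact(StratifiedTables([("s", t)]))
            assert p == pytest.approx(fisher_two_sided(t), abs=1e-12)
            assert or_mh == pytest.approx((t.a * t.d) / (t.b * t.c), rel=1e-12)

    def test_two_small_strata_match_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            tabs = []
            for _k in range(2):
                n = int(rng.integers(4, 21))
                r1 = int(rng.integers(1, n))
                c1 = int(rng.integers(1, n))
                a_lo, a_hi = max(0, c1 - (n - r1)), min(r1, c1)
                a = int(rng.integers(a_lo, a_hi + 1))
                tabs.append(ContingencyTable(a, r1 - a, c1 - a, (n - r1) - (c1 - a)))
            if any(min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0 for t in tabs):
                continue
            p, _, _ = cmh_exact(StratifiedTables([("1", tabs[0]), ("2", tabs[1])]))
            assert p == pytest.approx(cmh_enumeration_oracle(tabs), abs=1e-12)

    def test_published_strata_internal_consistency(self):
        """Combined evidence across the printed strata: the common odds ratio
        lies inside every stratum's Woolf CI envelope and the combined p is
        below each stratum's own p (concordant strata)."""
        st = itsn1_strata()
        p, or_mh, (lo, hi) = cmh_exact(st)
        stratum_ps = [fisher_two_sided(t) for t in st.tables()]
        assert p < min(stratum_ps)
        env_lo = min(odds_ratio_ci(t)[1] for t in st.tables())
        env_hi = max(odds_ratio_ci(t)[2] for t in st.tables())
        assert env_lo <= or_mh <= env_hi
        assert lo <= or_mh <= hi

    def test_or_mh_invariant_to_stratum_order(self):
        tabs = [("a", ContingencyTable(3, 7, 2, 12)), ("b", ContingencyTable(5, 10, 1, 20))]
        p1, or1, ci1 = cmh_exact(StratifiedTables(tabs))
        p2, or2, ci2 = cmh_exact(StratifiedTables(tabs[::-1]))
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert or1 == pytest.approx(or2, rel=1e-12)
        assert ci1 == pytest.approx(ci2, rel=1e-12)

    def test_or_mh_matches_statsmodels(self):
        """Independent cross-check of the MH estimate and RBG interval."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        tabs = [ContingencyTable(3, 7, 2, 12), ContingencyTable(5, 10, 1, 20),
                ContingencyTable(9, 3693, 54, 233324)]
        arr = np.array([[[t.a, t.b], [t.c, t.d]] for t in tabs]).transpose(1, 2, 0)
        st_sm = sm.StratifiedTable(arr.astype(float))
        _, or_mh, (lo, hi) = cmh_exact(
            StratifiedTables([(str(i), t) for i, t in enumerate(tabs)])
        )
        assert or_mh == pytest.approx(float(st_sm.oddsratio_pooled), rel=1e-10)
        sm_lo, sm_hi = st_sm.oddsratio_pooled_confint()
        assert lo == pytest.approx(float(sm_lo), rel=1e-3)
        assert hi == pytest.approx(float(sm_hi), rel=1e-3)

    def test_empty_margin_stratum_dropped_with_warning(self):
        tabs = [("ok", ContingencyTable(3, 7, 2, 12)), ("empty", ContingencyTable(0, 5, 0, 9))]
        with pytest.warns(UserWarning, match="empty"):
            p, _, _ = cmh_exact(StratifiedTables(tabs))
        assert p == pytest.approx(fisher_two_sided(ContingencyTable(3, 7, 2, 12)))

    def test_double_tail_rule_available(self):
        t = ContingencyTable(8, 2, 3, 9)
        p_pt, _, _ = cmh_exact(StratifiedTables([("s", t)]))
        p_dt, _, _ = cmh_exact(StratifiedTables([("s", t)]), two_sided="double-tail")
        assert 0 < p_dt <= 1 and p_dt != p_pt
        with pytest.raises(ValueError):
            cmh_exact(StratifiedTables([("s", t)]), two_sided="bogus")


class TestLambda:
    def test_identical_lists_give_one(self):
        p = np.linspace(0.01, 0.99, 101)
        assert estimate_lambda(p, p).lambda_gc == pytest.approx(1.0)

    def test_uniform_monte_carlo(self):
        rng = np.random.default_rng(2024)
        est = estimate_lambda(rng.random(10_000), rng.random(10_000))
        assert est.lambda_gc == pytest.approx(1.0, abs=0.05)
        assert est.n_units == 10_000

    def test_inflated_observed_gives_lambda_above_one(self):
        rng = np.random.default_rng(7)
        u = rng.random(5_000)
        assert estimate_lambda(u**2, rng.random(5_000)).lambda_gc > 1.0

    def test_p_one_maps_to_zero_quantile(self):
        # observed p = 1 everywhere -> zero quantiles -> lambda = 0
        est = estimate_lambda([1.0] * 10, [0.5] * 10)
        assert est.lambda_gc == 0.0
        # a degenerate null (median p = 1) leaves lambda undefined
        with pytest.raises(ValueError, match="undefined"):
            estimate_lambda([0.5] * 10, [1.0] * 9 + [0.5])

    def test_invariant_to_unit_relabeling(self):
        rng = np.random.default_rng(3)
        obs, nul = rng.random(500), rng.random(500)
        a = estimate_lambda(obs, nul).lambda_gc
        perm = rng.permutation(500)
        b = estimate_lambda(obs[perm], nul[perm]).lambda_gc
        assert a == b

    def test_errors(self):
        with pytest.raises(ValueError):
            estimate_lambda([], [])
        with pytest.raises(ValueError):
            estimate_lambda([0.5], [0.5, 0.6])


class TestPermutation:
    def test_same_seed_identical_and_counts_preserved(self):
        samples = pd.DataFrame(
            {"phenotype": ["case"] * 10 + ["control"] * 40}, index=range(50)
        )
        seen = {}

        def analysis(pheno):
            seen["counts"] = pheno.value_counts().to_dict()
            # unit p-values derived deterministically from the labels
            rng = np.random.default_rng(abs(hash(tuple(pheno))) % 2**31)
            return pd.Series(rng.random(5))

        p1 = permute_and_refit(samples, analysis, seed=5)
        c1 = seen["counts"]
        p2 = permute_and_refit(samples, analysis, seed=5)
        pd.testing.assert_series_equal(p1, p2)
        assert c1 == {"control": 40, "case": 10}


class TestPower:
    def test_null_power_bounded_by_alpha(self):
        spec = PowerSpec(caf=3e-4, or_=1.0, alpha=0.05, reps=400, seed=1)
        power, se = power_fisher(spec, 10_000)
        assert power <= 0.05 + 2 * se

    def test_power_monotone_in_n_and_or(self):
        grid_n = [4_000, 12_000, 36_000]
        powers = [
            power_fisher(PowerSpec(caf=3e-4, or_=10.0, reps=300, seed=3), n)[0]
            for n in grid_n
        ]
        assert powers == sorted(powers)
        by_or = [
            power_fisher(PowerSpec(caf=3e-4, or_=orr, reps=300, seed=3), 12_000)[0]
            for orr in (2.0, 6.0, 10.0)
        ]
        assert by_or == sorted(by_or)

    def test_required_n_monotone_in_or(self):
        n10, pw10 = required_n(PowerSpec(caf=3e-4, or_=10.0, reps=250, seed=4),
                               n_low=1_000, n_high=120_000)
        n6, pw6 = required_n(PowerSpec(caf=3e-4, or_=6.0, reps=250, seed=4),
                             n_low=1_000, n_high=120_000)
        assert n6 >= n10
        assert pw10 >= 0.8 and pw6 >= 0.8

    def test_doubling_caf_reduces_required_n(self):
        n1, _ = required_n(PowerSpec(caf=3e-4, or_=6.0, reps=250, seed=4),
                           n_low=1_000, n_high=120_000)
        n2, _ = required_n(PowerSpec(caf=6e-4, or_=6.0, reps=250, seed=4),
                           n_low=1_000, n_high=120_000)
        assert n2 < n1

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PowerSpec(caf=0.9, or_=2.0)
        with pytest.raises(ValueError):
            PowerSpec(caf=1e-4, or_=-1.0)
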