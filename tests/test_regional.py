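"""One-sample t decision machinery and regional priority classification."""

import math

import numpy as np
import pytest
from scipy import stats

from hdmprof import (
    DEFAULT_PANEL,
    PriorityConfig,
    ShareSeries,
    binarize,
    classify_all_regions,
    priority_molecules,
    region_shares,
    ttest_one_sample_greater,
)
from hdmprof.errors import ConfigError, ConsistencyError

from conftest import make_cohort
from _oracles import brute_force_priority, reference_pvalue, t_upper_tail_quad


def series(shares, n=100, region="R", group="all"):
    full = dict(shares)
    return ShareSeries(region, group, full, n)


class TestTTest:
    def test_mean_equals_popmean_gives_half(self):
        res = ttest_one_sample_greater([0.2, 0.4, 0.6], 0.4)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(0.5)

    def test_upper_tail_monotone_in_popmean(self):
        x = [0.1, 0.3, 0.5, 0.7]
        ps = [ttest_one_sample_greater(x, mu).pvalue for mu in (0.0, 0.4, 2.0, 1e9)]
        assert ps == sorted(ps)
        assert ps[-1] == pytest.approx(1.0)

    def test_agrees_with_scipy_ttest_1samp(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(0.4, 0.2, size=rng.integers(2, 12))
            mu = rng.normal(0.4, 0.3)
            mine = ttest_one_sample_greater(x, mu)
            ref = stats.ttest_1samp(x, mu, alternative="greater")
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_agrees_with_quadrature_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            x = rng.uniform(0, 1, size=5)
            mu = rng.uniform(0, 1)
            res = ttest_one_sample_greater(x, mu)
            if not res.degenerate:
                assert res.pvalue == pytest.approx(
                    t_upper_tail_quad(res.statistic, len(x) - 1), abs=1e-8
                )

    def test_constant_series_degenerate_convention(self):
        low = ttest_one_sample_greater([0.5, 0.5, 0.5], 0.6)
        high = ttest_one_sample_greater([0.5, 0.5, 0.5], 0.4)
        assert (low.pvalue, low.degenerate) == (1.0, True)
        assert (high.pvalue, high.degenerate) == (0.0, True)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ttest_one_sample_greater([0.5], 0.5)


class TestRegionShares:
    def test_share_arithmetic(self):
        rows = [(f"p{i}", 10, "A", {"Der f 1": 1.0}) for i in range(3)]
        rows.append(("p3", 10, "A", {"Der f 2": 1.0}))
        cohort = make_cohort(rows)
        s = region_shares(cohort, binarize(cohort), "A")
        assert s.shares["Der f 1"] == pytest.approx(0.75)
        assert s.shares["Der f 2"] == pytest.approx(0.25)
        assert s.n_sensitized == 4
        assert all(s.shares[m] == 0.0 for m in DEFAULT_PANEL[2:])

    def test_region_without_sensitized(self):
        cohort = make_cohort([("a", 10, "Empty", [0.0] * 11)])
        s = region_shares(cohort, binarize(cohort), "Empty")
        assert s.n_sensitized == 0 and set(s.shares.values()) == {0.0}

    def test_matches_bruteforce_recount(self, small_synthetic):
        cohort, matrix = small_synthetic
        region = sorted(cohort.region_set)[0]
        s = region_shares(cohort, matrix, region, "child")
        # brute force over patient records
        members = [
            (rec, row)
            for rec, row in zip(cohort.records, matrix.values)
            if rec.region == region and rec.age < 18 and row.any()
        ]
        assert s.n_sensitized == len(members)
        for j, m in enumerate(cohort.panel):
            expected = sum(int(row[j]) for _, row in members) / len(members)
            assert s.shares[m] == pytest.approx(expected)


class TestPriorityMolecules:
    def test_clear_margin_single(self):
        d = priority_molecules(series({"Der f 1": 0.60, "Der f 2": 0.50, "Der p 1": 0.10}))
        assert d.priority == ("Der f 1",)
        assert d.trace.rule_path == "margin_single"
        assert d.trace.margin_rule_fired

    def test_exactly_equal_maxima_keep_both(self):
        d = priority_molecules(series({"Der f 1": 0.50, "Der f 2": 0.50, "Der p 1": 0.10}))
        assert d.priority == ("Der f 1", "Der f 2")
        assert d.trace.rule_path == "margin_equal_pair"

    def test_close_maxima_retained_by_t_step(self):
        shares = {m: 0.10 for m in DEFAULT_PANEL}
        shares["Der f 2"], shares["Der p 2"] = 0.52, 0.49
        d = priority_molecules(series(shares))
        # verify the branch with the closed form computed here
        values = np.array(list(shares.values()))
        p = {m: reference_pvalue(values, s) for m, s in shares.items()}
        expected_pair = abs(p["Der p 2"] - p["Der f 2"]) / p["Der f 2"] <= 0.05
        assert expected_pair
        assert d.priority == ("Der f 2", "Der p 2")
        assert d.trace.rule_path == "ttest_pair"

    def test_t_step_can_reject_runner_up(self):
        # runner-up close in share, but its p-value differs by far more
        # than 5% from the absolute maximum's (0.5 vs ~0.89 at df=2)
        shares = {"Der f 1": 0.50, "Der f 2": 0.45, "Der p 1": 0.40}
        d = priority_molecules(series(shares))
        p = d.trace.p_values
        assert abs(p["Der f 2"] - p["Der f 1"]) / p["Der f 1"] > 0.05
        assert d.priority == ("Der f 1",)
        assert d.trace.rule_path == "ttest_single"

    def test_exclusions(self):
        d0 = priority_molecules(series({"Der f 1": 0.0}, n=0))
        d2 = priority_molecules(series({"Der f 1": 1.0}, n=2))
        assert (d0.excluded_reason, d0.priority) == ("no_sensitized", ())
        assert (d2.excluded_reason, d2.priority) == ("below_min_n", ())
        assert d0.excluded and d2.excluded

    def test_all_zero_shares_with_patients_is_inconsistent(self):
        with pytest.raises(ConsistencyError):
            priority_molecules(series({m: 0.0 for m in DEFAULT_PANEL}, n=10))

    def test_p_value_of_maximum_dominates(self):
        shares = {m: s for m, s in zip(DEFAULT_PANEL, np.linspace(0.05, 0.5, 11))}
        d = priority_molecules(series(shares))
        p = d.trace.p_values
        top = max(shares, key=shares.get)
        assert all(p[top] >= p[m] - 1e-12 for m in p)
        assert all(0.0 <= v <= 1.0 for v in p.values())

    def test_matches_bruteforce_on_random_series(self):
        rng = np.random.default_rng(13)
        molecules = DEFAULT_PANEL[:4]
        for _ in range(200):
            vals = np.round(rng.uniform(0, 1, size=4), 2)
            shares = dict(zip(molecules, vals))
            if max(vals) == 0:
                continue
            d = priority_molecules(series(shares))
            expected = brute_force_priority(shares, 100)
            assert (d.priority, d.trace.rule_path) == expected

    def test_scale_free_in_counts(self):
        rows = [(f"a{i}", 10, "R", {"Der f 2": 1.0, "Der p 2": 1.0}) for i in range(3)]
        rows += [(f"b{i}", 10, "R", {"Der p 23": 1.0}) for i in range(2)]
        small = make_cohort(rows)
        big = make_cohort(
            [(f"{pid}_{k}", age, region, {m: v for m, v in levels.items()})
             for k in range(5)
             for (pid, age, region, levels) in [
                 (r[0], r[1], r[2], r[3]) for r in rows
             ]]
        )
        d_small = priority_molecules(region_shares(small, binarize(small), "R"))
        d_big = priority_molecules(region_shares(big, binarize(big), "R"))
        assert d_small.priority == d_big.priority
        assert d_small.trace.rule_path == d_big.trace.rule_path


class TestClassifyAllRegions:
    def test_single_molecule_region(self):
        rows = [(f"r{i}", 10, "Solo", {"Der p 23": 1.0}) for i in range(4)]
        rows += [(f"o{i}", 10, "Other", {"Der f 2": 1.0, "Der p 2": 1.0}) for i in range(4)]
        cohort = make_cohort(rows)
        decisions = {d.region: d for d in classify_all_regions(cohort, binarize(cohort))}
        assert decisions["Solo"].priority == ("Der p 23",)

    def test_exclusions_reported_not_dropped(self):
        rows = [("a", 30, "Tiny", {"Der f 2": 1.0}), ("b", 31, "Tiny", {"Der f 2": 1.0})]
        rows += [(f"c{i}", 30, "None", [0.0] * 11) for i in range(3)]
        rows += [(f"d{i}", 30, "Full", {"Der f 2": 1.0}) for i in range(5)]
        cohort = make_cohort(rows)
        decisions = {d.region: d for d in classify_all_regions(cohort, binarize(cohort))}
        assert set(decisions) == {"Tiny", "None", "Full"}
        assert decisions["Tiny"].excluded_reason == "below_min_n"
        assert decisions["None"].excluded_reason == "no_sensitized"
        assert decisions["Full"].priority == ("Der f 2",)

    def test_age_split_and_determinism(self, small_synthetic):
        cohort, matrix = small_synthetic
        once = classify_all_regions(cohort, matrix, by="age")
        twice = classify_all_regions(cohort, matrix, by="age")
        assert once == twice  # no hidden randomness
        assert len(once) == 2 * len(cohort.region_set)
        assert {d.group for d in once} == {"child", "adult"}

    def test_unknown_grouping(self, toy_cohort):
        with pytest.raises(ConfigError):
            classify_all_regions(toy_cohort, binarize(toy_cohort), by="biome")


def test_priority_config_validation():
    with pytest.raises(ConfigError):
        PriorityConfig(margin=0.0)
    with pytest.raises(ConfigError):
        PriorityConfig(min_group_n=0)
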