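import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xomap import (
    GROUP_SIZES,
    agresti_coull_ci,
    apply_missing_scenario,
    call_events,
    centromeric_region,
    counts_to_callset,
    detection_power,
    fisher_intervals,
    mann_whitney_groups,
    region_compare,
    size_vs_rate,
    telomeric_region,
)
from xomap.stats import RegionSpec

from conftest import fisher_two_sided
from test_qc import line_panel, matrix_from_rows


class TestMannWhitney:
    def test_identical_groups_p1(self):
        a = np.arange(20)
        r = mann_whitney_groups(a, a.copy())
        assert r.p_value > 0.9
        assert not r.significant

    def test_constant_pooled_values(self):
        r = mann_whitney_groups(np.full(10, 5.0), np.full(8, 5.0))
        assert r.p_value == 1.0

    def test_disjoint_groups_significant(self):
        a = np.arange(1, 21)
        b = np.arange(31, 51)
        r = mann_whitney_groups(a, b, family_size=4)
        assert r.p_value < 1e-6
        assert r.significant

    def test_family_threshold(self):
        r = mann_whitney_groups([1, 2], [3, 4], family_size=4, family_alpha=0.05)
        assert r.threshold == pytest.approx(0.0125)

    def test_normal_approximation_oracle(self):
        """Brute-force normal approximation with continuity and tie correction."""
        rng = np.random.default_rng(0)
        a = rng.integers(0, 15, 30).astype(float)
        b = rng.integers(3, 18, 25).astype(float)
        r = mann_whitney_groups(a, b)
        n1, n2 = len(a), len(b)
        pooled = np.concatenate([a, b])
        from scipy.stats import norm, rankdata

        ranks = rankdata(pooled)
        u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        _, counts = np.unique(pooled, return_counts=True)
        tie = (counts**3 - counts).sum()
        n = n1 + n2
        var = n1 * n2 / 12 * (n + 1 - tie / (n * (n - 1)))
        z = (abs(u1 - n1 * n2 / 2) - 0.5) / np.sqrt(var)
        assert r.p_value == pytest.approx(2 * norm.sf(z), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_groups([], [1.0])


class TestAgrestiCoull:
    def test_x0_clipped(self):
        lo, hi = agresti_coull_ci(0, 100)
        assert lo == 0.0
        assert hi == pytest.approx(0.0444, abs=5e-4)

    def test_xn_clipped(self):
        lo, hi = agresti_coull_ci(100, 100)
        assert hi == 1.0
        assert lo == pytest.approx(1 - 0.0444, abs=5e-4)

    def test_symmetric_at_half(self):
        lo, hi = agresti_coull_ci(50, 100)
        assert lo + hi == pytest.approx(1.0)

    def test_exhaustive_grid_vs_formula(self):
        """All (x, n) with n <= 50 against an independent evaluation of the
        published formula (statsmodels)."""
        from statsmodels.stats.proportion import proportion_confint

        for n in range(1, 51):
            for x in range(n + 1):
                lo, hi = agresti_coull_ci(x, n)
                ref_lo, ref_hi = proportion_confint(x, n, alpha=0.05, method="agresti_coull")
                assert lo == pytest.approx(max(0.0, ref_lo), abs=1e-12)
                assert hi == pytest.approx(min(1.0, ref_hi), abs=1e-12)

    def test_n0_rejected(self):
        with pytest.raises(ValueError):
            agresti_coull_ci(0, 0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 500).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n))))
    def test_bounds_property(self, nx):
        n, x = nx
        lo, hi = agresti_coull_ci(x, n)
        assert 0.0 <= lo <= hi <= 1.0
        z2 = 1.959963984540054**2
        assert lo <= (x + z2 / 2) / (n + z2) <= hi


class TestFisherIntervals:
    def test_full_panel_family_threshold(self, ref_panel):
        calls = counts_to_callset()
        tab = fisher_intervals(calls)
        assert tab.attrs["family_size"] == 222
        assert round(tab.attrs["threshold"], 6) == 0.000225

    def test_identical_groups_p1(self):
        panel = line_panel(3)
        rows = [["B", "H", "B"], ["B", "B", "B"]]
        m = matrix_from_rows(rows * 2, groups=["FWT", "FWT", "FKO", "FKO"])
        calls = call_events(apply_missing_scenario(m, panel, "conservative"), panel)
        tab = fisher_intervals(calls, comparisons=[("FWT", "FKO")])
        assert (tab["p"] == 1.0).all()

    def test_example_table(self):
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[20, 59], [5, 74]])
        assert p == pytest.approx(fisher_two_sided([[20, 59], [5, 74]]), rel=1e-9)
        assert 1e-3 < p < 2e-3
        assert p > 0.000225 / 1  # not significant at the full-panel threshold

    def test_enumeration_agreement_small_tables(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(1)
        for _ in range(200):
            n1, n2 = rng.integers(1, 31, 2)
            x1 = rng.integers(0, n1 + 1)
            x2 = rng.integers(0, n2 + 1)
            table = [[int(x1), int(n1 - x1)], [int(x2), int(n2 - x2)]]
            _, p = fisher_exact(table)
            assert p == pytest.approx(fisher_two_sided(table), rel=1e-8, abs=1e-12)

    def test_cutoff_shrinks_family(self):
        calls = counts_to_callset()
        full = fisher_intervals(calls)
        cut = fisher_intervals(calls, proportion_cutoff=0.10)
        assert cut.attrs["family_size"] < full.attrs["family_size"]
        assert cut.attrs["threshold"] > full.attrs["threshold"]

    def test_family_derived_not_hardcoded(self, ref_panel):
        """Dropping a chromosome's markers shrinks the family accordingly."""
        from xomap import CHROM_COUNTS

        keep = [m.marker_id for m in ref_panel.markers if m.chrom != 1]
        panel = ref_panel.subset(keep)
        calls = counts_to_callset(CHROM_COUNTS.drop(index=1), panel=panel)
        tab = fisher_intervals(calls)
        assert tab.attrs["family_size"] == (111 - 12) * 2

    def test_null_simulation_family_wise_control(self, ref_panel):
        """WT and KO simulated from identical maps: Bonferroni controls the
        family-wise error, so at most a small minority of replicate cohorts
        may show any significant interval."""
        from xomap import SimConfig, simulate_offspring

        cohorts_with_hits = 0
        for seed in (101, 102, 103, 104, 105):
            cfg = SimConfig(panel=ref_panel, group_sizes={"FWT": 40, "FKO": 40},
                            missing_rate=0.0, seed=seed)
            matrix, _ = simulate_offspring(cfg)
            calls = call_events(apply_missing_scenario(matrix, ref_panel, "conservative"), ref_panel)
            tab = fisher_intervals(calls, comparisons=[("FWT", "FKO")])
            cohorts_with_hits += int(tab["significant"].sum()) > 0
        assert cohorts_with_hits <= 1


class TestRegions:
    def test_default_region_sizes(self):
        calls = counts_to_callset()
        r, summary = region_compare(calls, centromeric_region())
        assert (summary["n_intervals"] == 6).all()
        r, summary = region_compare(calls, telomeric_region())
        assert (summary["n_intervals"] == 12).all()

    def test_single_interval_equal_proportions(self):
        panel = line_panel(3)
        m = matrix_from_rows([["B", "H", "B"], ["B", "H", "B"]], groups=["FWT", "MWT"])
        calls = call_events(apply_missing_scenario(m, panel, "conservative"), panel)
        region = RegionSpec("one", [(1, "first")])
        r, summary = region_compare(calls, region)
        assert summary["mean"].nunique() == 1
        assert r.p_value == 1.0

    def test_unknown_interval_rejected(self):
        calls = counts_to_callset()
        with pytest.raises(ValueError, match="not found"):
            region_compare(calls, RegionSpec("bad", [(1, "no|pe")]))

    def test_empty_region_rejected(self):
        calls = counts_to_callset()
        with pytest.raises(ValueError, match="empty"):
            region_compare(calls, RegionSpec("void", []))

    def test_sex_trend_recovered_on_simulation(self, sim_cohort, ref_panel):
        """Female > male group means whenever the configured maps differ by
        >= 10% (parameter-recovery property, qualitative)."""
        from xomap import group_means

        cfg, matrix, _ = sim_cohort
        f = sum(cfg.map_cm["female"].values())
        m = sum(cfg.map_cm["male"].values())
        assert f / m > 1.1
        calls = call_events(apply_missing_scenario(matrix, ref_panel, "conservative"), ref_panel)
        means = group_means(calls)
        assert means.loc["FWT", "mean"] > means.loc["MWT", "mean"]
        assert means.loc["FKO", "mean"] > means.loc["MKO", "mean"]
        # and the genotype contrast is null by construction
        totals = calls.per_sample_total()
        r = mann_whitney_groups(totals[calls.group_mask("FWT")], totals[calls.group_mask("FKO")])
        assert not r.significant


class TestSizeVsRate:
    def test_fixture_ratio(self, ref_panel):
        calls = counts_to_callset()
        ratio = size_vs_rate(calls, ref_panel, group_sizes=GROUP_SIZES)
        assert ratio == pytest.approx((107 / 157) / 51.44 / ((149 / 157) / 187.48), rel=1e-9)
        assert ratio >= 2

    def test_identical_chromosomes_ratio_one(self, ref_panel):
        calls = counts_to_callset()
        assert size_vs_rate(calls, ref_panel, chrom_big=5, chrom_small=5,
                            group_sizes=GROUP_SIZES) == 1.0

    def test_flat_genome_ratio_near_one(self, two_chrom_panel):
        """Uniform cM/Mbp on both chromosomes -> pooled ratio ~= 1."""
        from xomap import SimConfig, simulate_offspring

        dens = 0.6  # cM per Mbp on both chromosomes
        cmap = {1: dens * 100, 2: dens * 60}
        cfg = SimConfig(panel=two_chrom_panel, group_sizes={"FWT": 300, "MWT": 300},
                        map_cm={"female": cmap, "male": cmap}, missing_rate=0.0, seed=6)
        matrix, _ = simulate_offspring(cfg)
        calls = call_events(apply_missing_scenario(matrix, two_chrom_panel, "conservative"),
                            two_chrom_panel)
        ratio = size_vs_rate(calls, two_chrom_panel, chrom_big=1, chrom_small=2)
        assert 0.8 < ratio < 1.25

    def test_zero_rate_rejected(self, ref_panel):
        from xomap import CHROM_COUNTS

        calls = counts_to_callset(CHROM_COUNTS * 0, {"FWT": 5, "FKO": 5, "MWT": 5, "MKO": 5})
        with pytest.raises(ValueError, match="zero event rate"):
            size_vs_rate(calls, ref_panel, group_sizes={"FWT": 5, "MWT": 5})


class TestDetectionPower:
    def test_dense_panel_no_cancellation_decomposition(self, dense_panel):
        from xomap import SimConfig, simulate_offspring

        cfg = SimConfig(panel=dense_panel, group_sizes={"FWT": 60},
                        map_cm={"female": {1: 90}, "male": {1: 90}},
                        missing_rate=0.0, seed=8)
        matrix, truth = simulate_offspring(cfg)
        calls = call_events(apply_missing_scenario(matrix, dense_panel, "conservative"), dense_panel)
        p = detection_power(calls, truth, dense_panel)
        assert p.residual == 0
        assert p.n_called == p.n_true - p.n_true_out_of_span - p.n_cancelled_in_span

    def test_zero_truth_rejected(self, dense_panel):
        from xomap import SimConfig, simulate_offspring

        cfg = SimConfig(panel=dense_panel, group_sizes={"FWT": 2},
                        map_cm={"female": {1: 0.0}, "male": {1: 0.0}}, missing_rate=0.0, seed=1)
        matrix, truth = simulate_offspring(cfg)
        calls = call_events(apply_missing_scenario(matrix, dense_panel, "conservative"), dense_panel)
        with pytest.raises(ValueError, match="zero crossovers"):
            detection_power(calls, truth, dense_panel)

    def test_sample_mismatch_rejected(self, sim_cohort, clean_cohort, ref_panel):
        _, matrix, _ = sim_cohort
        _, _, other_truth = clean_cohort
        calls = call_events(apply_missing_scenario(matrix, ref_panel, "conservative"), ref_panel)
        with pytest.raises(ValueError, match="different samples"):
            detection_power(calls, other_truth, ref_panel)

    def test_map_parameter_recovery_dense(self, dense_panel):
        """Per-chromosome estimated cM recovers the configured map within 3
        Monte-Carlo SEs on a dense panel."""
        from xomap import SimConfig, group_means, simulate_offspring

        true_cm = 85.0
        cfg = SimConfig(panel=dense_panel, group_sizes={"FWT": 500},
                        map_cm={"female": {1: true_cm}, "male": {1: true_cm}},
                        missing_rate=0.0, seed=10)
        matrix, _ = simulate_offspring(cfg)
        calls = call_events(apply_missing_scenario(matrix, dense_panel, "conservative"), dense_panel)
        totals = calls.per_sample_total()
        est_cm = 100 * totals.mean()
        se_cm = 100 * totals.std(ddof=1) / np.sqrt(len(totals))
        # dense 1-Mbp spacing still misses out-of-span and cancelled events (~few %)
        span_frac = dense_panel.span_mbp(1) / 100.0
        assert abs(est_cm - true_cm * span_frac) < 3 * se_cm + 0.02 * true_cm
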