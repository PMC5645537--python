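"""Wilcoxon, Friedman, Holm and the full statistical battery."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from rhythmtag.cohort import CohortConfig, IMAGERY_CONDITIONS, generate_cohort
from rhythmtag.pipeline import (
    RunConfig,
    amplitude_table,
    cohort_spectra,
)
from rhythmtag.stats import (
    StatsConfig,
    friedman_test,
    holm_adjust,
    run_stat_battery,
    wilcoxon_signed_rank,
)


def enumeration_wilcoxon_p(values: np.ndarray) -> float:
    """Exhaustive one-tailed signed-rank p over all 2^n sign assignments."""
    ranks = sps.rankdata(np.abs(values))
    w_obs = ranks[values > 0].sum()
    n = len(values)
    hits = 0
    for signs in product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        hits += w >= w_obs
    return hits / 2**n


class TestWilcoxon:
    def test_nine_positive_values_give_minimal_p(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 10.0))
        assert res.p_value == pytest.approx(1 / 512, abs=1e-12)
        assert res.marks == "**"

    def test_symmetric_values_near_null(self):
        values = [1.0, -1.1, 2.0, -2.1, 3.0, -3.1, 4.0, -4.1]
        res = wilcoxon_signed_rank(values)
        assert 0.3 < res.p_value < 0.7

    @pytest.mark.parametrize("n", [5, 6, 7, 8, 9])
    def test_matches_exhaustive_enumeration(self, n, rng):
        for _ in range(6):
            values = rng.normal(size=n)
            res = wilcoxon_signed_rank(values)
            assert res.p_value == pytest.approx(
                enumeration_wilcoxon_p(values), abs=1e-12
            )

    def test_minimal_p_is_floor_for_n9(self, rng):
        for _ in range(20):
            res = wilcoxon_signed_rank(rng.normal(size=9))
            assert res.p_value >= 1 / 512 - 1e-12

    def test_z_statistic_normal_approximation(self):
        # all-positive n=9: W+ = 45, mu = 22.5, sigma = sqrt(71.25)
        res = wilcoxon_signed_rank(np.arange(1.0, 10.0))
        assert res.statistic == pytest.approx(22.5 / np.sqrt(71.25), abs=1e-9)

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0] * 9)

    def test_too_few_nonzero_values_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 2.0])


class TestFriedman:
    def test_identical_columns_null(self):
        m = np.tile(np.arange(9.0)[:, None], (1, 3))
        res = friedman_test(m)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_closed_form_for_dominant_column(self):
        # one column always ranks highest; chi-square from the rank-sum formula
        rng = np.random.default_rng(0)
        base = rng.normal(size=(9, 3))
        base[:, 2] += 100.0
        res = friedman_test(base)
        ranks = np.apply_along_axis(sps.rankdata, 1, base)
        r_bar = ranks.mean(axis=0)
        n, k = base.shape
        expected = 12 * n / (k * (k + 1)) * np.sum((r_bar - (k + 1) / 2) ** 2)
        assert res.statistic == pytest.approx(expected)

    def test_agrees_with_scipy_for_three_treatments(self, rng):
        m = rng.normal(size=(9, 3))
        res = friedman_test(m)
        stat, p = sps.friedmanchisquare(m[:, 0], m[:, 1], m[:, 2])
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    def test_exact_enumeration_on_small_instance(self, rng):
        m = rng.normal(size=(4, 3))
        res = friedman_test(m, method="exact")
        # independent oracle: enumerate all within-row rank permutations
        from itertools import permutations

        perms = [np.array(p) for p in permutations([1, 2, 3])]
        obs_ranks = np.apply_along_axis(sps.rankdata, 1, m)

        def stat_of(ranks):
            n, k = ranks.shape
            rs = ranks.sum(axis=0)
            return 12 / (n * k * (k + 1)) * (rs**2).sum() - 3 * n * (k + 1)

        obs = stat_of(obs_ranks)
        hits = total = 0
        for combo in product(perms, repeat=4):
            hits += stat_of(np.vstack(combo)) >= obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    @pytest.mark.parametrize("wins", [3, 4, 5, 6])
    def test_two_treatments_match_sign_test_decision(self, wins):
        # rejection decision (alpha = 0.05) agrees with a two-sided sign test
        n = 6
        col_a = np.arange(1.0, n + 1)
        col_b = col_a + np.where(np.arange(n) < wins, 1.0, -1.0)
        res = friedman_test(np.column_stack([col_a, col_b]))
        sign_p = sps.binomtest(wins, n, 0.5).pvalue
        assert (res.p_value < 0.05) == (sign_p < 0.05)

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            friedman_test(np.zeros((5,)))


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.04]), [0.04])

    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06], atol=1e-12
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8)
    )
    def test_adjusted_never_below_raw_and_capped(self, p_values):
        adj = holm_adjust(p_values)
        assert np.all(adj >= np.asarray(p_values) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_smallest_raw_p_stays_smallest(self, rng):
        for _ in range(20):
            p = rng.uniform(size=6)
            adj = holm_adjust(p)
            assert np.argmin(adj) == np.argmin(p) or np.isclose(
                adj[np.argmin(adj)], adj[np.argmin(p)]
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


def _make_amplitude_table(rng, effects=None, sd=0.05):
    """Small synthetic per-subject amplitude table with planted effects."""
    effects = effects or {}
    rows = []
    tasks = ("marker_viewing",) + IMAGERY_CONDITIONS
    for subject in range(9):
        for task in tasks:
            for f in (0.8, 1.2, 1.6, 2.4, 3.2):
                base = effects.get((task, f), 0.0)
                for group in ("all", "occipital", "non_occipital", "frontal_pair"):
                    rows.append(
                        {
                            "subject": subject,
                            "condition": task,
                            "group": group,
                            "frequency": f,
                            "amplitude": base + rng.normal(0, sd),
                        }
                    )
    return pd.DataFrame(rows)


class TestBattery:
    def test_table1_shape_and_planted_effects(self, rng):
        effects = {
            ("ternary_meter", 0.8): 0.5,
            ("ternary_meter", 1.6): 0.25,
            ("marker_viewing", 2.4): 0.4,
            ("unaccented_beat", 2.4): 0.6,
            ("binary_meter", 1.2): 0.5,
            ("binary_meter", 2.4): 0.6,
        }
        report = run_stat_battery(_make_amplitude_table(rng, effects))
        assert len(report.table1) == 16
        t1 = report.table1.set_index(["task", "frequency"])
        assert t1.loc[("ternary_meter", 0.8), "p"] < 0.01
        assert t1.loc[("ternary_meter", 1.2), "p"] > 0.10
        assert len(report.pairwise) == 9
        assert len(report.friedman) == 4
        assert len(report.controls) == 3
        # harmonic decay: 0.8 > 1.6 > 3.2 within the ternary task
        assert (report.harmonic_contrasts["p"] < 0.05).all()

    def test_missing_cells_reported(self, rng):
        table = _make_amplitude_table(rng)
        broken = table[
            ~((table.condition == "binary_meter") & (table.frequency == 1.6))
        ]
        with pytest.raises(ValueError, match="binary_meter/1.6"):
            run_stat_battery(broken)

    def test_pairwise_gated_by_friedman(self, rng):
        null_report = run_stat_battery(_make_amplitude_table(rng))
        # no planted differences: Friedman rarely significant, gate mostly shut
        gated = null_report.pairwise["gated"]
        assert (~gated).any() or null_report.friedman["p"].min() < 0.10
        forced = run_stat_battery(
            _make_amplitude_table(rng), StatsConfig(always_pairwise=True)
        )
        assert forced.pairwise["gated"].all()
        assert forced.pairwise["p_raw"].notna().all()


class TestBatteryOnCohort:
    def test_default_cohort_battery_pattern(self, default_run):
        _, out_dir = default_run
        amp = pd.read_csv(out_dir / "group_amplitudes.csv", comment="#")
        report = run_stat_battery(amp)
        t1 = report.table1.set_index(["task", "frequency"])
        # fundamentals strongly expressed
        assert t1.loc[("ternary_meter", 0.8), "p"] < 0.01
        assert t1.loc[("binary_meter", 1.2), "p"] < 0.01
        assert t1.loc[("unaccented_beat", 2.4), "p"] < 0.01
        assert t1.loc[("marker_viewing", 2.4), "p"] < 0.01
        # no meter component in the ternary task at the binary frequency
        assert t1.loc[("ternary_meter", 1.2), "p"] > 0.10

    def test_contrast_type_one_error_at_zero_imagery(self):
        # imagery-vs-marker contrasts with no imagery signal: rejection rate
        # at the 0.10 level stays near nominal (scaled-down Monte Carlo)
        config = RunConfig()
        rejections = 0
        total = 0
        for seed in range(8):
            cohort_cfg = CohortConfig(
                imagery_amplitude=0.0, n_trials=4, seed=100 + seed
            )
            dataset = generate_cohort(cohort_cfg)
            spectra = cohort_spectra(dataset, config.preprocess, config.spectral)
            amp = amplitude_table(spectra, dataset, config.spectral)
            report = run_stat_battery(amp)
            rejections += int((report.visual_contrasts["p"] < 0.10).sum())
            total += len(report.visual_contrasts)
        rate = rejections / total
        assert rate <= 0.10 + 2 * np.sqrt(0.10 * 0.90 / total)
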