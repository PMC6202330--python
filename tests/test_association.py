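import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hs

from slpen import (
    GeneScoreMatrix,
    SimulationConfig,
    TimecourseConfig,
    aggregate_hairpins_to_gene,
    mp_test,
    mp_test_exact,
    run_mp_screen,
    simulate_hairpin_timecourse,
    status_calls_from_truth,
    trend_test,
    z_normalize_gene_scores,
)
from slpen import PlantedEffect
from slpen.rb_classify import DEFECTIVE, NOT_ALTERED, StatusCall


class TestAggregateHairpins:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([-3, -1, 0, 2], -2.0),  # mean of the two most depleted
            ([-5], -5.0),
            ([-1, -1, -1], -1.0),
        ],
    )
    def test_examples(self, scores, expected):
        assert aggregate_hairpins_to_gene(scores) == expected

    def test_mapping_input(self):
        assert aggregate_hairpins_to_gene({"hp1": -3.0, "hp2": 1.0, "hp3": -1.0}) == -2.0

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            aggregate_hairpins_to_gene([])

    @settings(derandomize=True, max_examples=100)
    @given(hs.lists(hs.floats(-10, 10, allow_nan=False), min_size=1, max_size=8))
    def test_permutation_invariant(self, scores):
        shuffled = list(reversed(sorted(scores)))
        assert aggregate_hairpins_to_gene(scores) == pytest.approx(
            aggregate_hairpins_to_gene(shuffled)
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        hs.lists(hs.floats(-10, 10, allow_nan=False), min_size=2, max_size=8),
        hs.floats(0.1, 5),
    )
    def test_lowering_a_lowest_score_never_raises_output(self, scores, drop):
        base = aggregate_hairpins_to_gene(scores)
        lowered = sorted(scores)
        lowered[0] -= drop
        assert aggregate_hairpins_to_gene(lowered) <= base + 1e-12


class TestZNormalize:
    def test_per_gene_moments(self, small_matrix):
        z = z_normalize_gene_scores(small_matrix, "per_gene")
        means = z.scores.mean(axis=1)
        sds = z.scores.std(axis=1, ddof=1)
        assert np.all(np.abs(means) < 1e-12)
        assert np.all(np.abs(sds - 1) < 1e-12)

    def test_missing_preserved(self, small_matrix):
        z = z_normalize_gene_scores(small_matrix, "per_gene")
        assert np.isnan(z.scores.loc["NULL1", "L3"])

    def test_per_line_moments(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.normal(size=(10, 6)),
            index=[f"G{i}" for i in range(10)],
            columns=[f"L{i}" for i in range(6)],
        )
        z = z_normalize_gene_scores(GeneScoreMatrix(df), "per_line")
        assert np.all(np.abs(z.scores.mean(axis=0)) < 1e-12)
        assert np.all(np.abs(z.scores.std(axis=0, ddof=1) - 1) < 1e-12)

    def test_zero_spread_names_offender(self):
        df = pd.DataFrame({"L1": [5.0, 1.0], "L2": [5.0, 2.0], "L3": [5.0, 3.0]},
                          index=["FLAT", "OK"])
        with pytest.raises(ValueError, match="FLAT"):
            z_normalize_gene_scores(GeneScoreMatrix(df), "per_gene")


class TestMpTestExact:
    def test_toy_partition_count(self):
        # only the observed split of C(5,2)=10 attains diff <= -3.5
        assert mp_test_exact([-3, -2], [0, 1, 2], side="less") == pytest.approx(0.1)

    def test_singleton_group_allowed(self):
        p = mp_test_exact([5], [1, 2], side="greater")
        assert p == pytest.approx(1 / 3)

    def test_label_swap_with_side_flip_is_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=4), rng.normal(size=5)
        assert mp_test_exact(a, b, "less") == pytest.approx(mp_test_exact(b, a, "greater"))

    def test_infeasible_size_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            mp_test_exact(np.zeros(15), np.zeros(15))


class TestMpTest:
    def test_all_ties_saturate_to_one(self):
        res = mp_test([0.0, 0.0, 0.0], [0.0, 0.0, 0.0], n_perm=500, seed=0, side="less")
        assert res.diff == 0.0
        assert res.p == pytest.approx(1.0)

    def test_monte_carlo_matches_exact_oracle(self):
        n_perm = 100_000
        res = mp_test([-3, -2], [0, 1, 2], n_perm=n_perm, seed=1, side="less")
        exact = 0.1
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p - exact) < 3 * se + 1 / n_perm

    def test_result_fields(self):
        res = mp_test([-3, -2], [0, 1, 2], n_perm=1000, seed=0)
        assert res.n_def == 2 and res.n_not == 3
        assert res.diff == pytest.approx(res.median_def - res.median_not)
        assert res.p >= 1 / 1001

    def test_invariant_to_shift_and_positive_rescale(self):
        rng = np.random.default_rng(7)
        d, n = rng.normal(-1, 1, 6), rng.normal(0, 1, 8)
        base = mp_test(d, n, n_perm=2000, seed=3).p
        shifted = mp_test(d + 5, n + 5, n_perm=2000, seed=3).p
        scaled = mp_test(d * 2.5, n * 2.5, n_perm=2000, seed=3).p
        assert base == shifted == scaled

    def test_reproducible_given_seed(self):
        d, n = [-2.0, -1.0, 0.5], [0.0, 1.0, 0.3, -0.2]
        assert mp_test(d, n, 1000, seed=9).p == mp_test(d, n, 1000, seed=9).p

    def test_group_too_small_is_error(self):
        with pytest.raises(ValueError, match="non-missing"):
            mp_test([1.0], [0.0, 1.0], n_perm=1000, seed=0)

    def test_all_missing_group_is_error(self):
        with pytest.raises(ValueError, match="non-missing"):
            mp_test([np.nan, np.nan], [0.0, 1.0, 2.0], n_perm=1000, seed=0)


class TestRunMpScreen:
    def test_planted_gene_attains_minimal_p(self, small_matrix, small_calls):
        results = run_mp_screen(small_matrix, small_calls, n_perm=1000, seed=2)
        by_gene = {r.gene_id: r for r in results}
        # SLG is shifted ~ -2.5 in defective lines: best achievable p
        assert by_gene["SLG"].p == min(r.p for r in results if r.tested)
        assert by_gene["SLG"].diff < -2

    def test_column_permutation_leaves_p_unchanged(self, small_matrix, small_calls):
        base = {r.gene_id: r.p for r in run_mp_screen(small_matrix, small_calls, 1000, seed=5)}
        permuted = GeneScoreMatrix(
            small_matrix.scores[["L4", "L2", "L6", "L1", "L3", "L5"]], "zgarp"
        )
        after = {r.gene_id: r.p for r in run_mp_screen(permuted, small_calls, 1000, seed=5)}
        assert base == after

    def test_untested_gene_reported_not_dropped(self, small_matrix, small_calls):
        df = small_matrix.scores.copy()
        df.loc["NULL1", ["L1", "L2"]] = np.nan  # one defective line left
        results = run_mp_screen(GeneScoreMatrix(df, "zgarp"), small_calls, 1000, seed=0)
        by_gene = {r.gene_id: r for r in results}
        assert not by_gene["NULL1"].tested
        assert np.isnan(by_gene["NULL1"].p)
        assert len(results) == 3

    def test_no_defective_lines_is_error(self, small_matrix):
        calls = [StatusCall(l, NOT_ALTERED) for l in small_matrix.line_ids]
        with pytest.raises(ValueError, match="defective"):
            run_mp_screen(small_matrix, calls, 1000, seed=0)

    def test_q_values_monotone_with_p(self, small_matrix, small_calls):
        results = run_mp_screen(small_matrix, small_calls, 1000, seed=1)
        tested = sorted((r for r in results if r.tested), key=lambda r: r.p)
        qs = [r.q for r in tested]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.q >= r.p for r in tested)


def _timecourse(gamma: float, seed: int, n_lines: int = 12, pi: float = 1.0):
    cfg = SimulationConfig(
        n_genes=1,
        n_lines=n_lines,
        frac_defective=0.5,
        seed=seed,
        planted_sl=(PlantedEffect("SLGENE", pi, 3.0),),
        timecourse=TimecourseConfig(gamma=gamma),
    )
    tc, truth = simulate_hairpin_timecourse(cfg)
    return tc, status_calls_from_truth(truth)


class TestTrendTest:
    def test_identical_slopes_give_zero_gamma(self):
        # deterministic construction: same slope everywhere
        rows = []
        for hp in ("hp1", "hp2"):
            for line in ("D1", "D2", "N1", "N2"):
                for t in (0.0, 1.0, 2.0):
                    rows.append(
                        {"hairpin_id": hp, "gene_id": "G", "line_id": line,
                         "time": t, "log_abundance": -0.5 * t}
                    )
        calls = [
            StatusCall("D1", DEFECTIVE, frozenset({"mrna_low"})),
            StatusCall("D2", DEFECTIVE, frozenset({"mrna_low"})),
            StatusCall("N1", NOT_ALTERED),
            StatusCall("N2", NOT_ALTERED),
        ]
        model = trend_test(pd.DataFrame(rows), calls, side="less")
        assert model.beta_group_trend == pytest.approx(0.0, abs=1e-10)
        assert model.p >= 0.5

    def test_single_hairpin_matches_ols_group_test(self):
        tc, calls = _timecourse(gamma=-0.5, seed=3)
        tc = tc[tc["hairpin_id"] == tc["hairpin_id"].iloc[0]]
        model = trend_test(tc, calls, side="less")
        assert model.method == "ols"
        # independent route: equal-variance t test on per-line OLS slopes
        slopes = {}
        for line, grp in tc.groupby("line_id"):
            slopes[line] = np.polyfit(grp["time"], grp["log_abundance"], 1)[0]
        status = {c.sample_id: c.status for c in calls}
        d = [s for l, s in slopes.items() if status[l] == DEFECTIVE]
        n = [s for l, s in slopes.items() if status[l] == NOT_ALTERED]
        t, p_two = st.ttest_ind(d, n, equal_var=True)
        expected = p_two / 2 if (np.mean(d) - np.mean(n)) < 0 else 1 - p_two / 2
        assert model.p == pytest.approx(expected, abs=1e-6)

    def test_negative_gamma_detected(self):
        tc, calls = _timecourse(gamma=-0.5, seed=11)
        model = trend_test(tc, calls, side="less")
        assert model.beta_group_trend < 0
        assert model.p < 0.05
        assert model.method == "mixed"

    def test_insufficient_time_points_error_lists_hairpins(self):
        tc, calls = _timecourse(gamma=-0.5, seed=1)
        broken = tc[(tc["hairpin_id"] != "SLGENE_hp0") | (tc["time"] == 0.0)]
        with pytest.raises(ValueError, match="SLGENE_hp0"):
            trend_test(broken, calls)
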