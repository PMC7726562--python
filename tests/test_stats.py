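"""Rank-statistics oracles: enumeration, permutation and hand computation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from athero3d.stats import fdr_adjust, mann_whitney, run_paper_analyses, spearman


def exact_mw_p(a, b):
    """Full-enumeration two-sided Mann-Whitney p: distribution of U over all
    C(n+m, n) assignments of the pooled values to group A."""
    pooled = np.concatenate([a, b])
    n = len(a)
    obs = sum(1.0 * (x > y) + 0.5 * (x == y) for x in a for y in b)
    us = []
    for idx in combinations(range(len(pooled)), n):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        us.append(sum(1.0 * (x > y) + 0.5 * (x == y) for x in ga for y in gb))
    us = np.asarray(us)
    mean_u = len(a) * len(b) / 2.0
    # two-sided: as or more extreme in |U - mean|
    return float(np.mean(np.abs(us - mean_u) >= np.abs(obs - mean_u) - 1e-12))


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_exact_enumeration(self):
        # (1,2,3) vs (4,5,6): U = 0, two-sided exact p = 2/20 = 0.1
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert min(res.statistic, 9 - res.statistic) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(3, 7))
        b = rng.normal(size=rng.integers(3, 7))
        res = mann_whitney(a, b)
        assert res.p_value == pytest.approx(exact_mw_p(a, b), abs=1e-12)

    def test_exact_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=5)
        b = rng.normal(size=5) + 1.0
        res = mann_whitney(a, b)
        # Monte-Carlo permutation estimate of the same two-sided p
        pooled = np.concatenate([a, b])
        obs = sum((x > y) for x in a for y in b)
        mean_u = 12.5
        hits = 0
        n_perm = 100_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            u = sum((x > y) for x in perm[:5] for y in perm[5:])
            hits += abs(u - mean_u) >= abs(obs - mean_u) - 1e-12
        assert res.p_value == pytest.approx(hits / n_perm, abs=0.01)

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="equal lengths"):
            mann_whitney([1, 2], [1, 2, 3], paired=True)

    def test_paired_is_signed_rank_on_differences(self):
        from scipy.stats import wilcoxon

        a = np.array([3.0, 5.0, 4.0, 6.5, 8.0, 2.0])
        b = np.array([1.0, 2.0, 4.5, 3.0, 9.25, 1.75])
        res = mann_whitney(a, b, paired=True)
        stat, p = wilcoxon(a - b, method="exact")
        assert res.p_value == pytest.approx(p)
        assert res.paired and res.test == "wilcoxon-signed-rank"

    def test_paired_zero_differences_dropped(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        r, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)

    def test_perfect_inverse(self):
        r, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    @pytest.mark.parametrize("y, expected", [
        ([2, 1, 4, 3, 5], 0.8),   # sum d^2 = 4 -> 1 - 24/120
        ([1, 2, 5, 3, 4], 0.7),   # sum d^2 = 6 -> 1 - 36/120
    ])
    def test_hand_computed_toy_pairs(self, y, expected):
        r, _ = spearman([1, 2, 3, 4, 5], y)
        assert r == pytest.approx(expected)

    def test_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        pearson = np.corrcoef(rx, ry)[0, 1]
        r, _ = spearman(x, y)
        assert r == pytest.approx(pearson, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFDR:
    def test_bh_by_hand(self):
        # min over tail of p*m/rank: all become 0.04
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_order_preserving(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=12)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-15)             # step-up never lowers below raw p
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)  # monotone in the p ordering

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=60)
    @given(p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20))
    def test_step_up_properties_hold_for_any_p_vector(self, p):
        """BH never lowers a p-value, stays in [0, 1] and preserves order."""
        q = fdr_adjust(p)
        p = np.asarray(p)
        assert np.all(q >= p - 1e-12)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


def _cohort_table(rng, n_per_group=10, effect=1.0):
    rows = []
    for diet in ("chow", "western"):
        scale = effect if diet == "western" else 1.0
        for i in range(n_per_group):
            total = rng.lognormal(mean=np.log(0.02 * scale), sigma=0.4)
            row = {"animal_id": f"{diet}{i}", "genotype": "ApoE-/-", "diet": diet,
                   "total_volume_mm3": total}
            for comp in ("DESC", "ARCH", "BCA", "LSA", "LCCA"):
                row[f"volume_{comp}_mm3"] = total * rng.uniform(0.05, 0.4)
                row[f"cd45_{comp}_mm3"] = row[f"volume_{comp}_mm3"] * rng.uniform(0.1, 0.6)
            rows.append(row)
    return pd.DataFrame(rows)


class TestAnalysisBattery:
    def test_strong_diet_effect_detected(self):
        rng = np.random.default_rng(7)
        report = run_paper_analyses(_cohort_table(rng, effect=5.0))
        diet = report[report.family == "diet"]
        assert len(diet) == 1 and diet.p_value.iloc[0] < 0.05

    def test_row_count_deterministic(self):
        rng = np.random.default_rng(1)
        table = _cohort_table(rng)
        r1 = run_paper_analyses(table)
        r2 = run_paper_analyses(table)
        # 1 diet + 10 compartment pairs + 5 cd45 contrasts for one genotype
        assert len(r1) == 16
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_cohorts_type_I_controlled(self):
        rng = np.random.default_rng(11)
        flagged = 0
        n_cohorts = 200
        for _ in range(n_cohorts):
            a = rng.lognormal(size=10)
            b = rng.lognormal(size=10)
            if mann_whitney(a, b).p_value < 0.05:
                flagged += 1
        assert flagged / n_cohorts <= 0.07

    def test_missing_columns_listed(self):
        with pytest.raises(ValueError, match="total_volume_mm3"):
            run_paper_analyses(pd.DataFrame({"animal_id": [1], "genotype": ["a"],
                                             "diet": ["chow"]}))

    def test_fdr_applied_within_families(self):
        rng = np.random.default_rng(5)
        report = run_paper_analyses(_cohort_table(rng))
        assert report.loc[report.family == "compartment", "q_value"].notna().all()
        assert report.loc[report.family == "diet", "q_value"].isna().all()
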