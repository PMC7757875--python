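"""Association battery: Fisher exact, multinomial AMEs, KW, Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coopgene.association import (
    BatteryConfig,
    TestFamily as BonferroniFamily,
    fisher_exact,
    kruskal_wallis,
    multinomial_ame,
    run_battery,
    scenario_means,
)


# ---------------------------------------------------------------------------
# scenario means

class TestScenarioMeans:
    def test_identity(self, identity_schedule):
        sm = scenario_means(identity_schedule)
        assert (sm.low, sm.mid, sm.high) == (3, 10, 17)

    def test_constant(self):
        sm = scenario_means((7,) * 21)
        assert (sm.low, sm.mid, sm.high) == (7, 7, 7)

    def test_zeros(self, zeros_schedule):
        sm = scenario_means(zeros_schedule)
        assert (sm.low, sm.mid, sm.high) == (0, 0, 0)

    def test_scenarios_average_to_full_mean(self, rng):
        for _ in range(20):
            entries = tuple(int(v) for v in rng.integers(0, 21, 21))
            sm = scenario_means(entries)
            assert (sm.low + sm.mid + sm.high) / 3 == pytest.approx(
                np.mean(entries)
            )


# ---------------------------------------------------------------------------
# multiple-testing ledger

class TestBonferroniLedger:
    @pytest.mark.parametrize(
        "m, printed", [(6, 0.008), (40, 0.00125), (18, 0.003)]
    )
    def test_printed_thresholds(self, m, printed):
        fam = BonferroniFamily("fam", m)
        assert fam.per_test_alpha == pytest.approx(0.05 / m)
        assert fam.per_test_alpha_printed == printed

    def test_flag_count_non_increasing_in_m(self, rng):
        ps = rng.random(30) * 0.05
        flags = [int((ps < BonferroniFamily("f", m).per_test_alpha).sum())
                 for m in (1, 6, 18, 40)]
        assert flags == sorted(flags, reverse=True)


# ---------------------------------------------------------------------------
# Fisher exact

class TestFisherExact:
    def test_perfect_association_2x2(self):
        """((5,0),(0,5)): only the table and its mirror are as extreme;
        p = 2 / C(10,5) = 2/252."""
        res = fisher_exact([[5, 0], [0, 5]])
        assert res.method == "exact"
        assert res.p == pytest.approx(2 / 252)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact([[7, 3], [7, 3]]).p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 7], [5, 2]],
            [[10, 2], [4, 9]],
            [[1, 8], [6, 1]],
            [[12, 12], [11, 13]],
        ],
    )
    def test_matches_scipy_on_2x2(self, table):
        mine = fisher_exact(table)
        ref = stats.fisher_exact(np.array(table))
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_sex_by_strategy_table(self):
        """4x2 strategy x sex table: two-sided p = 0.545 (R fisher.test
        gives 0.5444617 on the same counts)."""
        table = [[48, 44], [13, 9], [10, 8], [36, 20]]
        res = fisher_exact(table)
        assert res.method == "exact"
        assert res.p == pytest.approx(0.5444617, abs=5e-4)

    def test_invariant_to_row_and_column_permutations(self, rng):
        table = np.array([[8, 3, 6], [2, 9, 4], [5, 5, 1], [3, 2, 7]])
        base = fisher_exact(table).p
        for _ in range(5):
            t = table[rng.permutation(4)][:, rng.permutation(3)]
            assert fisher_exact(t).p == pytest.approx(base, rel=1e-9)
        assert fisher_exact(table.T).p == pytest.approx(base, rel=1e-9)

    def test_monte_carlo_agrees_with_exact(self, rng):
        table = np.array([[8, 3, 6], [2, 9, 4], [5, 5, 12]])
        exact = fisher_exact(table).p
        mc = fisher_exact(table, budget=10, rng=rng)
        assert mc.method == "monte-carlo"
        assert mc.draws >= 100_000
        assert mc.p == pytest.approx(exact, abs=0.01)

    def test_monte_carlo_minimum_draws_enforced(self, rng):
        with pytest.raises(ValueError, match="1e5"):
            fisher_exact([[8, 3], [2, 9]], budget=1, mc_draws=10_000, rng=rng)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fisher_exact([[0, 0], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[5]])


# ---------------------------------------------------------------------------
# multinomial marginal effects

class TestMultinomialAME:
    @staticmethod
    def _toy_cohort():
        labels = (["CC"] * 12 + ["FR"] * 5 + ["OT"] * 3
                  + ["CC"] * 6 + ["FR"] * 9 + ["OT"] * 5)
        genos = ["AA"] * 20 + ["GG"] * 20
        return np.array(labels), np.array(genos)

    def test_saturated_model_equals_proportion_differences(self, rng):
        labels, genos = self._toy_cohort()
        res = multinomial_ame(labels, genos, baseline="AA", rng=rng)
        by = {(r["level"], r["outcome"]): r["ame"] for _, r in res.iterrows()}
        assert by[("GG", "CC")] == pytest.approx(6 / 20 - 12 / 20)
        assert by[("GG", "FR")] == pytest.approx(9 / 20 - 5 / 20)
        assert by[("GG", "OT")] == pytest.approx(5 / 20 - 3 / 20)
        assert by[("GG", "HS")] == pytest.approx(0.0)

    def test_agrees_with_multinomial_logit_fit(self, rng):
        """Independent route: statsmodels MNLogit on dummy-coded genotype
        reproduces the same fitted probabilities, hence the same AMEs."""
        sm = pytest.importorskip("statsmodels.api")
        labels, genos = self._toy_cohort()
        y = pd.get_dummies(pd.Series(labels)).to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(genos)), (genos == "GG").astype(float)]
        )
        fit = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
        probs = fit.predict(np.array([[1.0, 0.0], [1.0, 1.0]]))
        outcome_names = sorted(set(labels))  # get_dummies column order
        mine = multinomial_ame(labels, genos, baseline="AA", rng=rng)
        by = {(r["level"], r["outcome"]): r["ame"] for _, r in mine.iterrows()}
        for j, name in enumerate(outcome_names):
            assert by[("GG", name)] == pytest.approx(
                probs[1, j] - probs[0, j], abs=1e-5
            )

    def test_identical_groups_have_zero_effects(self, rng):
        labels = np.array((["CC"] * 6 + ["FR"] * 4) * 2)
        genos = np.array(["AA"] * 10 + ["GG"] * 10)
        res = multinomial_ame(labels, genos, baseline="AA", rng=rng)
        assert (res["ame"] == 0).all()
        assert (res["p"].dropna() > 0.5).all()

    def test_effects_sum_to_zero_across_outcomes(self, rng):
        labels = np.array(["CC", "FR", "OT", "HS"] * 10 + ["CC"] * 12 + ["FR"] * 8)
        genos = np.array(["AA"] * 40 + ["GG"] * 20)
        res = multinomial_ame(labels, genos, baseline="AA", rng=rng)
        sums = res.groupby("level")["ame"].sum()
        assert np.allclose(sums, 0.0, atol=1e-12)

    def test_separation_is_flagged(self, rng):
        labels = np.array(["CC"] * 10 + ["CC"] * 4 + ["FR"] * 8)
        genos = np.array(["AA"] * 10 + ["GG"] * 12)
        res = multinomial_ame(labels, genos, baseline="AA", rng=rng)
        assert res["separated"].all()  # baseline shows a single strategy
        assert res["p"].notna().all()  # the pooled score p is still defined

    def test_planted_effect_ci_coverage(self):
        """Bootstrap CIs cover the true difference of probabilities in at
        least 90% of seeded replications at n = 5000."""
        p_a = {"CC": 0.40, "HS": 0.15, "FR": 0.15, "OT": 0.30}
        p_g = {"CC": 0.60, "HS": 0.10, "FR": 0.10, "OT": 0.20}
        true_ame_cc = p_g["CC"] - p_a["CC"]
        outcomes = list(p_a)
        hits = reps = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            n_half = 2500
            lab_a = rng.choice(outcomes, n_half, p=[p_a[o] for o in outcomes])
            lab_g = rng.choice(outcomes, n_half, p=[p_g[o] for o in outcomes])
            labels = np.concatenate([lab_a, lab_g])
            genos = np.array(["AA"] * n_half + ["GG"] * n_half)
            res = multinomial_ame(labels, genos, baseline="AA",
                                  bootstrap_reps=400, rng=rng)
            row = res[(res["level"] == "GG") & (res["outcome"] == "CC")].iloc[0]
            assert row["ame"] == pytest.approx(true_ame_cc, abs=0.05)
            assert row["p"] < 0.01  # a planted effect this large is detected
            hits += row["ci_low"] <= true_ame_cc <= row["ci_high"]
            reps += 1
        assert hits / reps >= 0.90

    def test_requires_two_levels_and_enough_reps(self, rng):
        labels = np.array(["CC"] * 5)
        with pytest.raises(ValueError):
            multinomial_ame(labels, np.array(["AA"] * 5), baseline="AA", rng=rng)
        with pytest.raises(ValueError):
            multinomial_ame(
                np.array(["CC", "FR"] * 5),
                np.array(["AA", "GG"] * 5),
                baseline="AA",
                bootstrap_reps=50,
                rng=rng,
            )


# ---------------------------------------------------------------------------
# Kruskal-Wallis

def _oracle_kw(values, groups):
    """Independent rank-based H with tie correction, computed by hand."""
    values = list(values)
    n = len(values)
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        eq = sum(1 for w in values if w == v)
        ranks.append(less + (eq + 1) / 2)
    h = 0.0
    for g in set(groups):
        r_g = [r for r, gg in zip(ranks, groups) if gg == g]
        h += len(r_g) * (np.mean(r_g) - (n + 1) / 2) ** 2
    h *= 12 / (n * (n + 1))
    # tie correction
    from collections import Counter
    ties = Counter(values)
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction


class TestKruskalWallis:
    def test_all_equal_values(self):
        h, p = kruskal_wallis([3, 3, 3, 3], ["a", "a", "b", "b"])
        assert h == 0.0 and p == 1.0

    def test_matches_hand_rank_computation(self):
        values = [1, 2, 3, 4, 5, 6]
        groups = ["a"] * 3 + ["b"] * 3
        h, p = kruskal_wallis(values, groups)
        assert h == pytest.approx(_oracle_kw(values, groups))
        assert h == pytest.approx(3.857, abs=0.001)

    def test_matches_hand_rank_computation_with_ties(self):
        values = [1, 1, 2, 2, 3, 5, 5, 7]
        groups = ["a", "b", "a", "b", "a", "b", "a", "b"]
        h, _ = kruskal_wallis(values, groups)
        assert h == pytest.approx(_oracle_kw(values, groups))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_permutation_null_rejection_rate(self, rng):
        """Rejection at 5% stays near nominal under label permutation."""
        values = rng.integers(0, 21, 60).astype(float)
        groups = np.array(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            perm = rng.permutation(groups)
            _, p = kruskal_wallis(values, perm)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


# ---------------------------------------------------------------------------
# the battery

def _make_frame(n_per_cell=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for sex in ("female", "male"):
        for strat in ("CC", "HS", "FR", "OT"):
            for _ in range(n_per_cell):
                rows.append(
                    {
                        "sex": sex,
                        "strategy": strat,
                        "maoa": rng.choice(["H", "L"]),
                        "oxtr": rng.choice(["AA", "GA", "GG"]),
                        "avpr1a": rng.choice(
                            ["Long/Long", "Short/Long", "Short/Short"]
                        ),
                        "uninformed": int(rng.integers(0, 21)),
                        "scenario_low": float(rng.uniform(0, 20)),
                        "scenario_mid": float(rng.uniform(0, 20)),
                        "scenario_high": float(rng.uniform(0, 20)),
                    }
                )
    return pd.DataFrame(rows)


class TestBattery:
    def test_structure_and_flag_consistency(self):
        frame = _make_frame()
        config = BatteryConfig(bootstrap_reps=200, seed=7)
        report = run_battery(frame, config)
        fams = report.families
        assert [fams[k].m for k in ("fisher", "ame", "kw_scenarios",
                                    "kw_uninformed")] == [6, 40, 18, 6]
        t = report.tests
        assert set(t["family"]) <= set(fams)
        normal = t["p"].notna()
        assert (
            t.loc[normal, "significant"]
            == (t.loc[normal, "p"] < t.loc[normal, "per_test_alpha"])
        ).all()
        # 6 fisher + 2*(8+8+4) ame + 18 kw + 6 kw
        assert t.groupby("family").size().to_dict() == {
            "fisher": 6, "ame": 40, "kw_scenarios": 18, "kw_uninformed": 6
        }

    def test_single_level_stratum_is_skipped_not_fatal(self):
        frame = _make_frame()
        frame.loc[frame["sex"] == "male", "maoa"] = "H"
        report = run_battery(frame, BatteryConfig(bootstrap_reps=200, seed=7))
        assert any("male/maoa" in s for s in report.skipped)
        # the family size (hence threshold) is unchanged
        assert report.families["fisher"].m == 6
        male_maoa = report.tests[
            (report.tests["sex"] == "male") & (report.tests["variant"] == "maoa")
        ]
        assert male_maoa.empty
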