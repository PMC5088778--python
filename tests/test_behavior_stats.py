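"""Behavioral statistics vs hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from alphalat import (
    CHANCE_3AFC,
    CHANCE_DISTRACTOR_INFORMED,
    SimulationParams,
    distractor_cost,
    exclude_subjects,
    generate_schedule,
    pairwise_bonferroni,
    pool_similarity,
    reject_trials,
    rm_anova_2x4,
    simulate_behavior,
    t_vs_chance,
)


def brute_force_rm_anova(y):
    """Full-model sums-of-squares oracle, written directly from definitions.

    Every sum of squares is computed by explicit summation over the table
    cells, independent of the implementation's vectorized path.
    """
    n, na, nb = y.shape
    gm = y.mean()
    ss = {k: 0.0 for k in ("A", "B", "AB", "AS", "BS", "ABS")}
    for i in range(na):
        ss["A"] += n * nb * (y[:, i, :].mean() - gm) ** 2
    for j in range(nb):
        ss["B"] += n * na * (y[:, :, j].mean() - gm) ** 2
    for i in range(na):
        for j in range(nb):
            ss["AB"] += n * (
                y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + gm
            ) ** 2
    for s in range(n):
        for i in range(na):
            ss["AS"] += nb * (
                y[s, i, :].mean() - y[s].mean() - y[:, i, :].mean() + gm
            ) ** 2
        for j in range(nb):
            ss["BS"] += na * (
                y[s, :, j].mean() - y[s].mean() - y[:, :, j].mean() + gm
            ) ** 2
        for i in range(na):
            for j in range(nb):
                ss["ABS"] += (
                    y[s, i, j]
                    - y[s, i, :].mean()
                    - y[s, :, j].mean()
                    - y[:, i, j].mean()
                    + y[s].mean()
                    + y[:, i, :].mean()
                    + y[:, :, j].mean()
                    - gm
                ) ** 2
    f_a = (ss["A"] / (na - 1)) / (ss["AS"] / ((na - 1) * (n - 1)))
    f_b = (ss["B"] / (nb - 1)) / (ss["BS"] / ((nb - 1) * (n - 1)))
    f_ab = (ss["AB"] / ((na - 1) * (nb - 1))) / (
        ss["ABS"] / ((na - 1) * (nb - 1) * (n - 1))
    )
    return f_a, f_b, f_ab


class TestRejectTrials:
    def test_counting_and_no_double_rejection(self):
        df = pd.DataFrame(
            {
                "correct": [True] * 7 + [False, False, True],
                "eye_movement": [False] * 9 + [True],
            }
        )
        assert len(reject_trials(df)) == 7
        # a trial both incorrect and eye-flagged is still only one rejection
        df2 = df.copy()
        df2.loc[8, "eye_movement"] = True
        assert len(reject_trials(df2)) == 7

    def test_all_clean_retains_all_in_order(self):
        df = pd.DataFrame({"correct": [True] * 5, "eye_movement": [False] * 5})
        assert np.array_equal(reject_trials(df), np.arange(5))


class TestRmAnova:
    def test_flat_table_gives_zero_f(self):
        y = np.ones((4, 2, 4)) * 7.0
        tab = rm_anova_2x4(y)
        assert (tab["F"] == 0).all()
        assert (tab["p"] == 1).all()

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            y = rng.standard_normal((4, 2, 4)) * 50 + 800
            tab = rm_anova_2x4(y)
            f_a, f_b, f_ab = brute_force_rm_anova(y)
            assert tab.loc["cue", "F"] == pytest.approx(f_a, rel=1e-10)
            assert tab.loc["distractor", "F"] == pytest.approx(f_b, rel=1e-10)
            assert tab.loc["interaction", "F"] == pytest.approx(f_ab, rel=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        y = rng.standard_normal((6, 2, 4)) * 30 + 500
        rows = []
        for s in range(6):
            for i, c in enumerate(("cued", "uncued")):
                for j, d in enumerate(("D1", "D2", "D3", "D4")):
                    rows.append({"subject": s, "cue": c, "distractor": d, "rt": y[s, i, j]})
        df = pd.DataFrame(rows)
        res = pg.rm_anova(data=df, dv="rt", within=["cue", "distractor"], subject="subject")
        tab = rm_anova_2x4(y)
        assert tab.loc["cue", "F"] == pytest.approx(res.loc[0, "F"], rel=1e-6)
        assert tab.loc["distractor", "F"] == pytest.approx(res.loc[1, "F"], rel=1e-6)
        assert tab.loc["interaction", "F"] == pytest.approx(res.loc[2, "F"], rel=1e-6)

    def test_subject_constant_shift_invariance(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal((5, 2, 4))
        y2 = y.copy()
        y2[2] += 123.4
        assert np.allclose(rm_anova_2x4(y)["F"], rm_anova_2x4(y2)["F"])

    def test_df_match_design(self):
        tab = rm_anova_2x4(np.random.default_rng(0).standard_normal((16, 2, 4)))
        assert tuple(tab.loc["cue", ["df_num", "df_den"]]) == (1, 15)
        assert tuple(tab.loc["distractor", ["df_num", "df_den"]]) == (3, 45)
        assert tuple(tab.loc["interaction", ["df_num", "df_den"]]) == (3, 45)

    def test_missing_cell_rejected(self):
        y = np.ones((3, 2, 4))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_2x4(y)


class TestPairwiseAndChance:
    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((10, 4))
        fam6 = pairwise_bonferroni(x, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
        single = pairwise_bonferroni(x, [(0, 1)])
        assert fam6.loc[0, "p_corrected"] == pytest.approx(
            min(1.0, fam6.loc[0, "p_raw"] * 6)
        )
        assert single.loc[0, "p_corrected"] == pytest.approx(single.loc[0, "p_raw"])

    def test_identical_conditions_capped_at_one(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 2))
        tab = pairwise_bonferroni(x, [(0, 1)])
        assert tab.loc[0, "p_corrected"] == 1.0

    def test_chance_levels(self):
        assert CHANCE_3AFC == pytest.approx(1 / 3)
        assert CHANCE_DISTRACTOR_INFORMED == 0.5

    def test_all_at_chance_gives_t_zero(self):
        res = t_vs_chance(np.full(6, 1 / 3), CHANCE_3AFC)
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_above_chance_detected(self):
        rng = np.random.default_rng(14)
        acc = 0.85 + 0.03 * rng.standard_normal(16)
        res = t_vs_chance(acc, CHANCE_3AFC)
        assert res.t > 0 and res.p < 1e-6


class TestPooling:
    def test_partition(self):
        levels = ["D1", "D2", "D3", "D4", "D1"]
        pooled = pool_similarity(levels)
        assert list(pooled) == ["high", "high", "low", "low", "high"]

    def test_counts_preserved_and_unknown_rejected(self):
        rng = np.random.default_rng(15)
        levels = rng.choice(["D1", "D2", "D3", "D4"], 100)
        pooled = pool_similarity(levels)
        assert (pooled == "high").sum() + (pooled == "low").sum() == 100
        with pytest.raises(ValueError):
            pool_similarity(["D5"])


def make_cohort_tables(params, seed, n_subjects=6):
    tables = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_subjects):
        rng = np.random.default_rng(child)
        sched = generate_schedule(params, rng=rng)
        beh = simulate_behavior(sched, params, rng=rng)
        t = sched.copy()
        for c in beh.columns:
            t[c] = beh[c]
        tables.append(t)
    return tables


class TestExclusion:
    def test_boundary_accuracy_retained(self):
        # A subject exactly at mean - 2 SD is retained (strict 'below').
        params = SimulationParams(trials_per_condition=24, rt_trial_sd=50.0)
        tables = make_cohort_tables(params, seed=20, n_subjects=5)
        rep = exclude_subjects(tables)
        cut = rep["group_mean"].iloc[0] - 2 * rep["group_sd"].iloc[0]
        at_boundary = np.isclose(rep["accuracy"], cut)
        assert not rep.loc[at_boundary, "accuracy_excluded"].any()
        below = rep["accuracy"] < cut
        assert (rep["accuracy_excluded"] == below).all()
        assert (
            rep["final_included"]
            == ~(rep["accuracy_excluded"] | rep["similarity_excluded"])
        ).all()

    def test_flat_rt_model_excluded_at_type_one_rate(self):
        # With no D1-D4 difference the similarity rule retains a subject only
        # by a type-I event of the one-sided-qualified test (~2.5%).
        means = {(c, d): 850.0 for c in ("cued", "uncued") for d in ("D1", "D2", "D3", "D4")}
        params = SimulationParams(trials_per_condition=24, rt_cell_means=means)
        tables = make_cohort_tables(params, seed=21, n_subjects=40)
        rep = exclude_subjects(tables)
        retained = (~rep["similarity_excluded"]).mean()
        assert retained < 0.15

    def test_paper_default_effect_never_similarity_excluded(self):
        # At the configured D1-D4 gap with 108 trials/cell the within-subject
        # t-test has essentially full power: no similarity exclusions.
        params = SimulationParams(trials_per_condition=108)
        n_excluded = 0
        for seed in range(10):
            tables = make_cohort_tables(params, seed=seed, n_subjects=4)
            rep = exclude_subjects(tables)
            n_excluded += int(rep["similarity_excluded"].sum())
        assert n_excluded == 0

    def test_zero_correct_trials_unevaluable(self):
        params = SimulationParams(trials_per_condition=12)
        tables = make_cohort_tables(params, seed=22, n_subjects=3)
        tables[0]["correct"] = False
        rep = exclude_subjects(tables)
        assert rep.loc[0, "unevaluable"]
        assert not rep.loc[0, "final_included"]

    def test_idempotent_on_retained_set(self):
        params = SimulationParams(trials_per_condition=48)
        tables = make_cohort_tables(params, seed=23, n_subjects=8)
        rep1 = exclude_subjects(tables)
        kept = [t for t, ok in zip(tables, rep1["final_included"]) if ok]
        if len(kept) >= 3:
            rep2 = exclude_subjects(kept)
            # similarity rule is per subject, so survivors still pass it
            assert not rep2["similarity_excluded"].any()


class TestDistractorCost:
    def test_positive_under_default_model_and_cued_ignored(self):
        params = SimulationParams(trials_per_condition=48)
        tables = make_cohort_tables(params, seed=24, n_subjects=4)
        cost = distractor_cost(tables)
        assert (cost > 0).all()
        uncued_only = [t[t["cue"] == "uninformative"] for t in tables]
        assert np.allclose(distractor_cost(uncued_only), cost)

    def test_equal_cells_give_zero(self):
        df = pd.DataFrame(
            {
                "cue": ["uninformative"] * 4,
                "distractor_level": ["D1", "D2", "D3", "D4"],
                "rt_ms": [800.0, 800.0, 800.0, 800.0],
                "correct": [True] * 4,
                "eye_movement": [False] * 4,
            }
        )
        assert distractor_cost([df])[0] == 0.0

    def test_empty_cell_yields_nan_with_warning(self):
        df = pd.DataFrame(
            {
                "cue": ["uninformative"] * 2,
                "distractor_level": ["D1", "D2"],
                "rt_ms": [800.0, 900.0],
                "correct": [True, True],
                "eye_movement": [False, False],
            }
        )
        with pytest.warns(UserWarning, match="empty pooled cell"):
            cost = distractor_cost([df])
        assert np.isnan(cost[0])
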