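"""Cross-validation, D-optimal combinations and designed scenarios."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crossgp import experiments as xp
from crossgp.popgen import vanraden_kinship
from crossgp.simdata import (
    SimConfig, TraitSpec, simulate_dataset, simulate_genotype_means,
)


@pytest.fixture(scope="module")
def prediction_world():
    """Medium multi-series population with entry means emulating stage 2."""
    cfg = SimConfig(
        n_series=4, genotypes_per_series=(250, 250, 250, 250), n_markers=400,
        n_founders=40, seed=17,
    )
    ds = simulate_dataset(cfg)
    K = vanraden_kinship(ds.complete)
    trait = cfg.traits[0].resolved(cfg.mean_envs_per_genotype(), cfg.mean_reps_per_plot())
    var_delta = trait.var_gxe + trait.var_resid / cfg.mean_reps_per_plot()
    n_envs = ds.plots.groupby("genotype")["env"].nunique().astype(float)
    y = simulate_genotype_means(ds.truth, "grain_yield", n_envs, var_delta, seed=5)
    series_of = pd.Series(ds.complete.series, index=ds.complete.genotypes)
    years_of = ds.plots.groupby("genotype")["year"].agg(lambda s: tuple(sorted(set(s))))
    return cfg, ds, K, y, series_of, n_envs, years_of


class TestWithinSeriesCV:
    def test_rep_count_and_determinism(self, prediction_world):
        cfg, ds, K, y, series_of, *_ = prediction_world
        blues = {s: y[series_of == s] for s in cfg.series_names()[:2]}
        runs1 = xp.within_series_cv(blues, ds.complete, reps=4, seed=9)
        runs2 = xp.within_series_cv(blues, ds.complete, reps=4, seed=9)
        assert len(runs1) == 8
        pd.testing.assert_frame_equal(runs1, runs2)
        assert (runs1.groupby("test_series").size() == 4).all()

    def test_noiseless_trait_high_ability(self, prediction_world):
        cfg, ds, K, y, series_of, *_ = prediction_world
        bv = ds.truth.bv("grain_yield")
        blues = {"s1": bv[series_of == "s1"]}
        runs = xp.within_series_cv(blues, ds.complete, reps=6, seed=1)
        assert runs["ability"].median() >= 0.95

    def test_small_series_skipped(self, prediction_world):
        cfg, ds, K, y, series_of, *_ = prediction_world
        blues = {"s1": y[series_of == "s1"].iloc[:10]}
        with pytest.warns(UserWarning, match="skipped"):
            runs = xp.within_series_cv(blues, ds.complete, reps=2, seed=0)
        assert len(runs) == 0


class TestDoptimal:
    def test_selecting_all_candidates_is_identity(self):
        cands = xp.candidate_series_sets(3)
        sel = xp.doptimal_series_combinations(3, len(cands), seed=0)
        assert set(sel) == set(cands)

    def test_matches_exhaustive_search(self):
        cands = xp.candidate_series_sets(3)
        X = xp._design_rows(cands, 3)
        best = -np.inf
        for sub in itertools.combinations(range(len(cands)), 4):
            sign, ld = np.linalg.slogdet(X[list(sub)].T @ X[list(sub)])
            if sign > 0:
                best = max(best, ld)
        sel = xp.doptimal_series_combinations(3, 4, seed=2)
        Xs = xp._design_rows(sel, 3)
        sign, ld = np.linalg.slogdet(Xs.T @ Xs)
        assert sign > 0
        assert ld == pytest.approx(best, abs=1e-9)

    def test_deterministic_given_seed(self):
        a = xp.doptimal_series_combinations(4, 8, seed=5)
        b = xp.doptimal_series_combinations(4, 8, seed=5)
        assert a == b

    def test_singular_selection_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            xp.doptimal_series_combinations(4, 3, seed=0)


class TestAcrossSeriesRuns:
    def test_leave_one_series_out_structure(self, prediction_world):
        cfg, ds, K, y, series_of, *_ = prediction_world
        combos = [frozenset({0, 1, 2}), frozenset({0, 1, 3})]
        runs = xp.across_series_runs(combos, y, series_of, {"lib": K},
                                     series_names=cfg.series_names())
        assert set(runs["test_series"]) == {"s4", "s3"}
        assert (runs.groupby("training_series").size() == 1).all()

    def test_variants_share_splits(self, prediction_world):
        cfg, ds, K, y, series_of, *_ = prediction_world
        combos = [frozenset({0}), frozenset({1, 2})]
        runs = xp.across_series_runs(
            combos, y, series_of, {"imputed": K, "unimputed": K},
            series_names=cfg.series_names(),
        )
        a = runs[runs["variant"] == "imputed"].drop(columns="variant").reset_index(drop=True)
        b = runs[runs["variant"] == "unimputed"].drop(columns="variant").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_bigger_pooled_training_beats_single_series(self, prediction_world):
        cfg, ds, K, y, series_of, *_ = prediction_world
        single = xp.across_series_runs(
            [frozenset({i}) for i in range(3)], y, series_of, {"lib": K},
            series_names=cfg.series_names(),
        )
        pooled = xp.across_series_runs(
            [frozenset({0, 1, 2})], y, series_of, {"lib": K},
            series_names=cfg.series_names(),
        )
        s4_single = single[single["test_series"] == "s4"]["ability"].mean()
        s4_pooled = pooled[pooled["test_series"] == "s4"]["ability"].mean()
        assert s4_pooled > s4_single - 0.02


class TestScenarios:
    def test_series_count_pairing_and_disjointness(self, prediction_world):
        cfg, ds, K, y, series_of, *_ = prediction_world
        runs = xp.scenario_series_count(
            y, series_of, K, n_train=200, n_test=60, reps=4, seed=3
        )
        assert len(runs) == 8
        assert set(runs["arm"]) == {"single", "multi"}
        paired = runs.pivot_table(index="replicate", columns="arm", values="ability")
        assert paired.notna().all().all()

    def test_series_exchangeability_small_arm_difference(self, prediction_world):
        cfg, ds, K, y, series_of, *_ = prediction_world
        runs = xp.scenario_series_count(
            y, series_of, K, n_train=200, n_test=80, reps=15, seed=21
        )
        paired = runs.pivot_table(index="replicate", columns="arm", values="ability")
        diff = (paired["multi"] - paired["single"]).mean()
        assert abs(diff) <= 0.05

    def test_env_groups_membership_and_control_size(self, prediction_world):
        cfg, ds, K, y, series_of, n_envs, _ = prediction_world
        runs = xp.scenario_env_groups(
            y, series_of, n_envs, K,
            groups=((1, 3), (4, 5), (6, 9), (10, np.inf)),
            n_train=150, n_test=60, reps=3, seed=4,
        )
        assert "(all)" in set(runs["env_group"])
        assert (runs["x_train"] == 150).all()

    def test_year_window_training_respects_window(self, prediction_world):
        cfg, ds, K, y, series_of, n_envs, years_of = prediction_world
        runs = xp.scenario_year_windows(
            y, series_of, years_of, K, n_train=150, windows=((1, 2), (1, 5)),
            n_test=50, reps=2, seed=6,
        )
        assert len(runs) > 0
        assert set(runs["window"]) <= {"1-2", "1-5"}
        for w, sub in runs.groupby("window"):
            assert (sub.groupby("test_year").size() == 2).all()
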