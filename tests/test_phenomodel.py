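"""Two-stage phenotypic analysis: outliers, stage-1 means, env QC, stage 2."""

import numpy as np
import pandas as pd
import pytest

from crossgp import phenomodel
from crossgp.phenomodel import (
    WithinEnvResult, across_env_analysis, detect_outliers_m5,
    environment_qc, within_env_analysis,
)
from crossgp.simdata import SimConfig, TraitSpec, simulate_dataset


def _rcbd(n_geno=20, n_rep=3, var_g=2.0, var_e=0.5, env="E1", seed=0, mu=10.0,
          block_eff=0.0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(var_g), n_geno)
    rows = []
    for rep in range(n_rep):
        b = block_eff * rng.normal()
        for i in range(n_geno):
            rows.append({
                "series": "s1", "location": "L1", "year": 2015, "env": env,
                "trial": "T1", "replication": str(rep + 1), "block": str(rep + 1),
                "genotype": f"g{i:03d}", "trait": "gy",
                "value": mu + g[i] + b + rng.normal(0, np.sqrt(var_e)),
            })
    return pd.DataFrame(rows)


class TestOutliers:
    def test_clean_noiseless_data_unflagged(self):
        plots = _rcbd(var_e=0.0, var_g=1.0)
        assert len(detect_outliers_m5(plots)) == 0

    def test_planted_large_outlier_flagged(self):
        hits, extra_flags = 0, 0
        for seed in range(10):
            plots = _rcbd(n_geno=50, n_rep=4, var_e=1.0, seed=seed)
            target = plots.sample(1, random_state=seed).index[0]
            plots.loc[target, "value"] += 10.0
            flagged = detect_outliers_m5(plots, alpha=0.05)
            if target in set(flagged["index"]):
                hits += 1
            extra_flags += max(len(flagged) - 1, 0)
        assert hits == 10
        assert extra_flags <= 10  # at most ~1 co-flag per 200-plot environment

    def test_alpha_zero_flags_nothing(self):
        plots = _rcbd(seed=1)
        plots.loc[0, "value"] += 50.0
        assert len(detect_outliers_m5(plots, alpha=0.0)) == 0

    def test_tiny_environment_skipped(self):
        plots = _rcbd(n_geno=3, n_rep=1)
        with pytest.warns(UserWarning, match="skipped"):
            flagged = detect_outliers_m5(plots)
        assert len(flagged) == 0


class TestWithinEnv:
    def test_balanced_rcbd_no_noise_reproduces_means(self):
        plots = _rcbd(var_e=0.0)
        res = within_env_analysis(plots, alpha=0.0)
        assert len(res) == 1
        means = plots.groupby("genotype")["value"].mean()
        assert np.allclose(res[0].blues.loc[means.index], means, atol=1e-6)
        assert res[0].repeatability > 0.999

    def test_zero_genetic_variance_gives_low_repeatability(self):
        r2s = []
        for seed in range(10):
            plots = _rcbd(n_geno=100, n_rep=3, var_g=0.0, var_e=1.0, seed=seed)
            res = within_env_analysis(plots, alpha=0.0)
            r2s.append(res[0].repeatability)
        assert np.mean(r2s) <= 0.1

    def test_unreplicated_trial_design_correction_helps(self):
        # strong block effects, one plot per genotype: subtracting the
        # estimated block effects must reduce the MSE against truth
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 120
            g = rng.normal(0, 1.0, n)
            blocks = np.repeat(np.arange(6), 20)
            beff = rng.normal(0, 2.0, 6)
            y = 10 + g + beff[blocks] + rng.normal(0, 0.3, n)
            plots = pd.DataFrame({
                "series": "s1", "location": "L1", "year": 2015, "env": "E1",
                "trial": "T1", "replication": "1",
                "block": [str(b + 1) for b in blocks],
                "genotype": [f"g{i:03d}" for i in range(n)],
                "trait": "gy", "value": y,
            })
            res = within_env_analysis(plots, alpha=0.0)[0]
            truth = pd.Series(10 + g, index=plots["genotype"])
            mse_adj = ((res.blues.loc[truth.index] - truth) ** 2).mean()
            mse_raw = ((pd.Series(y, index=plots["genotype"]) - truth) ** 2).mean()
            if mse_adj < mse_raw:
                wins += 1
        assert wins >= 9

    def test_single_plot_environment_dropped(self):
        plots = _rcbd().iloc[:1]
        with pytest.warns(UserWarning, match="inestimable"):
            assert within_env_analysis(plots, alpha=0.0) == []


def _env_result(env, r2, blues, trait="gy", series="s1"):
    return WithinEnvResult(
        env=env, trait=trait, blues=blues, repeatability=r2, var_g=1.0,
        var_resid=0.5, design_varcomps={}, n_plots_per_genotype=2.0,
        outliers=pd.DataFrame(), series=series,
    )


class TestEnvironmentQC:
    def test_repeatability_boundary_strict(self):
        base = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        results = [
            _env_result("keep", 0.30, base),
            _env_result("drop", 0.29, base + 0.1),
            _env_result("other", 0.9, base * 1.1),
        ]
        kept = {r.env for r in environment_qc(results)}
        assert kept == {"keep", "other"}

    def test_uncorrelated_environment_dropped(self):
        rng = np.random.default_rng(0)
        ids = [f"g{i}" for i in range(40)]
        signal = pd.Series(rng.normal(size=40), index=ids)
        results = [
            _env_result(f"E{k}", 0.8, signal + 0.1 * rng.normal(size=40))
            for k in range(4)
        ]
        results.append(_env_result("noise", 0.8, pd.Series(rng.normal(size=40), index=ids)))
        kept = {r.env for r in environment_qc(results)}
        assert "noise" not in kept
        assert {"E0", "E1", "E2", "E3"} <= kept

    def test_identical_environments_all_retained(self):
        base = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        results = [_env_result(f"E{k}", 0.8, base) for k in range(3)]
        assert len(environment_qc(results)) == 3


class TestAcrossEnv:
    def test_balanced_design_matches_direct_least_squares(self):
        rng = np.random.default_rng(2)
        genos = [f"g{i}" for i in range(8)]
        envs = [f"E{k}" for k in range(5)]
        g = dict(zip(genos, rng.normal(size=8)))
        e = dict(zip(envs, rng.normal(size=5)))
        results = []
        for env in envs:
            blues = pd.Series(
                [10 + g[x] + e[env] + 0.01 * rng.normal() for x in genos], index=genos
            )
            results.append(_env_result(env, 0.9, blues))
        res = across_env_analysis(results, include_series=False)
        # direct two-way least squares with env fixed gives the same
        # genotype contrasts on balanced data
        rows = [(x, env, r.blues[x]) for r in results for env, x in
                [(r.env, x) for x in genos]]
        df = pd.DataFrame(rows, columns=["g", "e", "y"])
        import scipy.linalg

        Xg = pd.get_dummies(df["g"], drop_first=True).to_numpy(float)
        Xe = pd.get_dummies(df["e"], drop_first=True).to_numpy(float)
        X = np.hstack([np.ones((len(df), 1)), Xg, Xe])
        beta, *_ = scipy.linalg.lstsq(X, df["y"].to_numpy())
        ls_contrasts = np.concatenate([[0.0], beta[1:8]])
        blue_contrasts = (res.blues - res.blues.iloc[0]).to_numpy()
        assert np.allclose(blue_contrasts, ls_contrasts - ls_contrasts[0], atol=1e-6)

    def test_h2_formula(self):
        # var_g=3, var_resid=4, n=4 -> H2 = 3 / (3 + 1) = 0.75
        assert 3.0 / (3.0 + 4.0 / 4) == pytest.approx(0.75)

    def test_heritability_recovery(self):
        ests = []
        for seed in range(5):
            cfg = SimConfig(
                n_series=1, genotypes_per_series=(200,), n_markers=200,
                n_founders=30, n_locations=2, stages=((1.0, 4, 2),),
                traits=(TraitSpec(h2_target=0.9),), seed=seed + 100,
            )
            ds = simulate_dataset(cfg)
            within = within_env_analysis(ds.plots, alpha=0.0)
            res = across_env_analysis(within, include_series=False)
            ests.append(res.h2)
        assert abs(np.mean(ests) - 0.9) < 0.05

    def test_disconnected_series_rejected(self):
        a = _env_result("E1", 0.9, pd.Series([1.0, 2.0, 3.0], index=list("abc")), series="s1")
        b = _env_result("E2", 0.9, pd.Series([1.0, 2.0, 3.0], index=list("xyz")), series="s2")
        with pytest.raises(ValueError, match="not connected"):
            across_env_analysis([a, b], include_series=True)

    def test_two_stage_no_noise_recovers_breeding_values(self):
        trait = TraitSpec(
            h2_target=1.0, mean=0.0, var_series=0.0, var_env=1.0, var_trial=0.0,
            var_rep=0.0, var_block=0.0, var_gxe=0.0, var_resid=0.0,
        )
        cfg = SimConfig(
            n_series=1, genotypes_per_series=(60,), n_markers=100, n_founders=20,
            n_locations=2, stages=((1.0, 4, 2),), traits=(trait,), seed=8,
        )
        ds = simulate_dataset(cfg)
        within = within_env_analysis(ds.plots, alpha=0.0)
        res = across_env_analysis(within, include_series=False)
        bv = ds.truth.bv("grain_yield").loc[res.blues.index]
        centred = res.blues - res.blues.mean()
        assert np.allclose(centred, bv - bv.mean(), atol=1e-6)
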