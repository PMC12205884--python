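"""Genomic prediction experiments: within-series CV, D-optimal
across-series combinations, and the three designed scenarios.

Within-series: 20 random 90/10 splits per series on within-series BLUEs.
Across-series: D-optimally chosen series combinations train GBLUP models
evaluated per left-out series and marker-set variant.  Scenarios hold
training size constant while varying the number of series, the
environment backing, and the year window of the training data.
"""

import pandas as pd

from common import RESULTS, SEED, study_config
from crossgp import experiments as xp
from crossgp import io, popgen


def main() -> None:
    out = RESULTS / "06_predictions"
    out.mkdir(parents=True, exist_ok=True)
    cfg = study_config()
    merged = io.read_dosage_csv(RESULTS / "02_genoqc" / "merged_dosages.csv")
    blues = pd.read_csv(RESULTS / "04_phenotypes" / "blue_table_grain_yield.csv")
    plots = io.read_plot_table(RESULTS / "01_simulate" / "plots.csv")
    kinships = {
        name: popgen.KinshipMatrix(
            pd.read_csv(RESULTS / "05_popgen" / f"kinship_{name}.csv", index_col=0),
            0, None,
        )
        for name in ("liberal_imputed", "liberal_unimputed",
                     "strict_imputed", "strict_unimputed")
    }
    frames = []

    within = blues[blues["level"] == "series"]
    by_series = {
        s: sub.set_index("genotype")["blue"]
        for s, sub in within.groupby("series")
    }
    cv = xp.within_series_cv(by_series, merged, trait="grain_yield",
                             reps=20, seed=SEED)
    print(cv.groupby("test_series")["ability"].median().rename("median CV ability"))
    frames.append(cv)

    across_blues = blues[blues["level"] == "all"].set_index("genotype")["blue"]
    series_of = pd.Series(merged.series, index=merged.genotypes)
    combos = xp.doptimal_series_combinations(cfg.n_series, 14, seed=SEED)
    runs = xp.across_series_runs(combos, across_blues, series_of, kinships,
                                 trait="grain_yield",
                                 series_names=cfg.series_names())
    print(runs[runs.variant == "liberal_imputed"]
          .groupby("x_train")["ability"].mean().rename("mean ability by size"))
    frames.append(runs)

    K = kinships["liberal_imputed"]
    n_envs = plots.groupby("genotype")["env"].nunique().astype(float)
    years_of = plots.groupby("genotype")["year"].agg(lambda s: tuple(sorted(set(s))))
    sc1 = xp.scenario_series_count(across_blues, series_of, K, n_train=500,
                                   n_test=100, reps=25, seed=SEED)
    paired = sc1.pivot_table(index="replicate", columns="arm", values="ability")
    print(f"single vs multi series (constant size): mean difference "
          f"{(paired['multi'] - paired['single']).mean():+.3f} "
          f"(SD {paired['multi'].std():.3f}/{paired['single'].std():.3f})")
    frames.append(sc1)
    sc2 = xp.scenario_env_groups(across_blues, series_of, n_envs, K,
                                 n_train=300, n_test=100, reps=25, seed=SEED)
    print(sc2.groupby("env_group")["ability"].mean().rename("ability by env group"))
    frames.append(sc2)
    sc3 = xp.scenario_year_windows(across_blues, series_of, years_of, K,
                                   n_train=300, n_test=100, reps=25, seed=SEED)
    if len(sc3):
        print(sc3.groupby("window")["ability"].mean().rename("ability by year window"))
        frames.append(sc3)

    pd.concat(frames, ignore_index=True).to_csv(out / "runs.csv", index=False)
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
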