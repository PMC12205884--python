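"""Two-stage phenotypic analysis of the unbalanced trial network.

Stage 1: within-environment adjusted means with residual-based outlier
removal and per-plot repeatability; environments with repeatability
< 0.3 or mean inter-environment correlation < 0.1 are discarded.
Stage 2: across-environment (and per-series) BLUEs/BLUPs with entry-mean
heritability.  Writes the tidy genotype-mean table consumed by the
prediction experiments.
"""

import numpy as np

from common import RESULTS
from crossgp import io, phenomodel


def main() -> None:
    src = RESULTS / "01_simulate"
    out = RESULTS / "04_phenotypes"
    out.mkdir(parents=True, exist_ok=True)
    plots = io.read_plot_table(src / "plots.csv")
    for trait, sub in plots.groupby("trait"):
        within = phenomodel.within_env_analysis(sub)
        n_outliers = sum(len(r.outliers) for r in within)
        kept = phenomodel.environment_qc(within)
        print(f"{trait}: {len(within)} environments analysed, "
              f"{len(within) - len(kept)} discarded by QC, "
              f"{n_outliers} outlier plots removed")
        reps = [r.repeatability for r in kept]
        print(f"  repeatability: min {min(reps):.2f}, median {np.median(reps):.2f}, "
              f"max {max(reps):.2f}")
        across = phenomodel.across_env_analysis(kept, include_series=True)
        per_series = phenomodel.within_series_blues(kept)
        table = phenomodel.blue_table(across, per_series)
        table.to_csv(out / f"blue_table_{trait}.csv", index=False)
        io.write_json(
            {
                "H2": across.h2, "var_g": across.var_g, "var_env": across.var_env,
                "var_resid": across.var_resid,
                "mean_envs_per_genotype": across.mean_envs_per_genotype,
                "per_series_H2": {s: r.h2 for s, r in per_series.items()},
            },
            out / f"heritability_{trait}.json",
        )
        print(f"  across-series H2 = {across.h2:.3f}; per series: "
              + ", ".join(f"{s}={r.h2:.3f}" for s, r in per_series.items()))
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
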