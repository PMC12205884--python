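"""Training-size scaling law and series-compatibility decomposition.

Fits the empirical power curve ability = alpha * size^(1/beta) per test
series on the across-series runs (liberal, imputed marker set), then
decomposes the size-corrected deviations into test-set main effects,
training-series main effects and pairwise interactions, each with a
REML-estimated variance.
"""

import pandas as pd

from common import RESULTS
from crossgp import io
from crossgp.scaling import decompose_deviations, fit_size_curve


def main() -> None:
    out = RESULTS / "07_scaling"
    out.mkdir(parents=True, exist_ok=True)
    runs = pd.read_csv(RESULTS / "06_predictions" / "runs.csv")
    across = runs[runs["variant"] == "liberal_imputed"]
    fit = fit_size_curve(across)
    fit.params.to_csv(out / "scaling_params.csv", index=False)
    print(fit.params.set_index("test_series")[["alpha", "beta"]])
    print(f"residual SD around the size curve: {fit.residuals['residual'].std():.3f}")

    decomp = decompose_deviations(fit.residuals)
    io.write_json(
        {
            "mu": decomp.mu,
            "varcomps": decomp.varcomps,
            "test_effects": decomp.test_effects.to_dict(),
            "training_effects": decomp.training_effects.to_dict(),
            "interaction_effects": decomp.interaction_effects.to_dict(),
        },
        out / "decomposition.json",
    )
    print("variance components of the deviation decomposition:")
    for k in ("eta", "theta", "kappa", "residual"):
        print(f"  {k}: {decomp.varcomps[k]:.5f}")
    top = decomp.interaction_effects.abs().sort_values(ascending=False).head(3)
    print("largest training->test interactions:")
    for pair in top.index:
        print(f"  {pair}: {decomp.interaction_effects[pair]:+.3f}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
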