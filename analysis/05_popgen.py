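"""Diversity structure and the kinship variants for prediction.

Builds the four VanRaden kinship variants (liberal/strict missingness x
imputed/unimputed), plus Rogers' distances on the pre-imputation data
(80% missingness cut, MAF >= 0.05) and their principal coordinates.
"""

import pandas as pd

from common import RESULTS
from crossgp import genoqc, io, popgen


def main() -> None:
    out = RESULTS / "05_popgen"
    out.mkdir(parents=True, exist_ok=True)
    merged = io.read_dosage_csv(RESULTS / "02_genoqc" / "merged_dosages.csv")
    imputed = io.read_dosage_csv(RESULTS / "03_impute" / "imputed_dosages.csv")
    pre_missing = pd.Series(merged.marker_missing_frac(), index=merged.markers.index)

    for label, cut in (("liberal", 0.80), ("strict", 0.30)):
        for tag, matrix, pre in (
            ("unimputed", merged, None),
            ("imputed", imputed, pre_missing),
        ):
            basis = genoqc.missingness_filter(matrix, cut, pre_missing=pre)
            basis = genoqc.maf_filter(basis, 0.05)
            K = popgen.vanraden_kinship(basis)
            K.values.to_csv(out / f"kinship_{label}_{tag}.csv")
            print(f"kinship {label}_{tag}: {basis.n_markers} markers, "
                  f"mean diagonal {K.values.to_numpy().diagonal().mean():.3f}")

    basis = genoqc.maf_filter(genoqc.missingness_filter(merged, 0.80), 0.05)
    dist = popgen.rogers_distance(basis)
    dist.values.to_csv(out / "rogers_distance.csv")
    coords, eigvals = popgen.pcoa(dist, k=3)
    coords.to_csv(out / "pcoa_coordinates.csv")
    explained = eigvals[:3] / eigvals[eigvals > 0].sum()
    print("PCoA variance explained by first three coordinates: "
          + ", ".join(f"{e:.1%}" for e in explained))
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
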