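"""Per-batch QC, strand harmonization over the batch graph, and merging.

Reads the batch VCFs from step 01, filters each batch (30%/10% genotype
and 90%/20% marker thresholds), harmonizes strand orientation along the
maximum spanning tree of batch overlaps, merges, and reports the marker
counts surviving the liberal (80%) and strict (30%) missingness cuts at
MAF >= 0.05.
"""

from common import RESULTS
from crossgp import genoqc, io


def main() -> None:
    src = RESULTS / "01_simulate"
    out = RESULTS / "02_genoqc"
    out.mkdir(parents=True, exist_ok=True)
    batches, reports = [], []
    for vcf in sorted(src.glob("batch_*.vcf")):
        batch = io.read_vcf(vcf)
        filtered, report = genoqc.filter_batch(batch)
        batches.append(filtered)
        reports.append(report)
        print(f"{report['batch']}: kept {report['genotypes_kept']} genotypes, "
              f"{report['markers_kept']} markers "
              f"(removed {report['genotypes_missing']}+{report['genotypes_het']} genotypes, "
              f"{report['markers_missing']}+{report['markers_het']} markers)")
    plan = genoqc.build_harmonization_plan(batches)
    print(f"harmonization root {plan.root}; tree edges {plan.edges}")
    merged = genoqc.merge_batches(batches, plan)
    io.write_json({"batch_qc": reports, "harmonization": plan.to_dict()},
                  out / "qc_report.json")
    io.write_dosage_csv(merged, out / "merged_dosages.csv")
    for label, cut in (("liberal", 0.80), ("strict", 0.30)):
        kept = genoqc.maf_filter(genoqc.missingness_filter(merged, cut), 0.05)
        print(f"{label} criterion (<= {cut:.0%} missing, MAF >= 0.05): "
              f"{kept.n_markers} markers")
    print(f"merged matrix: {merged.n_genotypes} genotypes x {merged.n_markers} markers; "
          f"outputs in {out}")


if __name__ == "__main__":
    main()
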