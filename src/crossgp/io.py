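"""File-format round-trips: VCF, dosage CSV, plot/BLUE tables, JSON reports.

Genotype batches travel as plain (uncompressed) VCF with a ``GT`` field —
one file per genotyping batch — or as dosage CSV tables.  Phenotypes travel
as tidy plot-level CSV.  All writers are exact inverses of the readers for
the content they carry (calls, identifiers, metadata; floats to 1e-12).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import GenotypeMatrix

PLOT_COLUMNS = [
    "series", "location", "year", "env", "trial", "replication", "block",
    "genotype", "trait", "value",
]

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write a batch as VCF (GT only, 1-based positions, ALT-dosage coding).

    ``REF`` is ``allele1`` and ``ALT`` is ``allele2``; the stored dosage is
    the ALT-allele count.  Per-sample series labels are preserved in
    ``##SAMPLE`` header lines so a round-trip is lossless.
    """
    path = Path(path)
    gm_sorted = gm.sort_markers()
    lines = ["##fileformat=VCFv4.2", f"##source=crossgp batch={gm.batch}"]
    for g, s in zip(gm_sorted.genotypes, gm_sorted.series):
        lines.append(f"##SAMPLE=<ID={g},Series={s}>")
    for chrom in pd.unique(gm_sorted.markers["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm_sorted.genotypes))
    calls = gm_sorted.calls
    for j, (mid, row) in enumerate(gm_sorted.markers.iterrows()):
        gts = "\t".join(
            "./." if np.isnan(calls[i, j]) else _GT_STRINGS[calls[i, j]]
            for i in range(gm_sorted.n_genotypes)
        )
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{mid}\t{row['allele1']}\t{row['allele2']}"
            f"\t.\t.\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | Path, batch: str | None = None) -> GenotypeMatrix:
    """Read a (plain or bgzipped) VCF into a :class:`GenotypeMatrix`.

    Unphased or phased heterozygotes (``0/1``, ``1|0`` ...) map to dosage 1;
    missing genotypes to nan.  Series labels are recovered from ``##SAMPLE``
    header lines when present.
    """
    path = Path(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    series_map = dict(
        re.findall(r"##SAMPLE=<ID=([^,>]*),Series=([^>]*)>", vcf.raw_header)
    )
    ids, chroms, poss, a1, a2, cols = [], [], [], [], [], []
    for var in vcf:
        ids.append(var.ID)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        a1.append(var.REF)
        a2.append(var.ALT[0] if var.ALT else var.REF)
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types, dtype=float)
        col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        cols.append(col)
    vcf.close()
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "allele1": a1, "allele2": a2},
        index=pd.Index(ids, name="marker"),
    )
    calls = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    series = np.array([series_map.get(s, "") for s in samples], dtype=object)
    return GenotypeMatrix(samples, markers, calls, series, batch or path.stem)


# ---------------------------------------------------------------------------
# Dosage CSV
# ---------------------------------------------------------------------------

def write_dosage_csv(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write calls as a genotype x marker CSV plus a marker-metadata sidecar."""
    path = Path(path)
    df = gm.to_frame()
    df.insert(0, "series", gm.series)
    df.index.name = "genotype"
    df.to_csv(path)
    meta = gm.markers.copy()
    meta.index.name = "marker"
    meta.to_csv(_sidecar(path))
    return path


def read_dosage_csv(path: str | Path, batch: str | None = None) -> GenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    series = df.pop("series").astype(object).fillna("").to_numpy()
    markers = pd.read_csv(_sidecar(path), index_col=0)
    markers.index = markers.index.astype(str)
    if list(markers.index) != list(df.columns):
        raise ValueError(f"{path}: marker sidecar does not match dosage columns")
    return GenotypeMatrix(
        [str(g) for g in df.index], markers, df.to_numpy(dtype=float), series,
        batch or path.stem,
    )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".markers.csv")


# ---------------------------------------------------------------------------
# Tidy tables and reports
# ---------------------------------------------------------------------------

def write_plot_table(plots: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    plots.to_csv(path, index=False)
    return path


def read_plot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={c: str for c in PLOT_COLUMNS if c not in ("value", "year")},
    )
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing plot-table columns {missing}")
    df["year"] = df["year"].astype(int)
    df["value"] = df["value"].astype(float)
    return df


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset, tuple)):
        return sorted(x) if isinstance(x, (set, frozenset)) else list(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")
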