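"""Per-batch SNP quality control, cross-batch strand harmonization, merging.

Genotyping batches from different providers may report the same SNP on
opposite strands.  With biallelic dosages a strand flip shows up as
``d -> 2 - d`` plus allele complementing, and for A/T and C/G SNPs it is
invisible from the allele labels alone.  Harmonization therefore models
batch overlaps as a graph (edge weight = number of shared marker x shared
genotype call pairs), takes its maximum spanning tree, and decides each
shared marker's orientation along tree edges from call concordance on the
overlapping genotypes, propagating transitively from a root batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import AMBIGUOUS_PAIRS, GenotypeMatrix, complement_alleles

KEEP, FLIP, DROP = "keep", "flip", "drop-ambiguous"


# ---------------------------------------------------------------------------
# Per-batch filtering
# ---------------------------------------------------------------------------

def filter_batch(
    batch: GenotypeMatrix,
    max_genotype_missing: float = 0.30,
    max_genotype_het: float = 0.10,
    max_marker_missing: float = 0.90,
    max_marker_het: float = 0.20,
) -> tuple[GenotypeMatrix, dict]:
    """Apply the per-batch genotype-then-marker QC thresholds.

    Genotypes with more than 30% missing or more than 10% heterozygous
    calls are discarded first; then markers with more than 90% missing or
    more than 20% heterozygous calls among the surviving genotypes.
    Fractions use the batch's own (on-panel) calls as denominator.
    """
    if batch.n_genotypes == 0 or batch.n_markers == 0:
        raise ValueError("empty batch")
    g_miss = batch.genotype_missing_frac()
    g_het = batch.genotype_het_frac()
    bad_miss = g_miss > max_genotype_missing
    bad_het = g_het > max_genotype_het
    kept = batch.take_genotypes(~(bad_miss | bad_het))
    report = {
        "batch": batch.batch,
        "genotypes_missing": int(bad_miss.sum()),
        "genotypes_het": int(bad_het.sum()),
    }
    if kept.n_genotypes == 0:
        warnings.warn(f"batch {batch.batch!r}: all genotypes removed by QC")
        report.update(markers_missing=0, markers_het=0)
        return kept, report
    m_miss = kept.marker_missing_frac() > max_marker_missing
    m_het = kept.marker_het_frac() > max_marker_het
    out = kept.take_markers(~(m_miss | m_het))
    report.update(markers_missing=int(m_miss.sum()), markers_het=int(m_het.sum()))
    report["genotypes_kept"] = out.n_genotypes
    report["markers_kept"] = out.n_markers
    return out, report


# ---------------------------------------------------------------------------
# Harmonization plan
# ---------------------------------------------------------------------------

@dataclass
class HarmonizationPlan:
    """Spanning tree over batches plus per-batch marker orientations.

    ``decisions[batch][marker]`` maps each shared marker to ``keep``,
    ``flip`` (complement alleles, dosage d -> 2-d) or ``drop-ambiguous``,
    expressed relative to the root batch's orientation.  Markers absent
    from a batch's entry default to ``keep``.
    """

    root: str
    edges: list[tuple[str, str, int]]
    decisions: dict[str, dict[str, str]] = field(default_factory=dict)

    def decision(self, batch: str, marker: str) -> str:
        return self.decisions.get(batch, {}).get(marker, KEEP)

    def to_dict(self) -> dict:
        return {"root": self.root, "edges": [list(e) for e in self.edges],
                "decisions": self.decisions}


def _overlap_weight(a: GenotypeMatrix, b: GenotypeMatrix) -> int:
    """Number of (shared marker, shared genotype) pairs observed in both."""
    gshared = sorted(set(a.genotypes) & set(b.genotypes))
    mshared = sorted(set(a.marker_ids) & set(b.marker_ids))
    if not gshared or not mshared:
        return 0
    sa = a.select_genotypes(gshared).select_markers(mshared)
    sb = b.select_genotypes(gshared).select_markers(mshared)
    return int((~np.isnan(sa.calls) & ~np.isnan(sb.calls)).sum())


def _edge_concordance(
    parent: GenotypeMatrix, child: GenotypeMatrix, parent_flip: dict[str, str]
) -> dict[str, str]:
    """Orientation of each shared marker in ``child`` vs the oriented parent."""
    gshared = sorted(set(parent.genotypes) & set(child.genotypes))
    mshared = sorted(set(parent.marker_ids) & set(child.marker_ids))
    out: dict[str, str] = {}
    if not gshared:
        return out
    pa = parent.select_genotypes(gshared).select_markers(mshared)
    ch = child.select_genotypes(gshared).select_markers(mshared)
    pcalls = pa.calls.copy()
    for j, m in enumerate(mshared):
        d = parent_flip.get(m, KEEP)
        if d == FLIP:
            pcalls[:, j] = 2.0 - pcalls[:, j]
        elif d == DROP:
            pcalls[:, j] = np.nan  # dropped in parent: no evidence through it
    both = ~np.isnan(pcalls) & ~np.isnan(ch.calls)
    for j, m in enumerate(mshared):
        obs = both[:, j]
        n = int(obs.sum())
        pair = (str(child.markers.iloc[j]["allele1"]), str(child.markers.iloc[j]["allele2"]))
        ambiguous = pair in AMBIGUOUS_PAIRS
        if n == 0:
            out[m] = DROP if ambiguous else KEEP
            continue
        asis = float((pcalls[obs, j] == ch.calls[obs, j]).mean())
        flipped = float((pcalls[obs, j] == 2.0 - ch.calls[obs, j]).mean())
        conclusive = n >= 3 and max(asis, flipped) >= 0.9
        if conclusive and flipped > asis:
            out[m] = FLIP
        elif conclusive:
            out[m] = KEEP
        else:
            out[m] = DROP if ambiguous else KEEP
    return out


def build_harmonization_plan(batches: list[GenotypeMatrix]) -> HarmonizationPlan:
    """Maximum-spanning-tree strand harmonization across batches.

    Edge weights count shared (marker, genotype) non-missing call pairs;
    ties resolve by lexicographic batch-name order.  The root (batch with
    the most genotypes) keeps its orientation; decisions propagate out
    along tree edges.
    """
    if len(batches) < 2:
        raise ValueError("need at least two batches to harmonize")
    names = [b.batch for b in batches]
    if len(set(names)) != len(names):
        raise ValueError("batch names must be unique")
    by_name = dict(zip(names, batches))
    graph = nx.Graph()
    graph.add_nodes_from(sorted(names))
    for i, na in enumerate(sorted(names)):
        for nb in sorted(names)[i + 1:]:
            w = _overlap_weight(by_name[na], by_name[nb])
            if w > 0:
                graph.add_edge(na, nb, weight=w)
    tree = nx.maximum_spanning_tree(graph, weight="weight")
    if tree.number_of_nodes() != len(names) or not nx.is_connected(tree):
        comps = list(nx.connected_components(graph))
        root_comp = next(c for c in comps if len(c) == max(len(x) for x in comps))
        orphans = sorted(set(names) - root_comp)
        raise ValueError(f"batches not connected by shared observations: {orphans}")
    root = max(names, key=lambda n: (by_name[n].n_genotypes, n))
    edges = sorted((min(u, v), max(u, v), int(d["weight"])) for u, v, d in tree.edges(data=True))
    decisions: dict[str, dict[str, str]] = {root: {}}
    for parent, child in nx.bfs_edges(tree, root):
        decisions[child] = _edge_concordance(
            by_name[parent], by_name[child], decisions[parent]
        )
    return HarmonizationPlan(root=root, edges=edges, decisions=decisions)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_batches(
    batches: list[GenotypeMatrix], plan: HarmonizationPlan | None = None
) -> GenotypeMatrix:
    """Union of genotypes and markers with orientation applied.

    Flips complement the allele pair and map dosage d -> 2-d;
    ``drop-ambiguous`` markers are removed from the affected batch before
    merging.  Where a genotype x marker call is observed in several
    batches the consensus is the majority call, ties -> missing.  Markers
    whose allele pairs disagree beyond complementing/swapping are dropped
    entirely.  Markers come out sorted by (chromosome, position).
    """
    oriented: list[GenotypeMatrix] = []
    for b in batches:
        bb = b.copy()
        if plan is not None:
            dec = plan.decisions.get(b.batch, {})
            drop = [m for m, d in dec.items() if d == DROP and m in bb.markers.index]
            flip = [m for m, d in dec.items() if d == FLIP and m in bb.markers.index]
            if drop:
                keepers = ~bb.markers.index.isin(drop)
                bb = bb.take_markers(keepers.nonzero()[0])
            if flip:
                cols = bb.markers.index.get_indexer(flip)
                bb.calls[:, cols] = 2.0 - bb.calls[:, cols]
                for m in flip:
                    a1, a2 = bb.markers.loc[m, ["allele1", "allele2"]]
                    bb.markers.loc[m, ["allele1", "allele2"]] = complement_alleles(a1, a2)
        oriented.append(bb)

    # marker metadata consensus; drop irreconcilable allele pairs
    meta: dict[str, pd.Series] = {}
    dropped: set[str] = set()
    for b in oriented:
        for m, row in b.markers.iterrows():
            if m in dropped:
                continue
            if m not in meta:
                meta[m] = row
                continue
            ref = meta[m]
            pairs = {
                (ref["allele1"], ref["allele2"]), (ref["allele2"], ref["allele1"]),
                complement_alleles(ref["allele1"], ref["allele2"]),
                complement_alleles(ref["allele2"], ref["allele1"]),
            }
            if (row["allele1"], row["allele2"]) not in pairs:
                warnings.warn(f"marker {m}: irreconcilable allele pairs, dropped")
                dropped.add(m)
                del meta[m]
    marker_ids = [m for m in meta]
    if meta:
        markers = pd.DataFrame(meta.values(), index=pd.Index(marker_ids, name="marker"))
    else:
        markers = pd.DataFrame(
            columns=["chrom", "pos", "allele1", "allele2"],
            index=pd.Index([], name="marker"),
        )

    genotypes: list[str] = []
    series: list[str] = []
    seen: dict[str, int] = {}
    for b in oriented:
        for g, s in zip(b.genotypes, b.series):
            if g not in seen:
                seen[g] = len(genotypes)
                genotypes.append(g)
                series.append(s)
    gpos = seen
    mpos = {m: j for j, m in enumerate(marker_ids)}
    counts = np.zeros((3, len(genotypes), len(marker_ids)), dtype=np.int16)
    for b in oriented:
        rows = np.array([gpos[g] for g in b.genotypes])
        keep_cols = [j for j, m in enumerate(b.marker_ids) if m in mpos]
        cols = np.array([mpos[b.marker_ids[j]] for j in keep_cols])
        if len(cols) == 0:
            continue
        sub = b.calls[:, keep_cols]
        for d in (0, 1, 2):
            hit = sub == float(d)
            counts[d][np.ix_(rows, cols)] += hit.astype(np.int16)
    total = counts.sum(axis=0)
    best = counts.max(axis=0)
    n_best = (counts == best[None]).sum(axis=0)
    calls = np.full((len(genotypes), len(marker_ids)), np.nan)
    decided = (total > 0) & (n_best == 1)
    calls[decided] = counts.argmax(axis=0)[decided].astype(float)
    merged = GenotypeMatrix(genotypes, markers, calls, np.array(series, dtype=object), "merged")
    return merged.sort_markers()


# ---------------------------------------------------------------------------
# Post-merge marker filters
# ---------------------------------------------------------------------------

def missingness_filter(
    matrix: GenotypeMatrix,
    max_missing: float,
    pre_missing: pd.Series | None = None,
) -> GenotypeMatrix:
    """Drop markers whose pre-imputation missing fraction exceeds the cut.

    ``pre_missing`` (marker id -> fraction) must be supplied when the
    matrix has already been imputed; by default the matrix's own
    missingness is used.  Liberal threshold 0.80, strict 0.30.
    """
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must lie in [0, 1]")
    if pre_missing is None:
        frac = matrix.marker_missing_frac()
    else:
        frac = pre_missing.reindex(matrix.markers.index).to_numpy(dtype=float)
        if np.isnan(frac).any():
            raise ValueError("pre_missing does not cover all markers")
    return matrix.take_markers(frac <= max_missing)


def maf_filter(matrix: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Keep markers with minor-allele frequency >= ``min_maf`` (inclusive).

    Heterozygous calls count one allele copy.  Markers with no observed
    calls are removed with a warning.
    """
    if not (0.0 <= min_maf <= 0.5):
        raise ValueError("min_maf must lie in [0, 0.5]")
    maf = matrix.maf()
    empty = np.isnan(maf)
    if empty.any():
        warnings.warn(f"{int(empty.sum())} markers with no observed calls removed")
    keep = ~empty & (np.nan_to_num(maf, nan=-1.0) >= min_maf)
    return matrix.take_markers(keep)
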