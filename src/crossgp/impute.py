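"""Missing-call imputation and masking-based accuracy validation.

The built-in imputer is a windowed k-nearest-genotype mode filler:
deterministic, LD-aware through a local marker window, and explicitly NOT
a re-implementation of a phasing-based tool (an external imputer can be
bridged over VCF instead).  Accuracy is quantified by the two masking
protocols used for panel-merging studies: *blocked* masking (hide all
high-density-panel calls of selected genotypes, mimicking cross-panel
gaps) and *random* masking (hide a uniform fraction of calls, mimicking
sequencing-style missingness).  With inbred material nearly all calls are
homozygous, so guessing uniformly between the two homozygous states gives
a baseline accuracy of 0.5.
"""

from __future__ import annotations

import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix


@dataclass
class MaskSpec:
    """A reproducible set of masked (genotype, marker) cells."""

    strategy: str
    rows: np.ndarray  # genotype indices into the source matrix
    cols: np.ndarray  # marker indices into the source matrix
    genotypes: list[str]
    markers: list[str]
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.rows)


def _mask_from_indices(matrix, rows, cols, strategy, params) -> MaskSpec:
    if len(rows) == 0:
        raise ValueError("empty mask")
    if np.isnan(matrix.calls[rows, cols]).any():
        raise AssertionError("mask covers originally-missing cells")
    return MaskSpec(
        strategy=strategy,
        rows=np.asarray(rows), cols=np.asarray(cols),
        genotypes=[matrix.genotypes[i] for i in rows],
        markers=[matrix.marker_ids[j] for j in cols],
        params=params,
    )


def blocked_mask(
    matrix: GenotypeMatrix,
    coverage_cut: float = 0.70,
    genotype_frac: float = 0.10,
    min_hd_frac: float = 0.50,
    seed: int = 0,
) -> MaskSpec:
    """Mask all high-density-panel calls for a random slice of genotypes.

    Markers with data for strictly more than ``coverage_cut`` of genotypes
    form the low-density (widely available) set; the rest are the
    high-density set.  Genotypes with data for more than ``min_hd_frac``
    of high-density markers are eligible; a ``genotype_frac`` random
    sample of them has every high-density call masked.
    """
    rng = np.random.default_rng(seed)
    coverage = 1.0 - matrix.marker_missing_frac()
    high = coverage <= coverage_cut
    if not high.any() or high.all():
        raise ValueError("coverage cut does not split markers into low- and high-density sets")
    hd_obs = ~np.isnan(matrix.calls[:, high])
    eligible = np.flatnonzero(hd_obs.mean(axis=1) > min_hd_frac)
    if eligible.size == 0:
        raise ValueError("no genotypes eligible for blocked masking")
    n_pick = max(int(round(genotype_frac * eligible.size)), 1)
    picked = rng.choice(eligible, size=n_pick, replace=False)
    sub = np.zeros_like(np.isnan(matrix.calls))
    sub[np.ix_(picked, np.flatnonzero(high))] = True
    sub &= ~np.isnan(matrix.calls)
    rows, cols = np.nonzero(sub)
    return _mask_from_indices(
        matrix, rows, cols, "blocked",
        {"coverage_cut": coverage_cut, "genotype_frac": genotype_frac,
         "min_hd_frac": min_hd_frac, "seed": seed,
         "n_genotypes_masked": int(n_pick), "n_high_density": int(high.sum())},
    )


def random_mask(matrix: GenotypeMatrix, frac: float = 0.01, seed: int = 0) -> MaskSpec:
    """Mask a uniform random fraction of all non-missing calls."""
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(~np.isnan(matrix.calls))
    n = int(round(frac * len(rows)))
    if n == 0:
        raise ValueError("empty mask: fraction too small for this matrix")
    pick = rng.choice(len(rows), size=n, replace=False)
    pick.sort()
    return _mask_from_indices(
        matrix, rows[pick], cols[pick], "random", {"frac": frac, "seed": seed},
    )


def apply_mask(matrix: GenotypeMatrix, mask: MaskSpec) -> GenotypeMatrix:
    out = matrix.copy()
    out.calls[mask.rows, mask.cols] = np.nan
    return out


# ---------------------------------------------------------------------------
# Imputers
# ---------------------------------------------------------------------------

def impute_builtin(
    matrix: GenotypeMatrix,
    k_neighbours: int = 10,
    window: int = 50,
    min_window_obs: int = 30,
) -> GenotypeMatrix:
    """Windowed k-nearest-genotype mode imputation.

    Markers (in map order) are processed in consecutive windows of
    ``window`` markers.  Within a window, genotype similarity is the
    allele-sharing score 1 - mean(|d_i - d_j|)/2 over mutually observed
    markers; each genotype's missing calls are filled with the dosage mode
    among its ``k_neighbours`` most similar genotypes (ties toward the
    nearer neighbour), falling back to the marker mode.  Genotypes with
    fewer than ``min_window_obs`` observed calls in a window — typically
    because a whole panel block is absent for their batch — are compared
    on all mutually observed markers instead, so that relatedness carries
    the information local LD cannot.  Markers with no observed call
    anywhere stay missing and are reported.
    """
    if matrix.n_genotypes < k_neighbours + 1:
        raise ValueError("need at least k_neighbours + 1 genotypes")
    out = matrix.copy()
    calls = out.calls
    n_g, n_m = calls.shape
    marker_mode = _column_mode(calls)
    fully_missing = np.isnan(marker_mode)
    if fully_missing.any():
        warnings.warn(
            f"{int(fully_missing.sum())} markers have no observed calls and stay missing"
        )
    indic = [(calls == d).astype(np.float64) for d in (0.0, 1.0, 2.0)]
    obs = (~np.isnan(calls)).astype(np.float64)

    def _similarity(cols: slice) -> np.ndarray:
        wobs = obs[:, cols]
        wind = [a[:, cols] for a in indic]
        shared = wobs @ wobs.T
        diff = np.zeros((n_g, n_g))  # sum over shared markers of |d_i - d_j|
        for u in range(3):
            for v in range(3):
                if u != v:
                    diff += abs(u - v) * (wind[u] @ wind[v].T)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = 1.0 - (diff / 2.0) / shared
        sim[shared == 0] = -np.inf
        np.fill_diagonal(sim, -np.inf)
        return sim

    # whole-matrix similarity backs genotypes with no observed call in a
    # window (e.g. a panel block entirely absent for their batch)
    global_sim = _similarity(slice(0, n_m))
    global_order = np.argsort(-global_sim, axis=1, kind="stable")
    for lo in range(0, n_m, window):
        hi = min(lo + window, n_m)
        sim = _similarity(slice(lo, hi))
        n_win_obs = (~np.isnan(calls[:, lo:hi])).sum(axis=1)
        weak = (n_win_obs < min(min_window_obs, hi - lo)) | ~np.isfinite(sim).any(axis=1)
        if weak.any():
            sim[weak] = global_sim[weak]
        order = np.argsort(-sim, axis=1, kind="stable")
        wmiss = np.isnan(calls[:, lo:hi])
        for g in np.flatnonzero(wmiss.any(axis=1)):
            neigh = order[g]
            neigh = neigh[np.isfinite(sim[g, neigh])][:k_neighbours]
            js = np.flatnonzero(wmiss[g])
            if neigh.size == 0:
                calls[g, lo + js] = marker_mode[lo + js]
                continue
            votes = calls[np.ix_(neigh, lo + js)]
            counts = np.stack([(votes == d).sum(axis=0) for d in (0.0, 1.0, 2.0)])
            top = counts.max(axis=0)
            n_top = (counts == top[None]).sum(axis=0)
            fill = counts.argmax(axis=0).astype(float)
            fill[top == 0] = np.nan
            # ties: take the call of the nearest neighbour holding a tied value
            for t in np.flatnonzero((n_top > 1) & (top > 0)):
                tied = np.flatnonzero(counts[:, t] == top[t]).astype(float)
                for nb in neigh:
                    v = calls[nb, lo + js[t]]
                    if not np.isnan(v) and v in tied:
                        fill[t] = v
                        break
            missing_fill = np.isnan(fill)
            fill[missing_fill] = marker_mode[lo + js[missing_fill]]
            calls[g, lo + js] = fill
    return out


def impute_marker_mode(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Baseline imputer: fill every missing call with the marker's mode."""
    out = matrix.copy()
    mode = _column_mode(out.calls)
    rows, cols = np.nonzero(np.isnan(out.calls))
    out.calls[rows, cols] = mode[cols]
    return out


def impute_random_guess(matrix: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Fill every missing call uniformly from the two homozygous states."""
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    rows, cols = np.nonzero(np.isnan(out.calls))
    out.calls[rows, cols] = rng.choice([0.0, 2.0], size=len(rows))
    return out


def _column_mode(calls: np.ndarray) -> np.ndarray:
    counts = np.stack([(calls == d).sum(axis=0) for d in (0.0, 1.0, 2.0)])
    mode = counts.argmax(axis=0).astype(float)
    mode[counts.sum(axis=0) == 0] = np.nan
    return mode


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------

def imputation_accuracy(
    original: GenotypeMatrix,
    imputed: GenotypeMatrix,
    mask: MaskSpec,
    replicate: int = 0,
) -> pd.DataFrame:
    """Per-marker fraction of masked calls whose imputed dosage matches.

    Matching is exact on the dosage (0/1/2); markers with zero masked
    calls are excluded.  Returns a tidy table with columns ``marker``,
    ``accuracy``, ``n_masked``, ``strategy``, ``replicate``.
    """
    if original.marker_ids != imputed.marker_ids or original.genotypes != imputed.genotypes:
        raise ValueError("original and imputed matrices are not aligned")
    truth = original.calls[mask.rows, mask.cols]
    guess = imputed.calls[mask.rows, mask.cols]
    if np.isnan(truth).any():
        raise ValueError("mask does not match matrix: masked cell missing in original")
    if np.isnan(guess).any():
        raise ValueError("imputed matrix leaves masked cells unfilled")
    correct = truth == guess
    df = pd.DataFrame({"col": mask.cols, "correct": correct})
    agg = df.groupby("col")["correct"].agg(["mean", "size"])
    return pd.DataFrame(
        {
            "marker": [original.marker_ids[j] for j in agg.index],
            "accuracy": agg["mean"].to_numpy(),
            "n_masked": agg["size"].to_numpy(dtype=int),
            "strategy": mask.strategy,
            "replicate": replicate,
        }
    )


def accuracy_percentiles(table: pd.DataFrame) -> dict[str, float]:
    """Lower-tail thresholds above which 95% / 75% of markers lie."""
    acc = table["accuracy"].to_numpy()
    return {"p95": float(np.percentile(acc, 5)), "p75": float(np.percentile(acc, 25))}


# ---------------------------------------------------------------------------
# External-tool bridge (optional; never required by tests)
# ---------------------------------------------------------------------------

def impute_external(
    matrix: GenotypeMatrix, command_template: str, workdir: str | Path
) -> GenotypeMatrix:
    """Bridge to an external VCF-based imputer.

    Writes the matrix as VCF, runs ``command_template`` (a format string
    receiving ``{vcf_in}`` and ``{vcf_out}``), and reads the result back.
    The orchestration never requires this bridge; it exists for users with
    a phasing-based imputer installed.
    """
    from .io import read_vcf, write_vcf

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    vcf_in = workdir / "to_impute.vcf"
    vcf_out = workdir / "imputed.vcf"
    write_vcf(matrix, vcf_in)
    cmd = command_template.format(vcf_in=vcf_in, vcf_out=vcf_out)
    subprocess.run(cmd, shell=True, check=True)
    imputed = read_vcf(vcf_out, batch=matrix.batch)
    return imputed.select_genotypes(matrix.genotypes).select_markers(matrix.marker_ids)
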