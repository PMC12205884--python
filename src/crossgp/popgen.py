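"""Genomic relationship and diversity structure.

Kinship follows VanRaden: K = Z Z' / (2 sum_j p_j (1 - p_j)) with Z the
allele-frequency-centred dosage matrix.  Mean-filling missing dosages
before centring zeroes their contribution, which is equivalent to basing
each pairwise product only on markers observed in both genotypes.

Diversity uses Rogers' distance — per locus
sqrt(0.5 * sum_alleles (f1 - f2)^2) with within-individual allele
frequencies (homozygote (1,0), heterozygote (0.5,0.5)), averaged over the
loci observed in both genotypes; for biallelic dosages the per-locus term
reduces to |d1 - d2| / 2 — followed by classical-scaling principal
coordinate analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix


@dataclass
class KinshipMatrix:
    values: pd.DataFrame           # square, genotype ids on both axes
    n_markers: int
    allele_freqs: np.ndarray

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    def submatrix(self, ids: list[str]) -> np.ndarray:
        return self.values.loc[ids, ids].to_numpy()

    def cross(self, rows: list[str], cols: list[str]) -> np.ndarray:
        return self.values.loc[rows, cols].to_numpy()


@dataclass
class DistanceMatrix:
    values: pd.DataFrame
    n_shared: pd.DataFrame         # per-pair count of mutually observed markers


def vanraden_kinship(matrix: GenotypeMatrix, impute_means: bool = True) -> KinshipMatrix:
    """VanRaden genomic relationship matrix.

    Allele frequencies come from the non-missing dosages per marker.  With
    ``impute_means`` missing cells are mean-filled (centred to zero);
    on complete data this is a no-op.  All-monomorphic input has a zero
    scaling denominator and is rejected.
    """
    if matrix.n_genotypes < 2:
        raise ValueError("need at least two genotypes")
    calls = matrix.calls
    obs = ~np.isnan(calls)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(calls, axis=0) / (2.0 * np.maximum(n_obs, 1))
    p = np.where(n_obs > 0, p, 0.0)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ZeroDivisionError("all markers monomorphic: VanRaden denominator is zero")
    Z = calls - 2.0 * p[None, :]
    if impute_means:
        Z = np.where(obs, Z, 0.0)
    elif np.isnan(Z).any():
        raise ValueError("matrix has missing calls; set impute_means=True")
    K = (Z @ Z.T) / denom
    values = pd.DataFrame(K, index=matrix.genotypes, columns=matrix.genotypes)
    return KinshipMatrix(values=values, n_markers=matrix.n_markers, allele_freqs=p)


def rogers_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Rogers' distances on mutually observed markers.

    Pairs sharing no observed marker get a missing (nan) entry and a
    warning.  Entries lie in [0, 1] with a zero diagonal.
    """
    calls = matrix.calls
    obs = ~np.isnan(calls)
    shared = (obs.astype(np.float64) @ obs.T.astype(np.float64))
    # sum over shared loci of |d_i - d_j| via dosage-indicator products
    ind = [(calls == d).astype(np.float64) for d in (0.0, 1.0, 2.0)]
    diff = np.zeros_like(shared)
    for u in range(3):
        for v in range(3):
            if u != v:
                diff += abs(u - v) * (ind[u] @ ind[v].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (diff / 2.0) / shared
    none_shared = shared == 0
    np.fill_diagonal(none_shared, False)
    if none_shared.any():
        warnings.warn(
            f"{int(none_shared.sum() // 2)} genotype pairs share no observed marker"
        )
        dist[none_shared] = np.nan
    np.fill_diagonal(dist, 0.0)
    ids = matrix.genotypes
    return DistanceMatrix(
        values=pd.DataFrame(dist, index=ids, columns=ids),
        n_shared=pd.DataFrame(shared.astype(int), index=ids, columns=ids),
    )


def pcoa(dist: DistanceMatrix | pd.DataFrame, k: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical-scaling principal coordinates of a distance matrix.

    Double-centres ``-D**2 / 2``, eigen-decomposes, and returns the top-k
    coordinates scaled by sqrt(eigenvalue).  Dimensions with negative
    eigenvalues are excluded (k truncated with a warning if needed); all
    eigenvalues are returned for inspection.
    """
    values = dist.values if isinstance(dist, DistanceMatrix) else dist
    D = np.asarray(values, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix has missing entries")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int((eigval > 1e-10 * max(abs(eigval[0]), 1.0)).sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; k truncated from {k}")
        k = n_pos
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])[None, :]
    idx = values.index if hasattr(values, "index") else pd.RangeIndex(n)
    frame = pd.DataFrame(coords, index=idx, columns=[f"PCo{i + 1}" for i in range(k)])
    return frame, eigval
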