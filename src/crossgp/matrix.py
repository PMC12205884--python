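"""Genotype call matrices and their bookkeeping.

The central in-memory object is :class:`GenotypeMatrix`: a genotypes x
markers table of biallelic minor-allele dosages (0, 1, 2 or missing)
together with marker metadata (chromosome, position, allele pair) and
per-genotype series/batch labels.  Quality control, harmonization,
imputation and kinship all act on this object.

Calls are stored as ``float64`` with ``numpy.nan`` marking missing so that
masking and column statistics vectorise cleanly; every non-missing entry
is one of {0.0, 1.0, 2.0}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Allele pairs for which a strand flip is invisible from the alleles alone.
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


def complement_alleles(a1: str, a2: str) -> tuple[str, str]:
    """Return the reverse-strand reading of an allele pair."""
    return _COMPLEMENT[a1], _COMPLEMENT[a2]


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix with marker and genotype metadata.

    Parameters
    ----------
    genotypes
        Unique genotype identifiers (rows).
    markers
        DataFrame indexed by unique marker identifiers (columns of
        ``calls``) with columns ``chrom``, ``pos`` (1-based bp),
        ``allele1``, ``allele2``.
    calls
        ``(n_genotypes, n_markers)`` float array of dosages in
        {0, 1, 2, nan}.
    series
        Per-genotype experimental-series label.
    batch
        Name of the genotyping batch (or merged product) this matrix
        represents.
    """

    genotypes: list[str]
    markers: pd.DataFrame
    calls: np.ndarray
    series: np.ndarray = field(default=None)  # type: ignore[assignment]
    batch: str = ""

    def __post_init__(self) -> None:
        self.genotypes = list(self.genotypes)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.genotypes), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.genotypes)} genotypes x {len(self.markers)} markers"
            )
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("duplicate genotype identifiers")
        if self.markers.index.has_duplicates:
            raise ValueError("duplicate marker identifiers")
        if self.series is None:
            self.series = np.array([""] * len(self.genotypes), dtype=object)
        else:
            self.series = np.asarray(self.series, dtype=object)
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"calls contain values outside {{0,1,2,missing}}: {bad}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers.index)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.genotypes),
            self.markers.copy(),
            self.calls.copy(),
            self.series.copy(),
            self.batch,
        )

    # -- per-row / per-column statistics --------------------------------
    def genotype_missing_frac(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=1)

    def marker_missing_frac(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=0)

    def genotype_het_frac(self) -> np.ndarray:
        """Heterozygous fraction among a genotype's non-missing calls."""
        obs = ~np.isnan(self.calls)
        het = self.calls == 1.0
        with np.errstate(invalid="ignore"):
            return np.where(obs.sum(axis=1) > 0, het.sum(axis=1) / np.maximum(obs.sum(axis=1), 1), 0.0)

    def marker_het_frac(self) -> np.ndarray:
        obs = ~np.isnan(self.calls)
        het = self.calls == 1.0
        n = obs.sum(axis=0)
        return np.where(n > 0, het.sum(axis=0) / np.maximum(n, 1), 0.0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker from non-missing dosages.

        Heterozygous calls contribute one allele copy.  Markers with no
        observed calls get nan.
        """
        obs = ~np.isnan(self.calls)
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(self.calls, axis=0) / (2.0 * np.maximum(n, 1))
        p = np.where(n > 0, p, np.nan)
        return np.minimum(p, 1.0 - p)

    # -- subsetting ------------------------------------------------------
    def take_genotypes(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            [self.genotypes[i] for i in idx],
            self.markers.copy(),
            self.calls[idx],
            self.series[idx],
            self.batch,
        )

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.genotypes),
            self.markers.iloc[idx].copy(),
            self.calls[:, idx],
            self.series.copy(),
            self.batch,
        )

    def select_genotypes(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {g: i for i, g in enumerate(self.genotypes)}
        return self.take_genotypes(np.array([pos[g] for g in ids]))

    def select_markers(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {m: i for i, m in enumerate(self.markers.index)}
        return self.take_markers(np.array([pos[m] for m in ids]))

    def sort_markers(self) -> "GenotypeMatrix":
        """Return a copy with markers ordered by (chromosome, position)."""
        order = np.lexsort((self.markers["pos"].to_numpy(), self.markers["chrom"].to_numpy()))
        return self.take_markers(order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.genotypes, columns=self.markers.index)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypeMatrix(batch={self.batch!r}, {self.n_genotypes} genotypes x "
            f"{self.n_markers} markers, {np.isnan(self.calls).mean():.1%} missing)"
        )
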