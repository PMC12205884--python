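"""Synthetic multi-series wheat breeding data with ground truth.

Emulates the statistical structure of pooled commercial and historical
inbred-line trial networks:

* several experimental series drawn from one weakly structured breeding
  pool, each genotyped on its own SNP-panel subset (block-wise
  missingness after merging) and connected by common check genotypes;
* inbred lines produced by crossing founder haplotypes and selfing to
  near-homozygosity, with linkage-block LD so kinship and imputation are
  non-trivial;
* unbalanced staged trials (few environments for many early-stage lines,
  many environments for few advanced lines) with trial / replicate /
  block design effects, series and environment main effects, unstructured
  G x E deviations and plot residuals;
* purely additive trait architecture, calibrated so that the entry-mean
  heritability hits a configurable target.

Everything is driven by a single integer seed; identical configuration and
seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

WHEAT_CHROMOSOMES = [f"{i}{g}" for i in range(1, 8) for g in "ABD"]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TraitSpec:
    """One simulated trait and its variance architecture.

    Variances are in squared trait units.  When ``var_gxe`` / ``var_resid``
    are left ``None`` they are calibrated at design-build time so that the
    entry-mean heritability H2 = var_g / (var_g + var_delta / n_env)
    equals ``h2_target``, with the stage-2 residual variance
    ``var_delta = var_gxe + var_resid`` split evenly between G x E and
    plot residual.
    """

    name: str = "grain_yield"
    h2_target: float = 0.85
    mean: float = 10.0
    var_g: float = 1.0
    var_series: float = 0.25
    var_env: float = 1.0
    var_trial: float = 0.10
    var_rep: float = 0.05
    var_block: float = 0.05
    var_gxe: float | None = None
    var_resid: float | None = None
    outlier_rate: float = 0.0
    outlier_magnitude: float = 8.0

    def resolved(self, mean_envs: float, mean_reps: float = 1.0) -> "TraitSpec":
        """Fill in ``var_gxe``/``var_resid`` to hit ``h2_target``.

        The entry-mean residual per environment is
        ``var_gxe + var_resid / r`` for ``r`` plots per genotype and
        environment, so the plot-residual half is scaled up by the average
        replication to keep the calibration exact under replicated trials.
        """
        if not (0.0 < self.h2_target <= 1.0):
            raise ValueError("h2_target must lie in (0, 1]")
        if self.var_gxe is not None and self.var_resid is not None:
            return self
        var_delta = self.var_g * mean_envs * (1.0 / self.h2_target - 1.0)
        out = TraitSpec(**{**self.__dict__})
        out.var_gxe = var_delta / 2.0 if self.var_gxe is None else self.var_gxe
        out.var_resid = mean_reps * var_delta / 2.0 if self.var_resid is None else self.var_resid
        return out


@dataclass
class SimConfig:
    """Study design for one synthetic multi-series dataset.

    ``stages`` is the staged-trial structure: (fraction of the series'
    genotypes, number of environments, replicates per environment).  The
    default 2/4/8/12-environment ladder reproduces the hallmark of
    commercial data — many early-stage candidates observed in very few
    environments, few advanced lines observed in many.
    """

    n_series: int = 4
    genotypes_per_series: tuple[int, ...] = (600, 600, 600, 600)
    n_markers: int = 2000
    n_checks: int = 5
    n_founders: int = 50
    block_len: int = 20
    n_ancestors: int = 8
    mutation_rate: float = 0.02
    selfing_generations: int = 6
    panels: list[np.ndarray] | None = None
    core_frac: float = 0.30
    batch_missing_rate: float = 0.02
    n_locations: int = 6
    years: tuple[tuple[int, ...], ...] | None = None
    first_year: int = 2012
    stages: tuple[tuple[float, int, int], ...] = (
        (0.4, 2, 1), (0.3, 4, 1), (0.2, 8, 2), (0.1, 12, 2),
    )
    traits: tuple[TraitSpec, ...] = (TraitSpec(),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_series < 1 or self.n_markers < 1 or self.n_checks < 1:
            raise ValueError("n_series, n_markers and n_checks must be >= 1")
        if len(self.genotypes_per_series) != self.n_series:
            raise ValueError("genotypes_per_series length must equal n_series")
        if not (1 <= self.block_len <= self.n_markers):
            raise ValueError("need n_markers >= block_len >= 1")
        for t in self.traits:
            for v in (t.var_g, t.var_series, t.var_env, t.var_trial, t.var_rep, t.var_block):
                if v < 0:
                    raise ValueError(f"negative variance in trait {t.name!r}")
        if self.years is None:
            self.years = tuple(
                (self.first_year + 2 * s, self.first_year + 2 * s + 1)
                for s in range(self.n_series)
            )
        if self.panels is None:
            self.panels = default_panels(
                self.n_markers, self.n_series, self.block_len, self.core_frac
            )
        for s, p in enumerate(self.panels):
            p = np.asarray(p)
            if p.size == 0:
                raise ValueError(f"empty marker panel for series {s}")
            if p.min() < 0 or p.max() >= self.n_markers:
                raise ValueError("panel indices outside master panel")

    def mean_envs_per_genotype(self) -> float:
        return float(sum(f * n for f, n, _ in self.stages) / sum(f for f, _, _ in self.stages))

    def mean_reps_per_plot(self) -> float:
        num = sum(f * n * r for f, n, r in self.stages)
        den = sum(f * n for f, n, _ in self.stages)
        return float(num / den)

    def series_names(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.n_series)]


def default_panels(
    n_markers: int, n_series: int, block_len: int, core_frac: float = 0.30
) -> list[np.ndarray]:
    """Overlapping per-series marker panels over the master panel.

    Whole linkage blocks are assigned: a core subset of blocks is shared by
    every series (the markers that end up widely available after merging),
    the remaining blocks go to one series each, with every second
    non-core block shared with the following series so that adjacent
    panels overlap beyond the core.
    """
    n_blocks = int(np.ceil(n_markers / block_len))
    blocks = [np.arange(b * block_len, min((b + 1) * block_len, n_markers)) for b in range(n_blocks)]
    core_every = max(int(round(1.0 / core_frac)), 2)
    panels: list[list[np.ndarray]] = [[] for _ in range(n_series)]
    noncore = 0
    for b, idx in enumerate(blocks):
        if b % core_every == 0:
            for p in panels:
                p.append(idx)
        else:
            owner = noncore % n_series
            panels[owner].append(idx)
            if noncore % 2 == 0 and n_series > 1:
                panels[(owner + 1) % n_series].append(idx)
            noncore += 1
    return [np.sort(np.concatenate(p)) for p in panels]


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests.

    ``breeding_values[trait]`` maps genotype id -> true additive value;
    the additive model ``bv = dosage . effects`` holds exactly for the
    complete (pre-panel-masking) dosage matrix.
    """

    marker_effects: dict[str, np.ndarray]
    breeding_values: dict[str, pd.Series]
    variance_components: dict[str, dict[str, float]]
    realized_h2: dict[str, float]

    def bv(self, trait: str) -> pd.Series:
        return self.breeding_values[trait]


# ---------------------------------------------------------------------------
# Founders and inbred genotypes
# ---------------------------------------------------------------------------

def simulate_founders(
    n_founders: int,
    n_markers: int,
    block_len: int,
    seed: int,
    n_ancestors: int = 8,
    mutation_rate: float = 0.02,
) -> np.ndarray:
    """Binary founder haplotype pool with block-structured LD.

    Markers are grouped into consecutive blocks of ``block_len``.  For each
    block a small set of ancestral block haplotypes is drawn; every founder
    copies one ancestor per block (independently across blocks) and mutates
    each allele with ``mutation_rate``.  Markers monomorphic across the
    pool are resampled from a fresh allele frequency so every column is
    polymorphic.
    """
    if n_founders < 1 or n_markers < 1 or block_len < 1:
        raise ValueError("n_founders, n_markers and block_len must be >= 1")
    if block_len > n_markers:
        raise ValueError("block_len cannot exceed n_markers")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n_markers / block_len))
    pool = np.empty((n_founders, n_markers), dtype=np.int8)
    for b in range(n_blocks):
        lo, hi = b * block_len, min((b + 1) * block_len, n_markers)
        ancestors = rng.integers(0, 2, size=(n_ancestors, hi - lo), dtype=np.int8)
        picks = rng.integers(0, n_ancestors, size=n_founders)
        block = ancestors[picks]
        if mutation_rate > 0:
            flips = rng.random(block.shape) < mutation_rate
            block = np.where(flips, 1 - block, block)
        pool[:, lo:hi] = block
    # resample monomorphic columns so allele frequencies stay in (0, 1)
    freqs = pool.mean(axis=0)
    mono = (freqs == 0.0) | (freqs == 1.0)
    for j in np.flatnonzero(mono):
        p = rng.uniform(0.1, 0.9)
        col = (rng.random(n_founders) < p).astype(np.int8)
        while col.min() == col.max():
            col = (rng.random(n_founders) < p).astype(np.int8)
        pool[:, j] = col
    return pool


def _make_inbreds(
    pool: np.ndarray, n_ind: int, block_len: int, generations: int, rng: np.random.Generator
) -> np.ndarray:
    """Cross random founder pairs and self for ``generations`` rounds.

    Gametes recombine freely at linkage-block boundaries and never within a
    block, preserving the founder LD structure.  Returns the dosage matrix
    (h1 + h2); residual heterozygosity is ~0.5**generations.
    """
    n_markers = pool.shape[1]
    n_blocks = int(np.ceil(n_markers / block_len))
    block_of = np.minimum(np.arange(n_markers) // block_len, n_blocks - 1)
    parents = rng.integers(0, pool.shape[0], size=(n_ind, 2))
    h1 = pool[parents[:, 0]].copy()
    h2 = pool[parents[:, 1]].copy()
    for _ in range(generations):
        new = []
        for _gamete in range(2):
            choice = rng.integers(0, 2, size=(n_ind, n_blocks), dtype=np.int8)
            take1 = choice[:, block_of].astype(bool)
            new.append(np.where(take1, h1, h2))
        h1, h2 = new
    return (h1 + h2).astype(np.int8)


def _marker_metadata(n_markers: int, block_len: int, rng: np.random.Generator) -> pd.DataFrame:
    n_blocks = int(np.ceil(n_markers / block_len))
    chrom_of_block = np.array(WHEAT_CHROMOSOMES)[
        (np.arange(n_blocks) * len(WHEAT_CHROMOSOMES)) // max(n_blocks, 1)
    ]
    chroms, positions = [], []
    pos_counter: dict[str, int] = {}
    for j in range(n_markers):
        c = chrom_of_block[min(j // block_len, n_blocks - 1)]
        pos_counter[c] = pos_counter.get(c, 0) + 1
        chroms.append(c)
        positions.append(pos_counter[c] * 100_000)
    bases = np.array(list("ACGT"))
    a1 = bases[rng.integers(0, 4, size=n_markers)]
    shift = rng.integers(1, 4, size=n_markers)
    a2 = bases[(np.searchsorted(bases, a1) + shift) % 4]
    return pd.DataFrame(
        {"chrom": chroms, "pos": positions, "allele1": a1, "allele2": a2},
        index=pd.Index([f"m{j:05d}" for j in range(n_markers)], name="marker"),
    )


def simulate_series_genotypes(
    config: SimConfig, pool: np.ndarray, seed: int | None = None
) -> tuple[list[GenotypeMatrix], GenotypeMatrix]:
    """Draw inbred genotypes for every series and cut them to panel batches.

    Returns ``(batches, complete)``: one :class:`GenotypeMatrix` per
    series-batch restricted to that series' marker panel (with per-batch
    random missingness added), and the complete master-panel matrix holding
    every genotype's full dosage vector (the truth the batches are views
    of).  The ``n_checks`` check genotypes appear identically in every
    batch under series label ``"multi"``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    markers = _marker_metadata(config.n_markers, config.block_len, rng)
    checks = _make_inbreds(pool, config.n_checks, config.block_len, config.selfing_generations, rng)
    check_ids = [f"CHK_{i + 1:02d}" for i in range(config.n_checks)]
    all_ids: list[str] = list(check_ids)
    all_series: list[str] = ["multi"] * config.n_checks
    all_dosages = [checks]
    for s, n in enumerate(config.genotypes_per_series):
        dos = _make_inbreds(pool, n, config.block_len, config.selfing_generations, rng)
        all_dosages.append(dos)
        all_ids.extend(f"{config.series_names()[s]}_g{i + 1:04d}" for i in range(n))
        all_series.extend([config.series_names()[s]] * n)
    complete = GenotypeMatrix(
        all_ids, markers, np.concatenate(all_dosages).astype(float),
        np.array(all_series, dtype=object), "complete",
    )
    batches = []
    for s, panel in enumerate(config.panels):
        name = config.series_names()[s]
        member = (complete.series == name) | (complete.series == "multi")
        batch = complete.take_genotypes(member).take_markers(np.asarray(panel))
        batch.batch = f"batch_{name}"
        if config.batch_missing_rate > 0:
            drop = rng.random(batch.calls.shape) < config.batch_missing_rate
            batch.calls[drop] = np.nan
        batches.append(batch)
    return batches, complete


# ---------------------------------------------------------------------------
# Trait truth and phenotype plots
# ---------------------------------------------------------------------------

def simulate_truth(config: SimConfig, complete: GenotypeMatrix, seed: int | None = None) -> SimTruth:
    """Draw additive marker effects and exact breeding values per trait.

    Effects are rescaled so the realized variance of the breeding values
    across all simulated genotypes equals the configured ``var_g``.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 104729)
    n_bar = config.mean_envs_per_genotype()
    r_bar = config.mean_reps_per_plot()
    effects, bvs, comps, h2 = {}, {}, {}, {}
    for trait in config.traits:
        t = trait.resolved(n_bar, r_bar)
        beta = rng.normal(size=config.n_markers)
        raw = complete.calls @ beta
        sd = raw.std()
        if sd == 0:
            raise ValueError("degenerate pool: breeding values have zero variance")
        beta *= np.sqrt(t.var_g) / sd
        bv = pd.Series(complete.calls @ beta, index=complete.genotypes, name=t.name)
        bv -= bv.mean()
        effects[t.name] = beta
        bvs[t.name] = bv
        comps[t.name] = {
            "var_g": float(bv.var(ddof=0)), "var_series": t.var_series,
            "var_env": t.var_env, "var_gxe": t.var_gxe, "var_trial": t.var_trial,
            "var_rep": t.var_rep, "var_block": t.var_block, "var_resid": t.var_resid,
        }
        delta = t.var_gxe + t.var_resid / r_bar
        h2[t.name] = float(t.var_g / (t.var_g + delta / n_bar))
    return SimTruth(effects, bvs, comps, h2)


def _series_environments(config: SimConfig, s: int) -> list[tuple[str, int]]:
    out = []
    for year in config.years[s]:
        for loc in range(config.n_locations):
            out.append((f"{config.series_names()[s]}L{loc + 1}", year))
    return out


def simulate_phenotype_plots(
    config: SimConfig, truth: SimTruth, seed: int | None = None
) -> pd.DataFrame:
    """Realize plot-level phenotypes for the staged multi-series design.

    plot value = mean + series + BV + env + GxE + trial + rep + block +
    residual, every term drawn iid from its configured variance.  A
    ``trait.outlier_rate`` fraction of plots is additionally perturbed by
    +/- ``outlier_magnitude`` residual SDs (the ``outlier`` column records
    which).  Check genotypes are grown in every environment of every
    series; other genotypes follow their stage's environment count.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 15485863)
    n_bar = config.mean_envs_per_genotype()
    r_bar = config.mean_reps_per_plot()
    sname = config.series_names()
    records: dict[str, list] = {c: [] for c in (
        "series", "location", "year", "env", "trial", "replication", "block", "genotype")}
    # build the design once, then overlay every trait
    for s in range(config.n_series):
        envs = _series_environments(config, s)
        ids = [g for g, lab in zip(truth.bv(config.traits[0].name).index,
                                   _series_of(truth, config))
               if lab == sname[s]]
        rng.shuffle(ids)
        fracs = np.array([f for f, _, _ in config.stages], dtype=float)
        bounds = np.floor(np.cumsum(fracs / fracs.sum()) * len(ids)).astype(int)
        start = 0
        assignments: list[tuple[str, int, int, int]] = []  # genotype, stage, n_env, reps
        for k, ((_, n_env, reps), stop) in enumerate(zip(config.stages, bounds)):
            for g in ids[start:stop]:
                assignments.append((g, k, min(n_env, len(envs)), reps))
            start = stop
        check_ids = [g for g, lab in zip(truth.bv(config.traits[0].name).index,
                                         _series_of(truth, config)) if lab == "multi"]
        env_order = {k: rng.permutation(len(envs)) for k in range(len(config.stages))}
        for g, k, n_env, reps in assignments:
            chosen = env_order[k][:n_env]
            for e in chosen:
                loc, year = envs[e]
                for r in range(reps):
                    _push(records, sname[s], loc, year, f"T{k + 1}", str(r + 1), g)
        # checks sit in every trial of every environment
        for g in check_ids:
            for k, (_, n_env, reps) in enumerate(config.stages):
                for e in env_order[k][:min(n_env, len(envs))]:
                    loc, year = envs[e]
                    for r in range(reps):
                        _push(records, sname[s], loc, year, f"T{k + 1}", str(r + 1), g)
    design = pd.DataFrame(records)
    design["env"] = design["location"] + "_" + design["year"].astype(str)
    # blocks: consecutive plots within (env, trial, replication) in groups of 20
    design["block"] = (
        design.groupby(["env", "trial", "replication"]).cumcount() // 20 + 1
    ).astype(str)
    frames = []
    for trait in config.traits:
        t = trait.resolved(n_bar, r_bar)
        df = design.copy()
        df["trait"] = t.name
        bv = truth.bv(t.name)
        eff = {}
        for col, var in (("series", t.var_series), ("env", t.var_env)):
            levels = df[col].unique()
            eff[col] = pd.Series(rng.normal(0, np.sqrt(var), len(levels)), index=levels)
        nest_keys = {
            "trial": df["env"] + ":" + df["trial"],
            "replication": df["env"] + ":" + df["trial"] + ":" + df["replication"],
            "block": df["env"] + ":" + df["trial"] + ":" + df["replication"] + ":" + df["block"],
        }
        for col, var in (("trial", t.var_trial), ("replication", t.var_rep), ("block", t.var_block)):
            key = nest_keys[col]
            levels = key.unique()
            lev_eff = pd.Series(rng.normal(0, np.sqrt(var), len(levels)), index=levels)
            df["_" + col] = lev_eff.loc[key].to_numpy()
        gxe_key = df["genotype"] + "@" + df["env"]
        gxe_levels = gxe_key.unique()
        gxe = pd.Series(rng.normal(0, np.sqrt(t.var_gxe), len(gxe_levels)), index=gxe_levels)
        resid = rng.normal(0, np.sqrt(t.var_resid), len(df))
        df["value"] = (
            t.mean
            + eff["series"].loc[df["series"]].to_numpy()
            + bv.loc[df["genotype"]].to_numpy()
            + eff["env"].loc[df["env"]].to_numpy()
            + gxe.loc[gxe_key].to_numpy()
            + df["_trial"].to_numpy() + df["_replication"].to_numpy() + df["_block"].to_numpy()
            + resid
        )
        out_flag = rng.random(len(df)) < t.outlier_rate
        signs = rng.choice([-1.0, 1.0], size=len(df))
        df.loc[out_flag, "value"] += (
            signs[out_flag] * t.outlier_magnitude * np.sqrt(t.var_resid)
        )
        df["outlier"] = out_flag
        frames.append(df.drop(columns=["_trial", "_replication", "_block"]))
    plots = pd.concat(frames, ignore_index=True)
    cols = ["series", "location", "year", "env", "trial", "replication", "block",
            "genotype", "trait", "value", "outlier"]
    return plots[cols]


def _series_of(truth: SimTruth, config: SimConfig) -> list[str]:
    ids = list(truth.bv(config.traits[0].name).index)
    out = []
    for g in ids:
        out.append("multi" if g.startswith("CHK_") else g.split("_g")[0])
    return out


def _push(records, series, loc, year, trial, rep, genotype) -> None:
    records["series"].append(series)
    records["location"].append(loc)
    records["year"].append(year)
    records["env"].append("")  # filled later
    records["trial"].append(trial)
    records["replication"].append(rep)
    records["block"].append("")  # filled later
    records["genotype"].append(genotype)


# ---------------------------------------------------------------------------
# Convenience: whole dataset, and an entry-mean emulator for large designs
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    config: SimConfig
    batches: list[GenotypeMatrix]
    complete: GenotypeMatrix
    truth: SimTruth
    plots: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generator: founders -> genotypes -> truth -> plots."""
    pool = simulate_founders(
        config.n_founders, config.n_markers, config.block_len, config.seed,
        config.n_ancestors, config.mutation_rate,
    )
    batches, complete = simulate_series_genotypes(config, pool)
    truth = simulate_truth(config, complete)
    plots = simulate_phenotype_plots(config, truth)
    return SimDataset(config, batches, complete, truth, plots)


def simulate_genotype_means(
    truth: SimTruth, trait: str, n_envs: pd.Series, var_delta: float, seed: int
) -> pd.Series:
    """Entry-mean emulator: BV + N(0, var_delta / n_env) per genotype.

    Stands in for the two-stage phenotypic analysis when only adjusted
    genotype means are needed at scales where fitting the full plot-level
    models would dominate runtime; ``var_delta`` is the stage-2 residual
    variance (G x E plus plot-residual contribution).
    """
    rng = np.random.default_rng(seed)
    bv = truth.bv(trait).loc[n_envs.index]
    noise = rng.normal(size=len(bv)) * np.sqrt(var_delta / n_envs.to_numpy(dtype=float))
    return pd.Series(bv.to_numpy() + noise, index=bv.index, name=trait)
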