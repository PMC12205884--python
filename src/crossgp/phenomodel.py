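"""Two-stage phenotypic analysis of unbalanced multi-environment trials.

Stage 1 fits each environment (location x year) separately: plot value =
mean + genotype + trial + replicate + block + residual, with whichever
design factors the trial layout provides, after residual-based outlier
removal.  Genotype enters fixed for adjusted means (BLUEs) and random for
the genotypic variance behind the per-plot repeatability
``r2 = var_g / (var_g + var_e / n_plots)``.

Stage 2 pools the within-environment adjusted means: value = mean +
series + genotype + environment + residual, series fixed, environment
random; genotype fixed gives across-environment BLUEs, random gives BLUPs
and the entry-mean heritability ``H2 = var_g / (var_g + var_e / n_env)``.
Stage 2 is unweighted: every within-environment mean enters with equal
residual variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LmmFit, LmmSpec, fit_lmm_reml

DESIGN_FACTORS = ("trial", "replication", "block")


@dataclass
class WithinEnvResult:
    env: str
    trait: str
    blues: pd.Series                 # genotype -> adjusted mean (trait units)
    repeatability: float
    var_g: float
    var_resid: float
    design_varcomps: dict[str, float]
    n_plots_per_genotype: float
    outliers: pd.DataFrame           # removed plot records
    series: str = ""


@dataclass
class AcrossEnvResult:
    trait: str
    blues: pd.Series
    blups: pd.Series
    var_g: float
    var_env: float
    var_resid: float
    h2: float
    mean_envs_per_genotype: float
    series_effects: pd.Series
    n_envs: pd.Series                # genotype -> number of environments
    fit_blue: LmmFit | None = None


# ---------------------------------------------------------------------------
# Outlier correction (residual-based, Bonferroni-Holm)
# ---------------------------------------------------------------------------

def detect_outliers_m5(
    plots: pd.DataFrame, alpha: float = 0.05, min_plots: int = 10
) -> pd.DataFrame:
    """Flag plots with extreme conditional residuals, per environment.

    For each environment the stage-1 model is fitted with genotype random;
    conditional residuals are re-scaled by their median absolute deviation
    (scaled to the normal), converted to two-sided normal p-values, and
    Bonferroni-Holm corrected within the environment.  Plots with adjusted
    p < ``alpha`` are returned.  Environments with fewer than
    ``min_plots`` plots are skipped with a warning.
    """
    flagged = []
    for (env, trait), sub in plots.groupby(["env", "trait"], sort=True):
        if len(sub) < min_plots:
            warnings.warn(f"env {env}: only {len(sub)} plots, outlier scan skipped")
            continue
        if alpha <= 0:
            continue
        sub = sub.reset_index()
        fit = _stage1_fit(sub, genotype_fixed=False)
        resid = sub["value"].to_numpy() - _fitted_values(fit, sub)
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = mad * 1.4826
        if scale <= 0:
            continue
        z = (resid - np.median(resid)) / scale
        p = 2.0 * stats.norm.sf(np.abs(z))
        reject = _holm(p, alpha)
        if reject.any():
            rec = sub.loc[reject].copy()
            rec["residual_z"] = z[reject]
            flagged.append(rec)
    if not flagged:
        return pd.DataFrame(columns=[*plots.columns, "index", "residual_z"])
    return pd.concat(flagged, ignore_index=True)


def _holm(p: np.ndarray, alpha: float) -> np.ndarray:
    """Bonferroni-Holm step-down rejection mask."""
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] > alpha / (m - rank):
            break
        reject[idx] = True
    return reject


def _stage1_fit(sub: pd.DataFrame, genotype_fixed: bool) -> LmmFit:
    sub = sub.copy()
    sub["_trial"] = sub["trial"].astype(str)
    sub["_replication"] = sub["_trial"] + ":" + sub["replication"].astype(str)
    sub["_block"] = sub["_replication"] + ":" + sub["block"].astype(str)
    design = [f for f in ("_trial", "_replication", "_block") if sub[f].nunique() > 1]
    fixed = ["genotype"] if genotype_fixed else []
    random = design if genotype_fixed else ["genotype", *design]
    return fit_lmm_reml(LmmSpec(sub, "value", fixed, random))


def _fitted_values(fit: LmmFit, sub: pd.DataFrame) -> np.ndarray:
    """Conditional mean (fixed + BLUP parts) for each plot of a stage-1 fit."""
    yhat = np.full(len(sub), fit.beta.get("(Intercept)", 0.0))
    sub = sub.copy()
    sub["_trial"] = sub["trial"].astype(str)
    sub["_replication"] = sub["_trial"] + ":" + sub["replication"].astype(str)
    sub["_block"] = sub["_replication"] + ":" + sub["block"].astype(str)
    for factor, blup in fit.blups.items():
        col = factor if factor in sub.columns else factor
        yhat += blup.reindex(sub[col].astype(str)).fillna(0.0).to_numpy()
    for factor, levels in fit.fixed_levels.items():
        eff = fit.blues_for(factor) - fit.beta.get("(Intercept)", 0.0)
        yhat += eff.reindex(sub[factor].astype(str)).fillna(0.0).to_numpy()
    return yhat


# ---------------------------------------------------------------------------
# Stage 1: within-environment analysis
# ---------------------------------------------------------------------------

def within_env_analysis(
    plots: pd.DataFrame, alpha: float = 0.05
) -> list[WithinEnvResult]:
    """Per-environment adjusted means, repeatability and outlier removal.

    Environments where genotype effects are inestimable (a single plot in
    total) are dropped with a warning.
    """
    outliers = detect_outliers_m5(plots, alpha=alpha)
    if len(outliers):
        plots = plots.drop(index=outliers["index"].to_numpy())
    results = []
    for (env, trait), sub in plots.groupby(["env", "trait"], sort=True):
        sub = sub.reset_index(drop=True)
        if len(sub) < 2 or sub["genotype"].nunique() < 2:
            warnings.warn(f"env {env}: genotype effects inestimable, dropped")
            continue
        fit_rand = _stage1_fit(sub, genotype_fixed=False)
        p_fixed = 1 + sub["genotype"].nunique() - 1
        if len(sub) - p_fixed >= 5:
            fit_blue = _stage1_fit(sub, genotype_fixed=True)
            blues = fit_blue.blues_for("genotype")
        else:
            # (nearly) unreplicated trial: estimate the design effects from
            # the genotype-random fit and subtract them from the plots, so
            # the adjusted measurement keeps mean + genotype + residual
            adj = sub["value"].to_numpy().copy()
            keyed = sub.copy()
            keyed["_trial"] = keyed["trial"].astype(str)
            keyed["_replication"] = keyed["_trial"] + ":" + keyed["replication"].astype(str)
            keyed["_block"] = keyed["_replication"] + ":" + keyed["block"].astype(str)
            for factor, blup in fit_rand.blups.items():
                if factor == "genotype":
                    continue
                adj -= blup.reindex(keyed[factor].astype(str)).fillna(0.0).to_numpy()
            blues = pd.Series(adj, index=sub["genotype"]).groupby(level=0).mean()
            blues.name = "genotype"
        var_g = fit_rand.varcomps.get("genotype", 0.0)
        var_e = fit_rand.varcomps["residual"]
        n_bar = len(sub) / sub["genotype"].nunique()
        denom = var_g + var_e / n_bar
        r2 = float(var_g / denom) if denom > 0 else 0.0
        env_outliers = outliers[(outliers["env"] == env) & (outliers["trait"] == trait)] \
            if len(outliers) else outliers
        results.append(
            WithinEnvResult(
                env=env, trait=trait, blues=blues, repeatability=r2,
                var_g=var_g, var_resid=var_e,
                design_varcomps={
                    k.lstrip("_"): v for k, v in fit_rand.varcomps.items()
                    if k not in ("genotype", "residual")
                },
                n_plots_per_genotype=float(n_bar),
                outliers=env_outliers,
                series=str(sub["series"].iloc[0]),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Environment quality control
# ---------------------------------------------------------------------------

def environment_qc(
    results: list[WithinEnvResult],
    min_repeatability: float = 0.3,
    min_mean_correlation: float = 0.1,
    min_common: int = 5,
) -> list[WithinEnvResult]:
    """Discard low-repeatability, then uncorrelated, environments.

    First pass drops environments with repeatability < 0.3 (strict); the
    second drops environments whose mean Pearson correlation of genotype
    adjusted means with every other environment (on common genotypes) is
    below 0.1.  Pairs sharing fewer than ``min_common`` genotypes are
    skipped in the mean and reported.
    """
    if len(results) < 2:
        raise ValueError("need at least two environments for QC")
    stage1 = [r for r in results if r.repeatability >= min_repeatability]
    kept = []
    for trait in sorted({r.trait for r in stage1}):
        rs = [r for r in stage1 if r.trait == trait]
        if len(rs) == 1:
            kept.extend(rs)
            continue
        means = []
        for r in rs:
            cors = []
            for other in rs:
                if other is r:
                    continue
                common = r.blues.index.intersection(other.blues.index)
                if len(common) < min_common:
                    warnings.warn(
                        f"envs {r.env}/{other.env} ({trait}): only {len(common)} "
                        "common genotypes, pair skipped in correlation mean"
                    )
                    continue
                a, b = r.blues.loc[common], other.blues.loc[common]
                if a.std() == 0 or b.std() == 0:
                    continue
                cors.append(float(np.corrcoef(a, b)[0, 1]))
            means.append(np.mean(cors) if cors else np.nan)
        for r, m in zip(rs, means):
            if np.isnan(m) or m >= min_mean_correlation:
                kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# Stage 2: across-environment analysis
# ---------------------------------------------------------------------------

def across_env_analysis(
    results: list[WithinEnvResult], include_series: bool = True
) -> AcrossEnvResult:
    """Pool within-environment means into across-environment BLUEs/BLUPs.

    Requires the environments to be connected through common genotypes
    when several series are involved; otherwise a connectivity error names
    the disconnected components.
    """
    if len(results) < 2:
        raise ValueError("need at least two environments after QC")
    traits = {r.trait for r in results}
    if len(traits) != 1:
        raise ValueError(f"mixed traits in across-environment analysis: {sorted(traits)}")
    trait = traits.pop()
    rows = []
    for r in results:
        for g, v in r.blues.items():
            rows.append((r.series, r.env, g, v))
    df = pd.DataFrame(rows, columns=["series", "env", "genotype", "value"])
    if include_series and df["series"].nunique() > 1:
        _check_connectivity(df)
    fixed = ["series", "genotype"] if include_series and df["series"].nunique() > 1 else ["genotype"]
    fit_blue = fit_lmm_reml(LmmSpec(df, "value", fixed, ["env"]))
    blues = fit_blue.blues_for("genotype")
    fit_rand = fit_lmm_reml(
        LmmSpec(df, "value", fixed[:-1], ["genotype", "env"])
    )
    var_g = fit_rand.varcomps.get("genotype", 0.0)
    var_e = fit_rand.varcomps["residual"]
    n_envs = df.groupby("genotype")["env"].nunique()
    n_bar = float(n_envs.mean())
    denom = var_g + var_e / n_bar
    h2 = float(var_g / denom) if denom > 0 else 0.0
    if include_series and "series" in fit_blue.fixed_levels:
        series_eff = fit_blue.blues_for("series") - fit_blue.beta["(Intercept)"]
    else:
        series_eff = pd.Series(dtype=float)
    return AcrossEnvResult(
        trait=trait, blues=blues, blups=fit_rand.blups["genotype"],
        var_g=var_g, var_env=fit_rand.varcomps.get("env", 0.0), var_resid=var_e,
        h2=h2, mean_envs_per_genotype=n_bar, series_effects=series_eff,
        n_envs=n_envs, fit_blue=fit_blue,
    )


def _check_connectivity(df: pd.DataFrame) -> None:
    import networkx as nx

    g = nx.Graph()
    for s in df["series"].unique():
        g.add_node(("series", s))
    for geno, sub in df.groupby("genotype"):
        for s in sub["series"].unique():
            g.add_edge(("genotype", geno), ("series", s))
    series_nodes = [n for n in g.nodes if n[0] == "series"]
    comps = list(nx.connected_components(g))
    series_comps = [
        sorted(n[1] for n in c if n[0] == "series") for c in comps
        if any(n[0] == "series" for n in c)
    ]
    if len(series_comps) > 1:
        raise ValueError(
            f"experimental series are not connected by common genotypes: {series_comps}"
        )


def within_series_blues(
    results: list[WithinEnvResult],
) -> dict[str, AcrossEnvResult]:
    """Stage-2 fit per series (no series effect): within-series BLUEs."""
    out = {}
    for s in sorted({r.series for r in results}):
        rs = [r for r in results if r.series == s]
        if len(rs) < 2:
            warnings.warn(f"series {s}: fewer than two environments, skipped")
            continue
        out[s] = across_env_analysis(rs, include_series=False)
    return out


def blue_table(
    across: AcrossEnvResult, per_series: dict[str, AcrossEnvResult]
) -> pd.DataFrame:
    """Tidy genotype-level means: one row per genotype x level."""
    rows = []
    for g in across.blues.index:
        rows.append(("all", "", across.trait, g, across.blues[g],
                     across.blups.get(g, np.nan), int(across.n_envs.get(g, 0))))
    for s, res in per_series.items():
        for g in res.blues.index:
            rows.append(("series", s, res.trait, g, res.blues[g],
                         res.blups.get(g, np.nan), int(res.n_envs.get(g, 0))))
    return pd.DataFrame(
        rows, columns=["level", "series", "trait", "genotype", "blue", "blup", "n_env"]
    )
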