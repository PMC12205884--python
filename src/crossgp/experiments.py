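"""Designed genomic-prediction experiments over the integrated data.

Covers the study designs the scaling analysis consumes:

* within-series 90/10 cross-validation (20 replicates) on within-series
  adjusted means, with per-series marker filtering (>= 80% call rate in
  that series, MAF >= 0.05);
* D-optimal selection (Fedorov exchange) of series combinations used as
  across-series training sets, and the across-series prediction runs per
  marker-set variant;
* three designed training-set scenarios at constant training size:
  single vs multiple series, environment-count groups, and year windows.

Every run is reproducible from (inputs, seed); a genotype never appears
in both the training and the test side of the same run.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .genoqc import maf_filter, missingness_filter
from .gblup import fit_gblup, prediction_ability
from .matrix import GenotypeMatrix
from .popgen import KinshipMatrix, vanraden_kinship

RUN_COLUMNS = [
    "test_series", "training_series", "x_train", "ability", "trait",
    "variant", "replicate",
]


def _run_row(test_series, training, x, ability, trait, variant, rep) -> dict:
    return {
        "test_series": test_series,
        "training_series": "+".join(sorted(training)),
        "x_train": int(x),
        "ability": float(ability),
        "trait": trait,
        "variant": variant,
        "replicate": int(rep),
    }


def _ability(blues: pd.Series, K: KinshipMatrix, train: list[str], test: list[str]) -> float:
    overlap = set(train) & set(test)
    assert not overlap, f"training/test overlap: {sorted(overlap)[:5]}"
    fit = fit_gblup(blues.loc[train], K, test_genotypes=list(test))
    pred = fit.predictions(list(test))
    return float(prediction_ability(pred, blues.loc[list(test)]).iloc[0])


# ---------------------------------------------------------------------------
# Within-series cross-validation
# ---------------------------------------------------------------------------

def within_series_cv(
    blues_by_series: dict[str, pd.Series],
    matrix: GenotypeMatrix,
    trait: str = "",
    train_frac: float = 0.9,
    reps: int = 20,
    seed: int = 0,
    min_call_rate: float = 0.80,
    min_maf: float = 0.05,
    min_genotypes: int = 20,
) -> pd.DataFrame:
    """Random 90/10 cross-validation within each series, ``reps`` times.

    Per series, markers are re-filtered on the series' own genotypes
    (call rate >= ``min_call_rate``, MAF >= ``min_maf``) before the
    kinship is computed.  Series with fewer than ``min_genotypes``
    genotypes carrying both means and SNP data are skipped with a report.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in sorted(blues_by_series):
        blues = blues_by_series[s]
        ids = [g for g in blues.index if g in set(matrix.genotypes)]
        if len(ids) < min_genotypes:
            warnings.warn(f"series {s}: only {len(ids)} usable genotypes, CV skipped")
            continue
        sub = matrix.select_genotypes(ids)
        sub = missingness_filter(sub, 1.0 - min_call_rate)
        sub = maf_filter(sub, min_maf)
        K = vanraden_kinship(sub)
        y = blues.loc[ids]
        n_train = int(round(train_frac * len(ids)))
        for rep in range(reps):
            perm = rng.permutation(len(ids))
            train = [ids[i] for i in perm[:n_train]]
            test = [ids[i] for i in perm[n_train:]]
            ability = _ability(y, K, train, test)
            rows.append(_run_row(s, [s], n_train, ability, trait, "within_cv", rep))
    return pd.DataFrame(rows, columns=RUN_COLUMNS)


# ---------------------------------------------------------------------------
# D-optimal series combinations (Fedorov exchange)
# ---------------------------------------------------------------------------

def candidate_series_sets(n_series: int) -> list[frozenset[int]]:
    """All non-empty proper subsets of the series indices."""
    out = []
    for r in range(1, n_series):
        out.extend(frozenset(c) for c in itertools.combinations(range(n_series), r))
    return out


def _design_rows(candidates: list[frozenset[int]], n_series: int) -> np.ndarray:
    X = np.zeros((len(candidates), n_series + 1))
    X[:, 0] = 1.0
    for i, c in enumerate(candidates):
        for j in c:
            X[i, 1 + j] = 1.0
    return X


def doptimal_series_combinations(
    n_series: int,
    n_select: int,
    seed: int = 0,
    n_restarts: int = 5,
) -> list[frozenset[int]]:
    """Select ``n_select`` series combinations maximizing det(X'X).

    Candidate design rows are intercept-plus-series-inclusion indicators
    for every non-empty proper subset of the series.  A Fedorov exchange
    (swap a selected row against an unselected candidate whenever the
    determinant increases) runs from ``n_restarts`` random starts; the
    best selection found is returned, deterministic given the seed.
    """
    candidates = candidate_series_sets(n_series)
    if n_select > len(candidates):
        raise ValueError(f"n_select={n_select} exceeds {len(candidates)} candidates")
    if n_select < n_series + 1:
        raise ValueError("n_select below n_series + 1 makes the design singular")
    X = _design_rows(candidates, n_series)
    rng = np.random.default_rng(seed)
    if n_select == len(candidates):
        return list(candidates)

    def logdet(sel: np.ndarray) -> float:
        M = X[sel].T @ X[sel]
        sign, ld = np.linalg.slogdet(M)
        return ld if sign > 0 else -np.inf

    best_sel, best_val = None, -np.inf
    for _ in range(n_restarts):
        sel = rng.choice(len(candidates), size=n_select, replace=False)
        selected = set(sel.tolist())
        val = logdet(np.fromiter(selected, int))
        improved = True
        while improved:
            improved = False
            for i in sorted(selected):
                for j in range(len(candidates)):
                    if j in selected:
                        continue
                    trial = (selected - {i}) | {j}
                    v = logdet(np.fromiter(trial, int))
                    if v > val + 1e-12:
                        selected, val = trial, v
                        improved = True
                        break
                if improved:
                    break
        if val > best_val:
            best_val, best_sel = val, selected
    return [candidates[i] for i in sorted(best_sel)]


# ---------------------------------------------------------------------------
# Across-series prediction runs
# ---------------------------------------------------------------------------

def across_series_runs(
    training_sets: list[frozenset[int]] | list[set[str]],
    blues: pd.Series,
    series_of: pd.Series,
    kinships: dict[str, KinshipMatrix],
    trait: str = "",
    series_names: list[str] | None = None,
) -> pd.DataFrame:
    """One GBLUP run per (training combination, marker-set variant).

    Training genotypes are all genotypes of the included series (each
    counted once); every series outside the combination serves as a test
    set, with abilities computed separately per test series against the
    across-series adjusted means.  Genotypes whose series label is not a
    plain series (e.g. checks present in several series) are excluded
    from both sides and logged once.
    """
    if series_names is None:
        series_names = sorted({s for s in series_of.unique() if s != "multi"})
    multi = series_of[~series_of.isin(series_names)].index
    if len(multi):
        warnings.warn(
            f"{len(multi)} genotypes in multiple/unknown series excluded from runs"
        )
    usable = [g for g in blues.index if series_of.get(g) in set(series_names)]
    blues = blues.loc[usable]
    series_of = series_of.loc[usable]
    rows = []
    for variant, K in kinships.items():
        in_k = set(K.values.index)
        for combo in training_sets:
            names = {series_names[i] if isinstance(i, (int, np.integer)) else i for i in combo}
            train = [g for g in blues.index if series_of[g] in names and g in in_k]
            if len(train) < 10:
                continue
            test_series = [s for s in series_names if s not in names]
            test_all = [
                g for g in blues.index
                if series_of[g] in set(test_series) and g in in_k
            ]
            if not test_all:
                continue
            fit = fit_gblup(blues.loc[train], K, test_genotypes=test_all)
            pred = fit.predictions(test_all)
            abil = prediction_ability(
                pred, blues.loc[test_all], grouping=series_of.loc[test_all]
            )
            for s, a in abil.items():
                if np.isnan(a):
                    continue
                rows.append(_run_row(s, names, len(train), a, trait, variant, 0))
    return pd.DataFrame(rows, columns=RUN_COLUMNS)


# ---------------------------------------------------------------------------
# Designed training-set scenarios
# ---------------------------------------------------------------------------

def _equal_share_sample(
    ids_by_series: dict[str, list[str]], n: int, rng: np.random.Generator
) -> list[str]:
    """Sample ``n`` genotypes at equal shares per series.

    Shares round down; the remainder tops up the largest series first.
    """
    series = sorted(ids_by_series)
    base = n // len(series)
    take = {s: min(base, len(ids_by_series[s])) for s in series}
    rest = n - sum(take.values())
    for s in sorted(series, key=lambda s: -len(ids_by_series[s])):
        extra = min(rest, len(ids_by_series[s]) - take[s])
        take[s] += extra
        rest -= extra
        if rest == 0:
            break
    out = []
    for s in series:
        pool = ids_by_series[s]
        out.extend(rng.choice(pool, size=take[s], replace=False).tolist())
    return out


def scenario_series_count(
    blues: pd.Series,
    series_of: pd.Series,
    K: KinshipMatrix,
    n_train: int = 800,
    n_test: int = 100,
    reps: int = 25,
    seed: int = 0,
    trait: str = "",
) -> pd.DataFrame:
    """Single-series vs multi-series training at constant size.

    Per replicate a test series is drawn; the paired arms train on
    ``n_train`` genotypes from one random eligible single series vs the
    same number sampled from all series but the test series, and predict
    the same ``n_test`` test genotypes.
    """
    rng = np.random.default_rng(seed)
    series_names = sorted({s for s in series_of.unique() if s != "multi"})
    ids = [g for g in blues.index if series_of.get(g) in set(series_names)]
    by_series = {s: [g for g in ids if series_of[g] == s] for s in series_names}
    rows = []
    for rep in range(reps):
        test_series = series_names[rng.integers(len(series_names))]
        eligible = [
            s for s in series_names
            if s != test_series and len(by_series[s]) >= n_train
        ]
        if not eligible:
            raise ValueError(
                f"no single series with >= {n_train} genotypes outside {test_series}"
            )
        single = eligible[rng.integers(len(eligible))]
        test = rng.choice(by_series[test_series], size=min(n_test, len(by_series[test_series])),
                          replace=False).tolist()
        train_single = rng.choice(by_series[single], size=n_train, replace=False).tolist()
        pool_multi = [g for g in ids if series_of[g] != test_series]
        train_multi = rng.choice(pool_multi, size=n_train, replace=False).tolist()
        for arm, train in (("single", train_single), ("multi", train_multi)):
            a = _ability(blues, K, train, test)
            rows.append({**_run_row(test_series, [arm], n_train, a, trait, "scenario_series", rep),
                         "arm": arm})
    df = pd.DataFrame(rows)
    return df


def scenario_env_groups(
    blues: pd.Series,
    series_of: pd.Series,
    n_envs: pd.Series,
    K: KinshipMatrix,
    groups: tuple[tuple[int, float], ...] = ((1, 3), (4, 5), (6, 9), (10, np.inf)),
    n_train: int = 300,
    n_test: int = 100,
    reps: int = 25,
    seed: int = 0,
    trait: str = "",
) -> pd.DataFrame:
    """Training sets drawn from environment-count groups, plus an
    unrestricted "(all)" control of equal size.

    The test set is sampled at equal series shares and shared by all
    groups within a replicate; under-filled groups are skipped with a
    report.
    """
    rng = np.random.default_rng(seed)
    series_names = sorted({s for s in series_of.unique() if s != "multi"})
    ids = [g for g in blues.index if series_of.get(g) in set(series_names)]
    rows = []
    skipped: set[str] = set()
    for rep in range(reps):
        by_series = {s: [g for g in ids if series_of[g] == s] for s in series_names}
        test = _equal_share_sample(by_series, n_test, rng)
        test_set = set(test)
        pool = [g for g in ids if g not in test_set]
        arms: list[tuple[str, list[str]]] = []
        for lo, hi in groups:
            label = f"{lo}-{int(hi)}" if np.isfinite(hi) else f"{lo}+"
            members = [g for g in pool if lo <= n_envs.get(g, 0) <= hi]
            if len(members) < n_train:
                if label not in skipped:
                    warnings.warn(f"environment group {label}: only {len(members)} "
                                  f"genotypes, group skipped")
                    skipped.add(label)
                continue
            arms.append((label, rng.choice(members, size=n_train, replace=False).tolist()))
        arms.append(("(all)", rng.choice(pool, size=n_train, replace=False).tolist()))
        for label, train in arms:
            a = _ability(blues, K, train, test)
            rows.append({**_run_row("(mixed)", [label], n_train, a, trait,
                                    "scenario_env_groups", rep),
                         "env_group": label})
    return pd.DataFrame(rows)


def scenario_year_windows(
    blues: pd.Series,
    series_of: pd.Series,
    years_of: pd.Series,
    K: KinshipMatrix,
    n_train: int = 600,
    windows: tuple[tuple[int, int], ...] = ((1, 2), (1, 5)),
    n_test: int = 100,
    reps: int = 50,
    seed: int = 0,
    trait: str = "",
) -> pd.DataFrame:
    """Recent vs historical training data at constant training size.

    For each feasible test year, training genotypes are sampled from
    those measured ``a``..``b`` years before it (per window), excluding
    everything measured in the test year; test years whose window holds
    fewer than ``n_train`` genotypes are skipped.
    """
    rng = np.random.default_rng(seed)
    years_of = years_of.loc[[g for g in years_of.index if g in set(blues.index)]]
    all_years = sorted({y for ys in years_of for y in ys})
    rows = []
    for test_year in all_years:
        tested = [g for g in years_of.index if test_year in years_of[g]]
        if len(tested) < n_test:
            continue
        for a, b in windows:
            window_years = set(range(test_year - b, test_year - a + 1))
            eligible = [
                g for g in years_of.index
                if (set(years_of[g]) & window_years) and test_year not in years_of[g]
            ]
            if len(eligible) < n_train:
                warnings.warn(
                    f"test year {test_year}, window {a}-{b}: only {len(eligible)} "
                    "eligible training genotypes, skipped"
                )
                continue
            for rep in range(reps):
                test = rng.choice(tested, size=n_test, replace=False).tolist()
                train = rng.choice(eligible, size=n_train, replace=False).tolist()
                ability = _ability(blues, K, train, test)
                rows.append({**_run_row(str(test_year), [f"{a}-{b}y"], n_train, ability,
                                        trait, "scenario_years", rep),
                             "window": f"{a}-{b}", "test_year": test_year})
    return pd.DataFrame(rows)
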