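"""Empirical training-size curve and deviation decomposition.

The ability of a run with training size x is approximated per test series
by the power curve ``y = alpha * x**(1/beta)`` (alpha, beta > 0; beta > 1
means diminishing returns).  The residuals — run performance corrected
for training-set size — are then decomposed into a grand mean, test-set
main effects, training-series main effects, and test x training
interaction effects, each group shrunk by its own REML-estimated
variance (a deterministic groupwise-ridge fit whose estimating equations
coincide with a Bayesian ridge posterior mode under flat hyperpriors).
A dominant interaction variance identifies specific series pairs that
predict each other unusually well or badly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize as opt

from .lmm import fit_lmm_matrices


@dataclass
class ScalingFit:
    params: pd.DataFrame        # test_series, alpha, beta, sse, n_runs
    residuals: pd.DataFrame     # runs + fitted + residual columns

    def predict(self, test_series: str, x: np.ndarray) -> np.ndarray:
        row = self.params.set_index("test_series").loc[test_series]
        return np.minimum(row["alpha"] * np.asarray(x, float) ** (1.0 / row["beta"]), 1.0)


@dataclass
class DecompositionResult:
    mu: float
    test_effects: pd.Series          # eta
    training_effects: pd.Series      # theta
    interaction_effects: pd.Series   # kappa, indexed "test|training"
    varcomps: dict[str, float]


# ---------------------------------------------------------------------------
# Size curve
# ---------------------------------------------------------------------------

def _fit_one_series(x: np.ndarray, y: np.ndarray, n_starts: int = 10):
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct training sizes per test series")
    ypos = np.clip(y, 1e-6, None)
    slope, inter = np.polyfit(np.log(x), np.log(ypos), 1)
    a0 = float(np.exp(inter))
    b0 = float(1.0 / slope) if slope > 1e-6 else 10.0
    rng = np.random.default_rng(0)
    starts = [(a0, max(b0, 1e-2))]
    starts += [
        (a0 * float(np.exp(rng.normal(0, 0.5))), max(b0, 1e-2) * float(np.exp(rng.normal(0, 0.5))))
        for _ in range(n_starts - 1)
    ]

    def resid(p):
        return p[0] * x ** (1.0 / p[1]) - y

    best = None
    for s in starts:
        try:
            res = opt.least_squares(
                resid, np.array(s), bounds=([1e-10, 1e-6], [np.inf, np.inf]),
                method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"size-curve fit failed from starts {starts[:2]} ...")
    return float(best.x[0]), float(best.x[1]), float(2 * best.cost)


def fit_size_curve(runs: pd.DataFrame, min_runs: int = 4) -> ScalingFit:
    """Per-test-series nonlinear least squares of ability vs training size.

    Requires ``runs`` with columns ``test_series``, ``x_train``,
    ``ability``; series with fewer than ``min_runs`` runs or fewer than 3
    distinct sizes are skipped with a warning.  Returns parameters and
    the per-run residuals for the decomposition.
    """
    params, frames = [], []
    for s, sub in runs.groupby("test_series", sort=True):
        if len(sub) < min_runs or sub["x_train"].nunique() < 3:
            warnings.warn(f"test series {s}: too few runs/sizes for the size curve")
            continue
        x = sub["x_train"].to_numpy(dtype=float)
        y = sub["ability"].to_numpy(dtype=float)
        alpha, beta, sse = _fit_one_series(x, y)
        fitted = alpha * x ** (1.0 / beta)
        out = sub.copy()
        out["fitted"] = fitted
        out["residual"] = y - fitted
        frames.append(out)
        params.append({"test_series": s, "alpha": alpha, "beta": beta,
                       "sse": sse, "n_runs": len(sub)})
    if not params:
        raise ValueError("no test series with enough runs for the size curve")
    return ScalingFit(
        params=pd.DataFrame(params),
        residuals=pd.concat(frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Deviation decomposition
# ---------------------------------------------------------------------------

def decompose_deviations(residuals: pd.DataFrame) -> DecompositionResult:
    """Groupwise-ridge decomposition of size-corrected run deviations.

    ``residuals`` needs columns ``test_series``, ``training_series``
    ("+"-joined series names) and ``residual``.  The model is
    r = mu + eta_test + sum_{j in training} (theta_j + kappa_{test,j}) + e
    with one REML-estimated variance per effect group; singular or empty
    groups come back with variance 0 and a warning.
    """
    df = residuals.reset_index(drop=True)
    r = df["residual"].to_numpy(dtype=float)
    tests = sorted(df["test_series"].astype(str).unique())
    train_lists = [str(t).split("+") for t in df["training_series"]]
    trainings = sorted({s for lst in train_lists for s in lst})
    t_pos = {s: i for i, s in enumerate(tests)}
    j_pos = {s: i for i, s in enumerate(trainings)}
    n = len(df)
    Z_eta = np.zeros((n, len(tests)))
    Z_theta = np.zeros((n, len(trainings)))
    pairs = [f"{i}|{j}" for i in tests for j in trainings]
    p_pos = {p: k for k, p in enumerate(pairs)}
    Z_kappa = np.zeros((n, len(pairs)))
    for row, (ti, lst) in enumerate(zip(df["test_series"].astype(str), train_lists)):
        Z_eta[row, t_pos[ti]] = 1.0
        for j in lst:
            Z_theta[row, j_pos[j]] = 1.0
            Z_kappa[row, p_pos[f"{ti}|{j}"]] = 1.0
    terms = [("eta", Z_eta, tests), ("theta", Z_theta, trainings), ("kappa", Z_kappa, pairs)]
    # drop structurally empty groups
    kept = []
    for name, Z, levels in terms:
        if Z.sum() == 0:
            warnings.warn(f"effect group {name} is empty; variance reported 0")
        else:
            kept.append((name, Z, levels))
    X = np.ones((n, 1))
    fit = fit_lmm_matrices(r, X, kept, fixed_names=["(Intercept)"])
    zeros = {name: pd.Series(0.0, index=levels) for name, _, levels in terms}
    eta = fit.blups.get("eta", zeros["eta"])
    theta = fit.blups.get("theta", zeros["theta"])
    kappa = fit.blups.get("kappa", zeros["kappa"])
    varcomps = {name: fit.varcomps.get(name, 0.0) for name, _, _ in terms}
    varcomps["residual"] = fit.varcomps["residual"]
    return DecompositionResult(
        mu=float(fit.beta.iloc[0]),
        test_effects=eta, training_effects=theta, interaction_effects=kappa,
        varcomps=varcomps,
    )
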