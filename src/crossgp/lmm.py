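"""A deterministic REML engine for linear mixed models with iid random factors.

Models have the form ``y = X beta + sum_k Z_k u_k + e`` with
``u_k ~ N(0, sigma2_k I)`` and ``e ~ N(0, sigma2_e I)``.  The restricted
likelihood is profiled over the residual variance and maximised over the
log variance ratios ``gamma_k = sigma2_k / sigma2_e`` by derivative-free
optimisation; solutions (BLUEs of the fixed effects, BLUPs of the random
effects) are evaluated through the Woodbury identity rather than by
forming the ``n x n`` covariance.  This path is independent of the dense
Henderson mixed-model-equation solver in :func:`solve_mme`, which serves
as a brute-force cross-check.

Fixed factors use first-level-reference coding (sorted levels, first
dropped); reported BLUEs add the intercept back so they live on the trait
scale.  Variance proposals are confined to be non-negative; estimates
hitting the zero boundary are reported in ``LmmFit.boundary``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize as opt
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError

_LOG_GAMMA_MIN, _LOG_GAMMA_MAX = -30.0, 12.0
_BOUNDARY_GAMMA = 1e-8


@dataclass
class LmmSpec:
    """Declarative model: response column, fixed and random factor lists."""

    data: pd.DataFrame
    response: str
    fixed: list[str] = field(default_factory=list)
    random: list[str] = field(default_factory=list)
    tol: float = 1e-10
    max_iter: int = 500

    def __post_init__(self) -> None:
        for c in [self.response, *self.fixed, *self.random]:
            if c not in self.data.columns:
                raise ValueError(f"column {c!r} not in data")


@dataclass
class LmmFit:
    """Converged REML fit."""

    beta: pd.Series                       # named fixed-effect coefficients
    blups: dict[str, pd.Series]           # factor -> level BLUPs
    varcomps: dict[str, float]            # factor -> variance, plus 'residual'
    loglik: float
    n_obs: int
    n_fixed: int
    boundary: list[str] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)
    fixed_levels: dict[str, list[str]] = field(default_factory=dict)

    def blues_for(self, factor: str) -> pd.Series:
        """Fixed-factor level means on the trait scale (intercept added back).

        The first (reference) level's BLUE is the intercept itself.
        """
        mu = self.beta.get("(Intercept)", 0.0)
        levels = self.fixed_levels[factor]
        vals = []
        for lev in levels:
            key = f"{factor}[{lev}]"
            vals.append(mu + self.beta.get(key, 0.0))
        return pd.Series(vals, index=levels, name=factor)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def factor_matrix(labels: pd.Series) -> tuple[sp.csr_matrix, list[str]]:
    """Full indicator matrix for a factor (one column per sorted level)."""
    labels = labels.astype(str)
    levels = sorted(labels.unique())
    pos = {lev: j for j, lev in enumerate(levels)}
    cols = labels.map(pos).to_numpy()
    rows = np.arange(len(labels))
    Z = sp.csr_matrix(
        (np.ones(len(labels)), (rows, cols)), shape=(len(labels), len(levels))
    )
    return Z, levels


def _fixed_design(df: pd.DataFrame, fixed: list[str]):
    n = len(df)
    blocks = [sp.csr_matrix(np.ones((n, 1)))]
    names = ["(Intercept)"]
    levels_of: dict[str, list[str]] = {}
    for f in fixed:
        Z, levels = factor_matrix(df[f])
        levels_of[f] = levels
        blocks.append(Z[:, 1:])  # first-level reference
        names.extend(f"{f}[{lev}]" for lev in levels[1:])
    return sp.hstack(blocks, format="csr"), names, levels_of


def _repair_rank(XtX: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[int]]:
    """Greedy forward selection of independent columns via incremental Cholesky."""
    p = XtX.shape[0]
    keep: list[int] = []
    L = np.zeros((p, p))
    diag = np.diag(XtX).copy()
    tol = 1e-10 * max(diag.max(), 1.0)
    for j in range(p):
        # forward substitution against already-kept columns
        k = len(keep)
        if k:
            c = np.empty(k)
            for t in range(k):
                c[t] = (XtX[j, keep[t]] - L[j, keep[:t]] @ L[keep[t], keep[:t]]) / L[keep[t], keep[t]]
                L[j, keep[t]] = c[t]
            d = XtX[j, j] - c @ c
        else:
            d = XtX[j, j]
        if d > tol:
            L[j, j] = np.sqrt(d)
            keep.append(j)
    return XtX[np.ix_(keep, keep)], keep


# ---------------------------------------------------------------------------
# Core REML machinery
# ---------------------------------------------------------------------------

def _optimize_gammas(ws: "_Workspace", k: int, max_iter: int) -> np.ndarray:
    """Maximise the restricted likelihood over log variance ratios.

    One ratio uses bounded Brent directly; several use cyclic coordinate
    descent with bounded Brent per coordinate, which is robust for the
    near-separable REML surfaces of iid-factor models and avoids the
    very long simplex walks of derivative-free joint search.
    """
    if k == 0:
        return np.empty(0)
    if k == 1:
        res = opt.minimize_scalar(
            lambda lg: ws.neg2_restricted_loglik(np.array([lg])),
            bounds=(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX), method="bounded",
            options={"xatol": 1e-12, "maxiter": max_iter},
        )
        if not res.success:
            raise RuntimeError(f"REML did not converge: {res}")
        return np.array([res.x])
    log_g = np.zeros(k)
    f_prev = ws.neg2_restricted_loglik(log_g)
    if not np.isfinite(f_prev):
        log_g = np.full(k, -2.0)
        f_prev = ws.neg2_restricted_loglik(log_g)
    best_f, best_g = f_prev, log_g.copy()
    trace = [f_prev]
    for _sweep in range(60):
        for j in range(k):
            def f_j(lg, j=j):
                trial = log_g.copy()
                trial[j] = lg
                return ws.neg2_restricted_loglik(trial)

            res = opt.minimize_scalar(
                f_j, bounds=(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX), method="bounded",
                options={"xatol": 1e-11, "maxiter": max_iter},
            )
            log_g[j] = res.x
        f_now = ws.neg2_restricted_loglik(log_g)
        trace.append(f_now)
        if f_now < best_f:
            best_f, best_g = f_now, log_g.copy()
        # flat ridges (boundary / unidentifiable directions) oscillate at
        # round-off level; a relative criterion on -2logL is the right stop
        if abs(f_prev - f_now) < 1e-9 * (1.0 + abs(f_now)):
            break
        f_prev = f_now
    if not np.isfinite(best_f):
        raise RuntimeError(f"REML did not converge; trace={trace[-5:]}")
    return best_g


class _Workspace:
    def __init__(self, y, X, Zs, q_sizes):
        self.y = y
        self.n, self.p = X.shape
        self.X = X
        self.Z = sp.hstack(Zs, format="csr") if Zs else None
        self.q_sizes = q_sizes
        self.XtX = np.asarray((X.T @ X).todense())
        self.Xty = X.T @ y
        if self.Z is not None:
            self.ZtZ = np.asarray((self.Z.T @ self.Z).todense())
            self.ZtX = np.asarray((self.Z.T @ X).todense())
            self.Zty = self.Z.T @ y
        self.yty = float(y @ y)

    def _pieces(self, gammas: np.ndarray):
        """Return (logdet V0, XtV0iX, XtV0iy, ytV0iy) for given ratios."""
        if self.Z is None or len(gammas) == 0:
            return 0.0, self.XtX, self.Xty, self.yty
        dinv = np.concatenate([
            np.full(q, 1.0 / g) for q, g in zip(self.q_sizes, gammas)
        ])
        M = self.ZtZ + np.diag(dinv)
        cf = cho_factor(M, lower=True)
        logdetM = 2.0 * np.log(np.diag(cf[0])).sum()
        logdetV0 = logdetM + float(np.log(gammas) @ np.array(self.q_sizes))
        W = cho_solve(cf, self.ZtX)         # M^-1 Zt X
        wy = cho_solve(cf, self.Zty)
        XtViX = self.XtX - self.ZtX.T @ W
        XtViy = self.Xty - self.ZtX.T @ wy
        ytViy = self.yty - float(self.Zty @ wy)
        return logdetV0, XtViX, XtViy, ytViy, cf

    def neg2_restricted_loglik(self, log_gammas: np.ndarray) -> float:
        gammas = np.exp(np.clip(log_gammas, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX))
        out = self._pieces(gammas)
        logdetV0, XtViX, XtViy = out[0], out[1], out[2]
        ytViy = out[3]
        try:
            cfx = cho_factor(XtViX, lower=True)
        except LinAlgError:
            return np.inf
        logdetX = 2.0 * np.log(np.diag(cfx[0])).sum()
        beta = cho_solve(cfx, XtViy)
        ypy = ytViy - float(XtViy @ beta)
        dof = self.n - self.p
        if dof <= 0:
            return np.inf
        # floor guards the perfect-fit limit (residual variance -> 0)
        s2 = max(ypy / dof, 1e-30 * (1.0 + self.yty / self.n))
        return dof * np.log(s2) + logdetV0 + logdetX + dof

    def solve(self, gammas: np.ndarray):
        """GLS solutions and BLUPs at given variance ratios."""
        out = self._pieces(gammas)
        logdetV0, XtViX, XtViy, ytViy = out[0], out[1], out[2], out[3]
        cfx = cho_factor(XtViX, lower=True)
        beta = cho_solve(cfx, XtViy)
        ypy = ytViy - float(XtViy @ beta)
        dof = max(self.n - self.p, 1)
        s2 = max(ypy / dof, 0.0)
        u = np.empty(0)
        if self.Z is not None and len(gammas):
            cf = out[4]
            # Zt V0^-1 r  with r = y - X beta, via Woodbury
            Ztr = self.Zty - self.ZtX @ beta
            u = np.concatenate([
                np.full(q, g) for q, g in zip(self.q_sizes, gammas)
            ]) * (Ztr - self.ZtZ @ cho_solve(cf, Ztr))
        logdetX = 2.0 * np.log(np.diag(cfx[0])).sum()
        n2ll = (self.n - self.p) * np.log(s2 if s2 > 0 else 1.0) + logdetV0 + logdetX + (
            (ypy / s2) if s2 > 0 else 0.0
        )
        return beta, u, s2, -0.5 * n2ll


def fit_lmm_reml(spec: LmmSpec) -> LmmFit:
    """REML fit of ``spec``; deterministic given input order.

    Raises a convergence error (with the optimizer trace attached) if the
    restricted likelihood cannot be maximised within ``spec.max_iter``
    evaluations per restart.
    """
    df = spec.data.reset_index(drop=True)
    y = df[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    X, names, fixed_levels = _fixed_design(df, spec.fixed)
    XtX = np.asarray((X.T @ X).todense())
    dropped: list[str] = []
    try:
        cholesky(XtX + 0.0, lower=True)
        keep_idx = list(range(X.shape[1]))
    except LinAlgError:
        _, keep_idx = _repair_rank(XtX, names)
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep_idx]
        X = X[:, keep_idx]
        names = [names[j] for j in keep_idx]
    Zs, q_sizes, rand_levels = [], [], {}
    for f in spec.random:
        Z, levels = factor_matrix(df[f])
        Zs.append(Z)
        q_sizes.append(len(levels))
        rand_levels[f] = levels
    ws = _Workspace(y, X, Zs, q_sizes)
    k = len(Zs)
    if k == 0:
        beta, u, s2, ll = ws.solve(np.empty(0))
        return _package(spec, names, fixed_levels, rand_levels, beta, u, s2, [], ll, dropped, ws)
    log_g = _optimize_gammas(ws, k, spec.max_iter)
    gammas = np.exp(np.clip(log_g, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX))
    boundary = [f for f, g in zip(spec.random, gammas) if g < _BOUNDARY_GAMMA]
    gammas = np.where(gammas < _BOUNDARY_GAMMA, 0.0, gammas)
    # re-solve with exact zeros dropped to avoid ill-conditioning
    active = gammas > 0
    ws_act = _Workspace(
        y, X, [Z for Z, a in zip(Zs, active) if a],
        [q for q, a in zip(q_sizes, active) if a],
    )
    beta, u_act, s2, ll = ws_act.solve(gammas[active])
    u = np.zeros(sum(q_sizes))
    offs = np.cumsum([0, *q_sizes])
    act_pos = 0
    for i, a in enumerate(active):
        if a:
            qa = q_sizes[i]
            u[offs[i]:offs[i] + qa] = u_act[act_pos:act_pos + qa]
            act_pos += qa
    return _package(
        spec, names, fixed_levels, rand_levels, beta, u, s2,
        list(zip(spec.random, gammas, q_sizes)), ll, dropped, ws, boundary,
    )


def _package(spec, names, fixed_levels, rand_levels, beta, u, s2, gamma_info,
             ll, dropped, ws, boundary=()):
    varcomps = {"residual": float(s2)}
    blups: dict[str, pd.Series] = {}
    off = 0
    for f, g, q in gamma_info:
        varcomps[f] = float(g * s2)
        blups[f] = pd.Series(u[off:off + q], index=rand_levels[f], name=f)
        off += q
    return LmmFit(
        beta=pd.Series(beta, index=names),
        blups=blups,
        varcomps=varcomps,
        loglik=float(ll),
        n_obs=ws.n,
        n_fixed=ws.p,
        boundary=list(boundary),
        dropped_columns=dropped,
        fixed_levels=fixed_levels,
    )


def fit_lmm_matrices(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[tuple[str, np.ndarray, list[str]]],
    fixed_names: list[str] | None = None,
    max_iter: int = 500,
) -> LmmFit:
    """REML fit with explicit design matrices.

    ``terms`` is a list of (name, Z, level names); each term carries one
    variance.  Z need not be an indicator matrix (rows may select several
    levels at once), which factor-column models cannot express.  Shares
    the optimizer and solution path with :func:`fit_lmm_reml`.
    """
    y = np.asarray(y, dtype=float)
    X = sp.csr_matrix(np.atleast_2d(np.asarray(X, dtype=float)))
    fixed_names = fixed_names or [f"x{j}" for j in range(X.shape[1])]
    Zs = [sp.csr_matrix(np.asarray(Z, dtype=float)) for _, Z, _ in terms]
    q_sizes = [Z.shape[1] for Z in Zs]
    ws = _Workspace(y, X, Zs, q_sizes)
    k = len(Zs)
    if k == 0:
        beta, u, s2, ll = ws.solve(np.empty(0))
        log_g = np.empty(0)
    else:
        log_g = _optimize_gammas(ws, k, max_iter)
    gammas = np.exp(np.clip(log_g, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX)) if k else np.empty(0)
    boundary = [t[0] for t, g in zip(terms, gammas) if g < _BOUNDARY_GAMMA]
    gammas = np.where(gammas < _BOUNDARY_GAMMA, 0.0, gammas) if k else gammas
    active = gammas > 0
    ws_act = _Workspace(
        y, X, [Z for Z, a in zip(Zs, active) if a],
        [q for q, a in zip(q_sizes, active) if a],
    )
    beta, u_act, s2, ll = ws_act.solve(gammas[active])
    u = np.zeros(sum(q_sizes))
    offs = np.cumsum([0, *q_sizes])
    pos = 0
    for i, a in enumerate(active):
        if a:
            u[offs[i]:offs[i] + q_sizes[i]] = u_act[pos:pos + q_sizes[i]]
            pos += q_sizes[i]
    varcomps = {"residual": float(s2)}
    blups = {}
    off = 0
    for (name, _, levels), g, q in zip(terms, gammas, q_sizes):
        varcomps[name] = float(g * s2)
        blups[name] = pd.Series(u[off:off + q], index=levels, name=name)
        off += q
    return LmmFit(
        beta=pd.Series(beta, index=fixed_names), blups=blups, varcomps=varcomps,
        loglik=float(ll), n_obs=ws.n, n_fixed=ws.p, boundary=boundary,
    )


# ---------------------------------------------------------------------------
# Dense Henderson mixed-model-equation solver (independent cross-check)
# ---------------------------------------------------------------------------

def solve_mme(
    X: np.ndarray, Zs: list[np.ndarray], y: np.ndarray,
    sigma2s: list[float], sigma2_e: float,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Direct dense solve of Henderson's mixed-model equations.

    ``C [beta; u] = rhs`` with ``C`` the usual blocked coefficient matrix
    and ridge ``sigma2_e / sigma2_k`` on each random block.  Intended as a
    brute-force oracle for :func:`fit_lmm_reml` at the same variances.
    """
    X = np.asarray(X, dtype=float)
    Zs = [np.asarray(Z, dtype=float) for Z in Zs]
    W = np.hstack([X, *Zs]) if Zs else X
    C = W.T @ W
    off = X.shape[1]
    for Z, s2 in zip(Zs, sigma2s):
        q = Z.shape[1]
        C[off:off + q, off:off + q] += np.eye(q) * (sigma2_e / s2)
        off += q
    sol = np.linalg.solve(C, W.T @ y)
    beta = sol[: X.shape[1]]
    us, off = [], X.shape[1]
    for Z in Zs:
        q = Z.shape[1]
        us.append(sol[off:off + q])
        off += q
    return beta, us
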