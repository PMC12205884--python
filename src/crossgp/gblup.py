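"""Genomic BLUP with a deterministic REML backend.

The model is ``y_i = mu + g_i + e_i`` with ``Cov(g) = K sigma2_g`` for a
marker-derived kinship K.  After eigendecomposing the training submatrix
of K (plus a small diagonal jitter for numerical positive
semi-definiteness), the restricted likelihood is profiled down to a 1-D
search over the variance ratio in the rotated basis, which makes the fit
deterministic and fast.  Unobserved genotypes are predicted by the
conditional expectation
``K_test,train (K_train sigma2_g + sigma2_e I)^-1 sigma2_g (y - mu)``.

Prediction ability is the Pearson correlation between predicted genetic
values and the observed adjusted means of a test set, computed per group
(typically per test series).  Its theoretical ceiling is the square root
of the trait's entry-mean heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize as opt

from .popgen import KinshipMatrix

_JITTER = 1e-8


@dataclass
class GblupFit:
    mu: float
    var_g: float
    var_e: float
    blups: pd.Series               # genetic values for training and test genotypes
    training: list[str]
    loglik: float

    def predictions(self, ids: list[str]) -> pd.Series:
        return self.mu + self.blups.loc[ids]


def fit_gblup(
    y: pd.Series,
    K: KinshipMatrix,
    test_genotypes: list[str] | None = None,
    min_training: int = 10,
) -> GblupFit:
    """REML GBLUP fit on training means ``y``; predicts ``test_genotypes``.

    ``y`` is indexed by training genotype ids, all of which must appear in
    K.  A variance ratio estimated at the zero boundary yields constant
    predictions and triggers a warning.
    """
    train = list(y.index)
    missing = [g for g in train if g not in K.values.index]
    if missing:
        raise KeyError(f"training genotypes absent from kinship: {missing[:5]} ...")
    if len(train) < min_training:
        raise ValueError(f"need >= {min_training} training genotypes, got {len(train)}")
    Ktt = K.submatrix(train)
    n = len(train)
    jitter = _JITTER * np.trace(Ktt) / n
    eigval, U = np.linalg.eigh(Ktt + jitter * np.eye(n))
    eigval = np.maximum(eigval, 0.0)
    yv = y.to_numpy(dtype=float)
    yt = U.T @ yv
    xt = U.T @ np.ones(n)

    def neg2ll(log_gamma: float) -> float:
        g = np.exp(log_gamma)
        d = g * eigval + 1.0
        xx = float(np.sum(xt * xt / d))
        mu = float(np.sum(xt * yt / d)) / xx
        r = yt - mu * xt
        ypy = float(np.sum(r * r / d))
        if ypy <= 0:
            return np.inf
        s2 = ypy / (n - 1)
        return (n - 1) * np.log(s2) + float(np.log(d).sum()) + np.log(xx) + (n - 1)

    res = opt.minimize_scalar(
        neg2ll, bounds=(-25.0, 12.0), method="bounded",
        options={"xatol": 1e-12, "maxiter": 500},
    )
    if not res.success:
        raise RuntimeError(f"GBLUP REML did not converge: {res}")
    gamma = float(np.exp(res.x))
    d = gamma * eigval + 1.0
    xx = float(np.sum(xt * xt / d))
    mu = float(np.sum(xt * yt / d)) / xx
    r = yt - mu * xt
    var_e = float(np.sum(r * r / d)) / (n - 1)
    var_g = gamma * var_e
    if gamma < 1e-7:
        warnings.warn("genetic variance estimated at the zero boundary; predictions constant")
    # training BLUPs: U diag(gamma*s/d) U' (y - mu)
    w = U.T @ (yv - mu)
    g_train = U @ (gamma * eigval / d * w)
    blups = pd.Series(g_train, index=train)
    if test_genotypes:
        extra = [g for g in test_genotypes if g not in y.index]
        if extra:
            Kxt = K.cross(extra, train)
            g_test = Kxt @ (U @ (gamma / d * w))
            blups = pd.concat([blups, pd.Series(g_test, index=extra)])
    return GblupFit(
        mu=mu, var_g=var_g, var_e=var_e, blups=blups, training=train,
        loglik=-0.5 * float(res.fun),
    )


def prediction_ability(
    predicted: pd.Series,
    observed: pd.Series,
    grouping: pd.Series | None = None,
    min_group: int = 3,
) -> pd.Series:
    """Pearson correlation of predicted vs observed means, per group.

    Groups smaller than ``min_group`` or with zero variance in either
    vector come out as nan (undefined) with a warning.
    """
    common = predicted.index.intersection(observed.index)
    pred, obs = predicted.loc[common], observed.loc[common]
    if grouping is None:
        grouping = pd.Series("all", index=common)
    else:
        grouping = grouping.loc[common]
    out = {}
    for grp, ids in grouping.groupby(grouping).groups.items():
        p, o = pred.loc[ids], obs.loc[ids]
        if len(ids) < min_group:
            warnings.warn(f"group {grp!r}: fewer than {min_group} genotypes, ability undefined")
            out[grp] = np.nan
        elif p.std() == 0 or o.std() == 0:
            warnings.warn(f"group {grp!r}: zero variance, ability undefined")
            out[grp] = np.nan
        else:
            out[grp] = float(np.corrcoef(p, o)[0, 1])
    return pd.Series(out, name="ability")
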