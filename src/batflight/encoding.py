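"""Per-unit Poisson encoding models on per-wingbeat kinematic features.

Spike counts per wingbeat cycle are regressed on the mean value of each
kinematic feature during that cycle (17 features by default, z-scored per
path).  Feature selection uses a Poisson elastic-net path (mixing 0.5) with
the penalty chosen by 5-fold cross-validated deviance and a 1-SE rule; the
selected features are then refit without penalty and scored by a
cross-validated deviance pseudo-R^2:

    cv_pseudo_R2 = 1 - D_cv(model) / D_cv(intercept only)

The participation ratio of the squared fitted weights, normalized by the
number of selected features, measures how distributed the unit's tuning is
across features (1 = maximally mixed selectivity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import participation_ratio
from .synthetic import FEATURE_NAMES

log = logging.getLogger(__name__)


@dataclass
class GlmFit:
    unit_id: int
    selected: list[str]
    coef: np.ndarray                 # over the full feature registry
    intercept: float
    cv_pseudo_r2: float
    weight_pr_normalized: float
    notes: list[str] = field(default_factory=list)


def build_feature_matrix(table: pd.DataFrame, kin_means: pd.DataFrame,
                         envelope_means: pd.DataFrame | None = None,
                         feature_names: list[str] | None = None):
    """Assemble and z-score the per-cycle feature matrix.

    ``kin_means`` holds per-wingbeat means of derived kinematics (indexed by
    wingbeat_id); ``envelope_means`` the envelope/asymmetry features.
    Missing envelope columns are dropped with a logged count.  Returns
    (X as DataFrame indexed by wingbeat_id, names actually used).
    """
    names = list(feature_names or FEATURE_NAMES)
    df = table[["wingbeat_id", "period_ms"]].merge(
        kin_means, on="wingbeat_id", how="left")
    if envelope_means is not None:
        df = df.merge(envelope_means, on="wingbeat_id", how="left")
    missing = [n for n in names if n not in df.columns]
    if missing:
        log.info("dropping %d unavailable features: %s", len(missing),
                 missing)
        names = [n for n in names if n not in missing]
    X = df.set_index("wingbeat_id")[names].astype(float)
    X = X.fillna(X.mean())
    mu, sd = X.mean(), X.std(ddof=0).replace(0, 1.0)
    return (X - mu) / sd, names


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """2 * sum[ y*log(y/mu) - (y - mu) ], with y log y -> 0 at y = 0."""
    y = np.asarray(y, float)
    mu = np.clip(np.asarray(mu, float), 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _kfold_indices(n, k, rng):
    idx = rng.permutation(n)
    return np.array_split(idx, k)


def _fit_elastic_net(y, X, alpha, l1_wt):
    Xd = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, Xd, family=sm.families.Poisson())
    # no penalty on the intercept
    pen = np.ones(Xd.shape[1]) * alpha
    pen[0] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_regularized(method="elastic_net", alpha=pen,
                                    L1_wt=l1_wt, maxiter=200)
    return np.asarray(res.params)


def select_features_elastic_net(counts: np.ndarray, X: np.ndarray,
                                feature_names: list[str], k_folds: int = 5,
                                l1_wt: float = 0.5,
                                n_alphas: int = 12, seed: int = 0):
    """Poisson elastic-net path with CV deviance and the 1-SE rule.

    Returns (selected names, alpha chosen).  All-zero counts yield an empty
    selection (fit skipped, logged).
    """
    y = np.asarray(counts, float)
    if y.sum() == 0:
        log.info("all-zero counts: selection skipped")
        return [], np.nan
    n = len(y)
    if n < 10 * k_folds:
        raise ValueError("need >= 10 cycles per fold")
    # alpha grid: from near-max (all zero) downward
    ybar = y.mean()
    grad0 = np.abs(X.T @ (y - ybar)) / n
    a_max = grad0.max() / max(l1_wt, 1e-3) * 1.1
    alphas = a_max * np.logspace(0, -3, n_alphas)
    rng = np.random.default_rng(seed)
    folds = _kfold_indices(n, k_folds, rng)
    dev = np.zeros((n_alphas, k_folds))
    for kf in range(k_folds):
        te = folds[kf]
        tr = np.concatenate([folds[j] for j in range(k_folds) if j != kf])
        # KKT bound: above this alpha the solution is intercept-only, so
        # its CV deviance is the null deviance (no fit needed)
        ybar_tr = y[tr].mean()
        a_null = np.abs(X[tr].T @ (y[tr] - ybar_tr)).max() / len(tr) \
            / max(l1_wt, 1e-3)
        dev_null = poisson_deviance(
            y[te], np.full(len(te), max(ybar_tr, 1e-12))) / len(te)
        for ai, alpha in enumerate(alphas):
            if alpha >= a_null:
                dev[ai, kf] = dev_null
                continue
            params = _fit_elastic_net(y[tr], X[tr], alpha, l1_wt)
            mu = np.exp(params[0] + X[te] @ params[1:])
            dev[ai, kf] = poisson_deviance(y[te], mu) / len(te)
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(k_folds)
    best = int(np.argmin(mean_dev))
    # 1-SE rule: alphas run large -> small, so the first acceptable index
    # is the sparsest model within one SE of the minimum CV deviance
    ok = mean_dev <= mean_dev[best] + se_dev[best]
    chosen = int(np.flatnonzero(ok)[0])
    params = _fit_elastic_net(y, X, alphas[chosen], l1_wt)
    sel = np.flatnonzero(np.abs(params[1:]) > 1e-8)
    return [feature_names[i] for i in sel], float(alphas[chosen])


def fit_poisson_glm_cv(counts: np.ndarray, X: np.ndarray,
                       feature_names: list[str], selected: list[str],
                       k_folds: int = 5, seed: int = 0,
                       unit_id: int = -1) -> GlmFit:
    """Unpenalized Poisson refit on the selected features + CV pseudo-R^2."""
    y = np.asarray(counts, float)
    names = list(feature_names)
    sel_idx = [names.index(s) for s in selected]
    coef = np.zeros(len(names))
    notes: list[str] = []
    if not selected:
        raise ValueError("selected set is empty")
    Xs = X[:, sel_idx]
    rng = np.random.default_rng(seed)
    folds = _kfold_indices(len(y), k_folds, rng)
    dev_model = 0.0
    dev_null = 0.0
    for kf in range(k_folds):
        te = folds[kf]
        tr = np.concatenate([folds[j] for j in range(k_folds) if j != kf])
        params = _fit_unpenalized(y[tr], Xs[tr], notes)
        mu = np.exp(np.clip(params[0] + Xs[te] @ params[1:], -30, 30))
        dev_model += poisson_deviance(y[te], mu)
        mu0 = np.full(len(te), max(y[tr].mean(), 1e-12))
        dev_null += poisson_deviance(y[te], mu0)
    params = _fit_unpenalized(y, Xs, notes)
    coef[sel_idx] = params[1:]
    r2 = 1.0 - dev_model / dev_null if dev_null > 0 else np.nan
    w2 = params[1:] ** 2
    pr_norm = participation_ratio(w2) / len(sel_idx) if np.any(w2 > 0) else np.nan
    return GlmFit(unit_id=unit_id, selected=list(selected), coef=coef,
                  intercept=float(params[0]), cv_pseudo_r2=float(r2),
                  weight_pr_normalized=float(pr_norm), notes=notes)


def _fit_unpenalized(y, Xs, notes):
    Xd = sm.add_constant(Xs, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, Xd, family=sm.families.Poisson()).fit(maxiter=100)
            if not res.converged:
                raise RuntimeError("no convergence")
            return np.asarray(res.params)
        except Exception:
            notes.append("ridge fallback after non-convergence")
            log.warning("Poisson IRLS failed; falling back to small ridge")
            res = sm.GLM(y, Xd, family=sm.families.Poisson()).fit_regularized(
                method="elastic_net", alpha=1e-4, L1_wt=0.0)
            return np.asarray(res.params)


def weight_participation_ratio(coefficients: np.ndarray) -> float:
    """Normalized PR of a weight vector: PR(w^2) / #nonzero, in (0, 1]."""
    w = np.asarray(coefficients, float)
    nz = w[w != 0]
    if len(nz) == 0:
        raise ValueError("all-zero weight vector")
    return participation_ratio(nz ** 2) / len(nz)


def fit_population(counts_by_unit: dict[int, np.ndarray], X: pd.DataFrame,
                   feature_names: list[str], k_folds: int = 5,
                   n_alphas: int = 12, seed: int = 0) -> list[GlmFit]:
    """Select + fit every unit; all-zero units are skipped (logged)."""
    Xa = X.to_numpy(float)
    fits = []
    for uid, y in sorted(counts_by_unit.items()):
        sel, _ = select_features_elastic_net(y, Xa, feature_names,
                                             k_folds=k_folds,
                                             n_alphas=n_alphas, seed=seed)
        if not sel:
            log.info("unit %d: empty selection, skipped", uid)
            continue
        fits.append(fit_poisson_glm_cv(y, Xa, feature_names, sel,
                                       k_folds=k_folds, seed=seed,
                                       unit_id=uid))
    return fits
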