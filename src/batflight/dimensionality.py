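"""Population dimensionality: PCA spectra, demixed PCA, GPFA.

Three complementary views of how many dimensions the population explores
across wingbeats:

* **PCA** on the group-mean matrix (units x concatenated group time bins):
  eigenvalue spectrum, n90 (PCs to 90% cumulative explained variance) and
  participation ratios of the "core" subspace (PCs carrying the first 50%
  of variance) and the "extended" subspace (all remaining PCs), each
  normalized by its maximal possible value.
* **dPCA** splits the trial-averaged tensor into a condition-invariant
  (time-only) marginalization and condition-specific (group, group x time)
  marginalizations, fits regularized reduced-rank components per
  marginalization (ridge chosen by cross-validation on held-out trials) and
  reports the explained-variance split and the specific/invariant ratio.
* **GPFA** models binned activity as shared latent factors with independent
  squared-exponential Gaussian-process priors (one learnable timescale per
  factor) plus private noise, fit by EM; shared dimensionality is selected
  by leave-one-neuron-out (LONO) prediction error with a 1% threshold
  relative to the minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import participation_ratio, smooth_series

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# group-mean matrix
# --------------------------------------------------------------------------

def build_group_mean_matrix(spikes: dict[int, np.ndarray],
                            table: pd.DataFrame,
                            n_phase_bins: int = 12,
                            min_trials: int = 4,
                            reliability_threshold: float = 0.3):
    """Trial-averaged, cycle-warped rate matrix (units x groups*bins).

    Each wingbeat cycle is warped onto ``n_phase_bins`` equal phase bins;
    rates are averaged across the cycles of each group, groups concatenated.
    Groups with fewer than ``min_trials`` cycles are dropped (logged), and
    units whose odd/even split-half correlation across the concatenated
    trace falls below ``reliability_threshold`` are removed.

    Returns (matrix, unit_ids, group_ids).
    """
    gcol = "group" if "group" in table.columns else "ordinal"
    counts = table.groupby(gcol).size()
    groups = [g for g in counts.index if counts[g] >= min_trials]
    dropped = len(counts) - len(groups)
    if dropped:
        log.info("dropped %d groups below %d trials", dropped, min_trials)
    unit_ids = sorted(spikes)
    G, B = len(groups), n_phase_bins
    full = np.zeros((len(unit_ids), G * B))
    odd = np.zeros_like(full)
    even = np.zeros_like(full)
    for gi, g in enumerate(groups):
        sub = table[table[gcol] == g]
        per_cycle = np.zeros((len(sub), len(unit_ids), B))
        for ci, wb in enumerate(sub.itertuples()):
            edges = np.linspace(wb.onset, wb.offset, B + 1)
            bw = (wb.offset - wb.onset) / B
            for ui, uid in enumerate(unit_ids):
                c, _ = np.histogram(spikes[uid], bins=edges)
                per_cycle[ci, ui] = c / bw
        sl = slice(gi * B, (gi + 1) * B)
        full[:, sl] = per_cycle.mean(axis=0)
        odd[:, sl] = per_cycle[1::2].mean(axis=0) if len(sub) > 1 else 0
        even[:, sl] = per_cycle[0::2].mean(axis=0)
    full = smooth_series(full, 1.0, 1.0, axis=1)  # 1-bin Gaussian smoothing
    keep = []
    for ui in range(len(unit_ids)):
        a, b = odd[ui], even[ui]
        if a.std() == 0 or b.std() == 0:
            continue
        if np.corrcoef(a, b)[0, 1] >= reliability_threshold:
            keep.append(ui)
    if len(keep) < len(unit_ids):
        log.info("reliability filter removed %d units",
                 len(unit_ids) - len(keep))
    return full[keep], [unit_ids[i] for i in keep], groups


# --------------------------------------------------------------------------
# PCA dimensionality
# --------------------------------------------------------------------------

@dataclass
class DimReport:
    spectrum: np.ndarray
    cumulative_ev: np.ndarray
    n90: int
    n90_fraction: float
    pr_core: float = np.nan
    pr_extended: float = np.nan
    dpca: dict = field(default_factory=dict)
    gpfa: dict = field(default_factory=dict)


def pca_dimensionality(matrix: np.ndarray) -> DimReport:
    """Eigen-spectrum of the unit covariance, n90 and normalized n90.

    Rows (units) are centered; the spectrum is padded with zeros to the
    number of units when rank-deficient.
    """
    X = matrix - matrix.mean(axis=1, keepdims=True)
    n_units = X.shape[0]
    s = np.linalg.svd(X, compute_uv=False)
    lam = s ** 2 / max(X.shape[1] - 1, 1)
    spectrum = np.zeros(n_units)
    spectrum[: min(len(lam), n_units)] = lam[:n_units]
    total = spectrum.sum()
    if total == 0:
        raise ValueError("zero-variance matrix")
    cum = np.cumsum(spectrum) / total
    n90 = int(np.searchsorted(cum, 0.9 - 1e-12) + 1)
    return DimReport(spectrum=spectrum, cumulative_ev=cum, n90=n90,
                     n90_fraction=n90 / n_units)


def participation_ratio_split(spectrum: np.ndarray,
                              core_fraction: float = 0.5):
    """Max-normalized PR of the core and extended eigenvalue subsets.

    Core = the leading PCs that capture the first ``core_fraction`` of the
    variance; extended = all remaining components.  Each PR is divided by
    its subset size, so 1 means variance spread uniformly over the subset.
    """
    lam = np.asarray(spectrum, float)
    cum = np.cumsum(lam) / lam.sum()
    k = int(np.searchsorted(cum, core_fraction - 1e-12) + 1)
    core = lam[:k]
    ext = lam[k:]
    pr_core = participation_ratio(core) / len(core)
    if len(ext) == 0 or ext.sum() == 0:
        log.warning("empty extended subspace")
        return float(pr_core), np.nan
    return float(pr_core), float(participation_ratio(ext) / len(ext))


# --------------------------------------------------------------------------
# demixed PCA
# --------------------------------------------------------------------------

def marginalize(X: np.ndarray):
    """Split a centered (units, groups, time) tensor into marginalizations.

    Returns dict with 'time' (group-invariant), 'group' (time-averaged
    group effect) and 'group_time' (interaction); the three sum to X
    exactly (reconstruction identity on the mean tensor).
    """
    m_time = X.mean(axis=1, keepdims=True) * np.ones_like(X)
    resid = X - m_time
    m_group = resid.mean(axis=2, keepdims=True) * np.ones_like(X)
    m_gt = resid - m_group
    return dict(time=m_time, group=m_group, group_time=m_gt)


def _rr_ridge(Phi: np.ndarray, Xf: np.ndarray, lam: float, rank: int):
    """Reduced-rank ridge regression Phi ~ A Xf; returns (F, D)."""
    N = Xf.shape[0]
    mu = np.trace(Xf @ Xf.T) / N
    A = Phi @ Xf.T @ np.linalg.inv(Xf @ Xf.T + lam * mu * np.eye(N))
    U, s, Vt = np.linalg.svd(A @ Xf, full_matrices=False)
    r = min(rank, np.sum(s > 1e-12))
    F = U[:, :r]
    D = F.T @ A
    return F, D


def dpca_decompose(trials: np.ndarray, lambda_grid=None,
                   n_components: int = 10) -> dict:
    """Demixed PCA of trial data (n_trials, units, groups, time).

    Marginalizes the trial average into time-only (condition-invariant)
    and group / group x time (condition-specific) parts, fits reduced-rank
    ridge components per marginalization, and reports the EV split.  The
    ridge is selected by cross-validation on held-out trials; with a single
    trial an analytic heuristic (lambda = 1e-6) is used with a warning.
    """
    trials = np.asarray(trials, float)
    n_trials, N, G, T = trials.shape
    if G < 2:
        raise ValueError("need >= 2 groups")
    if lambda_grid is None:
        lambda_grid = [0.0, 1e-6, 1e-4, 1e-3, 1e-2, 1e-1]

    def centered(avg):
        return avg - avg.mean(axis=(1, 2), keepdims=True)

    X = centered(trials.mean(axis=0))
    Xf = X.reshape(N, G * T)
    total = np.sum(Xf ** 2)

    def grouped(avg):
        """Condition-invariant (time) vs condition-specific (group +
        group x time) marginalizations, flattened."""
        m = marginalize(centered(avg))
        return dict(time=m["time"].reshape(N, G * T),
                    group_specific=(m["group"]
                                    + m["group_time"]).reshape(N, G * T))

    if n_trials >= 2:
        half = n_trials // 2
        Xa = centered(trials[:half].mean(axis=0)).reshape(N, G * T)
        Xb = centered(trials[half:].mean(axis=0)).reshape(N, G * T)
        margs_a = grouped(trials[:half].mean(0))
        margs_b = grouped(trials[half:].mean(0))
        errs = []
        for lam in lambda_grid:
            err = 0.0
            for key in margs_a:
                F, D = _rr_ridge(margs_a[key], Xa, lam, n_components)
                err += np.sum((margs_b[key] - F @ (D @ Xb)) ** 2)
            errs.append(err)
        lam = float(lambda_grid[int(np.argmin(errs))])
    else:
        log.warning("single trial: ridge CV degenerate, using heuristic")
        lam = 1e-6

    margs = grouped(trials.mean(axis=0))
    ev = {}
    comps = {}
    for key, Phi in margs.items():
        rank = min(n_components, np.linalg.matrix_rank(Phi))
        if rank == 0:
            ev[key] = 0.0
            comps[key] = (np.zeros((N, 0)), np.zeros((0, N)))
            continue
        F, D = _rr_ridge(Phi, Xf, lam, rank)
        resid = Phi - F @ (D @ Xf)
        ev[key] = float((np.sum(Phi ** 2) - np.sum(resid ** 2)) / total * 100)
        comps[key] = (F, D)
    specific = ev["group_specific"]
    invariant = ev["time"]
    ratio = specific / invariant if invariant > 0 else np.inf
    # first demixed component traces per marginalization
    dpc1 = {}
    for key, (F, D) in comps.items():
        if F.shape[1]:
            dpc1[key] = (D[0] @ Xf).reshape(G, T)
    sub_norms = {k: float(np.sum(v ** 2))
                 for k, v in marginalize(X).items()}
    return dict(ev=ev, ev_specific=specific, ev_invariant=invariant,
                specific_invariant_ratio=float(ratio), ridge_lambda=lam,
                components=comps, dpc1=dpc1,
                marginalization_norms=sub_norms)


# --------------------------------------------------------------------------
# GPFA
# --------------------------------------------------------------------------

@dataclass
class GpfaModel:
    C: np.ndarray          # (N, q) loadings
    d: np.ndarray          # (N,) offsets
    R: np.ndarray          # (N,) private noise variances
    taus: np.ndarray       # (q,) SE timescales, in bin units of `bin_ms`
    bin_ms: float
    n_bins: int
    log_likelihoods: list = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.C.shape[1]


def _se_kernel(T: int, tau_bins: float, jitter: float = 1e-6) -> np.ndarray:
    t = np.arange(T)
    K = np.exp(-0.5 * ((t[:, None] - t[None, :]) / max(tau_bins, 1e-3)) ** 2)
    return K + jitter * np.eye(T)


def _posterior(K_invs, logdet_Ks, C, R, T):
    """Shared posterior precision pieces for one parameter setting.

    Returns (Sigma, chol_P, logdet_P) for the stacked latent vector with
    factor-major indexing (factor q occupies rows q*T..q*T+T).
    """
    q = C.shape[1]
    G = (C / R[:, None]).T @ C           # q x q
    P = np.zeros((q * T, q * T))
    for a in range(q):
        P[a * T:(a + 1) * T, a * T:(a + 1) * T] = K_invs[a]
        for b in range(q):
            idx = np.arange(T)
            P[a * T + idx, b * T + idx] += G[a, b]
    L = np.linalg.cholesky(P)
    logdet_P = 2 * np.sum(np.log(np.diag(L)))
    Sigma = np.linalg.inv(P)
    return Sigma, L, logdet_P


def _posterior_means(Y, C, d, R, Sigma):
    """E[x] for each trial; Y is (n_trials, N, T)."""
    n_trials, N, T = Y.shape
    q = C.shape[1]
    H = np.einsum("nq,mnt->mqt", C / R[:, None], Y - d[:, None])
    h = H.reshape(n_trials, q * T)
    return h @ Sigma.T


def gpfa_fit(Y: np.ndarray, n_factors: int, bin_ms: float = 20.0,
             n_iter: int = 40, tau_init_ms: float = 100.0,
             update_tau_every: int = 2, seed: int = 0,
             tol: float = 1e-6) -> GpfaModel:
    """EM fit of the GPFA model to trials (n_trials, units, bins).

    The observation model is linear-Gaussian with diagonal private noise;
    each factor has an independent squared-exponential GP prior over time
    whose timescale is optimized in the M-step.  Raises if the marginal
    log-likelihood decreases beyond numerical tolerance.
    """
    Y = np.asarray(Y, float)
    n_trials, N, T = Y.shape
    q = n_factors
    rng = np.random.default_rng(seed)
    d = Y.mean(axis=(0, 2))
    Yc = (Y - d[:, None]).transpose(0, 2, 1).reshape(-1, N)
    # initialize loadings from PCA of the pooled data
    U, s, _ = np.linalg.svd(Yc - Yc.mean(0), full_matrices=False)
    C = (Yc - Yc.mean(0)).T @ U[:, :q] / np.sqrt(len(Yc))
    if C.shape[1] < q:
        C = np.column_stack([C, rng.normal(0, 1e-3,
                                           (N, q - C.shape[1]))])
    resid_var = Yc.var(axis=0) - np.sum(C ** 2, axis=1)
    R = np.clip(resid_var, 1e-4 * max(Yc.var(), 1e-8), None)
    taus = np.full(q, tau_init_ms / bin_ms)

    lls = []
    for it in range(n_iter):
        Ks = [_se_kernel(T, taus[a]) for a in range(q)]
        chols = [np.linalg.cholesky(K) for K in Ks]
        K_invs = [np.linalg.inv(K) for K in Ks]
        logdet_Ks = [2 * np.sum(np.log(np.diag(L))) for L in chols]
        Sigma, _, logdet_P = _posterior(K_invs, logdet_Ks, C, R, T)
        M = _posterior_means(Y, C, d, R, Sigma)   # (n_trials, qT)

        # marginal log-likelihood via the determinant lemma
        Yr = (Y - d[:, None]) / np.sqrt(R)[:, None]
        quad_direct = np.einsum("mnt,mnt->", Yr, Yr)
        quad_reduce = 0.0
        for m in range(n_trials):
            quad_reduce += float(M[m] @ np.linalg.solve(Sigma, M[m]))
        logdet = (np.sum(np.log(R)) * T + sum(logdet_Ks) + logdet_P)
        ll = -0.5 * (quad_direct - quad_reduce
                     + n_trials * (logdet + N * T * np.log(2 * np.pi)))
        if lls and ll < lls[-1] - max(1e-6, abs(lls[-1]) * tol):
            raise RuntimeError(
                f"EM log-likelihood decreased at iter {it}: "
                f"{lls[-1]:.6g} -> {ll:.6g}")
        lls.append(float(ll))

        # E[x_t x_t^T] time-diagonal blocks (shared across trials) + means
        Sig4 = Sigma.reshape(q, T, q, T)
        SigT = np.einsum("atbt->tab", Sig4)           # (T, q, q)
        Mq = M.reshape(n_trials, q, T)
        Exx = n_trials * SigT.sum(axis=0) \
            + np.einsum("mqt,mpt->qp", Mq, Mq)        # (q, q)
        Ex_sum = Mq.sum(axis=(0, 2))                  # (q,)
        nT = n_trials * T
        A = np.zeros((q + 1, q + 1))
        A[:q, :q] = Exx
        A[:q, q] = Ex_sum
        A[q, :q] = Ex_sum
        A[q, q] = nT
        Bm = np.zeros((N, q + 1))
        Bm[:, :q] = np.einsum("mnt,mqt->nq", Y, Mq)
        Bm[:, q] = Y.sum(axis=(0, 2))
        Cd = Bm @ np.linalg.inv(A + 1e-9 * np.eye(q + 1))
        C, d = Cd[:, :q], Cd[:, q]
        yy = np.einsum("mnt,mnt->n", Y, Y)
        R = np.clip((yy - np.einsum("nk,nk->n", Cd, Bm)) / nT,
                    1e-6 * max(Yc.var(), 1e-8), None)

        if (it + 1) % update_tau_every == 0:
            for a in range(q):
                S = n_trials * Sig4[a, :, a, :] \
                    + np.einsum("mt,ms->ts", Mq[:, a], Mq[:, a])

                def nll(log_tau, S=S):
                    K = _se_kernel(T, np.exp(log_tau))
                    sign, ld = np.linalg.slogdet(K)
                    return 0.5 * (n_trials * ld
                                  + np.trace(np.linalg.solve(K, S)))

                res = minimize_scalar(nll, bounds=(np.log(0.3),
                                                   np.log(5 * T)),
                                      method="bounded",
                                      options=dict(xatol=1e-2))
                taus[a] = float(np.exp(res.x))
    return GpfaModel(C=C, d=d, R=R, taus=taus * 1.0, bin_ms=bin_ms,
                     n_bins=T, log_likelihoods=lls)


def gpfa_latents(model: GpfaModel, Y: np.ndarray) -> np.ndarray:
    """Posterior mean latent trajectories (n_trials, q, T)."""
    T = Y.shape[2]
    q = model.n_factors
    Ks = [_se_kernel(T, model.taus[a]) for a in range(q)]
    K_invs = [np.linalg.inv(K) for K in Ks]
    Sigma, _, _ = _posterior(K_invs, None, model.C, model.R, T)
    M = _posterior_means(Y, model.C, model.d, model.R, Sigma)
    return M.reshape(len(Y), q, T)


def gpfa_loglik(model: GpfaModel, Y: np.ndarray) -> float:
    """Marginal log-likelihood of trials under a fitted model."""
    Y = np.asarray(Y, float)
    n_trials, N, T = Y.shape
    q = model.n_factors
    C, d, R = model.C, model.d, model.R
    Ks = [_se_kernel(T, model.taus[a]) for a in range(q)]
    chols = [np.linalg.cholesky(K) for K in Ks]
    K_invs = [np.linalg.inv(K) for K in Ks]
    logdet_Ks = [2 * np.sum(np.log(np.diag(L))) for L in chols]
    Sigma, _, logdet_P = _posterior(K_invs, logdet_Ks, C, R, T)
    M = _posterior_means(Y, C, d, R, Sigma)
    Yr = (Y - d[:, None]) / np.sqrt(R)[:, None]
    quad_direct = np.einsum("mnt,mnt->", Yr, Yr)
    quad_reduce = sum(float(M[m] @ np.linalg.solve(Sigma, M[m]))
                      for m in range(n_trials))
    logdet = np.sum(np.log(R)) * T + sum(logdet_Ks) + logdet_P
    return float(-0.5 * (quad_direct - quad_reduce
                         + n_trials * (logdet + N * T * np.log(2 * np.pi))))


def gpfa_lono_error(model: GpfaModel, Y: np.ndarray) -> float:
    """Leave-one-neuron-out mean squared prediction error.

    Each unit is predicted from the latents inferred using all *other*
    units, under the fitted parameters.
    """
    Y = np.asarray(Y, float)
    n_trials, N, T = Y.shape
    q = model.n_factors
    Ks = [_se_kernel(T, model.taus[a]) for a in range(q)]
    K_invs = [np.linalg.inv(K) for K in Ks]
    sse = 0.0
    for j in range(N):
        keep = np.arange(N) != j
        Sigma, _, _ = _posterior(K_invs, None, model.C[keep],
                                 model.R[keep], T)
        M = _posterior_means(Y[:, keep], model.C[keep], model.d[keep],
                             model.R[keep], Sigma)
        Xhat = M.reshape(n_trials, q, T)
        pred = np.einsum("q,mqt->mt", model.C[j], Xhat) + model.d[j]
        sse += np.sum((Y[:, j] - pred) ** 2)
    return float(sse / (n_trials * N * T))


def gpfa_dimensionality(Y: np.ndarray, dim_grid, bin_ms: float = 20.0,
                        n_iter: int = 30, threshold: float = 0.01,
                        test_Y: np.ndarray | None = None,
                        seed: int = 0) -> dict:
    """LONO error across candidate dimensionalities + selected range.

    For each candidate dimension the model is fit on ``Y`` and scored by
    LONO prediction error (on ``test_Y`` when given, else on the training
    trials).  The selected range contains all dims whose error is within
    ``threshold`` (default 1%) of the minimum.  Infeasible grid points are
    skipped with a log entry; the error curve reports every attempted dim.
    """
    N = Y.shape[1]
    errors = {}
    for qd in dim_grid:
        if qd < 1 or qd >= N:
            log.info("dim %d infeasible for %d units, skipped", qd, N)
            errors[int(qd)] = np.nan
            continue
        model = gpfa_fit(Y, qd, bin_ms=bin_ms, n_iter=n_iter, seed=seed)
        errors[int(qd)] = gpfa_lono_error(
            model, Y if test_Y is None else test_Y)
    vals = {k: v for k, v in errors.items() if np.isfinite(v)}
    emin = min(vals.values())
    selected = sorted(k for k, v in vals.items()
                      if v <= (1 + threshold) * emin)
    return dict(errors=errors, min_error=emin,
                selected_range=(selected[0], selected[-1]),
                selected_dims=selected,
                best_dim=min(vals, key=vals.get))
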