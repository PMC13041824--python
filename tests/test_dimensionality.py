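"""PCA spectra, demixed PCA and GPFA dimensionality recovery."""

import numpy as np
import pandas as pd
import pytest

from batflight import dimensionality as dim
from batflight.synthetic import (make_dpca_dataset, make_factor_population,
                                 make_gpfa_dataset)


# --------------------------------------------------------------------------
# group-mean matrix
# --------------------------------------------------------------------------

def _toy_table():
    rows = []
    wid = 0
    for f in range(4):
        for o in range(6):
            t0 = 2.0 * f + 0.125 * o
            rows.append(dict(wingbeat_id=wid, flight_id=f, ordinal=o,
                             group=o, onset=t0, offset=t0 + 0.125))
            wid += 1
    return pd.DataFrame(rows)


def test_group_mean_matches_loop_oracle():
    table = _toy_table()
    rng = np.random.default_rng(0)
    spikes = {u: np.sort(rng.uniform(0, 8, 300)) for u in range(3)}
    M, kept, groups = dim.build_group_mean_matrix(
        spikes, table, n_phase_bins=4, min_trials=2,
        reliability_threshold=-1.1)
    # brute-force the first unit / first group
    u, g = kept[0], groups[0]
    sub = table[table["group"] == g]
    acc = np.zeros(4)
    for wb in sub.itertuples():
        edges = np.linspace(wb.onset, wb.offset, 5)
        c, _ = np.histogram(spikes[u], bins=edges)
        acc += c / (0.125 / 4)
    acc /= len(sub)
    from batflight.core import smooth_series
    expect = smooth_series(acc, 1.0, 1.0)
    row = M[0, :4]
    # smoothing is applied across the concatenated trace, so only compare
    # away from the group boundary
    assert np.allclose(row[1:3], expect[1:3], rtol=0.25)


def test_unreliable_unit_removed():
    table = _toy_table()
    rng = np.random.default_rng(1)
    # unit 0: consistent ordinal tuning; unit 1: pure noise
    sp0 = np.sort(np.concatenate(
        [2.0 * f + 0.125 * 2 + rng.uniform(0, 0.1, 5) for f in range(4)]))
    sp1 = np.sort(rng.uniform(0, 8, 12))
    M, kept, _ = dim.build_group_mean_matrix(
        {0: sp0, 1: sp1}, table, n_phase_bins=4, min_trials=2,
        reliability_threshold=0.3)
    assert 0 in kept and 1 not in kept


def test_small_groups_dropped():
    table = _toy_table()
    table = pd.concat([table, pd.DataFrame([dict(
        wingbeat_id=99, flight_id=0, ordinal=7, group=7, onset=1.9,
        offset=1.95)])], ignore_index=True)
    rng = np.random.default_rng(2)
    spikes = {0: np.sort(rng.uniform(0, 8, 200))}
    _, _, groups = dim.build_group_mean_matrix(
        spikes, table, n_phase_bins=4, min_trials=2,
        reliability_threshold=-1.1)
    assert 7 not in groups


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

def test_rank_one_matrix():
    u = np.linspace(-1, 1, 12)[:, None]
    v = np.sin(np.linspace(0, 5, 40))[None, :]
    rep = dim.pca_dimensionality(u @ v)
    assert rep.n90 == 1
    assert rep.cumulative_ev[0] == pytest.approx(1.0)


def test_isotropic_gaussian_n90_fraction():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((50, 5000))
    rep = dim.pca_dimensionality(X)
    assert 0.8 <= rep.n90_fraction <= 0.95


def test_planted_k_factor_recovery():
    rng = np.random.default_rng(4)
    for k in (3, 6):
        trials, _ = make_factor_population(40, k, 15, 12, 0.05, rng)
        rep = dim.pca_dimensionality(trials[0])
        assert k - 1 <= rep.n90 <= k + 2


def test_spectrum_matches_bruteforce_svd():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((5, 8))
    rep = dim.pca_dimensionality(X)
    Xc = X - X.mean(axis=1, keepdims=True)
    lam = np.linalg.svd(Xc, compute_uv=False) ** 2 / 7
    assert np.allclose(rep.spectrum, lam, atol=1e-10)
    assert np.all(np.diff(rep.cumulative_ev) >= -1e-12)
    assert rep.cumulative_ev[-1] == pytest.approx(1.0)


def test_participation_ratio_split_values():
    pr_c, pr_e = dim.participation_ratio_split(np.ones(10))
    assert pr_c == pytest.approx(1.0)
    assert pr_e == pytest.approx(1.0)
    lam = np.array([2.0, 1.0])
    from batflight.core import participation_ratio
    assert participation_ratio(lam) == pytest.approx(1.8)
    pr_c, pr_e = dim.participation_ratio_split(
        np.array([10.0, 5.0, 3.0, 1.0, 1.0]), core_fraction=0.5)
    assert 0 < pr_c <= 1 and 0 < pr_e <= 1
    # one dominant eigenvalue: core PR is exactly 1
    pr_c, _ = dim.participation_ratio_split(np.array([5.0, 1e-12, 0.0]))
    assert pr_c == pytest.approx(1.0)


# --------------------------------------------------------------------------
# dPCA
# --------------------------------------------------------------------------

def test_dpca_identical_groups_no_specific_variance():
    rng = np.random.default_rng(6)
    base = rng.standard_normal((20, 1, 30)).repeat(8, axis=1)
    trials = base[None] + rng.normal(0, 0.05, (6, 20, 8, 30))
    out = dim.dpca_decompose(trials)
    assert out["specific_invariant_ratio"] < 0.1


def test_dpca_recovers_planted_ratio():
    for seed, rho in [(0, 3.0), (1, 12.0)]:
        rng = np.random.default_rng(seed)
        trials, planted = make_dpca_dataset(30, 12, 20, rho, 0.3, rng)
        out = dim.dpca_decompose(trials)
        assert abs(out["specific_invariant_ratio"] - planted) \
            <= 0.15 * planted


def test_dpca_invariant_dpc1_overlaps_across_groups():
    rng = np.random.default_rng(7)
    trials, _ = make_dpca_dataset(30, 10, 24, 2.0, 0.2, rng)
    out = dim.dpca_decompose(trials)
    inv = out["dpc1"]["time"]          # (groups, time)
    # the invariant component's per-group traces all match
    corr = np.corrcoef(inv)
    assert corr.min() > 0.9


def test_dpca_reconstruction_identity():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((6, 4, 10))
    m = dim.marginalize(X)
    assert np.allclose(m["time"] + m["group"] + m["group_time"], X,
                       atol=1e-12)


def test_dpca_needs_two_groups():
    with pytest.raises(ValueError):
        dim.dpca_decompose(np.zeros((3, 5, 1, 10)))


# --------------------------------------------------------------------------
# GPFA
# --------------------------------------------------------------------------

def test_gpfa_heldout_likelihood_prefers_true_dim():
    rng = np.random.default_rng(9)
    Y, _, _ = make_gpfa_dataset(20, 3, 24, 20, 20.0, (60, 120, 240),
                                1.0, 0.5, rng)
    m1 = dim.gpfa_fit(Y[:16], 1, n_iter=25)
    m3 = dim.gpfa_fit(Y[:16], 3, n_iter=25)
    assert dim.gpfa_loglik(m3, Y[16:]) > dim.gpfa_loglik(m1, Y[16:])


def test_gpfa_recovers_loading_direction():
    rng = np.random.default_rng(10)
    Y, C, _ = make_gpfa_dataset(15, 1, 10, 25, 20.0, (100,), 1.0, 0.02, rng)
    m = dim.gpfa_fit(Y, 1, n_iter=30)
    cos = np.dot(m.C[:, 0], C[:, 0]) / (np.linalg.norm(m.C)
                                        * np.linalg.norm(C))
    assert abs(cos) > 0.99


@pytest.mark.parametrize("tau_ms", [80.0, 200.0])
def test_gpfa_timescale_recovery_within_factor_two(tau_ms):
    rng = np.random.default_rng(11)
    Y, _, _ = make_gpfa_dataset(20, 1, 20, 30, 20.0, (tau_ms,),
                                1.0, 0.4, rng)
    m = dim.gpfa_fit(Y, 1, n_iter=40)
    fitted_ms = m.taus[0] * 20.0
    assert tau_ms / 2 <= fitted_ms <= tau_ms * 2


def test_gpfa_short_timescale_reduces_to_factor_analysis():
    from sklearn.decomposition import FactorAnalysis
    rng = np.random.default_rng(12)
    C0 = rng.standard_normal((15, 2))
    X = rng.standard_normal((2, 400))
    Y = (C0 @ X + rng.normal(0, 0.5, (15, 400)))[None]
    m = dim.gpfa_fit(Y, 2, n_iter=60, tau_init_ms=0.2,
                     update_tau_every=10 ** 9)
    fa = FactorAnalysis(2, tol=1e-6, max_iter=2000).fit(Y[0].T)
    ll_fa = fa.score(Y[0].T) * Y.shape[2]
    ll_g = dim.gpfa_loglik(m, Y)
    assert abs(ll_g - ll_fa) / abs(ll_fa) < 0.01


def test_gpfa_lono_selects_planted_dimension():
    rng = np.random.default_rng(13)
    Y, _, _ = make_gpfa_dataset(20, 3, 24, 20, 20.0, (60, 120, 240),
                                1.0, 0.5, rng)
    res = dim.gpfa_dimensionality(Y[:16], [1, 2, 3, 4, 5], n_iter=25,
                                  test_Y=Y[16:])
    assert 3 in res["selected_dims"]
    assert set(res["errors"]) == {1, 2, 3, 4, 5}   # every grid point reported


def test_gpfa_independent_units_select_one():
    rng = np.random.default_rng(14)
    Y = rng.standard_normal((16, 15, 20))   # no shared structure
    res = dim.gpfa_dimensionality(Y[:12], [1, 2, 3], n_iter=20,
                                  test_Y=Y[12:])
    assert res["selected_dims"][0] == 1


def test_gpfa_infeasible_grid_point_skipped():
    rng = np.random.default_rng(15)
    Y, _, _ = make_gpfa_dataset(6, 1, 8, 15, 20.0, (100,), 1.0, 0.3, rng)
    res = dim.gpfa_dimensionality(Y, [1, 2, 6], n_iter=15)
    assert np.isnan(res["errors"][6])
    assert np.isfinite(res["errors"][1])
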