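"""Penalized-regression path solvers.

Two solvers live here, both written for the n << p regime of per-SNP
neighborhood selection:

* an L1-penalized multinomial (softmax) logistic regression solved by FISTA
  with strong-rule screening and KKT verification along a decreasing lambda
  grid (numba-compiled inner loops);
* a group-LASSO linear regression solved by block proximal gradient (FISTA)
  along a lambda grid.

Both return, per lambda, the degrees of freedom (count of nonzero
coefficients), the unpenalized log-likelihood, and the per-predictor (or
per-group) coefficient norms needed to read off the selected neighbor set.
Proximal steps produce exact zeros, so the sparsity pattern is literal, not
thresholded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "multinomial_lasso_path",
    "group_lasso_path",
    "make_lambda_grid",
]


def make_lambda_grid(lam_max: float, n_lambda: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Geometric grid of shrinkage values from ``lam_max`` down to ``min_ratio * lam_max``."""
    if lam_max <= 0:
        # degenerate target (e.g. already perfectly predicted by the intercept)
        return np.full(n_lambda, 1e-12)
    return lam_max * np.power(min_ratio, np.linspace(0.0, 1.0, n_lambda))


# ---------------------------------------------------------------------------
# multinomial LASSO
# ---------------------------------------------------------------------------


@njit(cache=True)
def _softmax_loglik(Eta, Y):
    """Row-wise stable softmax; returns (P, total loglik)."""
    n, K = Eta.shape
    P = np.empty((n, K))
    ll = 0.0
    for i in range(n):
        m = Eta[i, 0]
        for k in range(1, K):
            if Eta[i, k] > m:
                m = Eta[i, k]
        s = 0.0
        for k in range(K):
            P[i, k] = np.exp(Eta[i, k] - m)
            s += P[i, k]
        logs = np.log(s) + m
        for k in range(K):
            P[i, k] /= s
            if Y[i, k] > 0.0:
                ll += Eta[i, k] - logs
    return P, ll


@njit(cache=True)
def _power_smax2(Xa, n_iter=40):
    """Largest squared singular value of Xa by power iteration on Xa'Xa."""
    p = Xa.shape[1]
    v = np.ones(p) / np.sqrt(p)
    s = 0.0
    for _ in range(n_iter):
        w = Xa.T @ (Xa @ v)
        s = np.sqrt(w @ w)
        if s <= 0.0:
            return 0.0
        v = w / s
    return s


@njit(cache=True)
def _fista_mlogit(Xs, Y, Bs, b, lam, L, tol, max_iter):
    """FISTA on the restricted design Xs; updates (Bs, b) in place.

    Objective: -(1/n) loglik + lam * sum|Bs|; intercepts b unpenalized.
    """
    n = Xs.shape[0]
    step = 1.0 / L
    Bz = Bs.copy()  # momentum point
    bz = b.copy()
    t = 1.0
    f_prev = 1e300
    for it in range(max_iter):
        Eta = Xs @ Bz + bz
        P, ll = _softmax_loglik(Eta, Y)
        R = (P - Y) / n
        G = Xs.T @ R
        gb = R.sum(axis=0)
        Bn = Bz - step * G
        # soft threshold
        thr = step * lam
        for a in range(Bn.shape[0]):
            for k in range(Bn.shape[1]):
                v = Bn[a, k]
                if v > thr:
                    Bn[a, k] = v - thr
                elif v < -thr:
                    Bn[a, k] = v + thr
                else:
                    Bn[a, k] = 0.0
        bn = bz - step * gb
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Bz = Bn + ((t - 1.0) / t_new) * (Bn - Bs)
        bz = bn + ((t - 1.0) / t_new) * (bn - b)
        Bs[:] = Bn
        b[:] = bn
        t = t_new
        if (it + 1) % 10 == 0:
            Eta = Xs @ Bs + b
            _, ll = _softmax_loglik(Eta, Y)
            f = -ll / n + lam * np.abs(Bs).sum()
            if f > f_prev:  # adaptive restart
                Bz = Bs.copy()
                bz = b.copy()
                t = 1.0
            denom = abs(f_prev)
            if denom < 1.0:
                denom = 1.0
            if abs(f_prev - f) / denom < tol:
                return it + 1
            f_prev = f
    return max_iter


@njit(cache=True)
def _full_gradient(X, Y, B, b):
    Eta = X @ B + b
    P, ll = _softmax_loglik(Eta, Y)
    n = X.shape[0]
    G = X.T @ ((P - Y) / n)
    return G, ll


@njit(cache=True)
def _mlogit_path(X, Y, lambdas, tol, max_iter, kkt_tol, dfmax):
    """Path over decreasing lambdas with strong-rule screening + KKT check.

    Returns (df, loglik, colnorm2, n_valid) where colnorm2[t, l] =
    sum_k B[l,k]^2 at lambda_t. The path is truncated (n_valid < n_lambda)
    once the fit saturates (loglik ~ 0) or selects more than ``dfmax``
    predictors — beyond either point no later lambda can improve an
    information criterion with penalty >= log(n) per predictor.
    """
    n, p = X.shape
    K = Y.shape[1]
    n_lam = lambdas.shape[0]
    B = np.zeros((p, K))
    # intercept-only start: b_k = log pi_k
    b = np.empty(K)
    for k in range(K):
        m = Y[:, k].mean()
        b[k] = np.log(m) if m > 0 else -30.0
    df = np.zeros(n_lam, dtype=np.int64)
    loglik = np.empty(n_lam)
    colnorm2 = np.zeros((n_lam, p))

    scr = np.zeros(p, dtype=np.bool_)
    prev_idx = np.empty(0, dtype=np.int64)
    L_cache = 1.0
    lam_prev = lambdas[0]
    G, ll = _full_gradient(X, Y, B, b)
    g_valid = True
    for tix in range(n_lam):
        lam = lambdas[tix]
        if not g_valid:
            G, ll = _full_gradient(X, Y, B, b)
            g_valid = True
        # strong rule on the sequential path + keep current support
        thr = 2.0 * lam - lam_prev
        for l in range(p):
            scr[l] = False
            for k in range(K):
                if abs(G[l, k]) >= thr or B[l, k] != 0.0:
                    scr[l] = True
                    break
        for _round in range(50):
            idx = np.where(scr)[0]
            if idx.shape[0] > 0:
                Xs = np.ascontiguousarray(X[:, idx])
                Bs = np.ascontiguousarray(B[idx])
                ns = idx.shape[0]
                same = ns == prev_idx.shape[0]
                if same:
                    for q in range(ns):
                        if idx[q] != prev_idx[q]:
                            same = False
                            break
                if not same:
                    # Lipschitz of the restricted smooth part (0.5/n for softmax)
                    Xa = np.empty((n, ns + 1))
                    Xa[:, 0] = 1.0
                    Xa[:, 1:] = Xs
                    L = 0.5 * _power_smax2(Xa) / n
                    if L <= 0.0:
                        L = 1.0
                    L_cache = L
                    prev_idx = idx.copy()
                Bpre = Bs.copy()
                bpre = b.copy()
                _fista_mlogit(Xs, Y, Bs, b, lam, L_cache * 1.01, tol, max_iter)
                B[idx] = Bs
                moved = False
                for q in range(Bs.shape[0]):
                    for k in range(K):
                        if Bs[q, k] != Bpre[q, k]:
                            moved = True
                            break
                    if moved:
                        break
                if not moved:
                    for k in range(K):
                        if b[k] != bpre[k]:
                            moved = True
                            break
                if moved:
                    g_valid = False
            else:
                # refit intercept only (one Newton-ish pass is enough: closed form)
                for k in range(K):
                    m = Y[:, k].mean()
                    b[k] = np.log(m) if m > 0 else -30.0
            if not g_valid:
                G, ll = _full_gradient(X, Y, B, b)
                g_valid = True
            viol = False
            for l in range(p):
                if not scr[l]:
                    for k in range(K):
                        if abs(G[l, k]) > lam + kkt_tol:
                            scr[l] = True
                            viol = True
                            break
            if not viol:
                break
        nz = 0
        nv = 0
        for l in range(p):
            s2 = 0.0
            for k in range(K):
                if abs(B[l, k]) > 1e-10:  # prox zeros are exact; this guards boundary residue
                    nz += 1
                    s2 += B[l, k] * B[l, k]
            if s2 > 0.0:
                nv += 1
            colnorm2[tix, l] = s2
        df[tix] = nz
        loglik[tix] = ll
        lam_prev = lam
        if ll > -1e-6 * n or nv > dfmax:
            return df, loglik, colnorm2, tix + 1
    return df, loglik, colnorm2, lambdas.shape[0]


def multinomial_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 2000,
    dfmax: int | None = None,
):
    """L1-penalized multinomial logistic regression along a lambda path.

    Parameters
    ----------
    X
        Standardized design, shape (n, p). Column for the response must
        already be excluded.
    y
        Integer class labels in {0, ..., K-1}; every class 0..K-1 must be
        observed (relabel before calling).

    Returns
    -------
    dict with keys ``lambdas``, ``df``, ``loglik``, ``colnorm2``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y)
    n, p = X.shape
    K = int(y.max()) + 1
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0
    pi = Y.mean(axis=0)
    G0 = X.T @ ((pi[None, :] - Y) / n)
    lam_max = float(np.abs(G0).max())
    lambdas = make_lambda_grid(lam_max, n_lambda, lambda_min_ratio)
    if dfmax is None:
        dfmax = n
    df, loglik, colnorm2, n_valid = _mlogit_path(
        X, Y, lambdas, tol, max_iter, 1e-9, int(dfmax)
    )
    sl = slice(0, n_valid)
    colnorm2 = colnorm2[sl]
    nvars = (colnorm2 > 0.0).sum(axis=1)
    return {
        "lambdas": lambdas[sl],
        "df": df[sl],
        "nvars": nvars,
        "loglik": loglik[sl],
        "colnorm2": colnorm2,
    }


# ---------------------------------------------------------------------------
# group LASSO
# ---------------------------------------------------------------------------


@njit(cache=True)
def _group_prox(a, gstart, gend, w, thr_base):
    for gi in range(gstart.shape[0]):
        s = 0.0
        for c in range(gstart[gi], gend[gi]):
            s += a[c] * a[c]
        nrm = np.sqrt(s)
        thr = thr_base * w[gi]
        if nrm <= thr:
            for c in range(gstart[gi], gend[gi]):
                a[c] = 0.0
        else:
            scale = 1.0 - thr / nrm
            for c in range(gstart[gi], gend[gi]):
                a[c] *= scale


@njit(cache=True)
def _group_lasso_path_nb(Zo, zc, lambdas, gstart, gend, w, tol, max_iter, dfmax):
    """Group-LASSO path with groupwise strong-rule screening + KKT checks.

    Returns (df, ngroups, rss, groupnorm2, coefs, n_valid); truncates once
    the fit saturates or selects more than ``dfmax`` groups.
    """
    n, p = Zo.shape
    n_groups = gstart.shape[0]
    n_lam = lambdas.shape[0]
    a = np.zeros(p)
    df = np.zeros(n_lam, dtype=np.int64)
    ngroups = np.zeros(n_lam, dtype=np.int64)
    rss = np.zeros(n_lam)
    groupnorm2 = np.zeros((n_lam, n_groups))
    coefs = np.zeros((n_lam, p))
    rss0 = zc @ zc
    scr = np.zeros(n_groups, dtype=np.bool_)
    prev_act = np.empty(0, dtype=np.int64)
    L_cache = 1.0
    lam_prev = lambdas[0]
    r = Zo @ a - zc
    g = Zo.T @ r / n
    g_valid = True
    for tix in range(n_lam):
        lam = lambdas[tix]
        if not g_valid:
            r = Zo @ a - zc
            g = Zo.T @ r / n
            g_valid = True
        for gi in range(n_groups):
            s = 0.0
            nz = False
            for c in range(gstart[gi], gend[gi]):
                s += g[c] * g[c]
                if a[c] != 0.0:
                    nz = True
            scr[gi] = nz or np.sqrt(s) >= w[gi] * (2.0 * lam - lam_prev)
        for _round in range(50):
            # restricted solve on screened groups
            tot = 0
            for gi in range(n_groups):
                if scr[gi]:
                    tot += gend[gi] - gstart[gi]
            if tot > 0:
                Zs = np.empty((n, tot))
                asub = np.empty(tot)
                gs2 = np.empty(n_groups, dtype=np.int64)
                ge2 = np.empty(n_groups, dtype=np.int64)
                pos = 0
                ng2 = 0
                gmapidx = np.empty(n_groups, dtype=np.int64)
                for gi in range(n_groups):
                    if scr[gi]:
                        m = gend[gi] - gstart[gi]
                        Zs[:, pos : pos + m] = Zo[:, gstart[gi] : gend[gi]]
                        asub[pos : pos + m] = a[gstart[gi] : gend[gi]]
                        gs2[ng2] = pos
                        ge2[ng2] = pos + m
                        gmapidx[ng2] = gi
                        pos += m
                        ng2 += 1
                ws = np.empty(ng2)
                for k in range(ng2):
                    ws[k] = w[gmapidx[k]]
                same = ng2 == prev_act.shape[0]
                if same:
                    for q in range(ng2):
                        if gmapidx[q] != prev_act[q]:
                            same = False
                            break
                if not same:
                    L = _power_smax2(Zs) / n
                    if L <= 0.0:
                        L = 1.0
                    L_cache = L
                    prev_act = gmapidx[:ng2].copy()
                apre = asub.copy()
                _group_lasso_fista(
                    Zs, zc, asub, gs2[:ng2], ge2[:ng2], ws, lam,
                    1.0 / (L_cache * 1.01), tol, max_iter,
                )
                pos = 0
                moved = False
                for k in range(ng2):
                    gi = gmapidx[k]
                    m = gend[gi] - gstart[gi]
                    a[gstart[gi] : gend[gi]] = asub[pos : pos + m]
                    for q in range(m):
                        if asub[pos + q] != apre[pos + q]:
                            moved = True
                    pos += m
                if moved:
                    g_valid = False
            # KKT check on excluded groups
            if not g_valid:
                r = Zo @ a - zc
                g = Zo.T @ r / n
                g_valid = True
            viol = False
            for gi in range(n_groups):
                if not scr[gi]:
                    s = 0.0
                    for c in range(gstart[gi], gend[gi]):
                        s += g[c] * g[c]
                    if np.sqrt(s) > w[gi] * lam + 1e-10:
                        scr[gi] = True
                        viol = True
            if not viol:
                break
        if g_valid:
            rss[tix] = r @ r
        else:
            res = Zo @ a - zc
            rss[tix] = res @ res
        nv = 0
        nz = 0
        for gi in range(n_groups):
            s = 0.0
            for c in range(gstart[gi], gend[gi]):
                if abs(a[c]) > 1e-12:
                    nz += 1
                    s += a[c] * a[c]
            groupnorm2[tix, gi] = s
            if s > 0.0:
                nv += 1
        df[tix] = nz
        ngroups[tix] = nv
        coefs[tix] = a
        lam_prev = lam
        if rss[tix] < 1e-10 * rss0 or nv > dfmax:
            return df, ngroups, rss, groupnorm2, coefs, tix + 1
    return df, ngroups, rss, groupnorm2, coefs, n_lam


@njit(cache=True)
def _group_lasso_fista(Z, zc, a, gstart, gend, w, lam, step, tol, max_iter):
    n = Z.shape[0]
    av = a.copy()
    t = 1.0
    f_prev = 1e300
    for it in range(max_iter):
        r = Z @ av - zc
        g = Z.T @ r / n
        anew = av - step * g
        _group_prox(anew, gstart, gend, w, step * lam)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        av = anew + ((t - 1.0) / t_new) * (anew - a)
        a[:] = anew
        t = t_new
        if (it + 1) % 10 == 0:
            res = Z @ a - zc
            pen = 0.0
            for gi in range(gstart.shape[0]):
                s = 0.0
                for c in range(gstart[gi], gend[gi]):
                    s += a[c] * a[c]
                pen += w[gi] * np.sqrt(s)
            f = 0.5 * (res @ res) / n + lam * pen
            if f > f_prev:  # adaptive restart
                av = a.copy()
                t = 1.0
            denom = abs(f_prev)
            if denom < 1.0:
                denom = 1.0
            if f_prev < 1e299 and abs(f_prev - f) / denom < tol:
                return
            f_prev = f


def group_lasso_path(
    Z: np.ndarray,
    z: np.ndarray,
    groups: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    group_weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 10000,
    dfmax: int | None = None,
):
    """Group-LASSO linear regression along a lambda path.

    Minimizes  (1/2n)||z - Z a||^2 + lam * sum_g w_g ||a_g||_2  by FISTA
    with a groupwise soft-threshold prox (warm-started along the decreasing
    grid). ``groups`` assigns each column of ``Z`` to an integer group id;
    ``group_weights`` defaults to 1 for every group (unweighted penalty).
    The intercept is handled by centering the response.

    Returns dict with ``lambdas``, ``df`` (nonzero coefficients), ``ngroups``
    (selected groups), ``rss``, ``groupnorm2`` (shape (n_lambda, n_groups)),
    ``coef`` and ``group_ids``.
    """
    Z = np.ascontiguousarray(Z, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64).ravel()
    groups = np.asarray(groups)
    n, p = Z.shape
    gids = np.unique(groups)
    n_groups = gids.shape[0]
    # reorder columns so each group is contiguous
    order = np.argsort(groups, kind="stable")
    Zo = np.ascontiguousarray(Z[:, order] - Z[:, order].mean(axis=0))
    go = groups[order]
    gstart = np.searchsorted(go, gids, side="left").astype(np.int64)
    gend = np.searchsorted(go, gids, side="right").astype(np.int64)
    if group_weights is None:
        w = np.ones(n_groups)
    else:
        w = np.asarray(group_weights, dtype=np.float64)

    zc = z - z.mean()
    corr = Zo.T @ zc / n
    lam_max = max(
        float(np.linalg.norm(corr[gstart[gi] : gend[gi]]) / w[gi]) for gi in range(n_groups)
    )
    lambdas = make_lambda_grid(lam_max, n_lambda, lambda_min_ratio)

    if dfmax is None:
        dfmax = n
    df, ngroups, rss, groupnorm2, coefs_o, n_valid = _group_lasso_path_nb(
        Zo, zc, lambdas, gstart, gend, w, tol, max_iter, int(dfmax)
    )
    sl = slice(0, n_valid)
    coefs = np.zeros((n_valid, p))
    coefs[:, order] = coefs_o[sl]
    return {
        "lambdas": lambdas[sl],
        "df": df[sl],
        "ngroups": ngroups[sl],
        "rss": rss[sl],
        "groupnorm2": groupnorm2[sl],
        "coef": coefs,
        "group_ids": gids,
    }
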