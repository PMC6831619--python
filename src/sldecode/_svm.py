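"""Soft-margin linear SVM solved in the dual on precomputed Gram matrices.

The decoding stages need millions of tiny SVM fits (one per leave-one-out
fold, per searchlight sphere, per label permutation), so the solver is a
compact SMO (sequential minimal optimization) written for numba. It solves
the standard C-SVC dual

    min_a  0.5 aᵀQa − eᵀa    s.t.  yᵀa = 0,  0 ≤ a_i ≤ C,

with Q_ij = y_i y_j K_ij, using maximal-violating-pair selection with the
second-order working-set rule, and returns libsvm-convention decision
values f(x) = Σ_j a_j y_j K(x_j, x) − rho. Agreement with libsvm
(scikit-learn's SVC with a precomputed kernel) is enforced in the test
suite rather than assumed; iteration behavior matches libsvm's on the
same problems.

Only the Gram matrix enters the optimization, so a searchlight sphere's
kernel is computed once and reused across folds and label permutations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TAU = 1e-12

#: KKT tolerance used for single public fits (libsvm's default).
DEFAULT_TOL = 1e-3


@njit(cache=True)
def _smo_h(K, y, C, alpha, H, tol, max_iter):
    """Core SMO on H = −y∘G (G the dual gradient); returns rho.

    Working with H makes the per-iteration update a pure two-row AXPY on
    the kernel matrix (no per-element label products):
    H_t ← H_t − Δ(a_i y_i) K_it − Δ(a_j y_j) K_jt. ``H`` must equal
    −y∘(Q@alpha − 1) on entry (i.e. +y for a cold start).
    The optimum satisfies max_{I_up} H − min_{I_low} H < tol.
    """
    n = y.shape[0]
    # initial selection of i over the "up" set
    gmax = -1e300
    i = -1
    for t in range(n):
        if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
            if H[t] >= gmax:
                gmax = H[t]
                i = t
    it = 0
    while it < max_iter:
        it += 1
        if i == -1:
            break
        Ki = K[i]
        kii = Ki[i]
        gmin = 1e300
        obj_min = 1e300
        j = -1
        for t in range(n):
            if (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C):
                h = H[t]
                if h < gmin:
                    gmin = h
                b = gmax - h
                if b > 0.0:
                    a = kii + K[t, t] - 2.0 * Ki[t]
                    if a <= 0.0:
                        a = _TAU
                    v2 = -(b * b) / a
                    if v2 <= obj_min:
                        obj_min = v2
                        j = t
        if j == -1 or gmax - gmin < tol:
            break

        # analytic two-variable update (libsvm conventions);
        # G_i = -y_i H_i reconstructs the gradient entries we need
        Kj = K[j]
        quad = kii + Kj[j] - 2.0 * Ki[j]
        if quad <= 0.0:
            quad = _TAU
        gi = -y[i] * H[i]
        gj = -y[j] * H[j]
        old_ai = alpha[i]
        old_aj = alpha[j]
        if y[i] != y[j]:
            delta = (-gi - gj) / quad
            diff = old_ai - old_aj
            ai = old_ai + delta
            aj = old_aj + delta
            if diff > 0.0:
                if aj < 0.0:
                    aj = 0.0
                    ai = diff
                if ai > C:
                    ai = C
                    aj = C - diff
            else:
                if ai < 0.0:
                    ai = 0.0
                    aj = -diff
                if aj > C:
                    aj = C
                    ai = C + diff
        else:
            delta = (gi - gj) / quad
            ssum = old_ai + old_aj
            ai = old_ai - delta
            aj = old_aj + delta
            if ssum > C:
                if ai > C:
                    ai = C
                    aj = ssum - C
                if aj > C:
                    aj = C
                    ai = ssum - C
            else:
                if aj < 0.0:
                    aj = 0.0
                    ai = ssum
                if ai < 0.0:
                    ai = 0.0
                    aj = ssum
        alpha[i] = ai
        alpha[j] = aj
        dai = (ai - old_ai) * y[i]
        daj = (aj - old_aj) * y[j]

        # fused pass: H update (branch-free AXPY) + selection of the next i
        gmax = -1e300
        i = -1
        for t in range(n):
            h = H[t] - Ki[t] * dai - Kj[t] * daj
            H[t] = h
            if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
                if h >= gmax:
                    gmax = h
                    i = t

    # rho from the KKT conditions (y G = -H)
    ub = 1e300
    lb = -1e300
    sum_free = 0.0
    nr_free = 0
    for t in range(n):
        yg = -H[t]
        if alpha[t] >= C:
            if y[t] < 0.0:
                ub = min(ub, yg)
            else:
                lb = max(lb, yg)
        elif alpha[t] <= 0.0:
            if y[t] > 0.0:
                ub = min(ub, yg)
            else:
                lb = max(lb, yg)
        else:
            nr_free += 1
            sum_free += yg
    if nr_free > 0:
        return sum_free / nr_free
    return (ub + lb) / 2.0


@njit(cache=True)
def _smo(K, y, C, alpha, G, tol, max_iter):
    """Optimize ``alpha`` in place; return rho.

    ``y`` is ±1 (float); ``G`` must equal Q@alpha − 1 on entry (−1 for a
    cold start) and holds the final gradient on exit.
    """
    n = y.shape[0]
    H = np.empty(n)
    for t in range(n):
        H[t] = -y[t] * G[t]
    rho = _smo_h(K, y, C, alpha, H, tol, max_iter)
    for t in range(n):
        G[t] = -y[t] * H[t]
    return rho


@njit(cache=True)
def _gradient_from_alpha(K, y, alpha, G):
    n = y.shape[0]
    for t in range(n):
        s = 0.0
        for u in range(n):
            if alpha[u] != 0.0:
                s += y[u] * alpha[u] * K[t, u]
        G[t] = y[t] * s - 1.0


@njit(cache=True)
def _fold_check_and_decision(K, y, C, h, alpha, tol):
    """Verify fold KKT at the requested tolerance; return decision value.

    Returns NaN when the supplied alphas do not satisfy the fold problem's
    KKT conditions within ``tol`` (caller falls back to the SMO path).
    rho is recomputed from the verified gradient, libsvm-style.
    """
    n = y.shape[0]
    gmax = -1e300
    gmin = 1e300
    ub = 1e300
    lb = -1e300
    sum_free = 0.0
    nr_free = 0
    for t in range(n):
        if t == h:
            continue
        s = 0.0
        for u in range(n):
            if u != h and alpha[u] != 0.0:
                s += y[u] * alpha[u] * K[t, u]
        g = y[t] * s - 1.0
        yg = y[t] * g
        if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
            v = -yg
            if v > gmax:
                gmax = v
        if (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C):
            v = -yg
            if v < gmin:
                gmin = v
        if alpha[t] >= C:
            if y[t] < 0.0:
                ub = min(ub, yg)
            else:
                lb = max(lb, yg)
        elif alpha[t] <= 0.0:
            if y[t] > 0.0:
                ub = min(ub, yg)
            else:
                lb = max(lb, yg)
        else:
            nr_free += 1
            sum_free += yg
    if gmax - gmin >= tol:
        return np.nan
    if nr_free > 0:
        rho = sum_free / nr_free
    else:
        rho = (ub + lb) / 2.0
    s = 0.0
    for u in range(n):
        if u != h and alpha[u] != 0.0:
            s += alpha[u] * y[u] * K[u, h]
    return s - rho


@njit(cache=True)
def _loo_decision_values(K, y, C, tol, max_iter, Ksub, ysub, alpha, G, afull, d):
    """Held-out decision value per subject, one SVM per leave-one-out fold.

    Strategy per fold: (1) if the held-out subject is not a support
    vector of the full fit, the fold optimum equals the full optimum
    (exact shortcut); (2) otherwise follow the exact decremental path
    that retires the subject's alpha while tracking the KKT system, and
    accept the result only if it passes a full KKT check at the solver
    tolerance; (3) on any degeneracy fall back to SMO warm-started from
    the repaired full solution. All three routes satisfy the same KKT
    tolerance, so the choice affects speed only.
    """
    n = y.shape[0]
    m = n - 1
    afull[:] = 0.0
    G[:n] = -1.0
    rho_full = _smo(K, y, C, afull, G[:n], tol, max_iter)
    gfull = np.empty(n)
    for t in range(n):
        gfull[t] = G[t]
    status0 = np.empty(n, np.int8)
    for t in range(n):
        if afull[t] <= 0.0:
            status0[t] = 0
        elif afull[t] >= C:
            status0[t] = 2
        else:
            status0[t] = 1
    beta0 = -rho_full
    hgrad0 = np.empty(n)
    for t in range(n):
        hgrad0[t] = gfull[t] + y[t] * beta0
    a_work = np.empty(n)
    status = np.empty(n, np.int8)
    hgrad = np.empty(n)
    work_M = np.empty((n + 1, n + 1))
    work_r = np.empty(n + 1)
    work_x = np.empty(n + 1)
    for h in range(n):
        if afull[h] <= 0.0:
            # held-out subject is not a support vector of the full fit, so
            # the fold's optimum equals the full optimum (exact shortcut)
            d[h] = y[h] * (gfull[h] + 1.0) - rho_full
            continue
        a_work[:] = afull
        status[:] = status0
        hgrad[:] = hgrad0
        beta = _decremental_fold(
            K, y, C, h, a_work, beta0, status, hgrad, work_M, work_r, work_x
        )
        if not np.isnan(beta):
            dv = _fold_check_and_decision(K, y, C, h, a_work, tol)
            if not np.isnan(dv):
                d[h] = dv
                continue
        k = 0
        for t in range(n):
            if t == h:
                continue
            ysub[k] = y[t]
            alpha[k] = afull[t]
            kk = 0
            for u in range(n):
                if u == h:
                    continue
                Ksub[k, kk] = K[t, u]
                kk += 1
            k += 1
        # repair the equality constraint after dropping subject h
        deficit = afull[h]  # alpha mass lost on class y[h]
        if deficit > 0.0:
            for t in range(m):
                if deficit <= 0.0:
                    break
                if ysub[t] == y[h] and alpha[t] < C:
                    room = C - alpha[t]
                    add = room if room < deficit else deficit
                    alpha[t] += add
                    deficit -= add
            if deficit > 1e-12:
                # same-class alphas saturated: shed mass from the other class
                for t in range(m):
                    if deficit <= 0.0:
                        break
                    if ysub[t] != y[h] and alpha[t] > 0.0:
                        take = alpha[t] if alpha[t] < deficit else deficit
                        alpha[t] -= take
                        deficit -= take
        _gradient_from_alpha(Ksub, ysub, alpha, G[:m])
        rho = _smo(Ksub, ysub, C, alpha, G[:m], tol, max_iter)
        s = 0.0
        k = 0
        for t in range(n):
            if t == h:
                continue
            if alpha[k] != 0.0:
                s += alpha[k] * ysub[k] * K[t, h]
            k += 1
        d[h] = s - rho
    return d


@njit(cache=True)
def _solve_gauss(M, r, x):
    """Gaussian elimination with partial pivoting; returns False if singular."""
    n = M.shape[0]
    for col in range(n):
        piv = col
        best = abs(M[col, col])
        for row in range(col + 1, n):
            v = abs(M[row, col])
            if v > best:
                best = v
                piv = row
        if best < 1e-10:
            return False
        if piv != col:
            for k in range(n):
                tmp = M[col, k]
                M[col, k] = M[piv, k]
                M[piv, k] = tmp
            tmp = r[col]
            r[col] = r[piv]
            r[piv] = tmp
        inv = 1.0 / M[col, col]
        for row in range(col + 1, n):
            factor = M[row, col] * inv
            if factor != 0.0:
                for k in range(col, n):
                    M[row, k] -= factor * M[col, k]
                r[row] -= factor * r[col]
    for col in range(n - 1, -1, -1):
        s = r[col]
        for k in range(col + 1, n):
            s -= M[col, k] * x[k]
        x[col] = s / M[col, col]
    return True


@njit(cache=True)
def _decremental_fold(K, y, C, h, alpha, beta, status, hgrad, work_M, work_r, work_x):
    """Exactly remove point h from an optimal solution by path-following.

    alpha/status/hgrad are the full-problem state (hgrad_t = Q a + y_t*beta - 1)
    and are modified in place toward the fold optimum with a_h = 0.
    status: 0 = at lower bound, 1 = free, 2 = at upper bound.
    Returns the final beta, or NaN to signal that the caller must fall
    back to the iterative solver (degenerate geometry, too many events).
    """
    n = y.shape[0]
    max_events = 6 * n
    eps = 1e-12
    for _ in range(max_events):
        rem = alpha[h]
        if rem <= eps:
            alpha[h] = 0.0
            return beta
        # collect the free set (excluding h)
        f = 0
        for t in range(n):
            if t != h and status[t] == 1:
                f += 1
        if f == 0:
            return np.nan
        idx = np.empty(f, np.int64)
        k = 0
        for t in range(n):
            if t != h and status[t] == 1:
                idx[k] = t
                k += 1
        # KKT system for the direction per unit decrease of a_h
        m = f + 1
        M = work_M[:m, :m]
        r = work_r[:m]
        x = work_x[:m]
        M[0, 0] = 0.0
        for a_ in range(f):
            ta = idx[a_]
            M[0, a_ + 1] = y[ta]
            M[a_ + 1, 0] = y[ta]
            for b_ in range(f):
                tb = idx[b_]
                M[a_ + 1, b_ + 1] = y[ta] * y[tb] * K[ta, tb]
        r[0] = y[h]
        for a_ in range(f):
            r[a_ + 1] = y[idx[a_]] * y[h] * K[idx[a_], h]
        if not _solve_gauss(M, r, x):
            return np.nan
        dbeta = x[0]
        # step limits: free variables hitting a box bound
        step = rem
        event_t = -1
        event_kind = 0  # 1 free->lower, 2 free->upper, 3 lower->free, 4 upper->free
        for a_ in range(f):
            da = x[a_ + 1]
            ta = idx[a_]
            if da < -eps:
                s = alpha[ta] / (-da)
                if s < step - eps:
                    step = s
                    event_t = ta
                    event_kind = 1
            elif da > eps:
                s = (C - alpha[ta]) / da
                if s < step - eps:
                    step = s
                    event_t = ta
                    event_kind = 2
        # bounded points whose KKT residual crosses zero
        for t in range(n):
            if t == h or status[t] == 1:
                continue
            dh = -y[t] * y[h] * K[t, h] + y[t] * dbeta
            for a_ in range(f):
                dh += y[t] * y[idx[a_]] * K[t, idx[a_]] * x[a_ + 1]
            if status[t] == 0 and dh < -eps:
                s = hgrad[t] / (-dh)
                if 0.0 <= s < step - eps:
                    step = s
                    event_t = t
                    event_kind = 3
            elif status[t] == 2 and dh > eps:
                s = (-hgrad[t]) / dh
                if 0.0 <= s < step - eps:
                    step = s
                    event_t = t
                    event_kind = 4
        if step < 0.0:
            step = 0.0
        # apply the step
        alpha[h] -= step
        beta += step * dbeta
        for a_ in range(f):
            ta = idx[a_]
            alpha[ta] += step * x[a_ + 1]
            if alpha[ta] < 0.0:
                alpha[ta] = 0.0
            elif alpha[ta] > C:
                alpha[ta] = C
        # update KKT residuals of bounded points
        for t in range(n):
            if t == h or status[t] == 1:
                continue
            dh = -y[t] * y[h] * K[t, h] + y[t] * dbeta
            for a_ in range(f):
                dh += y[t] * y[idx[a_]] * K[t, idx[a_]] * x[a_ + 1]
            hgrad[t] += step * dh
        if event_t >= 0:
            if event_kind == 1:
                alpha[event_t] = 0.0
                status[event_t] = 0
                hgrad[event_t] = 0.0
            elif event_kind == 2:
                alpha[event_t] = C
                status[event_t] = 2
                hgrad[event_t] = 0.0
            else:
                status[event_t] = 1
        elif step >= rem - eps:
            alpha[h] = 0.0
            return beta
    return np.nan


@njit(cache=True)
def _auc_sens_spec(d, y):
    """Rank-based AUC (ties half-credit) plus sensitivity/specificity at 0."""
    n = d.shape[0]
    npos = 0
    nneg = 0
    conc = 0.0
    tp = 0
    tn = 0
    for i in range(n):
        if y[i] > 0.0:
            npos += 1
            if d[i] > 0.0:
                tp += 1
        else:
            nneg += 1
            if d[i] <= 0.0:
                tn += 1
    for i in range(n):
        if y[i] > 0.0:
            for j in range(n):
                if y[j] < 0.0:
                    if d[i] > d[j]:
                        conc += 1.0
                    elif d[i] == d[j]:
                        conc += 0.5
    auc = conc / (npos * nneg)
    return auc, tp / npos, tn / nneg


@njit(cache=True)
def searchlight_stats(grams, y, C, tol, max_iter, store_decisions):
    """LOO-SVM AUC/sensitivity/specificity at every searchlight center.

    grams: (n_centers, n, n) kernel stack; y: ±1 labels (float64).
    """
    n_centers = grams.shape[0]
    n = y.shape[0]
    auc = np.empty(n_centers)
    sens = np.empty(n_centers)
    spec = np.empty(n_centers)
    if store_decisions:
        dvals = np.empty((n_centers, n))
    else:
        dvals = np.empty((0, n))
    Ksub = np.empty((n - 1, n - 1))
    ysub = np.empty(n - 1)
    alpha = np.empty(n - 1)
    G = np.empty(n)
    afull = np.empty(n)
    d = np.empty(n)
    for c in range(n_centers):
        _loo_decision_values(grams[c], y, C, tol, max_iter, Ksub, ysub, alpha, G, afull, d)
        auc[c], sens[c], spec[c] = _auc_sens_spec(d, y)
        if store_decisions:
            for t in range(n):
                dvals[c, t] = d[t]
    return auc, sens, spec, dvals


@njit(cache=True)
def grams_from_data(data_t, indices, indptr):
    """Per-center Gram stack from masked data.

    data_t: (n_voxels, n_subjects) feature matrix transposed so a voxel's
    subject vector is contiguous; indices/indptr: CSR layout of each
    center's sphere voxels (row indices into data_t).
    """
    n = data_t.shape[1]
    n_centers = indptr.shape[0] - 1
    grams = np.zeros((n_centers, n, n))
    for c in range(n_centers):
        for p in range(indptr[c], indptr[c + 1]):
            row = data_t[indices[p]]
            for i in range(n):
                ri = row[i]
                if ri != 0.0:
                    for j in range(i, n):
                        grams[c, i, j] += ri * row[j]
        for i in range(n):
            for j in range(i + 1, n):
                grams[c, j, i] = grams[c, i, j]
    return grams


def loo_decision_values_gram(K, y, C=1.0, tol=DEFAULT_TOL, max_iter=1_000_000):
    """Leave-one-out decision values for one problem given its Gram matrix."""
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n = y.shape[0]
    d = np.empty(n)
    _loo_decision_values(
        K, y, float(C), float(tol), int(max_iter),
        np.empty((n - 1, n - 1)), np.empty(n - 1), np.empty(n - 1),
        np.empty(n), np.empty(n), d,
    )
    return d


def svm_fit_gram(K, y, C=1.0, tol=DEFAULT_TOL, max_iter=1_000_000):
    """Single SVM fit on a Gram matrix; returns (alpha, rho).

    Decision value for a new point x is sum_j alpha_j y_j K(x_j, x) - rho.
    """
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n = y.shape[0]
    alpha = np.zeros(n)
    G = np.full(n, -1.0)
    rho = _smo(K, y, float(C), alpha, G, float(tol), int(max_iter))
    return alpha, rho
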