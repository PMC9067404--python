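"""Exact dynamic program for the weighted 1D fused lasso.

Solves

    minimize_x  0.5 * sum_i (x_i - y_i)^2
                + sum_i u_i |x_i|
                + sum_{i<n-1} w_i |x_{i+1} - x_i|

with elementwise sparsity weights ``u_i >= 0`` and edge fusion weights
``w_i >= 0``, by forward message passing with clipped piecewise-linear
derivatives and a backward pass (the classic O(n) taut-string-style
dynamic program for total-variation denoising, extended with node
penalties).  The forward messages

    V_1(x) = 0.5 (x - y_1)^2 + u_1 |x|
    V_i(x) = 0.5 (x - y_i)^2 + u_i |x| + min_z [ V_{i-1}(z) + w_{i-1}|x - z| ]

are convex and piecewise quadratic, so their derivatives are monotone
piecewise-linear functions (with upward jumps at 0 from the |x| terms).
The inf-convolution with w|.| clips the derivative to [-w, +w]; the clip
points t_lo/t_hi are stored and the backward pass sets
x_i = clip(x_{i+1}, t_lo_i, t_hi_i).

The derivative of each message is represented as a left-tail affine
function (A0*x + B0) plus a sorted list of knots, each carrying an
additive (slope, intercept) delta that applies to the right of it.
"""

from __future__ import annotations

import numpy as np


def _dp_core(y, u, w, kx1, ka1, kb1, kx2, ka2, kb2, tm, tp, x):
    n = y.shape[0]
    if n == 1:
        # soft threshold
        v = y[0]
        if v > u[0]:
            x[0] = v - u[0]
        elif v < -u[0]:
            x[0] = v + u[0]
        else:
            x[0] = 0.0
        return

    kx, ka, kb = kx1, ka1, kb1
    ox, oa, ob = kx2, ka2, kb2

    # V_0
    A0 = 1.0
    B0 = -y[0] - u[0]
    m = 0
    if u[0] > 0.0:
        kx[0] = 0.0
        ka[0] = 0.0
        kb[0] = 2.0 * u[0]
        m = 1
    # running right-tail totals
    aT = A0
    bT = B0
    for j in range(m):
        aT += ka[j]
        bT += kb[j]

    NEG = -1.0e300
    POS = 1.0e300

    for i in range(n - 1):
        wi = w[i]

        # lower clip point: V' crosses -wi
        ac = A0
        bc = B0
        jlo = 0
        lastx = NEG
        while jlo < m:
            # the left-limit test is only meaningful at the first knot of a
            # same-position group (zero-length segments are phantoms)
            if kx[jlo] > lastx and ac * kx[jlo] + bc > -wi:
                break
            ac += ka[jlo]
            bc += kb[jlo]
            lastx = kx[jlo]
            jlo += 1
        if ac > 0.0:
            t_lo = (-wi - bc) / ac
        else:
            t_lo = lastx
        if t_lo < lastx:
            t_lo = lastx
        a_lo = ac
        b_lo = bc

        # upper clip point: V' crosses +wi (walk from the right)
        ac = aT
        bc = bT
        jhi = m - 1
        nextx = POS
        while jhi >= 0:
            if kx[jhi] < nextx and ac * kx[jhi] + bc < wi:
                break
            ac -= ka[jhi]
            bc -= kb[jhi]
            nextx = kx[jhi]
            jhi -= 1
        if ac > 0.0:
            t_hi = (wi - bc) / ac
        else:
            t_hi = nextx
        if t_hi > nextx:
            t_hi = nextx
        a_hi = ac
        b_hi = bc
        if jhi < jlo - 1:
            # one jump crossed both clip levels: both walks absorbed the
            # same knot(s); collapse to a single clip point with a clean
            # -w -> +w jump so no slope/jump mass is double counted
            t_hi = t_lo
            a_hi = a_lo
            b_hi = b_lo
        if t_hi < t_lo:
            t_hi = t_lo

        tm[i] = t_lo
        tp[i] = t_hi

        # rebuild knot list for V_{i+1} into the other buffer
        u1 = u[i + 1]
        nm = 0
        zplaced = u1 <= 0.0
        # boundary knot at t_lo: from constant -wi to (a_lo, b_lo)
        if not zplaced and 0.0 < t_lo:
            ox[nm] = 0.0
            oa[nm] = 0.0
            ob[nm] = 2.0 * u1
            nm += 1
            zplaced = True
        ox[nm] = t_lo
        oa[nm] = a_lo
        ob[nm] = b_lo + wi
        nm += 1
        for j in range(jlo, jhi + 1):
            if not zplaced and 0.0 < kx[j]:
                ox[nm] = 0.0
                oa[nm] = 0.0
                ob[nm] = 2.0 * u1
                nm += 1
                zplaced = True
            ox[nm] = kx[j]
            oa[nm] = ka[j]
            ob[nm] = kb[j]
            nm += 1
        if not zplaced and 0.0 < t_hi:
            ox[nm] = 0.0
            oa[nm] = 0.0
            ob[nm] = 2.0 * u1
            nm += 1
            zplaced = True
        ox[nm] = t_hi
        oa[nm] = -a_hi
        ob[nm] = wi - b_hi
        nm += 1
        if not zplaced:
            ox[nm] = 0.0
            oa[nm] = 0.0
            ob[nm] = 2.0 * u1
            nm += 1

        # swap buffers
        tmpx, tmpa, tmpb = kx, ka, kb
        kx, ka, kb = ox, oa, ob
        ox, oa, ob = tmpx, tmpa, tmpb
        m = nm

        A0 = 1.0
        B0 = -y[i + 1] - wi - u1
        aT = A0
        bT = B0
        for j in range(m):
            aT += ka[j]
            bT += kb[j]

    # root of the final derivative
    ac = A0
    bc = B0
    j = 0
    lastx = NEG
    while j < m:
        if kx[j] > lastx and ac * kx[j] + bc > 0.0:
            break
        ac += ka[j]
        bc += kb[j]
        lastx = kx[j]
        j += 1
    if ac > 0.0:
        root = -bc / ac
    else:
        root = lastx
    if root < lastx:
        root = lastx

    x[n - 1] = root
    for i in range(n - 2, -1, -1):
        xi = x[i + 1]
        if xi < tm[i]:
            xi = tm[i]
        elif xi > tp[i]:
            xi = tp[i]
        x[i] = xi


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _dp_core_jit = njit(cache=False)(_dp_core)
except Exception:  # pragma: no cover
    _dp_core_jit = _dp_core


def weighted_fused_lasso(y, u, w):
    """Exact minimizer of the weighted 1D fused lasso.

    Parameters
    ----------
    y : array, shape (n,)
        Observations.
    u : array, shape (n,)
        Nonnegative elementwise l1 weights.
    w : array, shape (n-1,)
        Nonnegative fusion weights on successive differences.

    Returns
    -------
    x : array, shape (n,)
        The unique global minimizer.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    u = np.ascontiguousarray(u, dtype=np.float64)
    w = np.ascontiguousarray(w, dtype=np.float64)
    n = y.shape[0]
    if n == 0:
        return np.empty(0)
    if u.shape[0] != n or (n > 1 and w.shape[0] != n - 1):
        raise ValueError("weight arrays do not match signal length")
    if np.any(u < 0) or np.any(w < 0):
        raise ValueError("penalty weights must be nonnegative")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite values")
    cap = 3 * n + 8
    kx1 = np.empty(cap)
    ka1 = np.empty(cap)
    kb1 = np.empty(cap)
    kx2 = np.empty(cap)
    ka2 = np.empty(cap)
    kb2 = np.empty(cap)
    tm = np.empty(max(n - 1, 1))
    tp = np.empty(max(n - 1, 1))
    x = np.empty(n)
    _dp_core_jit(y, u, w, kx1, ka1, kb1, kx2, ka2, kb2, tm, tp, x)
    return x
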