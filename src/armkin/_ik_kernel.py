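"""Compiled inner loop of the inverse-kinematics solver.

Mirrors the pure-Python reference implementation in
:mod:`armkin.angle_methods` (``_solve_frame``) but processes a whole trial in
one call: sequential frames, warm-started, each solved by damped Gauss-Newton
with bound clipping. Kept separate so the readable reference path stays the
documentation of the algorithm; a unit test asserts both paths agree.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_DEG = math.pi / 180.0


@njit(cache=True)
def _fk_and_jac(q, clav, hum_len, fore_len, hand_off, w, targets, free_idx, lam, q_prev, r, J):
    """Residuals/Jacobian for one frame.

    ``w``/``targets``: weights and measured positions for (elbow, wrist, hand).
    Rows of ``r``/``J``: 3 per used keypoint, then one proximal row per free
    DOF. Returns the number of rows used.
    """
    p = q[0] * _DEG
    e = q[1] * _DEG
    rr = q[2] * _DEG
    f = q[3] * _DEG
    pr = q[4] * _DEG
    cp = math.cos(p); sp = math.sin(p)
    ce = math.cos(e); se = math.sin(e)
    cr = math.cos(rr); sr = math.sin(rr)
    cf = math.cos(f); sf = math.sin(f)
    cq = math.cos(pr); sq = math.sin(pr)

    # R_h = Ry(p) Rx(e) Ry(r)
    # Ry(p)Rx(e):
    a00 = cp; a01 = sp * se; a02 = sp * ce
    a10 = 0.0; a11 = ce; a12 = -se
    a20 = -sp; a21 = cp * se; a22 = cp * ce
    h00 = a00 * cr - a02 * sr; h01 = a01; h02 = a00 * sr + a02 * cr
    h10 = a10 * cr - a12 * sr; h11 = a11; h12 = a10 * sr + a12 * cr
    h20 = a20 * cr - a22 * sr; h21 = a21; h22 = a20 * sr + a22 * cr

    # R_hf = R_h Rz(f)
    g00 = h00 * cf + h01 * sf; g01 = -h00 * sf + h01 * cf; g02 = h02
    g10 = h10 * cf + h11 * sf; g11 = -h10 * sf + h11 * cf; g12 = h12
    g20 = h20 * cf + h21 * sf; g21 = -h20 * sf + h21 * cf; g22 = h22
    # R_f = R_hf Ry(pr)
    f00 = g00 * cq - g02 * sq; f01 = g01; f02 = g00 * sq + g02 * cq
    f10 = g10 * cq - g12 * sq; f11 = g11; f12 = g10 * sq + g12 * cq
    f20 = g20 * cq - g22 * sq; f21 = g21; f22 = g20 * sq + g22 * cq

    # positions
    sx, sy, sz = clav[0], clav[1], clav[2]
    ex_ = sx - h01 * hum_len; ey_ = sy - h11 * hum_len; ez_ = sz - h21 * hum_len
    wx = ex_ - f01 * fore_len; wy = ey_ - f11 * fore_len; wz = ez_ - f21 * fore_len
    hx = wx + f00 * hand_off[0] + f01 * hand_off[1] + f02 * hand_off[2]
    hy = wy + f10 * hand_off[0] + f11 * hand_off[1] + f12 * hand_off[2]
    hz = wz + f20 * hand_off[0] + f21 * hand_off[1] + f22 * hand_off[2]

    pos = np.empty((3, 3))
    pos[0, 0] = ex_; pos[0, 1] = ey_; pos[0, 2] = ez_
    pos[1, 0] = wx; pos[1, 1] = wy; pos[1, 2] = wz
    pos[2, 0] = hx; pos[2, 1] = hy; pos[2, 2] = hz

    # joint axes (world) and origins
    axes = np.empty((5, 3))
    axes[0, 0] = 0.0; axes[0, 1] = 1.0; axes[0, 2] = 0.0
    axes[1, 0] = cp; axes[1, 1] = 0.0; axes[1, 2] = -sp  # Ry(p) @ ex
    axes[2, 0] = h01; axes[2, 1] = h11; axes[2, 2] = h21  # humerus Y
    axes[3, 0] = h02; axes[3, 1] = h12; axes[3, 2] = h22  # humerus Z
    axes[4, 0] = g01; axes[4, 1] = g11; axes[4, 2] = g21  # forearm long axis
    orig = np.empty((5, 3))
    for j in range(3):
        orig[0, j] = clav[j]
        orig[1, j] = clav[j]
        orig[2, j] = clav[j]
        orig[3, j] = pos[0, j]
        orig[4, j] = pos[0, j]

    nf = free_idx.shape[0]
    row = 0
    for kp in range(3):
        if w[kp] <= 0.0:
            continue
        sw = math.sqrt(w[kp])
        for j in range(3):
            r[row + j] = sw * (pos[kp, j] - targets[kp, j])
        for col in range(nf):
            d = free_idx[col]
            moves = (d < 3) or (d == 3 and kp >= 1) or (d == 4 and kp == 2)
            if moves:
                rx = pos[kp, 0] - orig[d, 0]
                ry = pos[kp, 1] - orig[d, 1]
                rz = pos[kp, 2] - orig[d, 2]
                J[row + 0, col] = sw * _DEG * (axes[d, 1] * rz - axes[d, 2] * ry)
                J[row + 1, col] = sw * _DEG * (axes[d, 2] * rx - axes[d, 0] * rz)
                J[row + 2, col] = sw * _DEG * (axes[d, 0] * ry - axes[d, 1] * rx)
            else:
                J[row + 0, col] = 0.0
                J[row + 1, col] = 0.0
                J[row + 2, col] = 0.0
        row += 3
    sl = math.sqrt(lam)
    for col in range(nf):
        r[row] = sl * (q[free_idx[col]] - q_prev[free_idx[col]])
        for c2 in range(nf):
            J[row, c2] = sl if c2 == col else 0.0
        row += 1
    return row


@njit(cache=True)
def solve_trial(
    targets,  # (n, 3, 3): measured elbow/wrist/hand positions (mm)
    weights,  # (n, 3): per-frame weights (0 = unused/invalid)
    solve_mask,  # (n,) bool: False = frame unresolved, hold previous pose
    clav,  # (3,) clavicle offset mm
    hum_len,
    fore_len,
    hand_off,  # (3,) mm
    q_neutral,  # (5,) deg
    free_idx,  # indices of free DOFs
    lo,
    hi,  # per-free-DOF bounds deg
    lam,  # proximal penalty weight
    tol,  # convergence threshold on squared step (deg^2)
    gtol,  # convergence threshold on the cost gradient (mm^2/deg)
    max_iter,
    warm_start,  # bool
):
    """Sequential per-frame damped Gauss-Newton. Returns (poses, costs, iters)."""
    n = targets.shape[0]
    nf = free_idx.shape[0]
    nrows = 9 + nf
    poses = np.zeros((n, 5))
    costs = np.zeros(n)
    iters = np.zeros(n, dtype=np.int64)

    q_prev = q_neutral.copy()
    for j in range(nf):
        v = q_prev[free_idx[j]]
        if v < lo[j]:
            v = lo[j]
        if v > hi[j]:
            v = hi[j]
        q_prev[free_idx[j]] = v

    r = np.zeros(nrows)
    J = np.zeros((nrows, nf))
    r_new = np.zeros(nrows)
    J_new = np.zeros((nrows, nf))

    for i in range(n):
        if not solve_mask[i]:
            poses[i] = q_prev
            continue
        q = q_prev.copy() if warm_start else q_neutral.copy()
        m = _fk_and_jac(
            q, clav, hum_len, fore_len, hand_off, weights[i], targets[i],
            free_idx, lam, q_prev, r, J,
        )
        cost = 0.0
        for k in range(m):
            cost += r[k] * r[k]
        mu = 1e-4
        n_it = 0
        for _ in range(max_iter):
            n_it += 1
            g = np.zeros(nf)
            H = np.zeros((nf, nf))
            for k in range(m):
                for c in range(nf):
                    g[c] += J[k, c] * r[k]
                    for c2 in range(c, nf):
                        H[c, c2] += J[k, c] * J[k, c2]
            gmax = 0.0
            for c in range(nf):
                if abs(g[c]) > gmax:
                    gmax = abs(g[c])
            if gmax < gtol:
                break
            for c in range(nf):
                for c2 in range(c + 1, nf):
                    H[c2, c] = H[c, c2]
            accepted = False
            step_sq = 0.0
            for _try in range(20):
                A = H.copy()
                for c in range(nf):
                    A[c, c] += mu
                step = np.linalg.solve(A, -g)
                q_new = q.copy()
                for c in range(nf):
                    v = q[free_idx[c]] + step[c]
                    if v < lo[c]:
                        v = lo[c]
                    if v > hi[c]:
                        v = hi[c]
                    q_new[free_idx[c]] = v
                m2 = _fk_and_jac(
                    q_new, clav, hum_len, fore_len, hand_off, weights[i],
                    targets[i], free_idx, lam, q_prev, r_new, J_new,
                )
                cost_new = 0.0
                for k in range(m2):
                    cost_new += r_new[k] * r_new[k]
                if cost_new <= cost:
                    step_sq = 0.0
                    for c in range(nf):
                        d = q_new[free_idx[c]] - q[free_idx[c]]
                        step_sq += d * d
                    q = q_new
                    tmp = r; r = r_new; r_new = tmp
                    tmpJ = J; J = J_new; J_new = tmpJ
                    cost = cost_new
                    mu = max(mu * 0.1, 1e-12)
                    accepted = True
                    break
                mu *= 4.0
            if (not accepted) or step_sq < tol or cost < 1e-14:
                break
        # report the keypoint objective without the proximal penalty term
        penalty = 0.0
        for c in range(nf):
            d = q[free_idx[c]] - q_prev[free_idx[c]]
            penalty += lam * d * d
        poses[i] = q
        costs[i] = max(cost - penalty, 0.0)
        iters[i] = n_it
        q_prev = q
    return poses, costs, iters
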