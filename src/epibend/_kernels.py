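"""Numba-compiled inner loops of the vertex dynamics model.

The tissue is a single row of quadrilateral cells sharing two vertex chains:
``L`` (luminal, shape (n+1, 2)) and ``B`` (basal, shape (n+1, 2)); cell j
owns luminal vertices (j, j+1) and basal vertices (j, j+1). All kernels
mutate their array arguments in place.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def nuclear_depth_scalar(tau: float, tau_div: float, gamma: float) -> float:
    """Piecewise-linear nuclear depth d(τ): basalward excursion to γ during
    the first half of the cycle, return to the luminal side by 0.95·τ_div,
    then d = 0 through mitosis."""
    r = tau / tau_div
    if r <= 0.5:
        return 2.0 * gamma * r
    if r <= 0.95:
        return (0.95 - r) * gamma / 0.45
    return 0.0


@njit(cache=False)
def compute_targets(tau, tau_div, gamma, xi_max, xi_min, a_t, b_t):
    n = tau.shape[0]
    for j in range(n):
        d = nuclear_depth_scalar(tau[j], tau_div[j], gamma)
        a_t[j] = (xi_min - xi_max) * d + xi_max
        b_t[j] = (xi_max - xi_min) * d + xi_min


@njit(cache=False)
def compute_forces(L, B, a_t, b_t, ka, kb, kl, kA, kth, A_star, l_star, FL, FB):
    """Analytic −∇U of the five-term potential; accumulates into FL/FB
    (zeroed here)."""
    n = a_t.shape[0]
    FL[:] = 0.0
    FB[:] = 0.0

    # luminal and basal edge springs
    for j in range(n):
        ex = L[j + 1, 0] - L[j, 0]
        ey = L[j + 1, 1] - L[j, 1]
        a = (ex * ex + ey * ey) ** 0.5
        c = ka * (a - a_t[j]) / a
        FL[j, 0] += c * ex
        FL[j, 1] += c * ey
        FL[j + 1, 0] -= c * ex
        FL[j + 1, 1] -= c * ey

        ex = B[j + 1, 0] - B[j, 0]
        ey = B[j + 1, 1] - B[j, 1]
        b = (ex * ex + ey * ey) ** 0.5
        c = kb * (b - b_t[j]) / b
        FB[j, 0] += c * ex
        FB[j, 1] += c * ey
        FB[j + 1, 0] -= c * ex
        FB[j + 1, 1] -= c * ey

    # lateral springs: l_j is the mean of the cell's two lateral lengths
    lat = np.empty(n + 1)
    for m in range(n + 1):
        lat[m] = (
            (L[m, 0] - B[m, 0]) ** 2 + (L[m, 1] - B[m, 1]) ** 2
        ) ** 0.5
    for m in range(n + 1):
        g = 0.0
        if m > 0:
            g += 0.5 * kl * (0.5 * (lat[m - 1] + lat[m]) - l_star)
        if m < n:
            g += 0.5 * kl * (0.5 * (lat[m] + lat[m + 1]) - l_star)
        ux = (L[m, 0] - B[m, 0]) / lat[m]
        uy = (L[m, 1] - B[m, 1]) / lat[m]
        FL[m, 0] -= g * ux
        FL[m, 1] -= g * uy
        FB[m, 0] += g * ux
        FB[m, 1] += g * uy

    # area preservation: quad (L[j], L[j+1], B[j+1], B[j]), shoelace area
    for j in range(n):
        x0, y0 = L[j, 0], L[j, 1]
        x1, y1 = L[j + 1, 0], L[j + 1, 1]
        x2, y2 = B[j + 1, 0], B[j + 1, 1]
        x3, y3 = B[j, 0], B[j, 1]
        As = 0.5 * (
            x0 * y1 - x1 * y0 + x1 * y2 - x2 * y1 + x2 * y3 - x3 * y2 + x3 * y0 - x0 * y3
        )
        sgn = 1.0 if As >= 0.0 else -1.0
        c = kA * (abs(As) - A_star) * sgn
        # −c · ∂As/∂vertex with ∂As/∂(x_k, y_k) = 0.5(y_{k+1}−y_{k−1}, x_{k−1}−x_{k+1})
        FL[j, 0] -= c * 0.5 * (y1 - y3)
        FL[j, 1] -= c * 0.5 * (x3 - x1)
        FL[j + 1, 0] -= c * 0.5 * (y2 - y0)
        FL[j + 1, 1] -= c * 0.5 * (x0 - x2)
        FB[j + 1, 0] -= c * 0.5 * (y3 - y1)
        FB[j + 1, 1] -= c * 0.5 * (x1 - x3)
        FB[j, 0] -= c * 0.5 * (y0 - y2)
        FB[j, 1] -= c * 0.5 * (x2 - x0)

    # bending of each chain: θ_i is the turning angle at interior vertex i
    for chain in range(2):
        P = L if chain == 0 else B
        F = FL if chain == 0 else FB
        for i in range(1, n):
            ux = P[i, 0] - P[i - 1, 0]
            uy = P[i, 1] - P[i - 1, 1]
            wx = P[i + 1, 0] - P[i, 0]
            wy = P[i + 1, 1] - P[i, 1]
            cross = ux * wy - uy * wx
            dot = ux * wx + uy * wy
            theta = np.arctan2(cross, dot)
            c = kth * theta
            iu2 = 1.0 / (ux * ux + uy * uy)
            iw2 = 1.0 / (wx * wx + wy * wy)
            # ∇θ: perp(v) = (−v_y, v_x)
            gpx = -wy * iw2  # ∂θ/∂P[i+1]
            gpy = wx * iw2
            gmx = -uy * iu2  # ∂θ/∂P[i−1]
            gmy = ux * iu2
            F[i + 1, 0] -= c * gpx
            F[i + 1, 1] -= c * gpy
            F[i - 1, 0] -= c * gmx
            F[i - 1, 1] -= c * gmy
            F[i, 0] -= c * (-gpx - gmx)
            F[i, 1] -= c * (-gpy - gmy)


@njit(cache=False)
def run_steps(
    L,
    B,
    cvel,
    tau,
    tau_div,
    frozen,
    n_steps,
    dt,
    eta,
    ka,
    kb,
    kl,
    kA,
    kth,
    A_star,
    l_star,
    xi_max,
    xi_min,
    gamma,
    use_local_velocity,
):
    """Advance the tissue ``n_steps`` forward-Euler steps of
    η(ṙ_i − v_i) = −∇_i U with the lagged local-velocity scheme: v_i is the
    mean of the previous-step centroid velocities of the cells containing
    vertex i (and is shared by the luminal and basal vertex of the same
    index, which border the same cells). Timers of non-frozen cells advance
    by dt each step; targets follow d(τ) continuously. No divisions happen
    inside this kernel — the caller sizes ``n_steps`` to stop at the next
    cell-cycle event.
    """
    n = tau.shape[0]
    a_t = np.empty(n)
    b_t = np.empty(n)
    FL = np.empty((n + 1, 2))
    FB = np.empty((n + 1, 2))
    vx = np.empty(n + 1)
    vy = np.empty(n + 1)
    cold = np.empty((n, 2))
    inv_eta = 1.0 / eta

    for _ in range(n_steps):
        compute_targets(tau, tau_div, gamma, xi_max, xi_min, a_t, b_t)
        compute_forces(L, B, a_t, b_t, ka, kb, kl, kA, kth, A_star, l_star, FL, FB)

        if use_local_velocity:
            for i in range(n + 1):
                sx = 0.0
                sy = 0.0
                c = 0.0
                if i > 0:
                    sx += cvel[i - 1, 0]
                    sy += cvel[i - 1, 1]
                    c += 1.0
                if i < n:
                    sx += cvel[i, 0]
                    sy += cvel[i, 1]
                    c += 1.0
                vx[i] = sx / c
                vy[i] = sy / c
        else:
            vx[:] = 0.0
            vy[:] = 0.0

        for j in range(n):
            cold[j, 0] = 0.25 * (L[j, 0] + L[j + 1, 0] + B[j, 0] + B[j + 1, 0])
            cold[j, 1] = 0.25 * (L[j, 1] + L[j + 1, 1] + B[j, 1] + B[j + 1, 1])

        for i in range(n + 1):
            L[i, 0] += dt * (vx[i] + FL[i, 0] * inv_eta)
            L[i, 1] += dt * (vy[i] + FL[i, 1] * inv_eta)
            B[i, 0] += dt * (vx[i] + FB[i, 0] * inv_eta)
            B[i, 1] += dt * (vy[i] + FB[i, 1] * inv_eta)

        for j in range(n):
            cx = 0.25 * (L[j, 0] + L[j + 1, 0] + B[j, 0] + B[j + 1, 0])
            cy = 0.25 * (L[j, 1] + L[j + 1, 1] + B[j, 1] + B[j + 1, 1])
            cvel[j, 0] = (cx - cold[j, 0]) / dt
            cvel[j, 1] = (cy - cold[j, 1]) / dt

        for j in range(n):
            if not frozen[j]:
                tau[j] += dt
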