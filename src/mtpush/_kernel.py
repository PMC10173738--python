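"""Numba time-stepping kernel for the nucleus-centering model.

The kernel is a flat-array transcription of the update rules defined in
:mod:`mtpush.mt_dynamics` and :mod:`mtpush.mechanics`:

per step (forward Euler, two sub-steps):
  1. per-MT contact test and force/torque assembly from the state at the start
     of the step (polymerization force capped by Euler buckling with the
     geometric floor);
  2. MT growth/shrinkage and catastrophe-clock update (clock scheme: the clock
     runs faster by tau*/rescaled(tau*) during contact), instantaneous rescue at
     zero length with fresh catastrophe time and axis angle;
  3. nucleus translation with per-axis series drag (Stokes sphere in series
     with the summed slender-body drag of the longest MT per anchor) and
     rotation with the sphere rotational drag.

Left/right correlation modes: 0 = independent (fresh axis angle at every
rescue), 1 = correlated (a rescued left-side MT reuses the mirrored current
angle of its right-side partner), 2 = mirrored (diagnostic: only right-side MTs are integrated
and the left half is their exact mirror image, so the net longitudinal force is
identically zero and a centered nucleus must stay centered to machine
precision).

Randomness comes from numba's internal NumPy legacy generator, seeded once per
run; a run is therefore bit-reproducible from its seed.
"""

import math

import numpy as np
from numba import njit

MODE_INDEPENDENT = 0
MODE_CORRELATED = 1
MODE_MIRRORED = 2


@njit(cache=False)
def _draw_theta(spread):
    """Zero-centered normal with scale ``spread`` truncated to (-pi/2, pi/2)."""
    if spread <= 0.0:
        return 0.0
    half_pi = math.pi / 2.0
    while True:
        th = np.random.normal(0.0, spread)
        if -half_pi < th < half_pi:
            return th


@njit(cache=False)
def run_sim(
    seed,
    n_steps,
    out_every,
    dt,
    L,
    R,
    rnuc,
    rmt,
    eta,
    vg,
    vc,
    vs,
    fs,
    kappa,
    tau0c,
    n_cat,
    t_cat,
    theta_spread,
    mode,
    x0,
    y0,
    omega0,
    psi,
    side,
    anchor,
    n_anchors,
    theta,
    tau_star,
):
    np.random.seed(seed)
    n = psi.shape[0]

    length = np.zeros(n)
    clock = np.zeros(n)
    phase = np.zeros(n, dtype=np.int64)  # 0 growing, 1 shrinking
    ref_len = np.full(n, -1.0)
    contact = np.zeros(n, dtype=np.int64)

    x, y, om = x0, y0, omega0
    fp = fs * (1.0 - vc / vg)
    vratio = vc / vg
    kap_pi2 = kappa * math.pi**2
    znuc_t = 6.0 * math.pi * eta * rnuc
    znuc_r = 8.0 * math.pi * eta * rnuc**3
    x_max = L - rnuc
    y_max = R - rnuc
    drag_factor = 2.0 if mode == MODE_MIRRORED else 1.0

    best_len = np.zeros(n_anchors)
    best_th = np.zeros(n_anchors)

    n_out = n_steps // out_every + 1
    out_t = np.empty(n_out)
    out_x = np.empty(n_out)
    out_y = np.empty(n_out)
    out_om = np.empty(n_out)
    out_t[0] = 0.0
    out_x[0] = x
    out_y[0] = y
    out_om[0] = om
    k_out = 1
    clamp_events = 0

    for istep in range(n_steps):
        # -- forces from the state at the start of the step ------------------
        fx_tot = 0.0
        fy_tot = 0.0
        tq_tot = 0.0
        for i in range(n):
            contact[i] = 0
            if phase[i] != 0:
                continue
            a = om + psi[i]
            ca = math.cos(a)
            sa = math.sin(a)
            ax = x + rnuc * ca
            dx = side[i] * math.cos(theta[i])
            dy = math.sin(theta[i])
            tx = ax + length[i] * dx
            if side[i] > 0:
                touching = tx >= L
                gap = L - ax
            else:
                touching = tx <= -L
                gap = ax + L
            if not touching:
                continue
            contact[i] = 1
            if ref_len[i] < 0.0:
                absdx = abs(dx)
                if absdx > 1e-12:
                    ref_len[i] = max(gap / absdx, 1e-9)
                else:
                    ref_len[i] = 1e18
            li = max(length[i], 1e-9)
            fe = kap_pi2 / (li * li)
            fe_floor = kap_pi2 / (ref_len[i] * ref_len[i])
            if fe_floor > fe:
                fe = fe_floor
            f = fp if fp <= fe else fe
            fxi = -f * dx
            fyi = -f * dy
            fx_tot += fxi
            fy_tot += fyi
            tq_tot += rnuc * ca * fyi - rnuc * sa * fxi

        if mode == MODE_MIRRORED:
            # the mirror half contributes the exact opposite longitudinal
            # force, an equal transverse force, and the opposite torque
            fx_tot = 0.0
            fy_tot *= 2.0
            tq_tot = 0.0

        # -- drag: longest MT per anchor ------------------------------------
        for j in range(n_anchors):
            best_len[j] = 0.0
        for i in range(n):
            if length[i] > best_len[anchor[i]]:
                best_len[anchor[i]] = length[i]
                best_th[anchor[i]] = theta[i]
        zpar = 0.0
        zperp = 0.0
        for j in range(n_anchors):
            l = best_len[j]
            if l <= 0.0:
                continue
            th = best_th[j]
            lpar = l * abs(math.cos(th))
            lperp = l * abs(math.sin(th))
            if lpar > 0.0:
                arg = lpar / (2.0 * rmt)
                if arg > 1.0:
                    denom = math.log(arg) - 0.2
                    if denom > 0.0:
                        zpar += 2.0 * math.pi * eta * lpar / denom
            if lperp > 0.0:
                arg = lperp / (2.0 * rmt)
                if arg > 1.0:
                    denom = math.log(arg) + 0.84
                    if denom > 0.0:
                        zperp += 4.0 * math.pi * eta * lperp / denom
        zpar *= drag_factor
        zperp *= drag_factor
        zx = znuc_t if zpar == 0.0 else 1.0 / (1.0 / znuc_t + 1.0 / zpar)
        zy = znuc_t if zperp == 0.0 else 1.0 / (1.0 / znuc_t + 1.0 / zperp)

        # -- MT growth / catastrophe / rescue -------------------------------
        for i in range(n):
            if phase[i] == 0:
                if contact[i] == 1:
                    if tau_star[i] > tau0c:
                        rescaled = tau0c + (tau_star[i] - tau0c) * vratio
                    else:
                        rescaled = tau0c
                    length[i] += vc * dt
                    if rescaled > 0.0:
                        clock[i] += dt * tau_star[i] / rescaled
                    else:
                        clock[i] = tau_star[i]
                else:
                    length[i] += vg * dt
                    clock[i] += dt
                if clock[i] >= tau_star[i]:
                    phase[i] = 1
            else:
                length[i] -= vs * dt
                if length[i] <= 0.0:
                    length[i] = 0.0
                    phase[i] = 0
                    clock[i] = 0.0
                    ref_len[i] = -1.0
                    tau_star[i] = np.random.gamma(n_cat, t_cat)
                    if mode == MODE_CORRELATED and i >= n // 2:
                        theta[i] = theta[i - n // 2]
                    else:
                        theta[i] = _draw_theta(theta_spread)

        # -- nucleus forward Euler update -----------------------------------
        x += fx_tot / zx * dt
        y += fy_tot / zy * dt
        om += tq_tot / znuc_r * dt
        if x > x_max:
            x = x_max
            clamp_events += 1
        elif x < -x_max:
            x = -x_max
            clamp_events += 1
        if y > y_max:
            y = y_max
        elif y < -y_max:
            y = -y_max

        if (istep + 1) % out_every == 0:
            out_t[k_out] = (istep + 1) * dt
            out_x[k_out] = x
            out_y[k_out] = y
            out_om[k_out] = om
            k_out += 1

    return out_t[:k_out], out_x[:k_out], out_y[:k_out], out_om[:k_out], clamp_events
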