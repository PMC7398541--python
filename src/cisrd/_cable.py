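"""Numba kernel for the stochastic multicompartment cable model.

One time step advances (i) the Hodgkin–Huxley gating variables at every
Ranvier node with an exact (Rush–Larsen) exponential update plus Fox
diffusion-approximation channel noise, and (ii) the membrane potentials
of all compartments with a semi-implicit Crank–Nicolson step of the
cable equation (second-order in dt for the linear part; ionic
conductances frozen at the updated gate values), solved as a tridiagonal
system by the Thomas algorithm.  Rate functions are tabulated on a 0.1 mV grid for a
given dt before the loop.

Units: mV, ms, nS, pF (=> currents in pA).  V is membrane depolarization
relative to rest (rest = 0).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def run_cable(n_steps, dt,
              c, gl, el, ga_lo,            # per-compartment passive arrays
              node_comp, gna_max, gk_max,  # node indexing and max conductances
              e_na, e_k,
              inf_m, exp_m, a_m, b_m,
              inf_h, exp_h, a_h, b_h,
              inf_n, exp_n, a_n, b_n,
              v0_tab, dv_tab,
              n_na, n_k, noise_scale,
              drive_src, drive_amp, act,   # act[src, comp]: pA per mA of electrode current
              rec_comp, thresh, lockout,
              noise, noise_stride,         # pre-drawn unit normals; applied every noise_stride steps
              v_out, store_stride):
    """Integrate the cable and return spike times (ms) at ``rec_comp``.

    ``drive_src[t]`` is the active electrode index (-1 for none) and
    ``drive_amp[t]`` its signed current (mA) at step t; ``act`` maps that
    current to the extracellular axial drive of each compartment.
    ``noise`` holds pre-drawn unit normals for the Fox gate perturbations
    (empty disables noise); they are injected every ``noise_stride`` steps
    with variance scaled by the stride so the integrated noise power is
    preserved.  When ``store_stride > 0`` the full V matrix is written
    into ``v_out`` every ``store_stride`` steps.
    """
    use_noise = noise_scale > 0.0 and noise.shape[0] > 0
    ncomp = c.shape[0]
    nnode = node_comp.shape[0]
    ntab = inf_m.shape[0]

    v = np.zeros(ncomp)
    m = np.empty(nnode)
    h = np.empty(nnode)
    n_g = np.empty(nnode)
    # rest values from the tables at V = 0
    i0 = int((0.0 - v0_tab) / dv_tab + 0.5)
    for j in range(nnode):
        m[j] = inf_m[i0]
        h[j] = inf_h[i0]
        n_g[j] = inf_n[i0]

    gna_eff = np.zeros(nnode)
    gk_eff = np.zeros(nnode)

    # Thomas algorithm workspace
    bb = np.empty(ncomp)
    dd = np.empty(ncomp)
    cw = np.empty(ncomp)

    max_spikes = int(n_steps * dt / lockout) + 2
    spikes = np.empty(max_spikes)
    nspk = 0
    last_spike = -1e9
    prev_above = False

    inv_dt = 1.0 / dt
    inv_dv = 1.0 / dv_tab
    sq_na = np.sqrt(dt * noise_stride / n_na)
    sq_k = np.sqrt(dt * noise_stride / n_k)

    for step in range(n_steps):
        t = step * dt
        if store_stride > 0 and step % store_stride == 0:
            # V at the *start* of the step, i.e. at t = step*dt
            v_out[step // store_stride, :] = v
        inject = use_noise and step % noise_stride == 0
        irow = step // noise_stride
        # --- gating at nodes (uses V from the previous step) ---
        for j in range(nnode):
            vk = v[node_comp[j]]
            iv = int((vk - v0_tab) * inv_dv + 0.5)
            if iv < 0:
                iv = 0
            elif iv >= ntab:
                iv = ntab - 1
            mm = inf_m[iv] + (m[j] - inf_m[iv]) * exp_m[iv]
            hh = inf_h[iv] + (h[j] - inf_h[iv]) * exp_h[iv]
            nn = inf_n[iv] + (n_g[j] - inf_n[iv]) * exp_n[iv]
            if inject:
                var_m = a_m[iv] * (1.0 - mm) + b_m[iv] * mm
                if var_m > 0.0:
                    mm += noise_scale * np.sqrt(var_m) * sq_na * noise[irow, 3 * j]
                var_h = a_h[iv] * (1.0 - hh) + b_h[iv] * hh
                if var_h > 0.0:
                    hh += noise_scale * np.sqrt(var_h) * sq_na * noise[irow, 3 * j + 1]
                var_n = a_n[iv] * (1.0 - nn) + b_n[iv] * nn
                if var_n > 0.0:
                    nn += noise_scale * np.sqrt(var_n) * sq_k * noise[irow, 3 * j + 2]
                if mm < 0.0:
                    mm = 0.0
                elif mm > 1.0:
                    mm = 1.0
                if hh < 0.0:
                    hh = 0.0
                elif hh > 1.0:
                    hh = 1.0
                if nn < 0.0:
                    nn = 0.0
                elif nn > 1.0:
                    nn = 1.0
            m[j] = mm
            h[j] = hh
            n_g[j] = nn
            gna_eff[j] = gna_max[j] * mm * mm * mm * hh
            gk_eff[j] = gk_max[j] * nn * nn * nn * nn

        # --- assemble the tridiagonal system (Crank-Nicolson: the linear
        # membrane + axial operator is split half explicit, half implicit;
        # ionic conductances are frozen at the updated gate values) ---
        src = drive_src[step]
        amp = drive_amp[step]
        for k in range(ncomp):
            ga_l = ga_lo[k]
            ga_u = ga_lo[k + 1] if k + 1 < ncomp else 0.0
            g_tot = gl[k] + ga_l + ga_u
            rhs = (c[k] * inv_dt - 0.5 * g_tot) * v[k] + gl[k] * el[k]
            if k > 0:
                rhs += 0.5 * ga_l * v[k - 1]
            if k + 1 < ncomp:
                rhs += 0.5 * ga_u * v[k + 1]
            if src >= 0:
                rhs += amp * act[src, k]
            bb[k] = c[k] * inv_dt + 0.5 * g_tot
            dd[k] = rhs
        for j in range(nnode):
            k = node_comp[j]
            g_ion = gna_eff[j] + gk_eff[j]
            bb[k] += 0.5 * g_ion
            dd[k] += (gna_eff[j] * e_na + gk_eff[j] * e_k
                      - 0.5 * g_ion * v[k])

        # --- Thomas solve: sub/super diagonals are -ga_lo[k]/2 ---
        inv0 = 1.0 / bb[0]
        cw[0] = -0.5 * ga_lo[1] * inv0 if ncomp > 1 else 0.0
        dd[0] = dd[0] * inv0
        for k in range(1, ncomp):
            a_k = -0.5 * ga_lo[k]
            inv = 1.0 / (bb[k] - a_k * cw[k - 1])
            if k + 1 < ncomp:
                cw[k] = -0.5 * ga_lo[k + 1] * inv
            dd[k] = (dd[k] - a_k * dd[k - 1]) * inv
        v[ncomp - 1] = dd[ncomp - 1]
        for k in range(ncomp - 2, -1, -1):
            v[k] = dd[k] - cw[k] * v[k + 1]

        if not np.isfinite(v[rec_comp]):
            # signal numerical failure with a sentinel spike array
            spikes[0] = np.nan
            return spikes[:1]

        # --- spike detection at the record node ---
        above = v[rec_comp] >= thresh
        if above and not prev_above and (t - last_spike) >= lockout:
            spikes[nspk] = t
            nspk += 1
            last_spike = t
        prev_above = above

    return spikes[:nspk]
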