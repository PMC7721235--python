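"""Numba kernels for the stochastic neural / hemodynamic integration.

The Euler-Maruyama loop is inherently sequential, so it is compiled rather
than vectorized.  Noise is pre-generated by the caller (already scaled by
sigma*sqrt(dt)) to keep seeding in numpy Generator land.  The hemodynamic
stage may be integrated on a coarser grid (``bw_stride`` neural steps per
hemodynamic step, driven by the window-averaged gating activity): its time
constants are of order 1 s, an order of magnitude slower than the neural
kinetics.
"""

import numpy as np
from numba import njit

_FLOW_FLOOR = 1e-6


@njit(cache=True, fastmath=True)
def _firing_rate(u, d):
    # H(x) with u = a*x - b; removable singularity at u = 0 (limit 1/d)
    if abs(u) < 1e-9:
        return 1.0 / d
    return u / (1.0 - np.exp(-d * u))


@njit(cache=True, fastmath=True)
def integrate_gating(GC, wJ, I, dt, n_steps, noise, a, b, d, gamma_k, tau_s, S0):
    """Euler-Maruyama integration of the synaptic gating variables.

    Returns (trajectory[n_steps, n], clamp_count, diverged_step) where
    trajectory[t] is the state after step t+1; diverged_step is -1 if the
    run stayed finite.
    """
    n = wJ.shape[0]
    S = S0.copy()
    out = np.empty((n_steps, n))
    clamps = 0
    for t in range(n_steps):
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += GC[i, j] * S[j]
            out[t, i] = acc
        for i in range(n):
            xi = wJ[i] * S[i] + out[t, i] + I[i]
            u = a * xi - b
            H = _firing_rate(u, d)
            drift = -S[i] / tau_s + (1.0 - S[i]) * gamma_k * H
            Si = S[i] + dt * drift + noise[t, i]
            if Si < 0.0:
                Si = 0.0
                clamps += 1
            elif Si > 1.0:
                Si = 1.0
                clamps += 1
            elif not (Si <= 1.0):
                # NaN falls through both comparisons
                return out, clamps, t
            S[i] = Si
            out[t, i] = Si
    return out, clamps, -1


@njit(cache=True, fastmath=True)
def balloon_windkessel_states(z, dt, kappa, gamma_h, tau_h, alpha_g, rho):
    """Integrate the four hemodynamic states driven by neural activity z[n, T].

    Initial state per region is (s, f, v, q) = (0, 1, 1, 1).  Returns
    (s, f, v, q) trajectories of shape [n, T] (state after each input sample)
    and the count of flow/volume floor events.
    """
    n, T = z.shape
    inv_alpha = 1.0 / alpha_g
    s_out = np.empty((n, T))
    f_out = np.empty((n, T))
    v_out = np.empty((n, T))
    q_out = np.empty((n, T))
    floors = 0
    for i in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            ds = z[i, t] - kappa * s - gamma_h * (f - 1.0)
            df = s
            dv = (f - v ** inv_alpha) / tau_h
            dq = ((f / rho) * (1.0 - (1.0 - rho) ** (1.0 / f))
                  - q * v ** (inv_alpha - 1.0)) / tau_h
            s += dt * ds
            f += dt * df
            v += dt * dv
            q += dt * dq
            if f < _FLOW_FLOOR:
                f = _FLOW_FLOOR
                floors += 1
            if v < _FLOW_FLOOR:
                v = _FLOW_FLOOR
                floors += 1
            s_out[i, t] = s
            f_out[i, t] = f
            v_out[i, t] = v
            q_out[i, t] = q
    return s_out, f_out, v_out, q_out, floors


@njit(cache=True, fastmath=True)
def simulate_bold(GC, wJ, I, dt, n_steps, noise, decim, bw_stride,
                  a, b, d, gamma_k, tau_s,
                  kappa, gamma_h, tau_h, alpha_g, rho, V0, k1, k2, k3, S0):
    """Fused neural + hemodynamic integration emitting decimated BOLD.

    The hemodynamic states advance every ``bw_stride`` neural steps with step
    dt*bw_stride, driven by the gating activity averaged over that window.
    BOLD is sampled every ``decim`` steps (``decim`` must be a multiple of
    ``bw_stride``).  Returns (bold[n, n_out], clamp_count, floor_count,
    diverged_step).
    """
    n = wJ.shape[0]
    S = S0.copy()
    hs = np.zeros(n)
    hf = np.ones(n)
    hv = np.ones(n)
    hq = np.ones(n)
    z_acc = np.zeros(n)
    x = np.empty(n)
    inv_alpha = 1.0 / alpha_g
    dt_bw = dt * bw_stride
    n_out = n_steps // decim
    bold = np.empty((n, n_out))
    clamps = 0
    floors = 0
    out_i = 0
    for t in range(n_steps):
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += GC[i, j] * S[j]
            x[i] = acc
        for i in range(n):
            xi = wJ[i] * S[i] + x[i] + I[i]
            u = a * xi - b
            H = _firing_rate(u, d)
            drift = -S[i] / tau_s + (1.0 - S[i]) * gamma_k * H
            Si = S[i] + dt * drift + noise[t, i]
            if Si < 0.0:
                Si = 0.0
                clamps += 1
            elif Si > 1.0:
                Si = 1.0
                clamps += 1
            elif not (Si <= 1.0):
                return bold, clamps, floors, t
            S[i] = Si
            z_acc[i] += Si
        if (t + 1) % bw_stride == 0:
            for i in range(n):
                z = z_acc[i] / bw_stride
                z_acc[i] = 0.0
                ds = z - kappa * hs[i] - gamma_h * (hf[i] - 1.0)
                df = hs[i]
                dv = (hf[i] - hv[i] ** inv_alpha) / tau_h
                dq = ((hf[i] / rho) * (1.0 - (1.0 - rho) ** (1.0 / hf[i]))
                      - hq[i] * hv[i] ** (inv_alpha - 1.0)) / tau_h
                hs[i] += dt_bw * ds
                hf[i] += dt_bw * df
                hv[i] += dt_bw * dv
                hq[i] += dt_bw * dq
                if hf[i] < _FLOW_FLOOR:
                    hf[i] = _FLOW_FLOOR
                    floors += 1
                if hv[i] < _FLOW_FLOOR:
                    hv[i] = _FLOW_FLOOR
                    floors += 1
        if (t + 1) % decim == 0:
            for i in range(n):
                bold[i, out_i] = V0 * (k1 * (1.0 - hq[i])
                                       + k2 * (1.0 - hq[i] / hv[i])
                                       + k3 * (1.0 - hv[i]))
            out_i += 1
    return bold, clamps, floors, -1
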