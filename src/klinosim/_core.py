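"""Compiled inner loop for full chemotaxis assays.

One forward-Euler step advances, in order: concentration sensing at the
current position, the ring-buffered averaging windows of the sensory
transducer, a synchronous update of the eight stateful neurons, recomputation
of releases, and finally the heading and position of the point worm.  The
loop is numerically identical to the plain reference stepper in
:mod:`klinosim.dynamics`; it exists because the evolutionary search runs
thousands of assays of tens of thousands of steps each.

Neuron index order throughout: AIYL, AIYR, AIZL, AIZR, SMBDL, SMBVL, SMBDR,
SMBVR.  Environment codes: 0 conical, 1 gaussian, 2 prescribed uniform
concentration series (used by step-response probes).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ENV_CONICAL = 0
ENV_GAUSSIAN = 1
ENV_SERIES = 2

IDX_AIYL, IDX_AIYR, IDX_AIZL, IDX_AIZR = 0, 1, 2, 3
IDX_SMBDL, IDX_SMBVL, IDX_SMBDR, IDX_SMBVR = 4, 5, 6, 7


@njit(cache=True, fastmath=False)
def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


@njit(cache=True, fastmath=False)
def _concentration(env_kind, px, py, peak_x, peak_y, alpha, c0, lam, c_series, i):
    if env_kind == ENV_SERIES:
        return c_series[i]
    dx = px - peak_x
    dy = py - peak_y
    d = math.sqrt(dx * dx + dy * dy)
    if env_kind == ENV_CONICAL:
        return alpha * d
    return c0 * math.exp(-(d * d) / (2.0 * lam * lam))


@njit(cache=True, fastmath=False)
def simulate(
    n_steps, dt,
    n_recent, n_early,
    w_on, w_off,            # (2,) -> AIYL, AIYR
    theta, tau,             # (8,)
    w_aiy_aiz,              # (2,) AIYL->AIZL, AIYR->AIZR
    g_aiy, g_aiz,
    w_aiz_smb,              # (2,) shared per side
    w_self,                 # (2,) shared per side
    w_osc, w_nmj, period, speed,
    env_kind, peak_x, peak_y, alpha, c0, lam, c_series,
    x0, y0, mu0,
    y_init,                 # (8,)
    record_state,
    stride,
):
    """Integrate a full assay; returns trajectory and optional state traces.

    Rows are recorded every ``stride`` steps (``n_steps`` must be a multiple
    of ``stride``); row j is the state at time ``j*stride*dt``.  With the
    default stride of 1, ``phi[i]`` is the turning rate implied by the
    releases at time i*dt; the heading update of step i applies ``phi[i+1]``
    (releases are refreshed before the worm moves).  ``status`` is 0 on
    success, 1 when the state became non-finite (arrays are valid up to the
    failing row).
    """
    n_out = n_steps // stride + 1
    xs = np.empty(n_out)
    ys = np.empty(n_out)
    mus = np.empty(n_out)
    phis = np.empty(n_out)
    concs = np.empty(n_out)
    if record_state:
        y_rec = np.empty((n_out, 8))
        z_rec = np.empty((n_out, 8))
        zon_rec = np.empty(n_out)
        zoff_rec = np.empty(n_out)
    else:
        y_rec = np.empty((1, 8))
        z_rec = np.empty((1, 8))
        zon_rec = np.empty(1)
        zoff_rec = np.empty(1)

    # sensory ring buffer, chronological with head pointer at the oldest
    buf_len = n_recent + n_early
    buf = np.empty(buf_len)
    c_start = _concentration(env_kind, x0, y0, peak_x, peak_y, alpha, c0, lam,
                             c_series, 0)
    for i in range(buf_len):
        buf[i] = c_start
    sum_recent = c_start * n_recent
    sum_early = c_start * n_early
    head = 0

    y = y_init.copy()
    z = np.empty(8)
    for i in range(8):
        z[i] = _sigmoid(y[i] + theta[i])

    px, py, mu = x0, y0, mu0
    phi = w_nmj * (z[IDX_SMBDL] + z[IDX_SMBDR] - z[IDX_SMBVL] - z[IDX_SMBVR])
    status = 0

    two_pi_over_T = 2.0 * math.pi / period
    dy = np.empty(8)

    for i in range(n_steps + 1):
        # 1) sense at the current position, push into the history windows
        c_now = _concentration(env_kind, px, py, peak_x, peak_y, alpha, c0,
                               lam, c_series, i)
        v_old = buf[head]                        # leaves the earlier window
        cross = buf[(head + n_early) % buf_len]  # moves recent -> earlier
        sum_early += cross - v_old
        sum_recent += c_now - cross
        buf[head] = c_now
        head = (head + 1) % buf_len

        # 2) coarse-grained derivative, split into ON/OFF drive
        zd = 100.0 * (sum_recent / n_recent - sum_early / n_early)
        z_on = zd if zd > 0.0 else 0.0
        z_off = -zd if zd < 0.0 else 0.0

        if i % stride == 0:
            j = i // stride
            xs[j] = px
            ys[j] = py
            mus[j] = mu
            phis[j] = phi
            concs[j] = c_now
            if record_state:
                for k in range(8):
                    y_rec[j, k] = y[k]
                    z_rec[j, k] = z[k]
                zon_rec[j] = z_on
                zoff_rec[j] = z_off

        if i == n_steps:
            break

        # 3) synchronous Euler update from previous-step values
        t_now = i * dt
        osc = math.sin(two_pi_over_T * t_now)
        dy[IDX_AIYL] = (-y[IDX_AIYL] + g_aiy * (y[IDX_AIYR] - y[IDX_AIYL])
                        + w_on[0] * z_on + w_off[0] * z_off) / tau[IDX_AIYL]
        dy[IDX_AIYR] = (-y[IDX_AIYR] + g_aiy * (y[IDX_AIYL] - y[IDX_AIYR])
                        + w_on[1] * z_on + w_off[1] * z_off) / tau[IDX_AIYR]
        dy[IDX_AIZL] = (-y[IDX_AIZL] + w_aiy_aiz[0] * z[IDX_AIYL]
                        + g_aiz * (y[IDX_AIZR] - y[IDX_AIZL])) / tau[IDX_AIZL]
        dy[IDX_AIZR] = (-y[IDX_AIZR] + w_aiy_aiz[1] * z[IDX_AIYR]
                        + g_aiz * (y[IDX_AIZL] - y[IDX_AIZR])) / tau[IDX_AIZR]
        dy[IDX_SMBDL] = (-y[IDX_SMBDL] + w_aiz_smb[0] * z[IDX_AIZL]
                         + w_self[0] * z[IDX_SMBDL] + w_osc * osc) / tau[IDX_SMBDL]
        dy[IDX_SMBVL] = (-y[IDX_SMBVL] + w_aiz_smb[0] * z[IDX_AIZL]
                         + w_self[0] * z[IDX_SMBVL] - w_osc * osc) / tau[IDX_SMBVL]
        dy[IDX_SMBDR] = (-y[IDX_SMBDR] + w_aiz_smb[1] * z[IDX_AIZR]
                         + w_self[1] * z[IDX_SMBDR] + w_osc * osc) / tau[IDX_SMBDR]
        dy[IDX_SMBVR] = (-y[IDX_SMBVR] + w_aiz_smb[1] * z[IDX_AIZR]
                         + w_self[1] * z[IDX_SMBVR] - w_osc * osc) / tau[IDX_SMBVR]
        for k in range(8):
            y[k] = y[k] + dt * dy[k]
            z[k] = _sigmoid(y[k] + theta[k])

        # 4) turn, then move at constant speed along the new heading
        phi = w_nmj * (z[IDX_SMBDL] + z[IDX_SMBDR]
                       - z[IDX_SMBVL] - z[IDX_SMBVR])
        if not math.isfinite(phi):
            status = 1
            for j in range(i // stride + 1, n_out):
                xs[j] = px
                ys[j] = py
                mus[j] = mu
                phis[j] = 0.0
                concs[j] = c_now
            break
        mu = mu + phi * dt
        px = px + speed * dt * math.cos(mu)
        py = py + speed * dt * math.sin(mu)

    return xs, ys, mus, phis, concs, y_rec, z_rec, zon_rec, zoff_rec, status
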