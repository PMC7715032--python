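"""Fixed-step network integration kernel (numba).

Membrane dynamics are integrated at a fixed time step (default 0.025 ms)
with a semi-implicit scheme: gating variables advance by forward Euler
at the current voltage, then the voltage of the eight-compartment chain
is solved implicitly (Thomas algorithm) with the updated channel and
synaptic conductances held linear in v over the step.

Synaptic conductances are sums of exponentials updated analytically
between events; presynaptic spikes (from feedforward spike sources or
recurrent cells) deposit normalized weight increments into a ring buffer
indexed by arrival step, so each edge's conduction delay is exact to one
time step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NCOMP = 8
SOMA = 5

E_NA = 60.0
E_K = -75.0
E_CA = 80.0

# voltage offset between absolute mV and the rate-function frame
# (classical reduced-model kinetics are written relative to a -60 mV rest)
VSH = 60.0

CA_PHI = 0.13       # Ca influx scaling (per uA/cm^2)
CA_BETA = 0.075     # Ca removal rate (1/ms)
CA_INIT = 0.2


@njit(cache=True)
def _vtrap(x, c):
    # x / (exp(x/c) - 1) with the removable singularity handled
    if abs(x / c) < 1e-6:
        return c * (1.0 - x / (2.0 * c))
    return x / (np.exp(x / c) - 1.0)


@njit(cache=True)
def _na_minf(vp):
    am = 0.32 * _vtrap(13.1 - vp, 4.0)
    bm = 0.28 * _vtrap(vp - 40.1, 5.0)
    return am / (am + bm)


@njit(cache=True)
def _h_rates(vp):
    ah = 0.128 * np.exp((17.0 - vp) / 18.0)
    bh = 4.0 / (1.0 + np.exp((40.0 - vp) / 5.0))
    return ah, bh


@njit(cache=True)
def _n_rates(vp):
    an = 0.016 * _vtrap(35.1 - vp, 5.0)
    bn = 0.25 * np.exp(0.5 - 0.025 * vp)
    return an, bn


@njit(cache=True)
def _s_rates(vp):
    as_ = 1.6 / (1.0 + np.exp(-0.072 * (vp - 65.0)))
    bs = 0.02 * _vtrap(vp - 51.1, 5.0)
    return as_, bs


@njit(cache=True)
def _c_rates(vp):
    if vp <= 50.0:
        ac = np.exp((vp - 10.0) / 11.0 - (vp - 6.5) / 27.0) / 18.975
        bc = 2.0 * np.exp((6.5 - vp) / 27.0) - ac
    else:
        ac = 2.0 * np.exp((6.5 - vp) / 27.0)
        bc = 0.0
    return ac, bc


@njit(cache=True)
def _km_zinf(v):
    return 1.0 / (1.0 + np.exp(-(v + 35.0) / 5.0))


@njit(cache=True)
def steady_gates(v, ca):
    """Steady-state (h, n, s, c, q, z) at voltage v (absolute mV)."""
    vp = v + VSH
    ah, bh = _h_rates(vp)
    an, bn = _n_rates(vp)
    as_, bs = _s_rates(vp)
    ac, bc = _c_rates(vp)
    aq = min(0.00002 * ca, 0.01)
    bq = 0.001
    return (ah / (ah + bh), an / (an + bn), as_ / (as_ + bs),
            ac / (ac + bc), aq / (aq + bq), _km_zinf(v))


@njit(cache=True)
def run_network(
    dt, nsteps,
    # per-compartment cell parameters (shared by all cells of the population)
    cap, gl_abs, e_leak, gna_abs, gkdr_abs, gca_abs, gkc_abs, gkahp_abs,
    gkm_abs, tau_km, gax, gca_density,
    v_init, ncell,
    # synapse kinetics per compartment
    dA1, dA2, pfA, dN1, dN2, dN3, wN, pfN, mg_mM, has_syn,
    # feedforward sources: spike list sorted by step + CSR adjacency by source id
    src_step, src_id,
    src_indptr, src_tcell, src_tcomp, src_delay, src_wa, src_wn,
    # recurrent adjacency CSR by source cell
    rec_indptr, rec_tcell, rec_tcomp, rec_delay, rec_wa, rec_wn,
    horizon,
    # somatic current injection (nA) per cell over [inj_start, inj_end)
    inj_amp, inj_start, inj_end,
    # spike detection
    vthresh, lockout_steps,
    spike_cap, record_cell,
):
    v = np.full((ncell, NCOMP), v_init)
    h = np.empty((ncell, NCOMP))
    ng = np.empty((ncell, NCOMP))
    sg = np.empty((ncell, NCOMP))
    cg = np.empty((ncell, NCOMP))
    qg = np.empty((ncell, NCOMP))
    zg = np.empty((ncell, NCOMP))
    ca = np.full((ncell, NCOMP), CA_INIT)
    h0, n0, s0, c0, q0, z0 = steady_gates(v_init, CA_INIT)
    h[:] = h0
    ng[:] = n0
    sg[:] = s0
    cg[:] = c0
    qg[:] = q0
    zg[:] = z0

    SA1 = np.zeros((ncell, NCOMP))
    SA2 = np.zeros((ncell, NCOMP))
    SN1 = np.zeros((ncell, NCOMP))
    SN2 = np.zeros((ncell, NCOMP))
    SN3 = np.zeros((ncell, NCOMP))

    RBa = np.zeros((horizon, ncell, NCOMP), dtype=np.float32)
    RBn = np.zeros((horizon, ncell, NCOMP), dtype=np.float32)

    spk_cell = np.empty(spike_cap, dtype=np.int32)
    spk_step = np.empty(spike_cap, dtype=np.int64)
    nspk = 0
    last_spike = np.full(ncell, -10 ** 9, dtype=np.int64)

    nrec = nsteps if record_cell >= 0 else 1
    vrec = np.zeros(nrec)

    # Thomas algorithm scratch
    diag = np.empty(NCOMP)
    rhs = np.empty(NCOMP)
    cp = np.empty(NCOMP)

    ffp = 0
    nff = len(src_step)
    cinv_dt = cap / dt
    syn_comps = np.nonzero(has_syn)[0]
    nsyn_comps = len(syn_comps)

    for step in range(nsteps):
        # 1. consume deliveries arriving at this step
        slot = step % horizon
        for i in range(ncell):
            for kk in range(nsyn_comps):
                k = syn_comps[kk]
                wa = RBa[slot, i, k]
                if wa != 0.0:
                    SA1[i, k] += wa
                    SA2[i, k] += wa
                    RBa[slot, i, k] = 0.0
                wn = RBn[slot, i, k]
                if wn != 0.0:
                    SN1[i, k] += wn
                    SN2[i, k] += wn
                    SN3[i, k] += wn
                    RBn[slot, i, k] = 0.0

        # 2. schedule feedforward source spikes occurring at this step
        while ffp < nff and src_step[ffp] == step:
            s = src_id[ffp]
            for e in range(src_indptr[s], src_indptr[s + 1]):
                d = src_delay[e]
                slot2 = (step + d) % horizon
                tc = src_tcell[e]
                tk = src_tcomp[e]
                RBa[slot2, tc, tk] += src_wa[e]
                RBn[slot2, tc, tk] += src_wn[e]
            ffp += 1

        inj_on = inj_start <= step < inj_end

        # 3. integrate every cell
        for i in range(ncell):
            # --- gates and conductances
            for k in range(NCOMP):
                vk = v[i, k]
                vp = vk + VSH
                if gna_abs[k] > 0.0:
                    ah, bh = _h_rates(vp)
                    h[i, k] += dt * (ah * (1.0 - h[i, k]) - bh * h[i, k])
                    an, bn = _n_rates(vp)
                    ng[i, k] += dt * (an * (1.0 - ng[i, k]) - bn * ng[i, k])
                if gca_abs[k] > 0.0:
                    as_, bs = _s_rates(vp)
                    sg[i, k] += dt * (as_ * (1.0 - sg[i, k]) - bs * sg[i, k])
                    ac, bc = _c_rates(vp)
                    cg[i, k] += dt * (ac * (1.0 - cg[i, k]) - bc * cg[i, k])
                    aq = 0.00002 * ca[i, k]
                    if aq > 0.01:
                        aq = 0.01
                    qg[i, k] += dt * (aq * (1.0 - qg[i, k]) - 0.001 * qg[i, k])
                    ica_density = gca_density[k] * sg[i, k] * sg[i, k] * (vk - E_CA)
                    ca[i, k] += dt * (-CA_PHI * ica_density - CA_BETA * ca[i, k])
                if gkm_abs[k] > 0.0:
                    zg[i, k] += dt * (_km_zinf(vk) - zg[i, k]) / tau_km

            # --- assemble tridiagonal system
            for k in range(NCOMP):
                vk = v[i, k]
                g_tot = gl_abs[k]
                ge_sum = gl_abs[k] * e_leak
                if gna_abs[k] > 0.0:
                    vp = vk + VSH
                    minf = _na_minf(vp)
                    g = gna_abs[k] * minf * minf * h[i, k]
                    g_tot += g
                    ge_sum += g * E_NA
                    g = gkdr_abs[k] * ng[i, k]
                    g_tot += g
                    ge_sum += g * E_K
                if gca_abs[k] > 0.0:
                    g = gca_abs[k] * sg[i, k] * sg[i, k]
                    g_tot += g
                    ge_sum += g * E_CA
                    chi = ca[i, k] / 250.0
                    if chi > 1.0:
                        chi = 1.0
                    g = gkc_abs[k] * cg[i, k] * chi + gkahp_abs[k] * qg[i, k]
                    g_tot += g
                    ge_sum += g * E_K
                if gkm_abs[k] > 0.0:
                    g = gkm_abs[k] * zg[i, k]
                    g_tot += g
                    ge_sum += g * E_K
                if has_syn[k]:
                    gA = SA2[i, k] - SA1[i, k]
                    if gA < 0.0:
                        gA = 0.0
                    gN = wN[k] * SN3[i, k] + (1.0 - wN[k]) * SN2[i, k] - SN1[i, k]
                    if gN < 0.0:
                        gN = 0.0
                    block = 1.0 / (1.0 + np.exp(-0.062 * vk) * mg_mM / 3.57)
                    g_tot += gA + gN * block
                    # E_syn = 0 mV: no contribution to ge_sum
                diag[k] = cinv_dt[k] + g_tot
                rhs[k] = cinv_dt[k] * vk + ge_sum
                if k > 0:
                    diag[k] += gax[k - 1]
                if k < NCOMP - 1:
                    diag[k] += gax[k]
            if inj_on:
                rhs[SOMA] += inj_amp[i]

            # --- Thomas solve (chain: sub/super diagonal = -gax)
            cp[0] = -gax[0] / diag[0]
            rhs[0] = rhs[0] / diag[0]
            for k in range(1, NCOMP):
                m = diag[k] + gax[k - 1] * cp[k - 1]
                if k < NCOMP - 1:
                    cp[k] = -gax[k] / m
                rhs[k] = (rhs[k] + gax[k - 1] * rhs[k - 1]) / m
            vnew7 = rhs[NCOMP - 1]
            v_prev_soma = v[i, SOMA]
            v[i, NCOMP - 1] = vnew7
            for k in range(NCOMP - 2, -1, -1):
                v[i, k] = rhs[k] - cp[k] * v[i, k + 1]

            if abs(v[i, SOMA]) > 200.0:
                return spk_cell, spk_step, -(i + 1), vrec

            # --- spike detection at the soma
            if (v[i, SOMA] >= vthresh and v_prev_soma < vthresh
                    and step - last_spike[i] > lockout_steps):
                last_spike[i] = step
                if nspk >= spike_cap:
                    return spk_cell, spk_step, -1000000000, vrec
                spk_cell[nspk] = i
                spk_step[nspk] = step
                nspk += 1
                for e in range(rec_indptr[i], rec_indptr[i + 1]):
                    d = rec_delay[e]
                    slot2 = (step + d) % horizon
                    tc = rec_tcell[e]
                    tk = rec_tcomp[e]
                    RBa[slot2, tc, tk] += rec_wa[e]
                    RBn[slot2, tc, tk] += rec_wn[e]

            # --- decay synaptic states
            for kk in range(nsyn_comps):
                k = syn_comps[kk]
                SA1[i, k] *= dA1[k]
                SA2[i, k] *= dA2[k]
                SN1[i, k] *= dN1[k]
                SN2[i, k] *= dN2[k]
                SN3[i, k] *= dN3[k]

        if record_cell >= 0:
            vrec[step] = v[record_cell, SOMA]

    return spk_cell, spk_step, nspk, vrec
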