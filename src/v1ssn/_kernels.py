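"""Numba kernels for the batched rate integrator and the spiking network.

The rate model integrates many independent stimuli at once: rates are (N, M)
arrays whose columns are stimuli, and the four CSR weight blocks are shared.
The inner loops are written so the per-column loop vectorizes.
"""

from __future__ import annotations

import numba as nb
import numpy as np

_EPS = 1e-6
#: rates below this are flushed to exact zero.  Far outside the stimulus the
#: drive underflows toward the subnormal float range and K*drive^n would
#: otherwise populate the state with subnormals, which many CPUs process
#: orders of magnitude more slowly; the flush threshold is ~1e9 times smaller
#: than any physiologically meaningful rate.
_RATE_FLOOR = 1e-12


@nb.njit(cache=True, fastmath=True)
def csr_matmul(indptr, indices, data, B, out):
    """out = A @ B for CSR A (N x N) and C-contiguous B (N x M)."""
    N, M = B.shape
    for i in range(N):
        for m in range(M):
            out[i, m] = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            c = indices[p]
            v = data[p]
            for m in range(M):
                out[i, m] += v * B[c, m]
    return out


@nb.njit(cache=True, fastmath=True)
def euler_chunk(
    iEE, jEE, vEE, iEI, jEI, vEI, iIE, jIE, vIE, iII, jII, vII,
    drive, rE, rI,
    dt, tau_E, tau_I, K, n_E, n_I, steps, cap,
    recE, recI, netE, netI,
):
    """Run ``steps`` forward-Euler steps in place on (rE, rI).

    recE/recI/netE/netI are (N, M) work arrays.  Returns (code, metric) where
    code is 0 on success, 1 if any rate exceeded ``cap`` or went non-finite,
    and metric[m] is the relative derivative criterion
    max_cells |dr| * tau / (r + eps) evaluated on the final step.
    """
    N, M = drive.shape
    metric = np.zeros(M, dtype=drive.dtype)
    aE = dt / tau_E
    aI = dt / tau_I
    for s in range(steps):
        csr_matmul(iEE, jEE, vEE, rE, recE)
        csr_matmul(iEI, jEI, vEI, rI, netE)
        csr_matmul(iIE, jIE, vIE, rE, recI)
        csr_matmul(iII, jII, vII, rI, netI)
        last = s == steps - 1
        bad = False
        for i in range(N):
            for m in range(M):
                xE = drive[i, m] + recE[i, m] - netE[i, m]
                xI = drive[i, m] + recI[i, m] - netI[i, m]
                fE = K * (max(xE, 0.0) ** n_E)
                fI = K * (max(xI, 0.0) ** n_I)
                dE = fE - rE[i, m]
                dI = fI - rI[i, m]
                rE[i, m] += aE * dE
                rI[i, m] += aI * dI
                if rE[i, m] < _RATE_FLOOR:
                    rE[i, m] = 0.0
                if rI[i, m] < _RATE_FLOOR:
                    rI[i, m] = 0.0
                if rE[i, m] > cap or rI[i, m] > cap or not (
                    np.isfinite(rE[i, m]) and np.isfinite(rI[i, m])
                ):
                    bad = True
                if last:
                    mE = abs(dE) / (rE[i, m] + _EPS)
                    mI = abs(dI) / (rI[i, m] + _EPS)
                    if mE > metric[m]:
                        metric[m] = mE
                    if mI > metric[m]:
                        metric[m] = mI
        if bad:
            return 1, metric
    return 0, metric


@nb.njit(cache=True, fastmath=True)
def euler_record(
    iEE, jEE, vEE, iEI, jEI, vEI, iIE, jIE, vIE, iII, jII, vII,
    drive, rE, rI,
    dt, tau_E, tau_I, K, n_E, n_I, steps, cap,
    rec_rows, outE, outI,
    recE, recI, netE, netI,
):
    """As euler_chunk, but records rE/rI at rec_rows[m] for column m each step.

    outE/outI have shape (steps, M); outE[s, m] is the rate *after* step s.
    """
    N, M = drive.shape
    aE = dt / tau_E
    aI = dt / tau_I
    for s in range(steps):
        csr_matmul(iEE, jEE, vEE, rE, recE)
        csr_matmul(iEI, jEI, vEI, rI, netE)
        csr_matmul(iIE, jIE, vIE, rE, recI)
        csr_matmul(iII, jII, vII, rI, netI)
        for i in range(N):
            for m in range(M):
                xE = drive[i, m] + recE[i, m] - netE[i, m]
                xI = drive[i, m] + recI[i, m] - netI[i, m]
                rE[i, m] += aE * (K * (max(xE, 0.0) ** n_E) - rE[i, m])
                rI[i, m] += aI * (K * (max(xI, 0.0) ** n_I) - rI[i, m])
                if rE[i, m] < _RATE_FLOOR:
                    rE[i, m] = 0.0
                if rI[i, m] < _RATE_FLOOR:
                    rI[i, m] = 0.0
        for m in range(M):
            outE[s, m] = rE[rec_rows[m], m]
            outI[s, m] = rI[rec_rows[m], m]
        for m in range(M):
            if not (np.isfinite(outE[s, m]) and np.isfinite(outI[s, m])):
                return 1
            if outE[s, m] > cap or outI[s, m] > cap:
                return 1
    return 0


@nb.njit(cache=True, fastmath=True)
def spiking_chunk(
    V, gE, gI, gin, ref,                    # state, length Ntot (E block then I block)
    noiseV, noiseG,                          # (steps, Ntot) standard normals
    gin_bar,                                 # (Ntot,) OU mean
    sigma_gin,                               # (Ntot,) OU stationary-driving sigma
    # presynaptic adjacency, CSC-style: for pre neuron p (0..Ntot-1),
    # targets tgt[tp[p]:tp[p+1]] receive conductance jump w[..] on its spike
    tpE, tgtE, wE,                           # E-presynaptic: jumps onto gE of targets
    tpI, tgtI, wI,                           # I-presynaptic: jumps onto gI of targets
    dt, tau_m, tau_sE, tau_sI, R_L, R_E, R_I, g_L,
    sigma_V, V_th, V_r, ref_steps,
    spk_n, spk_t, n_spikes, max_spikes, t0,
    counts,                                  # per-neuron spike counts (whole chunk)
    acc_gE, acc_gI, acc_IE, acc_II, acc_Iin, acc_V,  # per-neuron accumulators
    accumulate,                              # 0/1: add conductance/current averages
    rec_idx, traceV, traceG,                 # per-step traces for selected neurons
):
    """Advance the spiking network by noiseV.shape[0] steps.

    Synaptic and input conductances decay exactly between spikes; the input
    conductance follows an exact-update OU process whose stationary variance
    is sigma_gin^2 / 2; the membrane potential uses Euler-Maruyama with
    stationary noise std sigma_V.  During the refractory period the voltage is
    clamped at V_r and noise is not integrated.  Returns (code, n_spikes);
    code 1 signals spike-buffer overflow, 2 a non-finite state.
    """
    steps = noiseV.shape[0]
    Ntot = V.shape[0]
    decE = np.exp(-dt / tau_sE)
    decI = np.exp(-dt / tau_sI)
    # exact OU update for g_in: g <- bar + (g - bar) a + s * xi,
    # stationary var = sigma_gin^2/2  =>  s = sigma_gin * sqrt((1 - a^2)/2)
    aOU = np.exp(-dt / tau_sE)
    sOU = np.sqrt((1.0 - aOU * aOU) / 2.0)
    vnoise = sigma_V * np.sqrt(2.0 * dt / tau_m)
    k = n_spikes
    for s in range(steps):
        t = t0 + s * dt
        for i in range(Ntot):
            gE[i] *= decE
            gI[i] *= decI
            gin[i] = gin_bar[i] + (gin[i] - gin_bar[i]) * aOU + sigma_gin[i] * sOU * noiseG[s, i]
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = V_r
            else:
                dV = (-(V[i] - R_L)
                      + (gE[i] * (R_E - V[i]) + gI[i] * (R_I - V[i])
                         + gin[i] * (R_E - V[i])) / g_L) * (dt / tau_m)
                V[i] += dV + vnoise * noiseV[s, i]
                if not np.isfinite(V[i]):
                    return 2, k
                if V[i] >= V_th:
                    V[i] = V_r
                    ref[i] = ref_steps
                    counts[i] += 1
                    if k >= max_spikes:
                        return 1, k
                    spk_n[k] = i
                    spk_t[k] = t
                    k += 1
                    # propagate: E presynaptic rows have entries in (tpE, tgtE),
                    # I presynaptic rows in (tpI, tgtI); the other list is empty
                    for p in range(tpE[i], tpE[i + 1]):
                        gE[tgtE[p]] += wE[p]
                    for p in range(tpI[i], tpI[i + 1]):
                        gI[tgtI[p]] += wI[p]
        if accumulate == 1:
            for i in range(Ntot):
                acc_gE[i] += gE[i]
                acc_gI[i] += gI[i]
                acc_IE[i] += gE[i] * (R_E - V[i])
                acc_II[i] += gI[i] * (R_I - V[i])
                acc_Iin[i] += gin[i] * (R_E - V[i])
                acc_V[i] += V[i]
        for r in range(rec_idx.shape[0]):
            traceV[s, r] = V[rec_idx[r]]
            traceG[s, r] = gin[rec_idx[r]]
    return 0, k
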