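"""Conductance-based leaky integrate-and-fire backend.

Every grid location hosts one E and one I neuron (E indices 0..N-1, I indices
N..2N-1).  The membrane potential obeys

    tau_m dV/dt = -(V - R_L) + [g_E (R_E - V) + g_I (R_I - V)
                                + g_in (R_E - V)] / g_L + noise

with synaptic conductances that jump by g_XY per presynaptic spike and decay
exponentially, and an external input conductance g_in modeled as an
Ornstein-Uhlenbeck process.  The OU process stands in for N_input Poisson
afferents firing at the stimulus-determined rate r_ext: by the central limit
theorem the summed conductance has mean N_input r_ext tau_E g_ext and
stationary variance (N_input r_ext tau_E g_ext^2) / 2.  Membrane noise is
white, scaled so the stationary voltage fluctuation is sigma_V; it is what
generates spontaneous activity (about 1.5 Hz for E and 3 Hz for I cells with
the default sigma_V).

Conductance-valued connectivity reuses the rate model's spatial and
orientation kernels with g_XY in place of J_XY.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .connectivity import ConnectivityParams, WeightSet, build_weights
from .geometry import OrientationMap
from .stimulus import InputParams, StimulusSpec, render_input

__all__ = [
    "SpikingParams",
    "SpikeRecord",
    "ConductanceTrace",
    "external_drive_stats",
    "conductance_params",
    "build_conductances",
    "run_trial",
    "isi_cv",
]


@dataclass(frozen=True)
class SpikingParams:
    """Spiking-neuron parameters (ms, mV, nS); identical for E and I cells."""

    tau_m: float = 15.0         # membrane time constant, ms
    tau_sE: float = 3.0         # excitatory synaptic conductance decay, ms
    tau_sI: float = 3.0         # inhibitory synaptic conductance decay, ms
    R_L: float = -70.0          # leak reversal, mV
    R_E: float = 0.0            # excitatory reversal, mV
    R_I: float = -80.0          # inhibitory reversal, mV
    g_L: float = 10.0           # leak conductance, nS
    V_th: float = -50.0         # spike threshold, mV
    V_r: float = -56.0          # post-spike reset, mV
    tau_ref: float = 3.0        # refractory period, ms
    sigma_V: float = 6.85       # stationary membrane-noise std, mV
    N_input: int = 200          # external afferents per cell
    g_ext: float = 0.1          # conductance per external spike, nS
    dt: float = 0.05            # integration step, ms

    def __post_init__(self) -> None:
        if not (self.R_I < self.V_r < self.V_th < self.R_E):
            raise ValueError("require R_I < V_r < V_th < R_E")
        if self.dt > 0.1:
            raise ValueError("spiking integration requires dt <= 0.1 ms")


#: conductance scales (nS) replacing the rate model's J values
DEFAULT_CONDUCTANCES = dict(
    g_EE_short=1.8, g_IE_short=1.76, g_EE_long=0.7, g_IE_long=0.65,
    g_EI=3.3, g_II=2.0,
)


def conductance_params(base: ConnectivityParams = ConnectivityParams(),
                       **overrides) -> ConnectivityParams:
    """Connectivity parameters with conductance scales in place of J values."""
    g = {**DEFAULT_CONDUCTANCES, **overrides}
    return replace(
        base,
        J_EE_short=g["g_EE_short"], J_IE_short=g["g_IE_short"],
        J_EE_long=g["g_EE_long"], J_IE_long=g["g_IE_long"],
        J_EI=g["g_EI"], J_II=g["g_II"],
    )


def build_conductances(omap: OrientationMap, **overrides) -> WeightSet:
    """Conductance-valued WeightSet (nS) with the standard p and q kernels."""
    return build_weights(omap, conductance_params(**overrides))


def external_drive_stats(r_ext, params: SpikingParams = SpikingParams()):
    """Mean and driving amplitude of the external input conductance.

    For afferent rate ``r_ext`` (Hz), returns (gbar_in, sigma_gin) in nS with
    gbar_in = N_input r_ext tau_E g_ext and
    sigma_gin^2 = N_input r_ext tau_E g_ext^2; the stationary variance of the
    OU conductance is sigma_gin^2 / 2.
    """
    r = np.asarray(r_ext, dtype=float)
    if np.any(r < 0):
        raise ValueError("external rate must be nonnegative")
    tau_s = params.tau_sE / 1000.0  # ms -> s against Hz rates
    gbar = params.N_input * r * tau_s * params.g_ext
    sigma = np.sqrt(params.N_input * r * tau_s * params.g_ext**2)
    return gbar, sigma


@dataclass
class SpikeRecord:
    """Spike events from one trial (measurement window only)."""

    neuron: np.ndarray        # global neuron indices (E: 0..N-1, I: N..2N-1)
    time: np.ndarray          # spike times in ms, globally nondecreasing
    n_cells: int              # cells per population (N)
    duration: float           # measurement window, ms
    seed: int

    def rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rate_E, rate_I) in Hz, each length n_cells."""
        counts = np.bincount(self.neuron, minlength=2 * self.n_cells)
        hz = counts / (self.duration / 1000.0)
        return hz[: self.n_cells], hz[self.n_cells:]

    def spike_times(self, neuron: int) -> np.ndarray:
        return self.time[self.neuron == neuron]


@dataclass
class ConductanceTrace:
    """Time-averaged conductances (nS), currents (nS*mV) and voltage per neuron.

    Currents follow the conductance convention I = <g (R - V)>: the inhibitory
    current is negative, the external and recurrent excitatory currents
    positive.
    """

    g_E: np.ndarray
    g_I: np.ndarray
    I_exc_recurrent: np.ndarray
    I_inh: np.ndarray
    I_ext: np.ndarray
    V_mean: np.ndarray


def _presyn_adjacency(gW: WeightSet):
    """CSC-style arrays mapping each global presynaptic index to its targets.

    Cached on the WeightSet: trials reuse the same arrays.
    """
    cached = getattr(gW, "_presyn_cache", None)
    if cached is not None:
        return cached
    N = gW.n
    T_E = sp.vstack([gW.W_EE, gW.W_IE]).tocsc()  # E presyn -> jumps on g_E
    T_I = sp.vstack([gW.W_EI, gW.W_II]).tocsc()  # I presyn -> jumps on g_I
    tail = np.full(N, T_E.indptr[-1], dtype=T_E.indptr.dtype)
    tpE = np.concatenate([T_E.indptr, tail])
    head = np.zeros(N, dtype=T_I.indptr.dtype)
    tpI = np.concatenate([head, T_I.indptr])
    out = (tpE.astype(np.int64), T_E.indices.astype(np.int64), T_E.data.astype(np.float64),
           tpI.astype(np.int64), T_I.indices.astype(np.int64), T_I.data.astype(np.float64))
    object.__setattr__(gW, "_presyn_cache", out)
    return out


def run_trial(
    spec: StimulusSpec,
    omap: OrientationMap,
    gW: WeightSet,
    params: SpikingParams = SpikingParams(),
    duration: float = 1000.0,
    warmup: float = 500.0,
    seed: int | None = None,
    input_params: InputParams = InputParams(),
    chunk_steps: int = 1000,
    max_rate_hz: float = 250.0,
):
    """Simulate one trial and return (SpikeRecord, ConductanceTrace).

    The stimulus sets the external afferent rate r_ext per cell via the same
    stimulus-to-drive transformation as the rate model.  The first ``warmup``
    ms are discarded; spike counts, conductance and current averages are
    accumulated over the following ``duration`` ms.  A seed is required so
    runs are reproducible.
    """
    if seed is None:
        raise ValueError("run_trial requires an explicit seed")
    N = omap.grid.n_cells
    Ntot = 2 * N
    drive = render_input(spec, omap, input_params)   # Hz per location
    gbar1, sig1 = external_drive_stats(drive, params)
    gbar = np.concatenate([gbar1, gbar1])
    sig = np.concatenate([sig1, sig1])

    adj = _presyn_adjacency(gW)
    rng = np.random.default_rng(seed)

    V = params.R_L + params.sigma_V * rng.standard_normal(Ntot)
    V = np.minimum(V, params.V_th - 0.1)
    gE = np.zeros(Ntot)
    gI = np.zeros(Ntot)
    gin = gbar.copy()
    ref = np.zeros(Ntot, dtype=np.int64)
    ref_steps = int(round(params.tau_ref / params.dt))

    counts = np.zeros(Ntot, dtype=np.int64)
    accs = [np.zeros(Ntot) for _ in range(6)]

    max_spikes = int(max_rate_hz * Ntot * (duration + warmup) / 1000.0) + 10_000
    spk_n = np.empty(max_spikes, dtype=np.int64)
    spk_t = np.empty(max_spikes, dtype=np.float64)

    no_rec = np.zeros(0, dtype=np.int64)
    no_trace = np.zeros((0, 0), dtype=np.float64)

    def run_phase(t0, t1, accumulate):
        n_spk = 0
        steps_left = int(round((t1 - t0) / params.dt))
        t = t0
        done = 0
        meas_steps = 0
        while steps_left > 0:
            steps = min(chunk_steps, steps_left)
            noiseV = rng.standard_normal((steps, Ntot), dtype=np.float32)
            noiseG = rng.standard_normal((steps, Ntot), dtype=np.float32)
            code, n_spk = _kernels.spiking_chunk(
                V, gE, gI, gin, ref, noiseV, noiseG, gbar, sig,
                *adj,
                params.dt, params.tau_m, params.tau_sE, params.tau_sI,
                params.R_L, params.R_E, params.R_I, params.g_L,
                params.sigma_V, params.V_th, params.V_r, ref_steps,
                spk_n, spk_t, n_spk, max_spikes, t,
                counts, *accs, accumulate,
                no_rec, no_trace, no_trace,
            )
            if code == 1:
                raise RuntimeError(
                    f"spike buffer overflow (> {max_rate_hz} Hz network mean); "
                    "raise max_rate_hz or shorten the trial")
            if code == 2:
                raise RuntimeError("non-finite membrane state in spiking simulation")
            steps_left -= steps
            done += steps
            t = t0 + done * params.dt
            if accumulate:
                meas_steps += steps
        return n_spk, meas_steps

    # warm-up: discard spikes and accumulators
    run_phase(0.0, warmup, 0)
    counts[:] = 0
    n_spk, meas_steps = run_phase(warmup, warmup + duration, 1)

    record = SpikeRecord(
        neuron=spk_n[:n_spk].copy(), time=spk_t[:n_spk].copy(),
        n_cells=N, duration=duration, seed=seed,
    )
    gE_m, gI_m, IE_m, II_m, Iin_m, V_m = (a / meas_steps for a in accs)
    trace = ConductanceTrace(
        g_E=gE_m, g_I=gI_m,
        I_exc_recurrent=IE_m, I_inh=II_m, I_ext=Iin_m, V_mean=V_m,
    )
    return record, trace


def simulate_single_neuron(
    gin_bar: float,
    sigma_gin: float,
    params: SpikingParams = SpikingParams(),
    duration: float = 1000.0,
    seed: int = 0,
    V0: float | None = None,
    record: bool = False,
):
    """One unconnected neuron driven by the OU input conductance.

    Useful for closed-form checks: with ``sigma_gin = 0`` and ``sigma_V = 0``
    the voltage settles at (g_L R_L + gin_bar R_E) / (g_L + gin_bar); with
    drive only through noise the stationary moments of V and g_in can be
    compared against theory.  Returns a dict with spike times, final state,
    and (if ``record``) per-step V and g_in traces.
    """
    rng = np.random.default_rng(seed)
    Ntot = 1
    V = np.array([params.R_L if V0 is None else V0], dtype=float)
    gE = np.zeros(1)
    gI = np.zeros(1)
    gin = np.array([gin_bar], dtype=float)
    ref = np.zeros(1, dtype=np.int64)
    gbar = np.array([gin_bar], dtype=float)
    sig = np.array([sigma_gin], dtype=float)
    empty_ptr = np.zeros(2 * Ntot + 1, dtype=np.int64)
    empty_idx = np.zeros(0, dtype=np.int64)
    empty_val = np.zeros(0, dtype=np.float64)
    steps = int(round(duration / params.dt))
    max_spikes = steps + 1
    spk_n = np.empty(max_spikes, dtype=np.int64)
    spk_t = np.empty(max_spikes, dtype=np.float64)
    counts = np.zeros(1, dtype=np.int64)
    accs = [np.zeros(1) for _ in range(6)]
    if record:
        rec_idx = np.zeros(1, dtype=np.int64)
        traceV = np.empty((steps, 1))
        traceG = np.empty((steps, 1))
    else:
        rec_idx = np.zeros(0, dtype=np.int64)
        traceV = np.zeros((0, 0))
        traceG = np.zeros((0, 0))
    n_spk = 0
    chunk = 200000
    done = 0
    while done < steps:
        k = min(chunk, steps - done)
        noiseV = rng.standard_normal((k, 1), dtype=np.float32)
        noiseG = rng.standard_normal((k, 1), dtype=np.float32)
        code, n_spk = _kernels.spiking_chunk(
            V, gE, gI, gin, ref, noiseV, noiseG, gbar, sig,
            empty_ptr, empty_idx, empty_val, empty_ptr, empty_idx, empty_val,
            params.dt, params.tau_m, params.tau_sE, params.tau_sI,
            params.R_L, params.R_E, params.R_I, params.g_L,
            params.sigma_V, params.V_th, params.V_r,
            int(round(params.tau_ref / params.dt)),
            spk_n, spk_t, n_spk, max_spikes, done * params.dt,
            counts, *accs, 0,
            rec_idx,
            traceV[done:done + k] if record else traceV,
            traceG[done:done + k] if record else traceG,
        )
        if code != 0:
            raise RuntimeError("single-neuron simulation failed")
        done += k
    return {
        "V": float(V[0]), "g_in": float(gin[0]),
        "spike_times": spk_t[:n_spk].copy(),
        "trace_V": traceV[:, 0] if record else None,
        "trace_gin": traceG[:, 0] if record else None,
    }


def isi_cv(record: SpikeRecord, min_spikes: int = 5) -> np.ndarray:
    """Coefficient of variation of interspike intervals per neuron.

    Returns CVs for every neuron with at least ``min_spikes`` spikes in the
    measurement window.
    """
    order = np.lexsort((record.time, record.neuron))
    nrn = record.neuron[order]
    t = record.time[order]
    cvs = []
    start = 0
    for end in np.flatnonzero(np.diff(nrn))[::1].tolist() + [nrn.size - 1]:
        seg = t[start:end + 1]
        if seg.size >= min_spikes:
            isi = np.diff(seg)
            m = isi.mean()
            if m > 0:
                cvs.append(isi.std() / m)
        start = end + 1
    return np.asarray(cvs)
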