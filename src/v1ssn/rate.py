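"""Supralinear rate dynamics: steady states, current decomposition, decay runs.

Each grid location hosts one E and one I unit.  Rates obey

    tau_E dr_E/dt = -r_E + K [ I_ext + W_EE r_E - W_EI r_I ]_+ ^ n
    tau_I dr_I/dt = -r_I + K [ I_ext + W_IE r_E - W_II r_I ]_+ ^ n

with a rectified power-law transfer function r = K [I]_+^n, n = 2.2.  The
supralinear transfer function is the heart of the stabilized supralinear
network: effective synaptic gain grows with drive, moving the circuit from a
feedforward-dominated to a recurrent, inhibition-stabilized regime.

Integration is forward Euler from zero initial rates for every stimulus (so
results are independent of stimulus order), batched over stimuli.  Steady
states are accepted when the relative derivative criterion
max |dr| tau / (r + eps) drops below tolerance; non-convergent or diverging
runs are flagged, never silently accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _kernels
from .connectivity import WeightSet

__all__ = [
    "RateParams",
    "RateState",
    "CurrentDecomposition",
    "IntegrationError",
    "rate_rhs",
    "integrate_to_steady",
    "decompose_currents",
    "decay_protocol",
    "isn_diagnostics",
]


class IntegrationError(RuntimeError):
    """Raised when the rate dynamics diverge or a state goes non-finite."""


@dataclass(frozen=True)
class RateParams:
    """Rate-model parameters (times in ms, K and rates in arbitrary units)."""

    tau_E: float = 10.0
    tau_I: float = 6.67
    K: float = 0.01
    n_E: float = 2.2
    n_I: float = 2.2
    dt: float = 1.0
    T: float = 2000.0          # integration horizon
    tol: float = 1e-6          # relative-derivative steady-state tolerance
    rate_cap: float = 1e4      # divergence guard

    def __post_init__(self) -> None:
        if min(self.tau_E, self.tau_I, self.K, self.dt) <= 0:
            raise ValueError("tau, K and dt must be positive")
        if self.n_E < 1 or self.n_I < 1:
            raise ValueError("power-law exponents must be >= 1")
        if self.dt > min(self.tau_E, self.tau_I) / 5.0:
            raise ValueError("dt must be <= min(tau_E, tau_I)/5 for stability")


@dataclass
class RateState:
    """Rates of the two populations; columns index stimuli if batched."""

    rE: np.ndarray
    rI: np.ndarray
    t: float
    converged: np.ndarray | bool = True


@dataclass(frozen=True)
class CurrentDecomposition:
    """Input currents to one recorded cell at steady state (all >= 0; the
    inhibitory component is reported positive and enters the net with a
    minus sign)."""

    I_ext: float
    I_exc_recurrent: float
    I_inh: float

    @property
    def net(self) -> float:
        return self.I_ext + self.I_exc_recurrent - self.I_inh

    @property
    def total(self) -> float:
        return self.I_ext + self.I_exc_recurrent + self.I_inh

    @property
    def network_fraction(self) -> float:
        """Share of total input that is recurrent (network) rather than external."""
        return (self.I_exc_recurrent + self.I_inh) / self.total

    @property
    def excitatory_network_fraction(self) -> float:
        """Share of the network (recurrent) input that is excitatory."""
        denom = self.I_exc_recurrent + self.I_inh
        return self.I_exc_recurrent / denom if denom > 0 else np.nan


def _csr_arrays(W: WeightSet, dtype):
    """CSR triples of the four blocks in the requested dtype, cached on W."""
    key = np.dtype(dtype).name
    cache = getattr(W, "_csr_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(W, "_csr_cache", cache)
    if key not in cache:
        out = []
        for name in ("EE", "EI", "IE", "II"):
            block = W.blocks()[name]
            m = block.tocsr() if sp.issparse(block) else sp.csr_matrix(block)
            out.extend([m.indptr, m.indices, np.ascontiguousarray(m.data, dtype=dtype)])
        cache[key] = tuple(out)
    return cache[key]


def rate_rhs(rE, rI, drive, W: WeightSet, params: RateParams = RateParams()):
    """Time derivatives (drE/dt, drI/dt) of the rate equations."""
    rE = np.asarray(rE, dtype=float)
    rI = np.asarray(rI, dtype=float)
    if not (np.all(np.isfinite(rE)) and np.all(np.isfinite(rI))):
        raise IntegrationError("non-finite rate state passed to rate_rhs")
    netE = drive + W.W_EE @ rE - W.W_EI @ rI
    netI = drive + W.W_IE @ rE - W.W_II @ rI
    dE = (-rE + params.K * np.clip(netE, 0.0, None) ** params.n_E) / params.tau_E
    dI = (-rI + params.K * np.clip(netI, 0.0, None) ** params.n_I) / params.tau_I
    return dE, dI


def integrate_to_steady(
    drive,
    W: WeightSet,
    params: RateParams = RateParams(),
    init: RateState | None = None,
    dtype=np.float64,
    check_every: int = 25,
    max_dt_halvings: int = 3,
) -> RateState:
    """Integrate the rate equations to steady state for one or many stimuli.

    ``drive`` is a length-N vector or an (N, M) matrix whose columns are
    independent stimuli (each integrated from zero rates unless ``init`` is
    given).  Columns are retired from the batch as they converge.  If the
    dynamics diverge (rate cap exceeded), integration restarts with a halved
    time step up to ``max_dt_halvings`` times before raising
    :class:`IntegrationError`.

    Returns a :class:`RateState` whose ``converged`` field is a boolean array
    over stimuli (scalar input -> 1-column arrays are squeezed back).
    """
    drive = np.asarray(drive, dtype=dtype)
    squeeze = drive.ndim == 1
    if squeeze:
        drive = drive[:, None]
    N, M = drive.shape
    if N != W.n:
        raise ValueError(f"drive length {N} does not match weight size {W.n}")

    csr = _csr_arrays(W, dtype)
    dt = params.dt
    for attempt in range(max_dt_halvings + 1):
        rE_full = np.zeros((N, M), dtype=dtype)
        rI_full = np.zeros((N, M), dtype=dtype)
        if init is not None:
            rE_full[:] = np.asarray(init.rE, dtype=dtype).reshape(N, -1)
            rI_full[:] = np.asarray(init.rI, dtype=dtype).reshape(N, -1)
        converged = np.zeros(M, dtype=bool)
        active = np.arange(M)
        rE = np.ascontiguousarray(rE_full)
        rI = np.ascontiguousarray(rI_full)
        dr = np.ascontiguousarray(drive)
        work = [np.empty_like(rE) for _ in range(4)]
        steps_total = int(np.ceil(params.T / dt))
        step = 0
        diverged = False
        while step < steps_total and active.size:
            nsteps = min(check_every, steps_total - step)
            code, metric = _kernels.euler_chunk(
                *csr, dr, rE, rI,
                dtype(dt), dtype(params.tau_E), dtype(params.tau_I),
                dtype(params.K), dtype(params.n_E), dtype(params.n_I),
                nsteps, dtype(params.rate_cap),
                *work,
            )
            step += nsteps
            if code != 0:
                diverged = True
                break
            done = metric < params.tol
            if np.any(done):
                rE_full[:, active] = rE
                rI_full[:, active] = rI
                converged[active[done]] = True
                keep = ~done
                active = active[keep]
                if active.size:
                    rE = np.ascontiguousarray(rE[:, keep])
                    rI = np.ascontiguousarray(rI[:, keep])
                    dr = np.ascontiguousarray(drive[:, active])
                    work = [np.empty_like(rE) for _ in range(4)]
        if diverged:
            dt /= 2.0
            continue
        if active.size:
            rE_full[:, active] = rE
            rI_full[:, active] = rI
        state = RateState(
            rE=rE_full[:, 0] if squeeze else rE_full,
            rI=rI_full[:, 0] if squeeze else rI_full,
            t=step * dt,
            converged=bool(converged[0]) if squeeze else converged,
        )
        return state
    raise IntegrationError(
        f"rate dynamics exceeded cap {params.rate_cap} even at dt={dt * 2}; "
        f"params={params}"
    )


def decompose_currents(state: RateState, drive, W: WeightSet, cell: int,
                       population: str = "E") -> CurrentDecomposition:
    """Split the steady-state input to one cell into external, recurrent
    excitatory, and inhibitory (reported positive) components."""
    drive = np.asarray(drive, dtype=float)
    rE = np.asarray(state.rE, dtype=float)
    rI = np.asarray(state.rI, dtype=float)
    if rE.ndim != 1 or drive.ndim != 1:
        raise ValueError("decompose_currents expects a single-stimulus state; "
                         "select one column of a batched RateState")
    if population == "E":
        Wexc, Winh = W.W_EE, W.W_EI
    elif population == "I":
        Wexc, Winh = W.W_IE, W.W_II
    else:
        raise ValueError("population must be 'E' or 'I'")
    exc = float(np.asarray(Wexc[cell] @ rE).ravel()[0])
    inh = float(np.asarray(Winh[cell] @ rI).ravel()[0])
    return CurrentDecomposition(I_ext=float(drive[cell]), I_exc_recurrent=exc, I_inh=inh)


def decay_protocol(
    drive,
    W: WeightSet,
    params: RateParams = RateParams(),
    t_off: float = 200.0,
    t_post: float = 80.0,
    cells=None,
    dtype=np.float64,
    dt_record: float = 0.05,
    pre_tol: float = 1e-4,
):
    """Drive the network to steady state, silence the input, record the decay.

    The external input is integrated for ``t_off`` ms (checking that an
    operational steady state was reached), set to zero, and the decaying rates
    of the recorded cells are logged every ``dt_record`` ms for ``t_post`` ms.
    The recording step defaults to 0.05 ms, much finer than the pre-offset
    integration step: a forward-Euler step of size dt shortens an exponential
    decay constant tau to -dt/ln(1 - dt/tau), a ~5% bias at dt = 1 ms that
    the finer step removes from the fitted constants.  ``cells`` maps batch columns to recorded grid indices
    (one recorded cell per stimulus column); both the E and I rate at that
    location are recorded.

    Returns (times_ms, traceE, traceI, state_at_off); traces have shape
    (n_times, M) and start at t_off.
    """
    drive = np.asarray(drive, dtype=dtype)
    squeeze = drive.ndim == 1
    if squeeze:
        drive = drive[:, None]
    N, M = drive.shape
    if cells is None:
        raise ValueError("decay_protocol requires the recorded cell index per column")
    cells = np.atleast_1d(np.asarray(cells, dtype=np.int64))
    if cells.size != M:
        raise ValueError("need exactly one recorded cell per stimulus column")

    # Input removal happens at a fixed wall-clock time, as in the biological
    # silencing experiments; require only an operational steady state by then.
    pre = RateParams(**{**params.__dict__, "T": t_off, "tol": max(params.tol, pre_tol)})
    state = integrate_to_steady(drive, W, pre, dtype=dtype)
    conv = np.atleast_1d(state.converged)
    if not np.all(conv):
        warnings.warn(
            f"{int(np.sum(~conv))} stimuli had relative rate drift above {pre.tol} "
            f"at t_off={t_off} ms; proceeding with input removal",
            stacklevel=2,
        )

    dt = dt_record
    steps = int(round(t_post / dt))
    rE = np.ascontiguousarray(np.atleast_2d(state.rE.T).T.astype(dtype))
    rI = np.ascontiguousarray(np.atleast_2d(state.rI.T).T.astype(dtype))
    zero_drive = np.zeros_like(drive)
    outE = np.empty((steps, M), dtype=dtype)
    outI = np.empty((steps, M), dtype=dtype)
    work = [np.empty_like(rE) for _ in range(4)]
    csr = _csr_arrays(W, dtype)
    code = _kernels.euler_record(
        *csr, zero_drive, rE, rI,
        dtype(dt), dtype(params.tau_E), dtype(params.tau_I),
        dtype(params.K), dtype(params.n_E), dtype(params.n_I),
        steps, dtype(params.rate_cap),
        cells, outE, outI, *work,
    )
    if code != 0:
        raise IntegrationError("decay run diverged after input removal")
    times = t_off + dt * np.arange(1, steps + 1)
    return times, outE, outI, state


def isn_diagnostics(state: RateState, drive, W: WeightSet,
                    params: RateParams = RateParams(), k: int = 4):
    """Inhibition-stabilized-network check at a steady state.

    Linearizes the dynamics about (rE, rI).  Returns a dict with the leading
    real part of the E-subnetwork Jacobian eigenvalue (I rates frozen) and of
    the full 2N x 2N Jacobian.  The ISN signature is e_sub > 0 (the excitatory
    subnetwork alone is unstable) together with full < 0 (feedback inhibition
    stabilizes the whole circuit).
    """
    drive = np.asarray(drive, dtype=float)
    rE = np.asarray(state.rE, dtype=float)
    rI = np.asarray(state.rI, dtype=float)
    netE = drive + W.W_EE @ rE - W.W_EI @ rI
    netI = drive + W.W_IE @ rE - W.W_II @ rI
    phiE = params.K * params.n_E * np.clip(netE, 0.0, None) ** (params.n_E - 1.0)
    phiI = params.K * params.n_I * np.clip(netI, 0.0, None) ** (params.n_I - 1.0)

    DE = sp.diags(phiE)
    DI = sp.diags(phiI)
    N = W.n
    I_N = sp.identity(N, format="csr")
    # E subnetwork alone: tau_E dr/dt = (-I + diag(phiE) W_EE) r
    J_sub = (DE @ W.W_EE - I_N) / params.tau_E
    J_full = sp.bmat([
        [(DE @ W.W_EE - I_N) / params.tau_E, -(DE @ W.W_EI) / params.tau_E],
        [(DI @ W.W_IE) / params.tau_I, (-(DI @ W.W_II) - I_N) / params.tau_I],
    ], format="csr")

    def leading_real(A):
        vals = spla.eigs(A, k=k, which="LR", return_eigenvectors=False,
                         maxiter=5000, tol=1e-8)
        return float(np.max(vals.real))

    return {
        "e_subnetwork_leading_real": leading_real(J_sub),
        "full_leading_real": leading_real(J_full),
    }
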