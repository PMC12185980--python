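"""Distance- and orientation-dependent recurrent connectivity.

The connection strength from a presynaptic unit of type Y at grid location b
to a postsynaptic unit of type X at location a is

    W_XY[a, b] = J_XY * p_XY(|x_a - x_b|) * q_XY(|theta_a - theta_b|)

where distances wrap on the torus and orientation differences wrap on the
180-degree circle.  Excitatory projections have a flat plateau of radius
``L_o`` followed by a Gaussian tail, with *different* strength and orientation
tuning for the short-range (<= L_o) and long-range (> L_o) portions:
short-range connections are strong and broadly tuned in orientation,
long-range connections are weaker and sharply tuned.  Inhibitory projections
are purely local Gaussians with broad orientation tuning.  The connectivity is
completely deterministic given the orientation map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .geometry import GridSpec, OrientationMap, orientation_distance, torus_displacement

__all__ = [
    "ConnectivityParams",
    "WeightSet",
    "RegimeDiagnostics",
    "spatial_kernel_E",
    "spatial_kernel_I",
    "orientation_kernel",
    "build_weights",
    "regime_diagnostics",
    "weight_vs_distance_profile",
]

#: drop connections whose spatial factor falls below this in sparse mode
SPARSE_P_CUTOFF = 1e-4


@dataclass(frozen=True)
class ConnectivityParams:
    """Connectivity parameters; defaults are the model's standard values.

    ``J`` values are dimensionless synaptic strengths (the spiking backend
    passes conductances in nS through the same fields).  Distances are in grid
    intervals, orientation widths in degrees.  Index convention: ``J_XY`` is
    the strength from presynaptic type Y onto postsynaptic type X.
    """

    L_o: float = 3.0            # plateau radius of E projections
    sigma_EE: float = 3.0       # Gaussian tail widths of E projections
    sigma_IE: float = 6.0
    sigma_EI: float = 2.0       # Gaussian widths of I projections
    sigma_II: float = 2.0
    J_EE_short: float = 0.072
    J_IE_short: float = 0.06
    J_EE_long: float = 0.036
    J_IE_long: float = 0.036
    J_EI: float = 0.0528
    J_II: float = 0.0288
    # orientation kernel: short-range E and all I projections
    A_short: float = 0.2
    B_short: float = 0.8
    sigma_ori_short: float = 55.0
    # orientation kernel: long-range E projections
    A_long: float = 0.14
    B_long: float = 0.86
    sigma_ori_long: float = 25.0
    include_autapses: bool = True  # self-connections within a type (E->E, I->I)

    def __post_init__(self) -> None:
        for name in ("sigma_EE", "sigma_IE", "sigma_EI", "sigma_II",
                     "sigma_ori_short", "sigma_ori_long"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("J_EE_short", "J_IE_short", "J_EE_long", "J_IE_long", "J_EI", "J_II"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def scaled(self, factor: float) -> "ConnectivityParams":
        """All J values multiplied by ``factor`` (useful for controls)."""
        return replace(
            self,
            J_EE_short=self.J_EE_short * factor, J_IE_short=self.J_IE_short * factor,
            J_EE_long=self.J_EE_long * factor, J_IE_long=self.J_IE_long * factor,
            J_EI=self.J_EI * factor, J_II=self.J_II * factor,
        )


def spatial_kernel_E(x, sigma: float, L_o: float = 3.0):
    """Spatial profile of excitatory projections: plateau then Gaussian tail.

    Equals 1 for x <= L_o and exp(-(x - L_o)^2 / (2 sigma^2)) beyond, so the
    profile is continuous at the plateau edge.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    return np.where(x <= L_o, 1.0, np.exp(-((x - L_o) ** 2) / (2.0 * sigma**2)))


def spatial_kernel_I(x, sigma: float):
    """Spatial profile of inhibitory projections: a centered Gaussian."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    return np.exp(-(x**2) / (2.0 * sigma**2))


def orientation_kernel(dtheta, A: float, B: float, sigma_ori: float):
    """Orientation-difference factor: Gaussian with a nonzero baseline.

    q(Δθ) = A + B exp(-Δθ² / (2 σ_ori²)); with A + B = 1 the kernel is
    normalized to 1 at Δθ = 0.
    """
    dtheta = np.asarray(dtheta, dtype=float)
    return A + B * np.exp(-(dtheta**2) / (2.0 * sigma_ori**2))


@dataclass
class WeightSet:
    """The four connectivity blocks, each shape (N, N) with N = n_side².

    Blocks are CSR sparse (default) or dense ndarrays.  ``W_EE[a, b]`` is the
    connection from E cell b to E cell a; rates propagate as ``W @ r``.
    """

    W_EE: sp.csr_matrix | np.ndarray
    W_EI: sp.csr_matrix | np.ndarray
    W_IE: sp.csr_matrix | np.ndarray
    W_II: sp.csr_matrix | np.ndarray
    params: ConnectivityParams
    omap: OrientationMap

    @property
    def n(self) -> int:
        return self.W_EE.shape[0]

    def blocks(self):
        return {"EE": self.W_EE, "EI": self.W_EI, "IE": self.W_IE, "II": self.W_II}

    def save(self, path) -> None:
        """Persist as coordinate-triplet arrays (npz) plus map/params metadata."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        path = Path(path)
        arrays = {}
        for name, w in self.blocks().items():
            coo = w.tocoo() if sp.issparse(w) else sp.coo_matrix(w)
            arrays[f"{name}_row"] = coo.row
            arrays[f"{name}_col"] = coo.col
            arrays[f"{name}_val"] = coo.data
        np.savez_compressed(path.with_suffix(".npz"), theta=self.omap.theta, **arrays)
        meta = {
            "params": asdict(self.params),
            "grid": {"n_side": self.omap.grid.n_side,
                     "field_of_view": self.omap.grid.field_of_view,
                     "cmf": self.omap.grid.cmf},
            "map": {"k": self.omap.k, "n_waves": self.omap.n_waves, "seed": self.omap.seed},
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "WeightSet":
        import json
        from pathlib import Path

        from .geometry import GridSpec, OrientationMap

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        grid = GridSpec(**meta["grid"])
        with np.load(path.with_suffix(".npz")) as z:
            omap = OrientationMap(grid=grid, theta=z["theta"], **meta["map"])
            N = grid.n_cells
            blocks = {}
            for name in ("EE", "EI", "IE", "II"):
                blocks[name] = sp.csr_matrix(
                    (z[f"{name}_val"], (z[f"{name}_row"], z[f"{name}_col"])), shape=(N, N))
        return cls(W_EE=blocks["EE"], W_EI=blocks["EI"], W_IE=blocks["IE"],
                   W_II=blocks["II"], params=ConnectivityParams(**meta["params"]), omap=omap)

    def astype_csr32(self) -> dict:
        """Blocks as float32 CSR for the fast integrator path."""
        out = {}
        for name, w in self.blocks().items():
            m = sp.csr_matrix(w) if not sp.issparse(w) else w.tocsr()
            out[name] = m.astype(np.float32)
        return out


@dataclass(frozen=True)
class RegimeDiagnostics:
    """SSN regime parameters built from mean total synaptic weights.

    omega_E = W̄_II − W̄_EI and omega_I = W̄_IE − W̄_EE, where W̄_XY is the
    mean over postsynaptic cells of type X of the total (row-summed) weight
    from presynaptic type Y.  omega_E < 0 puts the network in the regime where
    excitatory responses saturate with increasing drive.
    """

    omega_E: float
    omega_I: float
    mean_totals: dict
    map_seed: int


def _offsets_within(n_side: int, radius: float) -> np.ndarray:
    """All (di, dj) wrapped offsets with torus distance <= radius, incl. (0,0)."""
    ax = np.arange(n_side)
    wrap = np.minimum(ax, n_side - ax).astype(float)
    dist = np.hypot(wrap[:, None], wrap[None, :])
    di, dj = np.nonzero(dist <= radius)
    return np.column_stack([di, dj])


def _e_kernel_cutoff(sigma: float, L_o: float) -> float:
    return L_o + sigma * np.sqrt(2.0 * np.log(1.0 / SPARSE_P_CUTOFF))


def _i_kernel_cutoff(sigma: float) -> float:
    return sigma * np.sqrt(2.0 * np.log(1.0 / SPARSE_P_CUTOFF))


def build_weights(
    omap: OrientationMap,
    params: ConnectivityParams = ConnectivityParams(),
    mode: Literal["sparse", "dense"] = "sparse",
    dense_cap_cells: int = 2500,
) -> WeightSet:
    """Build the four weight blocks from the orientation map.

    In ``sparse`` mode, connections whose spatial factor p falls below
    ``SPARSE_P_CUTOFF`` (1e-4, about 4.3 sigma into the Gaussian tail) are
    dropped and blocks are CSR matrices.  ``dense`` mode keeps every pair and
    returns ndarrays; it is refused above ``dense_cap_cells`` cells per side
    squared to avoid accidental multi-GB allocations.

    The construction iterates over wrapped lattice offsets: every pair at the
    same offset shares the spatial factor, while the orientation factor is
    evaluated from the map for all pairs of that offset at once.
    """
    grid = omap.grid
    n = grid.n_side
    N = grid.n_cells
    theta = omap.theta

    if mode == "dense" and N > dense_cap_cells:
        raise MemoryError(
            f"dense mode with N={N} cells would allocate 4x{N}x{N} doubles; "
            "use sparse mode for large grids"
        )

    base = np.arange(N, dtype=np.int64).reshape(n, n)

    if mode == "dense":
        max_r = float(np.hypot(n, n))  # keep all offsets
        cutoffs = {"EE": max_r, "IE": max_r, "EI": max_r, "II": max_r}
    else:
        cutoffs = {
            "EE": _e_kernel_cutoff(params.sigma_EE, params.L_o),
            "IE": _e_kernel_cutoff(params.sigma_IE, params.L_o),
            "EI": _i_kernel_cutoff(params.sigma_EI),
            "II": _i_kernel_cutoff(params.sigma_II),
        }
    offsets = _offsets_within(n, max(cutoffs.values()))
    wrap_ax = np.minimum(np.arange(n), n - np.arange(n)).astype(float)

    rows = {k: [] for k in cutoffs}
    cols = {k: [] for k in cutoffs}
    data = {k: [] for k in cutoffs}
    dense = None
    if mode == "dense":
        dense = {k: np.zeros((N, N)) for k in cutoffs}

    a_rows = np.arange(N, dtype=np.int64)
    for di, dj in offsets:
        d = float(np.hypot(wrap_ax[di], wrap_ax[dj]))
        # preferred orientations of pre cells at offset (di, dj) from each post cell
        theta_b = np.roll(theta, shift=(-di, -dj), axis=(0, 1))
        dth = orientation_distance(theta, theta_b).ravel()
        col_idx = np.roll(base, shift=(-di, -dj), axis=(0, 1)).ravel()
        is_self = di == 0 and dj == 0

        # E projections: short-range strengths/tuning strictly below L_o;
        # at exactly L_o the long-range values apply with p = 1 (continuity)
        if d < params.L_o:
            q_e = orientation_kernel(dth, params.A_short, params.B_short, params.sigma_ori_short)
            vals = {"EE": params.J_EE_short * q_e, "IE": params.J_IE_short * q_e}
        else:
            q_e = orientation_kernel(dth, params.A_long, params.B_long, params.sigma_ori_long)
            p_EE = spatial_kernel_E(d, params.sigma_EE, params.L_o)
            p_IE = spatial_kernel_E(d, params.sigma_IE, params.L_o)
            vals = {"EE": params.J_EE_long * p_EE * q_e, "IE": params.J_IE_long * p_IE * q_e}
        # I projections: single kernel class
        q_i = orientation_kernel(dth, params.A_short, params.B_short, params.sigma_ori_short)
        vals["EI"] = params.J_EI * spatial_kernel_I(d, params.sigma_EI) * q_i
        vals["II"] = params.J_II * spatial_kernel_I(d, params.sigma_II) * q_i

        for cls, v in vals.items():
            if d > cutoffs[cls]:
                continue
            if is_self and not params.include_autapses and cls in ("EE", "II"):
                continue
            if dense is not None:
                dense[cls][a_rows, col_idx] = v
            else:
                rows[cls].append(a_rows)
                cols[cls].append(col_idx)
                data[cls].append(v)

    if dense is not None:
        blocks = dense
    else:
        blocks = {}
        for cls in cutoffs:
            r = np.concatenate(rows[cls]).astype(np.int32)
            c = np.concatenate(cols[cls]).astype(np.int32)
            v = np.concatenate(data[cls])
            blocks[cls] = sp.csr_matrix((v, (r, c)), shape=(N, N))

    return WeightSet(W_EE=blocks["EE"], W_EI=blocks["EI"], W_IE=blocks["IE"],
                     W_II=blocks["II"], params=params, omap=omap)


def regime_diagnostics(W: WeightSet) -> RegimeDiagnostics:
    """Compute the SSN regime parameters Ω_E and Ω_I from a WeightSet."""
    totals = {}
    for name, block in W.blocks().items():
        if sp.issparse(block):
            totals[name] = float(np.asarray(block.sum(axis=1)).mean())
        else:
            totals[name] = float(block.sum(axis=1).mean())
    return RegimeDiagnostics(
        omega_E=totals["II"] - totals["EI"],
        omega_I=totals["IE"] - totals["EE"],
        mean_totals=totals,
        map_seed=W.omap.seed,
    )


def weight_vs_distance_profile(
    W: WeightSet,
    max_mm: float = 2.0,
    bin_mm: float = 0.05,
):
    """Mean connection strength vs cortical distance, per class.

    Averages W_XY over *all* ordered cell pairs whose torus distance falls in
    each cortical-distance bin, evaluating the connection-strength rule
    J·p·q directly (so the 0-mm bin reports the same-site kernel value
    irrespective of the autapse bookkeeping convention).  Returns a dict of
    class name -> (bin_centers_mm, mean_weight); bins containing no pairs
    hold NaN.
    """
    grid = W.omap.grid
    p = W.params
    n = grid.n_side
    theta = W.omap.theta
    wrap_ax = np.minimum(np.arange(n), n - np.arange(n)).astype(float)
    max_r = max_mm / grid.mm_per_cell
    offsets = _offsets_within(n, max_r)

    nbins = int(np.ceil(max_mm / bin_mm))
    sums = {k: np.zeros(nbins) for k in ("EE", "EI", "IE", "II")}
    counts = np.zeros(nbins)

    for di, dj in offsets:
        d = float(np.hypot(wrap_ax[di], wrap_ax[dj]))
        b = int(d * grid.mm_per_cell / bin_mm)
        if b >= nbins:
            continue
        theta_b = np.roll(theta, shift=(-di, -dj), axis=(0, 1))
        dth = orientation_distance(theta, theta_b)
        q_i = orientation_kernel(dth, p.A_short, p.B_short, p.sigma_ori_short)
        if d < p.L_o:
            q_e = q_i
            w = {"EE": p.J_EE_short * q_e, "IE": p.J_IE_short * q_e}
        else:
            q_e = orientation_kernel(dth, p.A_long, p.B_long, p.sigma_ori_long)
            w = {"EE": p.J_EE_long * spatial_kernel_E(d, p.sigma_EE, p.L_o) * q_e,
                 "IE": p.J_IE_long * spatial_kernel_E(d, p.sigma_IE, p.L_o) * q_e}
        w["EI"] = p.J_EI * spatial_kernel_I(d, p.sigma_EI) * q_i
        w["II"] = p.J_II * spatial_kernel_I(d, p.sigma_II) * q_i
        npairs = theta.size
        counts[b] += npairs
        for cls in sums:
            sums[cls][b] += float(np.sum(w[cls]))

    centers = (np.arange(nbins) + 0.5) * bin_mm
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for cls in sums:
            mean = np.where(counts > 0, sums[cls] / np.maximum(counts, 1), np.nan)
            out[cls] = (centers, mean)
    return out
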