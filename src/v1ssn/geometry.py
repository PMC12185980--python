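"""Cortical grid geometry and orientation-map synthesis.

The model cortex is a periodic square lattice of ``n_side × n_side`` grid
points.  Each point hosts one excitatory and one inhibitory cell.  The lattice
is calibrated both in visual degrees (``field_of_view`` degrees per side) and
in cortical millimetres through the cortical magnification factor (``cmf``,
mm of cortex per degree of visual angle).

A smooth orientation preference map is synthesized by superposing ``n_waves``
complex plane waves with random signs and phases; the preferred orientation at
each point is half the phase of the resulting complex field, so orientations
live on the 180-degree circle.  The map itself is *not* periodic (there is an
orientation discontinuity at the borders), but positions, distances and
connections wrap around the torus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "OrientationMap",
    "make_orientation_map",
    "torus_displacement",
    "torus_distance",
    "orientation_distance",
    "map_autocorrelation",
]


@dataclass(frozen=True)
class GridSpec:
    """Square periodic grid with visual-field and cortical calibration.

    Parameters
    ----------
    n_side
        Grid points per side (default 75, i.e. 5625 cells of each type).
    field_of_view
        Visual degrees represented per side (default 16.0).
    cmf
        Cortical magnification factor in mm of cortex per degree (default 0.5).
    """

    n_side: int = 75
    field_of_view: float = 16.0
    cmf: float = 0.5

    def __post_init__(self) -> None:
        if self.n_side < 4:
            raise ValueError(f"n_side must be >= 4, got {self.n_side}")
        if self.field_of_view <= 0 or self.cmf <= 0:
            raise ValueError("field_of_view and cmf must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_side * self.n_side

    @property
    def deg_per_cell(self) -> float:
        """Visual degrees per grid interval (defaults give ~0.2133 deg)."""
        return self.field_of_view / self.n_side

    @property
    def mm_per_cell(self) -> float:
        """Cortical mm per grid interval (defaults give ~0.1067 mm)."""
        return self.deg_per_cell * self.cmf

    def positions_deg(self) -> np.ndarray:
        """Visual-field positions of all cells, shape (n_cells, 2).

        Cell (i, j) sits at ((i + 0.5) * deg_per_cell, (j + 0.5) * deg_per_cell);
        the half-cell offset centers the lattice in its visual field.  Cells are
        enumerated in row-major order (index = i * n_side + j).
        """
        ax = (np.arange(self.n_side) + 0.5) * self.deg_per_cell
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def cell_index(self, i: int, j: int) -> int:
        return i * self.n_side + j


def torus_displacement(delta: np.ndarray, n_side: int) -> np.ndarray:
    """Per-axis wrapped displacement magnitude min(|d|, n_side - |d|)."""
    d = np.abs(np.asarray(delta))
    return np.minimum(d, n_side - d)


def torus_distance(a, b, grid: GridSpec) -> float:
    """Shortest Euclidean distance (in grid intervals) across the periodic grid.

    ``a`` and ``b`` are (i, j) grid coordinates.  Each axis displacement wraps
    independently: min(|Δ|, n_side − |Δ|).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(a >= grid.n_side) or np.any(b < 0) or np.any(b >= grid.n_side):
        raise ValueError("grid coordinates out of range")
    w = torus_displacement(a - b, grid.n_side)
    return float(np.hypot(w[..., 0], w[..., 1]))


def orientation_distance(theta_a, theta_b):
    """Shortest angular distance on the 180-degree orientation circle.

    Inputs in degrees (any real values; reduced mod 180).  Result in [0, 90].
    """
    d = np.abs(np.mod(np.asarray(theta_a, dtype=float) - np.asarray(theta_b, dtype=float), 180.0))
    return np.minimum(d, 180.0 - d)


@dataclass
class OrientationMap:
    """Preferred-orientation map over a :class:`GridSpec`.

    ``theta`` holds orientations in degrees in [0, 180), shape
    (n_side, n_side).  ``signs`` and ``phases`` are the random plane-wave
    parameters actually used, kept for provenance.
    """

    grid: GridSpec
    theta: np.ndarray
    k: float
    n_waves: int
    seed: int
    signs: np.ndarray = field(repr=False, default=None)
    phases: np.ndarray = field(repr=False, default=None)

    @property
    def theta_flat(self) -> np.ndarray:
        """Row-major flattened orientations, aligned with GridSpec.positions_deg."""
        return self.theta.ravel()

    def save(self, path) -> None:
        """Save as a dense ``.npy`` array plus a JSON sidecar of parameters."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.theta)
        sidecar = {
            "n_side": self.grid.n_side,
            "field_of_view": self.grid.field_of_view,
            "cmf": self.grid.cmf,
            "k": self.k,
            "n_waves": self.n_waves,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "OrientationMap":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        grid = GridSpec(meta["n_side"], meta["field_of_view"], meta["cmf"])
        theta = np.load(path.with_suffix(".npy"))
        return cls(grid=grid, theta=theta, k=meta["k"], n_waves=meta["n_waves"], seed=meta["seed"])


def make_orientation_map(
    grid: GridSpec = GridSpec(),
    k: float = 8.0 / 75.0,
    n_waves: int = 30,
    seed: int = 0,
) -> OrientationMap:
    """Synthesize an orientation map from superposed complex plane waves.

    z(x) = Σ_j exp(i (l_j k_j · x + φ_j)), with wave vectors
    k_j = 2πk (cos(jπ/n), sin(jπ/n)) for j = 1..n, random signs
    l_j ∈ {+1, −1} and random phases φ_j ∈ [0, 2π).  The preferred orientation
    is arg(z)/2 mapped to degrees in [0, 180).

    Parameters
    ----------
    k
        Map spatial frequency in cycles per grid interval.  The default
        8/75 gives on average eight full map periods per grid side.
    n_waves
        Number of superposed plane waves (default 30).
    seed
        Seed for the random signs/phases.  Draw order is fixed: first all
        phases (uniform [0, 2π)), then all signs (uniform ±1), so maps are
        reproducible across platforms.
    """
    if n_waves < 1:
        raise ValueError(f"n_waves must be >= 1, got {n_waves}")
    if k <= 0:
        raise ValueError(f"map wavenumber k must be positive, got {k}")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
    signs = np.where(rng.random(n_waves) < 0.5, 1.0, -1.0)

    j = np.arange(1, n_waves + 1)
    ang = j * np.pi / n_waves
    kvec = 2.0 * np.pi * k * np.column_stack([np.cos(ang), np.sin(ang)])  # rad per interval

    ax = np.arange(grid.n_side, dtype=float)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    z = np.zeros((grid.n_side, grid.n_side), dtype=complex)
    for lj, ph, (kx, ky) in zip(signs, phases, kvec):
        z += np.exp(1j * (lj * (kx * xx + ky * yy) + ph))

    theta = np.degrees(np.mod(np.angle(z), 2.0 * np.pi)) / 2.0
    # guard against theta == 180 from rounding at mod boundary
    theta = np.where(theta >= 180.0, theta - 180.0, theta)
    return OrientationMap(grid=grid, theta=theta, k=k, n_waves=n_waves, seed=seed,
                          signs=signs, phases=phases)


def map_autocorrelation(omap: OrientationMap, max_lag: int | None = None):
    """Radially averaged spatial autocorrelation of exp(2iθ).

    Returns (lags, corr) with lags in grid intervals and corr normalized to 1
    at zero lag.  Computed with periodic wrap via FFT; only the real part is
    returned (the imaginary part vanishes on average by symmetry).
    """
    n = omap.grid.n_side
    if max_lag is None:
        max_lag = n // 2
    u = np.exp(2j * np.radians(omap.theta))
    f = np.fft.fft2(u)
    acf = np.fft.ifft2(f * np.conj(f)).real / u.size
    acf /= acf[0, 0]
    dx = np.minimum(np.arange(n), n - np.arange(n))
    dist = np.hypot(dx[:, None], dx[None, :])
    bins = np.arange(max_lag + 1)
    idx = np.clip(np.round(dist).astype(int), 0, None)
    mask = idx <= max_lag
    sums = np.bincount(idx[mask], weights=acf[mask], minlength=max_lag + 1)
    counts = np.bincount(idx[mask], minlength=max_lag + 1)
    return bins.astype(float), sums / counts
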