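"""Summary statistics and fits for the measurement protocols.

Covers the suppression index SI = (r_max - r_inf)/r_max over size-tuning
curves, the modified suppression index SI_m for center/surround composites,
summation field size (argmax for noiseless rate curves, a
difference-of-Gaussian-integrals fit for noisy spiking curves), surround
modulation maps, von Mises population fits with nonnegative plaid weight
decomposition, and exponential decay-constant fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, nnls
from scipy.special import erf

__all__ = [
    "SizeTuningCurve",
    "SuppressionMetrics",
    "PlaidDecomposition",
    "suppression_index",
    "modified_suppression_index",
    "summation_field_size",
    "double_gaussian_curve",
    "fit_double_gaussian",
    "surround_modulation_map",
    "von_mises",
    "fit_von_mises",
    "plaid_weight_fit",
    "fit_exponential_decay",
]

#: minimum coefficient of determination for a fit to count as usable
FIT_R2_THRESHOLD = 0.6


@dataclass
class SizeTuningCurve:
    """Response versus stimulus width for one cell at one contrast."""

    sizes: np.ndarray       # degrees, strictly increasing
    responses: np.ndarray   # rate (Hz-like a.u.) or current, >= 0
    cell: int = -1
    contrast: float = np.nan

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.sizes.ndim != 1 or self.sizes.size != self.responses.size:
            raise ValueError("sizes and responses must be 1-D and equal length")
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")


@dataclass(frozen=True)
class SuppressionMetrics:
    SI: float
    SFS: float
    r_max: float
    r_inf: float


def suppression_index(curve: SizeTuningCurve) -> float:
    """SI = (r_max - r_inf) / r_max with r_inf the response at the largest
    tested size.  1 means complete suppression, 0 none."""
    if curve.sizes.size < 3:
        raise ValueError("need at least 3 sizes for a suppression index")
    r_max = float(np.max(curve.responses))
    if r_max <= 0:
        raise ValueError("suppression index undefined for an all-zero curve")
    r_inf = float(curve.responses[-1])
    return (r_max - r_inf) / r_max


def modified_suppression_index(r_center: float, r_center_plus_surround: float) -> float:
    """SI_m = (r_c - r_cs)/r_c; negative = facilitation, positive = suppression."""
    if r_center <= 0:
        raise ValueError("modified suppression index undefined for r_center <= 0")
    return (r_center - r_center_plus_surround) / r_center


def summation_field_size(curve: SizeTuningCurve, method: str = "argmax") -> float:
    """Stimulus width (deg) of maximal response before surround suppression.

    ``argmax`` (rate model) returns the tested size of peak response, ties
    broken toward the smallest size.  ``double_gaussian`` (spiking model) fits
    a difference of Gaussian integrals and returns the analytic peak of the
    fitted curve; raises ValueError if the fit quality is below threshold.
    """
    if method == "argmax":
        return float(curve.sizes[int(np.argmax(curve.responses))])
    if method == "double_gaussian":
        fit = fit_double_gaussian(curve)
        if fit is None:
            raise ValueError("double-Gaussian fit failed or below quality threshold")
        return fit["sfs"]
    raise ValueError(f"unknown SFS method {method!r}")


def double_gaussian_curve(s, k_e, sig_e, k_i, sig_i):
    """Difference-of-Gaussian-integrals size-tuning curve.

    R(s) = k_e * E(s, sig_e) - k_i * E(s, sig_i) where
    E(s, sig) = erf(s / (sqrt(2) sig))^2 is the (squared, separable) integral
    of a centered Gaussian over a square of width s.
    """
    s = np.asarray(s, dtype=float)
    return (k_e * erf(s / (np.sqrt(2.0) * sig_e)) ** 2
            - k_i * erf(s / (np.sqrt(2.0) * sig_i)) ** 2)


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)


def fit_double_gaussian(curve: SizeTuningCurve, r2_threshold: float = FIT_R2_THRESHOLD):
    """Fit the difference-of-Gaussian-integrals model to a size-tuning curve.

    Returns a dict with the parameters, the fitted-curve SI (r_inf at the
    largest tested size), the analytic SFS, and the R^2 — or None when the
    optimizer fails or R^2 falls below threshold.
    """
    s, r = curve.sizes, curve.responses
    rmax = float(np.max(r))
    if rmax <= 0:
        return None
    s_peak = s[int(np.argmax(r))]
    p0 = (2.0 * rmax, max(s_peak / 2.0, 0.1), rmax, max(s_peak, 0.2))
    bounds = ([0.0, 1e-3, 0.0, 1e-3], [np.inf, 50.0, np.inf, 50.0])
    try:
        popt, _ = curve_fit(double_gaussian_curve, s, r, p0=p0, bounds=bounds,
                            maxfev=20000)
    except RuntimeError:
        return None
    yhat = double_gaussian_curve(s, *popt)
    r2 = _r2(r, yhat)
    if r2 < r2_threshold:
        return None
    grid = np.linspace(s[0], s[-1], 2000)
    smooth = double_gaussian_curve(grid, *popt)
    sfs = float(grid[int(np.argmax(smooth))])
    r_max_fit = float(np.max(smooth))
    r_inf_fit = float(smooth[-1])
    si = (r_max_fit - r_inf_fit) / r_max_fit if r_max_fit > 0 else np.nan
    return {"params": popt, "r2": r2, "sfs": sfs, "si": si,
            "r_max": r_max_fit, "r_inf": r_inf_fit}


def surround_modulation_map(center_surround: np.ndarray, center_only: np.ndarray,
                            surround_offsets: np.ndarray):
    """Normalized surround-modulation matrix and most-suppressive surround.

    ``center_surround`` has shape (n_center, n_surround): response with the
    annulus at each surround orientation for each center orientation.
    ``center_only`` has shape (n_center,).  Each row is divided by its
    center-only response and shifted so its minimum is exactly zero.  Rows
    with a nonpositive center-only response are dropped (returned mask).

    Returns (modulation, most_suppressive_offset, row_mask): the
    most-suppressive surround (per kept row) is the surround offset at the
    row's minimum of the *raw* ratio, ties broken toward the offset closest
    to the row's center orientation (assumed encoded in the same offset
    coordinates, i.e. offsets are relative to a common reference).
    """
    cs = np.asarray(center_surround, dtype=float)
    co = np.asarray(center_only, dtype=float)
    offs = np.asarray(surround_offsets, dtype=float)
    if cs.shape[0] != co.size or cs.shape[1] != offs.size:
        raise ValueError("shape mismatch between responses and offsets")
    mask = co > 0
    ratio = cs[mask] / co[mask, None]
    modulation = ratio - ratio.min(axis=1, keepdims=True)
    most = np.empty(int(mask.sum()))
    for r in range(ratio.shape[0]):
        row = ratio[r]
        cand = np.flatnonzero(row == row.min())
        most[r] = offs[cand[np.argmin(np.abs(offs[cand]))]]
    return modulation, most, mask


def von_mises(theta_deg, baseline, amplitude, kappa, mu_deg):
    """180-degree-periodic von Mises tuning curve.

    b + a * exp(kappa * (cos(2 (theta - mu)) - 1)); the -1 normalizes the
    peak to b + a.
    """
    d = np.radians(np.asarray(theta_deg, dtype=float) - mu_deg)
    return baseline + amplitude * np.exp(kappa * (np.cos(2.0 * d) - 1.0))


def fit_von_mises(theta_deg, responses, r2_threshold: float = FIT_R2_THRESHOLD):
    """Fit a von Mises curve to population responses vs preferred orientation.

    Returns (params, r2) or None when the fit fails or is below threshold.
    """
    theta = np.asarray(theta_deg, dtype=float)
    r = np.asarray(responses, dtype=float)
    if theta.size < 5:
        return None
    b0 = float(np.min(r))
    a0 = float(np.max(r) - b0)
    mu0 = float(theta[int(np.argmax(r))])
    if a0 <= 0:
        return None
    try:
        popt, _ = curve_fit(
            von_mises, theta, r, p0=(b0, a0, 2.0, mu0),
            bounds=([-np.inf, 0.0, 0.0, mu0 - 90.0], [np.inf, np.inf, 50.0, mu0 + 90.0]),
            maxfev=20000,
        )
    except RuntimeError:
        return None
    r2 = _r2(r, von_mises(theta, *popt))
    if r2 < r2_threshold:
        return None
    return popt, r2


@dataclass
class PlaidDecomposition:
    """Weights of the plaid response as w1*P1 + w2*P2 over the population.

    ``missing`` flags decompositions where a component fit or the weight fit
    fell below the quality threshold (such points are excluded from
    aggregates, mirroring how unfittable stimulus configurations are dropped).
    """

    w1: float
    w2: float
    r2: float
    plaid_angle: float = np.nan
    rotation: float = np.nan
    missing: bool = False
    degenerate: bool = False


def plaid_weight_fit(theta_bins, resp_comp1, resp_comp2, resp_plaid,
                     plaid_angle: float = np.nan, rotation: float = np.nan,
                     r2_threshold: float = FIT_R2_THRESHOLD) -> PlaidDecomposition:
    """Decompose a plaid population response onto its component responses.

    P1 and P2 are von Mises fits to the component-alone responses over
    preferred-orientation bins; (w1, w2) solve a nonnegative least-squares fit
    of the plaid (or plaid+surround) response against (P1, P2) evaluated at
    the same bins.  No additive baseline is fitted.  A zero plaid angle makes
    the design collinear: the decomposition is flagged ``degenerate`` and the
    summed weight is reported in w1 (w2 = 0).
    """
    theta = np.asarray(theta_bins, dtype=float)
    f1 = fit_von_mises(theta, resp_comp1, r2_threshold)
    f2 = fit_von_mises(theta, resp_comp2, r2_threshold)
    if f1 is None or f2 is None:
        return PlaidDecomposition(np.nan, np.nan, np.nan, plaid_angle, rotation, missing=True)
    P1 = von_mises(theta, *f1[0])
    P2 = von_mises(theta, *f2[0])
    y = np.asarray(resp_plaid, dtype=float)
    if np.isclose(plaid_angle % 180.0, 0.0):
        w, _ = nnls(P1[:, None], y)
        yhat = w[0] * P1
        return PlaidDecomposition(float(w[0]), 0.0, _r2(y, yhat), plaid_angle,
                                  rotation, degenerate=True)
    A = np.column_stack([P1, P2])
    w, _ = nnls(A, y)
    yhat = A @ w
    r2 = _r2(y, yhat)
    if r2 < r2_threshold:
        return PlaidDecomposition(float(w[0]), float(w[1]), r2, plaid_angle,
                                  rotation, missing=True)
    return PlaidDecomposition(float(w[0]), float(w[1]), r2, plaid_angle, rotation)


def fit_exponential_decay(times, values, t_off: float = 0.0,
                          floor_fraction: float = 0.01,
                          start_delay: float = 1.0) -> float:
    """Decay constant tau (same units as ``times``) from a log-linear fit.

    The fit window runs from ``t_off + start_delay`` until the trace first
    falls below ``floor_fraction`` of its value at the window start reference
    (the first recorded point at/after t_off).  Raises ValueError for traces
    that are too short, non-positive, or non-decaying.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values must have equal length")
    after = t >= t_off
    t, y = t[after], y[after]
    if t.size == 0 or y[0] <= 0:
        raise ValueError("no positive activity at input-removal time")
    ref = y[0]
    below = np.flatnonzero(y < floor_fraction * ref)
    end = below[0] if below.size else t.size
    win = (t >= t_off + start_delay) & (np.arange(t.size) < end) & (y > 0)
    if int(win.sum()) < 5:
        raise ValueError("fewer than 5 usable points in the decay window")
    slope, _ = np.polyfit(t[win], np.log(y[win]), 1)
    if slope >= -1e-12:
        raise ValueError("trace is not decaying; tau undefined")
    return float(-1.0 / slope)
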