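"""Declarative visual stimuli and the feedforward drive they evoke.

Stimuli are reduced to three features: contrast, orientation and size.
A stimulus component is a square grating (or a square annulus, i.e. the
difference of two concentric squares) of contrast C and orientation theta_s.
The external input it delivers to a cell at visual position x_o with
preferred orientation theta_o factorizes as

    f(C) * h_l(x_s - x_o) * g(|theta_s - theta_o|)

where f is a Naka-Rushton contrast-response function, h_l is the square
aperture blurred by a small Gaussian (closed form in terms of erf) and g is a
Gaussian orientation-match factor.  Multiple components (plaids,
center+surround composites) contribute additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .geometry import OrientationMap, orientation_distance

__all__ = [
    "InputParams",
    "Grating",
    "Annulus",
    "StimulusSpec",
    "contrast_response",
    "aperture_profile",
    "orientation_gain",
    "render_input",
]


@dataclass(frozen=True)
class InputParams:
    """Parameters of the stimulus-to-input transformation.

    f_max
        Maximal external drive (and, for the spiking backend, the maximal
        external-population firing rate in Hz).
    c50, exponent
        Naka-Rushton half-saturation contrast and exponent.
    sigma_in
        Gaussian blur of the square aperture, visual degrees.
    sigma_f_ori
        Width of the orientation-match factor g, degrees.
    """

    f_max: float = 50.0
    c50: float = 11.0
    exponent: float = 3.5
    sigma_in: float = 0.09
    sigma_f_ori: float = 20.0

    def __post_init__(self) -> None:
        if min(self.f_max, self.c50, self.exponent, self.sigma_in, self.sigma_f_ori) <= 0:
            raise ValueError("all InputParams fields must be positive")


@dataclass(frozen=True)
class Grating:
    """Square grating patch: contrast, orientation (deg), width (deg), center (deg)."""

    contrast: float
    orientation: float
    width: float
    center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.contrast < 0:
            raise ValueError("contrast must be nonnegative")
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class Annulus:
    """Square annulus: the region between two concentric squares.

    ``inner`` and ``outer`` are the widths (side lengths, degrees) of the two
    squares.  Its aperture profile is h_outer - h_inner, which is exact by
    linearity of the Gaussian blur.
    """

    contrast: float
    orientation: float
    inner: float
    outer: float
    center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.contrast < 0:
            raise ValueError("contrast must be nonnegative")
        if not 0 < self.inner < self.outer:
            raise ValueError("annulus requires 0 < inner width < outer width")


@dataclass(frozen=True)
class StimulusSpec:
    """A stimulus: a list of additive Grating / Annulus components."""

    components: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))

    @classmethod
    def grating(cls, contrast, orientation, width, center):
        return cls((Grating(contrast, orientation, width, center),))

    @classmethod
    def center_surround(cls, center_stim: Grating, surround: Annulus):
        return cls((center_stim, surround))

    @classmethod
    def plaid(cls, contrast, orientation1, orientation2, width, center):
        """Two superimposed gratings, each at the stated per-component contrast."""
        return cls((
            Grating(contrast, orientation1, width, center),
            Grating(contrast, orientation2, width, center),
        ))


def contrast_response(C, params: InputParams = InputParams()):
    """Naka-Rushton contrast response f(C) = f_max C^n / (C50^n + C^n)."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("contrast must be nonnegative")
    n = params.exponent
    Cn = np.power(C, n)
    return params.f_max * Cn / (params.c50**n + Cn)


def aperture_profile(dx, dy, width: float, sigma_in: float = 0.09):
    """Blurred square aperture, separable erf product in each axis.

    ``(dx, dy)`` is the displacement (deg) of the stimulus center from the
    cell's position; returns values in [0, 1], ~1 well inside the square and
    ~0 well outside.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    s = sigma_in * np.sqrt(2.0)
    half = width / 2.0
    hx = erf((half + np.asarray(dx, dtype=float)) / s) + erf((half - np.asarray(dx)) / s)
    hy = erf((half + np.asarray(dy, dtype=float)) / s) + erf((half - np.asarray(dy)) / s)
    return 0.25 * hx * hy


def orientation_gain(dtheta, sigma_f_ori: float = 20.0):
    """Orientation-match factor g = exp(-dtheta^2 / (2 sigma_f^2)), dtheta in deg."""
    dtheta = np.asarray(dtheta, dtype=float)
    return np.exp(-(dtheta**2) / (2.0 * sigma_f_ori**2))


def _component_drive(comp, positions: np.ndarray, theta: np.ndarray, params: InputParams):
    dx = comp.center[0] - positions[:, 0]
    dy = comp.center[1] - positions[:, 1]
    if isinstance(comp, Grating):
        h = aperture_profile(dx, dy, comp.width, params.sigma_in)
    elif isinstance(comp, Annulus):
        h = (aperture_profile(dx, dy, comp.outer, params.sigma_in)
             - aperture_profile(dx, dy, comp.inner, params.sigma_in))
    else:  # pragma: no cover - guarded by StimulusSpec construction
        raise TypeError(f"unknown stimulus component {type(comp)!r}")
    g = orientation_gain(orientation_distance(comp.orientation, theta), params.sigma_f_ori)
    return contrast_response(comp.contrast, params) * h * g


def render_input(
    spec: StimulusSpec,
    omap: OrientationMap,
    params: InputParams = InputParams(),
) -> np.ndarray:
    """External drive vector (length N, nonnegative) for a stimulus.

    Components add linearly; the result is clipped at zero (annulus
    differences can undershoot by floating-point rounding only).  The same
    drive feeds both the E and I cell at each location.
    """
    positions = omap.grid.positions_deg()
    theta = omap.theta_flat
    drive = np.zeros(omap.grid.n_cells)
    for comp in spec.components:
        drive += _component_drive(comp, positions, theta, params)
    drive = np.clip(drive, 0.0, None)
    # flush the far-field erf tail to exact zero: it is physically negligible
    # and would otherwise seed subnormal-range rates that stall the integrator
    drive[drive < 1e-12] = 0.0
    return drive


def render_inputs(
    specs,
    omap: OrientationMap,
    params: InputParams = InputParams(),
) -> np.ndarray:
    """Drive matrix of shape (N, len(specs)); column j renders specs[j]."""
    return np.column_stack([render_input(s, omap, params) for s in specs])
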