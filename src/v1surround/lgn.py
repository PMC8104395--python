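"""LGN front end: difference-of-Gaussians spatial filtering of grating stimuli.

LGN cells act as fixed linear filters with a center-surround receptive field.
The response of the LGN group at lattice point z* to a full-contrast drifting
grating of radius R (represented abstractly by the indicator g_R of the
stimulated disk) is the rectified convolution

    LGN(z*) = max{ sum_z  h^2 f_DoG(z - z*) g_R(z), 0 },

the integral being approximated by a Riemann sum over the lattice.  The DoG
kernel is

    f_DoG(z) = (1/Z) [ (1 + S)/(2 pi r_in^2) exp(-|z|^2 / (2 r_in^2))
                       - S/(2 pi r_out^2)   exp(-|z|^2 / (2 r_out^2)) ],

with shape parameter S, center/surround widths r_in < r_out and a fixed
normalizer Z.  With the default constants the center response over the default
radius grid peaks at R = 0.25 degrees and levels off for large gratings.

Orientation tuning is not generated by the LGN filter itself: a multiplicative
gain on the LGN current, depending on the angular difference between a group's
preferred orientation and the grating orientation, is applied to excitatory
cortical groups at system-assembly time (inhibitory groups receive ungated
LGN input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .geometry import Lattice, patch_center

#: Default grating radius grid, 0.05 to 1.6 degrees in steps of 0.05.
DEFAULT_RADIUS_GRID = np.round(np.arange(1, 33) * 0.05, 10)


@dataclass(frozen=True)
class DoGKernelParams:
    """Constants of the LGN difference-of-Gaussians filter."""

    shape: float = 4.1          # S, dimensionless center/surround shape parameter
    r_in: float = 0.1           # SD of the excitatory center Gaussian (deg)
    r_out: float = 0.31         # SD of the inhibitory surround Gaussian (deg)
    z_norm: float = 3.62283     # normalizer controlling the response scale

    def __post_init__(self) -> None:
        if not (self.r_out > self.r_in > 0):
            raise ValueError("require r_out > r_in > 0")
        if self.z_norm <= 0 or self.shape <= 0:
            raise ValueError("shape and z_norm must be positive")


@dataclass(frozen=True)
class GratingStimulus:
    """Full-contrast drifting grating: orientation theta0, radius R (deg),
    centered at ``center`` (defaults to the patch center)."""

    theta0: float = 90.0
    radius: float = 0.25
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("grating radius must be nonnegative")
        if self.theta0 not in (0.0, 45.0, 90.0, 135.0):
            raise ValueError("grating orientation must be one of 0, 45, 90, 135")


def dog_kernel(offset, params: DoGKernelParams = DoGKernelParams()) -> np.ndarray:
    """DoG kernel value at a spatial offset (scalar pair or array of shape (..., 2))."""
    offset = np.asarray(offset, dtype=float)
    r2 = np.sum(offset * offset, axis=-1)
    return dog_kernel_r2(r2, params)


def dog_kernel_r2(r2, params: DoGKernelParams = DoGKernelParams()) -> np.ndarray:
    """DoG kernel as a function of squared distance (vectorized)."""
    r2 = np.asarray(r2, dtype=float)
    s, a, b = params.shape, params.r_in, params.r_out
    center = (1.0 + s) / (2 * np.pi * a * a) * np.exp(-r2 / (2 * a * a))
    surround = s / (2 * np.pi * b * b) * np.exp(-r2 / (2 * b * b))
    return (center - surround) / params.z_norm


def grating_indicator(lattice: Lattice, stimulus: GratingStimulus) -> np.ndarray:
    """g_R sampled on the lattice: 1 inside the stimulated disk, 0 outside."""
    center = stimulus.center if stimulus.center is not None else patch_center(lattice)
    x, y = lattice.meshgrid()
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    return (d2 <= stimulus.radius**2 * (1 + 1e-12)).astype(float)


def lgn_response(
    lattice: Lattice,
    stimulus: GratingStimulus,
    params: DoGKernelParams = DoGKernelParams(),
    area_weight: bool = True,
) -> np.ndarray:
    """Rectified DoG filtering of the grating on the lattice.

    Returns the nonnegative LGN output field, shape ``(n_side, n_side)``.
    ``area_weight`` selects the h^2 cell-area factor of the Riemann sum
    (the default; disabling it rescales the field by 1/h^2).
    """
    center = stimulus.center if stimulus.center is not None else patch_center(lattice)
    if not (0 <= center[0] <= lattice.extent and 0 <= center[1] <= lattice.extent):
        raise ValueError("stimulus center lies outside the lattice extent")
    if stimulus.radius == 0.0:
        return np.zeros((lattice.n_side, lattice.n_side))

    g = grating_indicator(lattice, stimulus)
    n = lattice.n_side
    off = (np.arange(2 * n - 1) - (n - 1)) * lattice.h
    ox, oy = np.meshgrid(off, off, indexing="ij")
    kern = dog_kernel_r2(ox * ox + oy * oy, params)
    # radially symmetric odd-sized kernel: 'same' convolution = correlation at
    # every lattice point with full support
    out = fftconvolve(g, kern, mode="same")
    weight = lattice.h**2 if area_weight else 1.0
    return np.maximum(out * weight, 0.0)


def orientation_gain(theta: float, theta0: float, population: str) -> float:
    """Multiplicative gain on LGN current by orientation-preference mismatch.

    Excitatory groups: 1 for matched orientation, 0.4 for a 45-degree offset
    (either direction, mod 180), 0.1 for orthogonal.  Inhibitory groups
    receive LGN input independent of orientation preference (gain 1).
    """
    if population not in ("4E", "4I", "6E", "6I"):
        raise ValueError(f"unknown population {population!r}")
    if population.endswith("I"):
        return 1.0
    diff = abs(theta - theta0) % 180.0
    diff = min(diff, 180.0 - diff)
    return {0.0: 1.0, 45.0: 0.4, 90.0: 0.1}[diff]


def orientation_gain_field(theta_map: np.ndarray, theta0: float) -> np.ndarray:
    """The gain omega(z*) for excitatory groups, over the whole lattice."""
    diff = np.abs(theta_map - theta0) % 180.0
    diff = np.minimum(diff, 180.0 - diff)
    gain = np.empty_like(diff)
    gain[diff == 0.0] = 1.0
    gain[diff == 45.0] = 0.4
    gain[diff == 90.0] = 0.1
    return gain
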