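"""Hypercolumn lattice geometry and the discrete orientation-preference map.

The modeled cortical patch is a square array of hypercolumns (HCs), each
covering ``hc_size`` x ``hc_size`` degrees of visual field and containing a
``g x g`` grid of neuron groups (g = ``groups_per_hc_side``).  Every group has
one of four preferred orientations (0, 45, 90, 135 degrees); each HC square is
split by its two diagonals into four triangular orientation domains, and the
assignment is mirrored on a checkerboard so that domains preferring the same
orientation in adjacent HCs abut across the shared border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)

# Orientation of the N/E/S/W triangle in an even-parity (hc_row + hc_col) HC.
# The odd-parity assignment swaps N<->S and E<->W, which makes facing
# triangles across every HC border share an orientation, and puts the center
# point of the central HC (always even parity) in a 90-degree domain.
_EVEN_TRIANGLES = {"N": 90.0, "E": 45.0, "S": 0.0, "W": 135.0}
_ODD_TRIANGLES = {"N": 0.0, "E": 135.0, "S": 90.0, "W": 45.0}


class ConfigurationError(ValueError):
    """Raised for structurally invalid model configuration."""


@dataclass(frozen=True)
class Lattice:
    """Square lattice of neuron-group positions covering the modeled patch.

    Points sit at ``(h/2 + m*h, h/2 + n*h)`` for ``0 <= m, n < n_side`` with
    ``h = hc_size / groups_per_hc_side``; ``m`` indexes x, ``n`` indexes y,
    and 2D fields over the lattice are arrays of shape ``(n_side, n_side)``
    indexed ``[m, n]`` (row-major flattening defines the canonical ordering).
    """

    n_hc_per_side: int = 17
    groups_per_hc_side: int = 7
    hc_size: float = 0.25

    @property
    def h(self) -> float:
        """Grid spacing in degrees."""
        return self.hc_size / self.groups_per_hc_side

    @property
    def n_side(self) -> int:
        return self.n_hc_per_side * self.groups_per_hc_side

    @property
    def n_points(self) -> int:
        return self.n_side * self.n_side

    @property
    def extent(self) -> float:
        """Side length of the patch in degrees."""
        return self.n_hc_per_side * self.hc_size

    @property
    def coords_1d(self) -> np.ndarray:
        """The shared x/y coordinate values ``h/2 + k*h``."""
        return self.h / 2 + np.arange(self.n_side) * self.h

    def points(self) -> np.ndarray:
        """All lattice points as an ``(n_points, 2)`` array, row-major in (m, n)."""
        c = self.coords_1d
        x, y = np.meshgrid(c, c, indexing="ij")
        return np.column_stack([x.ravel(), y.ravel()])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        c = self.coords_1d
        return np.meshgrid(c, c, indexing="ij")

    def index_of(self, z: tuple[float, float]) -> tuple[int, int]:
        """Indices (m, n) of the lattice point nearest to coordinate ``z``."""
        c = self.coords_1d
        m = int(np.argmin(np.abs(c - z[0])))
        n = int(np.argmin(np.abs(c - z[1])))
        return m, n


@dataclass(frozen=True)
class OrientationMap:
    """Preferred orientation (degrees) and HC index for every lattice point."""

    lattice: Lattice
    theta: np.ndarray   # (n_side, n_side), values in ORIENTATIONS
    hc_row: np.ndarray  # (n_side, n_side) int, y-direction HC index
    hc_col: np.ndarray  # (n_side, n_side) int, x-direction HC index

    def mask(self, orientation: float) -> np.ndarray:
        return self.theta == orientation


def build_lattice(
    n_hc_per_side: int = 17,
    groups_per_hc_side: int = 7,
    hc_size: float = 0.25,
) -> Lattice:
    """Construct the lattice; ``groups_per_hc_side`` must be odd so each HC
    has a center point."""
    if n_hc_per_side < 1 or groups_per_hc_side < 1 or hc_size <= 0:
        raise ConfigurationError("lattice dimensions must be positive")
    if groups_per_hc_side % 2 == 0:
        raise ConfigurationError(
            "groups_per_hc_side must be odd so each hypercolumn has a center point"
        )
    return Lattice(n_hc_per_side, groups_per_hc_side, hc_size)


def _triangle_of(u: int, v: int) -> str:
    """Triangle (N/E/S/W) of a point with integer offsets (u, v) from the HC
    center; the center itself and points on the diagonals are assigned by a
    fixed angular-bin rule (E: [-45, 45), N: [45, 135), ...)."""
    if u == 0 and v == 0:
        return "N"
    ang = np.degrees(np.arctan2(v, u))
    return ("E", "N", "W", "S")[int(((ang + 45.0) % 360.0) // 90.0)]


def assign_orientations(lattice: Lattice) -> OrientationMap:
    """Deterministic four-domain orientation map (diagonal triangle partition,
    checkerboard-mirrored across hypercolumns)."""
    g = lattice.groups_per_hc_side
    ns = lattice.n_side
    c = (g - 1) // 2

    m_idx, n_idx = np.meshgrid(np.arange(ns), np.arange(ns), indexing="ij")
    hc_col = m_idx // g
    hc_row = n_idx // g

    # Precompute the g x g triangle labels once; identical in every HC.
    tri = np.empty((g, g), dtype="U1")
    for u in range(g):
        for v in range(g):
            tri[u, v] = _triangle_of(u - c, v - c)

    theta = np.empty((ns, ns), dtype=float)
    local_u = m_idx % g
    local_v = n_idx % g
    parity = (hc_row + hc_col) % 2
    for name in "NESW":
        sel = tri[local_u, local_v] == name
        theta[sel & (parity == 0)] = _EVEN_TRIANGLES[name]
        theta[sel & (parity == 1)] = _ODD_TRIANGLES[name]

    return OrientationMap(lattice=lattice, theta=theta, hc_row=hc_row, hc_col=hc_col)


def patch_center(lattice: Lattice) -> tuple[float, float]:
    """Geometric center of the modeled patch, in absolute lattice coordinates.

    All stimulus distances and "center group" quantities are measured relative
    to this point; in re-centered coordinates it is (0, 0).
    """
    c = lattice.extent / 2
    return (c, c)


def center_group(lattice: Lattice) -> tuple[int, int]:
    """Indices (m, n) of the lattice point nearest the patch center."""
    return lattice.index_of(patch_center(lattice))
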