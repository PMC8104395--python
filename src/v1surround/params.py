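"""Model parameters: projection specifications, long-range profiles, ambient
drives and firing-rate-dependent coupling multipliers.

Local (and inter-laminar) projections are truncated 2D Gaussians, each defined
by a coupling weight W, a Gaussian SD sigma (degrees) and a cutoff radius
expressed as a multiple of sigma.  Only the anatomically present projections
exist: LGN contacts all four cortical populations; 4E contacts everything; 4I
stays within L4; 6I stays within L6; 6E contacts everything and in addition
makes long-range connections within L6 to groups of like orientation
preference, with distance profiles p_E(d) (E targets) and p_I(d) (I targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

POPULATIONS = ("4E", "4I", "6E", "6I")
SOURCES = ("LGN", "4E", "4I", "6E", "6I")

#: Radius of the local circuit in degrees; long-range connectivity takes over
#: beyond this distance.
LOCAL_CIRCUIT_RADIUS = 0.15


class UnknownProjectionError(KeyError):
    """Raised when a projection pair absent from the circuit is requested."""


@dataclass(frozen=True)
class ProjectionSpec:
    """Truncated-Gaussian projection: weight W, SD sigma (deg), cutoff at
    ``cutoff_mult`` SDs."""

    source: str
    target: str
    weight: float
    sigma: float
    cutoff_mult: float

    def __post_init__(self) -> None:
        if self.weight < 0 or self.sigma <= 0 or self.cutoff_mult <= 0:
            raise ValueError(f"invalid projection spec {self}")

    @property
    def radius(self) -> float:
        """Footprint radius in degrees."""
        return self.cutoff_mult * self.sigma


# Local-circuit couplings: (source, target) -> (W, sigma, cutoff_mult).
# The 6E->4E weight is the control parameter and is filled in from
# ModelParameters.w_6e4e.
_TABLE_LOCAL: dict[tuple[str, str], tuple[float | None, float, float]] = {
    ("LGN", "4E"): (0.3, 0.2, 1.0),
    ("LGN", "4I"): (0.25, 0.2, 1.0),
    ("LGN", "6E"): (0.12, 0.2, 1.0),
    ("LGN", "6I"): (0.12, 0.2, 1.0),
    ("4E", "4E"): (1.44, 0.077, 2.0),
    ("4E", "4I"): (0.95, 0.077, 2.0),
    ("4E", "6E"): (0.42, 0.06, 1.0),
    ("4E", "6I"): (0.75, 0.06, 1.0),
    ("4I", "4E"): (0.9, 0.055, 1.5),
    ("4I", "4I"): (0.7, 0.055, 1.5),
    ("6E", "4E"): (None, 0.07, 2.0),
    ("6E", "4I"): (0.81, 0.07, 2.0),
    ("6E", "6E"): (0.94, 0.075, 2.0),
    ("6E", "6I"): (0.96, 0.075, 2.0),
    ("6I", "6E"): (0.7, 0.05, 2.0),
    ("6I", "6I"): (0.7, 0.05, 2.0),
}

#: Default value of the 6E->4E control weight (middle of the explored
#: 0.44 - 0.48 range).
DEFAULT_W_6E4E = 0.46


def default_projections(w_6e4e: float = DEFAULT_W_6E4E) -> dict[tuple[str, str], ProjectionSpec]:
    """The packaged local-circuit parameterization."""
    out = {}
    for (src, tgt), (w, sigma, cut) in _TABLE_LOCAL.items():
        weight = w_6e4e if w is None else w
        out[(src, tgt)] = ProjectionSpec(src, tgt, weight, sigma, cut)
    return out


@dataclass(frozen=True)
class LongRangeProfile:
    """Piecewise-linear long-range connection-probability profiles p_E(d) and
    p_I(d) for 6E sources, anchored at p(0.15) = 1 and p(1.6) = 0."""

    pe_knots: tuple[tuple[float, float], ...]
    pi_knots: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for name, knots in (("p_E", self.pe_knots), ("p_I", self.pi_knots)):
            d = np.array([k[0] for k in knots])
            v = np.array([k[1] for k in knots])
            if len(knots) < 2 or np.any(np.diff(d) <= 0):
                raise ValueError(f"{name}: knot distances must be strictly increasing")
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name}: values must lie in [0, 1]")
            if not np.isclose(d[0], LOCAL_CIRCUIT_RADIUS) or not np.isclose(v[0], 1.0):
                raise ValueError(f"{name}: must start at ({LOCAL_CIRCUIT_RADIUS}, 1.0)")
            if not np.isclose(d[-1], 1.6) or not np.isclose(v[-1], 0.0):
                raise ValueError(f"{name}: must end at (1.6, 0.0)")

    def _eval(self, d, knots) -> np.ndarray:
        xs = np.array([k[0] for k in knots])
        vs = np.array([k[1] for k in knots])
        d = np.asarray(d, dtype=float)
        out = np.interp(d, xs, vs, left=1.0, right=0.0)
        return out

    def p_e(self, d) -> np.ndarray:
        return self._eval(d, self.pe_knots)

    def p_i(self, d) -> np.ndarray:
        return self._eval(d, self.pi_knots)


@dataclass(frozen=True)
class NonlinearMultiplier:
    """Firing-rate-dependent coupling multiplier m(eta) for one projection:
    1 below the threshold, rising linearly with slope kappa above it, capped
    at m_max."""

    projection: tuple[str, str]
    eta_th: float
    kappa: float
    m_max: float = 2.0

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.m_max < 1:
            raise ValueError("require kappa >= 0 and m_max >= 1")
        if self.projection not in NONLINEAR_PROJECTIONS:
            raise ValueError(f"no multiplier defined for projection {self.projection}")

    def __call__(self, eta) -> np.ndarray:
        eta = np.asarray(eta, dtype=float)
        return np.minimum(1.0 + self.kappa * np.maximum(eta - self.eta_th, 0.0), self.m_max)


NONLINEAR_PROJECTIONS = (("6E", "4I"), ("4E", "4E"), ("6E", "6E"))


@dataclass(frozen=True)
class ModelParameters:
    """Everything that defines the circuit apart from lattice and stimulus."""

    projections: dict[tuple[str, str], ProjectionSpec]
    longrange: LongRangeProfile
    ambient: dict[str, float]
    w_6e4e: float = DEFAULT_W_6E4E
    multipliers: tuple[NonlinearMultiplier, ...] = ()
    nonlinear: bool = False

    def __post_init__(self) -> None:
        if set(self.projections) != set(_TABLE_LOCAL):
            missing = set(_TABLE_LOCAL) ^ set(self.projections)
            raise UnknownProjectionError(f"projection set mismatch: {sorted(missing)}")
        if set(self.ambient) != set(POPULATIONS):
            raise ValueError("ambient drives must cover exactly 4E, 4I, 6E, 6I")
        if any(v < 0 for v in self.ambient.values()):
            raise ValueError("ambient drives must be nonnegative")
        # the control weight overrides whatever sits in the projection table
        spec = self.projections[("6E", "4E")]
        if spec.weight != self.w_6e4e:
            object.__setattr__(
                self, "projections",
                {**self.projections, ("6E", "4E"): replace(spec, weight=self.w_6e4e)},
            )

    def projection(self, source: str, target: str) -> ProjectionSpec:
        try:
            return self.projections[(source, target)]
        except KeyError:
            raise UnknownProjectionError(f"no {source}->{target} projection in the circuit")

    def multiplier_for(self, source: str, target: str) -> NonlinearMultiplier | None:
        if not self.nonlinear:
            return None
        for m in self.multipliers:
            if m.projection == (source, target):
                return m
        return None

    # ---- scalar-parameter registry (used by the sensitivity analysis) ----

    def get_value(self, name: str) -> float:
        kind, *rest = name.split(".")
        if kind == "weight":
            src, tgt = rest[0].split("->")
            return self.projection(src, tgt).weight
        if kind == "ambient":
            return self.ambient[rest[0]]
        if kind == "longrange":
            which, idx = rest[0], int(rest[1])
            knots = self.longrange.pe_knots if which == "pe" else self.longrange.pi_knots
            return knots[idx][1]
        if kind == "multiplier":
            src, tgt = rest[0].split("->")
            for m in self.multipliers:
                if m.projection == (src, tgt):
                    return getattr(m, rest[1])
            raise KeyError(name)
        raise KeyError(f"unknown parameter {name!r}")

    def with_value(self, name: str, value: float) -> "ModelParameters":
        """Copy of the parameter set with one registered scalar replaced."""
        kind, *rest = name.split(".")
        if kind == "weight":
            src, tgt = rest[0].split("->")
            spec = replace(self.projection(src, tgt), weight=value)
            projections = {**self.projections, (src, tgt): spec}
            w = value if (src, tgt) == ("6E", "4E") else self.w_6e4e
            return replace(self, projections=projections, w_6e4e=w)
        if kind == "ambient":
            return replace(self, ambient={**self.ambient, rest[0]: value})
        if kind == "longrange":
            which, idx = rest[0], int(rest[1])
            src_knots = self.longrange.pe_knots if which == "pe" else self.longrange.pi_knots
            knots = tuple(
                (d, value if i == idx else v) for i, (d, v) in enumerate(src_knots)
            )
            lr = replace(
                self.longrange,
                **({"pe_knots": knots} if which == "pe" else {"pi_knots": knots}),
            )
            return replace(self, longrange=lr)
        if kind == "multiplier":
            src, tgt = rest[0].split("->")
            ms = tuple(
                replace(m, **{rest[1]: value}) if m.projection == (src, tgt) else m
                for m in self.multipliers
            )
            return replace(self, multipliers=ms)
        raise KeyError(f"unknown parameter {name!r}")
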