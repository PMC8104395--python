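"""Analysis products: size-tuning curves, suppression indices, DoG-area fits,
input-weight decompositions, parameter sensitivities and activity maps.

A size-tuning curve is the background-subtracted output of the center group
plotted against grating radius R.  The suppression index SI = 1 - f(R_max) /
max_R f(R) quantifies how far the response falls from its peak by the largest
radius studied; 0 means no surround suppression, 1 complete suppression.
Size-tuning curves are well approximated by a difference-of-Gaussian-areas
model, r(R) = k_e A(R; sigma_e) - k_i A(R; sigma_i) with
A(R; s) = integral_0^R exp(-x^2 / (2 s^2)) dx and sigma_i > sigma_e.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from .circuit import AssembledSystem, assemble_system
from .geometry import Lattice, OrientationMap, center_group
from .lgn import DEFAULT_RADIUS_GRID, DoGKernelParams, GratingStimulus, lgn_response
from .params import ModelParameters, POPULATIONS
from .solvers import CircuitState, background_state, solve_linear, solve_nonlinear


@dataclass(frozen=True)
class SizeTuningCurve:
    """Background-subtracted center response versus grating radius."""

    radii: np.ndarray
    responses: np.ndarray
    population: str
    location: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.responses):
            raise ValueError("radii and responses must have equal length")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")

    @property
    def peak_radius(self) -> float:
        return float(self.radii[int(np.argmax(self.responses))])


@dataclass(frozen=True)
class WeightBreakdown:
    """Signed input current to one group, by presynaptic source class."""

    population: str
    location: tuple[int, int]
    components: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))


@dataclass(frozen=True)
class DoGAreaFit:
    """Difference-of-Gaussian-areas description of a size-tuning curve."""

    k_e: float
    sigma_e: float
    k_i: float
    sigma_i: float
    residual: float

    def __call__(self, radii) -> np.ndarray:
        return dog_area_model(np.asarray(radii, dtype=float),
                              self.k_e, self.sigma_e, self.k_i, self.sigma_i)


@dataclass(frozen=True)
class SensitivityReport:
    """Finite-difference derivative of a scalar functional w.r.t. one parameter."""

    parameter: str
    functional: str
    derivative: float
    step: float
    value: float  # functional at the base point


class FitError(RuntimeError):
    pass


class UndefinedSIError(ValueError):
    pass


# ---------------------------------------------------------------------------
# size tuning


def size_tuning_all(
    params: ModelParameters,
    lattice: Lattice,
    omap: OrientationMap,
    radii=None,
    theta0: float = 90.0,
    dog: DoGKernelParams = DoGKernelParams(),
    location: tuple[int, int] | None = None,
    tol: float = 1e-9,
    method: str = "auto",
    nonlinear: bool | None = None,
    progress=None,
) -> dict[str, SizeTuningCurve]:
    """Size-tuning curves for all four populations in a single sweep.

    One steady-state solve per radius; the LGN-off background is solved once
    and subtracted.  Consecutive solves are warm-started with the previous
    solution, which leaves the results unchanged but speeds up the Krylov
    iteration considerably.
    """
    radii = DEFAULT_RADIUS_GRID.copy() if radii is None else np.asarray(radii, float)
    loc = center_group(lattice) if location is None else location
    use_nl = params.nonlinear if nonlinear is None else nonlinear

    bg = background_state(params, lattice, omap, tol=tol, method=method)
    responses = {p: [] for p in POPULATIONS}
    x0 = None
    for r in radii:
        lgn = lgn_response(lattice, GratingStimulus(theta0=theta0, radius=float(r)), dog)
        if use_nl:
            state = solve_nonlinear(
                params, lattice, omap, lgn, theta0=theta0, linear_tol=tol, method=method
            )
        else:
            system = assemble_system(lattice, omap, params, lgn, theta0)
            state = solve_linear(system, tol=tol, x0=x0, method=method)
            x0 = system.join(state.fields)
        for p in POPULATIONS:
            responses[p].append(state.output(p, loc) - bg.output(p, loc))
        if progress is not None:
            progress(float(r))
    return {
        p: SizeTuningCurve(radii=radii, responses=np.array(responses[p]),
                           population=p, location=loc)
        for p in POPULATIONS
    }


def size_tuning(
    params: ModelParameters,
    lattice: Lattice,
    omap: OrientationMap,
    population: str = "4E",
    radii=None,
    theta0: float = 90.0,
    **kwargs,
) -> SizeTuningCurve:
    """Size-tuning curve for one population (see ``size_tuning_all``)."""
    return size_tuning_all(params, lattice, omap, radii=radii, theta0=theta0,
                           **kwargs)[population]


def suppression_index(curve: SizeTuningCurve, tail: int = 1) -> float:
    """SI = 1 - (asymptotic response) / (peak response), in [0, 1].

    The asymptote is estimated from the largest grid radius (``tail`` = 1,
    the default) or the mean of the last ``tail`` points.  Values that are
    negative only through numerical noise are clipped to 0.
    """
    peak = float(np.max(curve.responses))
    if peak <= 0:
        raise UndefinedSIError("suppression index undefined for nonpositive peak")
    asym = float(np.mean(curve.responses[-tail:]))
    si = 1.0 - asym / peak
    if -1e-9 < si < 0.0:
        si = 0.0
    return min(si, 1.0) if si >= 0.0 else si


def si_dog_variant(fit: DoGAreaFit) -> float:
    """Alternative suppression measure from the fitted Gaussian areas,
    k_i sigma_i / (k_e sigma_e).  Exploratory variant only; the published
    definition it approximates is not reproduced here."""
    return fit.k_i * fit.sigma_i / (fit.k_e * fit.sigma_e)


# ---------------------------------------------------------------------------
# DoG-area fit


def gaussian_area(radii, sigma: float) -> np.ndarray:
    """A(R; sigma) = integral_0^R exp(-x^2/(2 sigma^2)) dx."""
    radii = np.asarray(radii, dtype=float)
    return sigma * np.sqrt(np.pi / 2) * erf(radii / (sigma * np.sqrt(2)))


def dog_area_model(radii, k_e, sigma_e, k_i, sigma_i) -> np.ndarray:
    return k_e * gaussian_area(radii, sigma_e) - k_i * gaussian_area(radii, sigma_i)


def fit_dog_area(curve: SizeTuningCurve) -> DoGAreaFit:
    """Least-squares DoG-area fit with positivity and sigma_i > sigma_e
    constraints, multi-started from a deterministic grid of initializations."""
    radii = curve.radii
    y = curve.responses
    if len(radii) < 6:
        raise FitError("need at least 6 radii for a DoG-area fit")
    scale = max(float(np.max(np.abs(y))), 1e-12)

    def resid(x):
        k_e, s_e, k_i, ds = x
        return dog_area_model(radii, k_e, s_e, k_i, s_e + ds) - y

    best = None
    # deterministic multi-start over plausible center/surround widths
    for s_e in (0.1, 0.2, 0.35):
        for ds in (0.2, 0.5, 1.0):
            for k_ratio in (0.0, 0.5, 0.9):
                k_e0 = scale / max(gaussian_area(radii[-1], s_e), 1e-9)
                x0 = [k_e0, s_e, k_ratio * k_e0, ds]
                try:
                    sol = least_squares(
                        resid, x0,
                        bounds=([1e-12, 1e-3, 0.0, 1e-3], [np.inf] * 4),
                        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    )
                except Exception:
                    continue
                cost = float(np.linalg.norm(sol.fun))
                if best is None or cost < best[0]:
                    best = (cost, sol.x)
    if best is None:
        raise FitError("all DoG-area fit starts failed")
    cost, (k_e, s_e, k_i, ds) = best
    return DoGAreaFit(k_e=float(k_e), sigma_e=float(s_e), k_i=float(k_i),
                      sigma_i=float(s_e + ds), residual=cost)


# ---------------------------------------------------------------------------
# weight analysis


def weight_analysis(
    state: CircuitState,
    system: AssembledSystem,
    population: str,
    location: tuple[int, int] | None = None,
) -> WeightBreakdown:
    """Decompose the total input to one group by source class.

    The components satisfy the steady-state identity: their sum equals the
    group's output (to solver tolerance)."""
    loc = center_group(system.lattice) if location is None else location
    comps = system.input_components(state.fields, population, loc)
    return WeightBreakdown(population=population, location=loc, components=comps)


# ---------------------------------------------------------------------------
# sensitivity analysis


def sensitivity(
    params: ModelParameters,
    parameter: str,
    functional,
    step: float = 1e-4,
    functional_name: str = "functional",
) -> SensitivityReport:
    """Central-difference derivative of ``functional(params)`` w.r.t. one
    registered scalar parameter (relative step ``step``)."""
    p0 = params.get_value(parameter)
    h = step * max(abs(p0), 1e-3)
    f_plus = functional(params.with_value(parameter, p0 + h))
    f_minus = functional(params.with_value(parameter, p0 - h))
    deriv = (f_plus - f_minus) / (2 * h)
    if abs(f_plus - f_minus) < 1e-13 * max(abs(f_plus), abs(f_minus), 1.0):
        # difference at cancellation level: derivative is numerically zero
        deriv = 0.0 if f_plus == f_minus else deriv
    return SensitivityReport(parameter=parameter, functional=functional_name,
                             derivative=float(deriv), step=h,
                             value=float(functional(params)))


def sensitivity_linear_analytic(
    params: ModelParameters,
    parameter: str,
    lattice: Lattice,
    omap: OrientationMap,
    lgn_field: np.ndarray,
    theta0: float,
    population: str,
    location: tuple[int, int],
) -> float:
    """Derivative of one output via the linear-model identity
    dTheta = H^{-1} (db/dp - (dH/dp) Theta).

    H and b are affine in every registered scalar parameter, so dH/dp and
    db/dp are computed exactly from a unit parameter displacement.  Uses the
    explicit sparse operator; intended for reduced lattices.
    """
    import scipy.sparse.linalg as spla

    base = assemble_system(lattice, omap, params, lgn_field, theta0)
    H0 = base.to_sparse().tocsc()
    theta = spla.spsolve(H0, base.b)

    p0 = params.get_value(parameter)
    # H is affine in the parameter, so the difference quotient is exact for
    # any displacement; pick one that respects the parameter's domain (e.g.
    # long-range knot values live in [0, 1])
    bumped_params = None
    for delta in (0.01, -0.01, 1.0, -1.0):
        try:
            bumped_params = params.with_value(parameter, p0 + delta)
            break
        except ValueError:
            continue
    if bumped_params is None:
        raise ValueError(f"no admissible displacement for parameter {parameter!r}")
    bumped = assemble_system(lattice, omap, bumped_params, lgn_field, theta0)
    dH = (bumped.to_sparse() - H0) / delta
    db = (bumped.b - base.b) / delta
    dtheta = spla.spsolve(H0, db - dH @ theta)
    idx = base.index_of(population, *location)
    return float(dtheta[idx])


# ---------------------------------------------------------------------------
# activity maps


def activity_map(
    state: CircuitState,
    background: CircuitState,
    layer: str,
    population: str = "E",
) -> np.ndarray:
    """Background-subtracted output field of one layer/population on the
    lattice grid (the Fig-style cortical activity map)."""
    if layer not in ("L4", "L6") or population not in ("E", "I"):
        raise ValueError("layer must be L4/L6 and population E/I")
    key = ("4" if layer == "L4" else "6") + population
    a = state.fields[key]
    b = background.fields[key]
    if a.shape != b.shape:
        raise ValueError("state and background lattices do not match")
    return a - b
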