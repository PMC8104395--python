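"""Steady-state solvers: the linear solve H Theta = b, the LGN-off background
state, and the damped fixed-point iteration for the rate-dependent nonlinear
system H(Theta) Theta = b.

The linear solve uses restarted GMRES on the matrix-free operator (an explicit
sparse factorization is used automatically for small systems).  The model is
solved unconstrained; negative outputs mark an invalid parameter regime and
are recorded on the returned state rather than silently clipped.  An optional
rectified iteration (clamping at zero each fixed-point step) is available but
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .circuit import AssembledSystem, assemble_system
from .geometry import Lattice, OrientationMap
from .params import ModelParameters, POPULATIONS

#: below this dimension the explicit sparse direct solve is used by default
_DIRECT_SOLVE_MAX_DIM = 20_000


class SolverError(RuntimeError):
    """Raised when an iterative solve fails to reach the requested tolerance."""

    def __init__(self, message: str, residuals: list[float] | None = None,
                 iterates: tuple[np.ndarray, ...] | None = None):
        super().__init__(message)
        self.residuals = residuals or []
        self.iterates = iterates or ()


@dataclass
class CircuitState:
    """Solution Theta as one field per population, plus solver diagnostics."""

    fields: dict[str, np.ndarray]
    residual: float
    iterations: int
    nonnegative: bool
    metadata: dict = field(default_factory=dict)

    def vector(self, system: AssembledSystem) -> np.ndarray:
        return system.join(self.fields)

    def output(self, population: str, location: tuple[int, int]) -> float:
        return float(self.fields[population][location])


def _make_state(system: AssembledSystem, vec: np.ndarray, residual: float,
                iterations: int, **metadata) -> CircuitState:
    if not np.all(np.isfinite(vec)):
        raise SolverError("solution contains non-finite values")
    return CircuitState(
        fields=system.split(vec),
        residual=residual,
        iterations=iterations,
        nonnegative=bool(np.all(vec >= -1e-12)),
        metadata=metadata,
    )


def solve_linear(
    system: AssembledSystem,
    tol: float = 1e-10,
    maxiter: int = 3000,
    restart: int = 150,
    x0: np.ndarray | None = None,
    method: str = "auto",
) -> CircuitState:
    """Solve H Theta = b to relative residual ``tol``.

    ``method``: 'auto' (direct for small systems, GMRES otherwise),
    'direct' (explicit sparse LU) or 'gmres' (matrix-free).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    b = system.b
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return _make_state(system, np.zeros(system.dimension), 0.0, 0, method="trivial")

    if method == "auto":
        method = "direct" if system.dimension <= _DIRECT_SOLVE_MAX_DIM else "gmres"

    if method == "direct":
        H = system.to_sparse().tocsc()
        x = spla.spsolve(H, b)
        res = np.linalg.norm(system.matvec(x) - b) / bnorm
        if res > max(tol, 1e-9):
            raise SolverError(f"direct solve residual {res:.3e} above tolerance", [res])
        return _make_state(system, x, res, 1, method="direct")

    op = spla.LinearOperator(
        (system.dimension, system.dimension), matvec=system.matvec, dtype=float
    )
    iters = 0

    def count(_):
        nonlocal iters
        iters += 1

    x, info = spla.gmres(
        op, b, x0=x0, rtol=tol / 4, atol=0.0, restart=restart, maxiter=maxiter,
        callback=count, callback_type="pr_norm",
    )
    res = np.linalg.norm(system.matvec(x) - b) / bnorm
    if info != 0 or res > tol:
        raise SolverError(
            f"GMRES failed to converge (info={info}, residual={res:.3e}, tol={tol:.1e})",
            [res],
        )
    return _make_state(system, x, res, iters, method="gmres")


def background_state(
    params: ModelParameters,
    lattice: Lattice,
    omap: OrientationMap,
    tol: float = 1e-10,
    method: str = "auto",
) -> CircuitState:
    """Solve with the LGN turned off (ambient drive only); stimulus-independent."""
    lgn_zero = np.zeros((lattice.n_side, lattice.n_side))
    system = assemble_system(lattice, omap, params, lgn_zero)
    return solve_linear(system, tol=tol, method=method)


def _multiplier_fields(
    params: ModelParameters, fields: dict[str, np.ndarray]
) -> dict[tuple[str, str], np.ndarray]:
    out = {}
    for m in params.multipliers:
        src, _tgt = m.projection
        out[m.projection] = m(fields[src])
    return out


def solve_nonlinear(
    params: ModelParameters,
    lattice: Lattice,
    omap: OrientationMap,
    lgn_field: np.ndarray,
    theta0: float = 90.0,
    tol: float = 1e-8,
    damping: float = 0.5,
    max_iter: int = 500,
    linear_tol: float = 1e-10,
    rectify: bool = False,
    method: str = "auto",
) -> CircuitState:
    """Damped fixed-point (Picard) iteration for H(Theta) Theta = b.

    Starting from the linear solution (all multipliers set to 1), each step
    freezes the rate-dependent multipliers at the current iterate, solves the
    resulting linear system and damps:
    Theta_{k+1} = (1 - alpha) Theta_k + alpha solve(H(Theta_k), b).
    Convergence requires both a small relative state change and the nonlinear
    fixed-point residual ||H(Theta) Theta - b|| / ||b|| <= tol.
    """
    if not (0.0 < damping <= 1.0):
        raise ValueError("damping must lie in (0, 1]")
    base = assemble_system(lattice, omap, params, lgn_field, theta0)
    lin = solve_linear(base, tol=linear_tol, method=method)
    if not params.nonlinear or not params.multipliers:
        return lin

    bnorm = np.linalg.norm(base.b)
    theta = lin.vector(base)
    history: list[float] = []
    prev = theta
    change = 1.0
    for k in range(1, max_iter + 1):
        mult = _multiplier_fields(params, base.split(theta))
        system_k = base.with_multiplier_fields(mult)
        # inner solves need not exceed the accuracy of the current outer
        # iterate; tighten as the fixed point is approached
        inner_tol = max(linear_tol, min(1e-3, 0.05 * change))
        step = solve_linear(system_k, tol=inner_tol, x0=theta, method=method)
        new = (1.0 - damping) * theta + damping * step.vector(system_k)
        if rectify:
            new = np.maximum(new, 0.0)
        change = np.linalg.norm(new - theta) / max(np.linalg.norm(new), 1e-300)
        prev, theta = theta, new

        mult_now = _multiplier_fields(params, base.split(theta))
        res = (
            np.linalg.norm(base.with_multiplier_fields(mult_now).matvec(theta) - base.b)
            / bnorm
        )
        history.append(res)
        if change <= tol and res <= tol:
            return _make_state(
                base, theta, res, k, method="picard", damping=damping,
                residual_history=history,
            )
    raise SolverError(
        f"fixed-point iteration did not converge in {max_iter} steps "
        f"(last residual {history[-1]:.3e})",
        residuals=history,
        iterates=(prev, theta),
    )
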