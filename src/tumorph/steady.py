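"""Steady-state engine for the radial diffusion-reaction systems.

The spheroid and the Krogh tissue annulus share the same structure: a
stack of finite-volume shells, each carrying the same ordered set of
solutes, with nearest-neighbour diffusive coupling.  Ordering the state
shell-major makes the Jacobian banded with half-bandwidth equal to the
number of solutes, which both the stiff pseudo-time integrator and the
Newton polish exploit.

Strategy: integrate the stiff ODE system in pseudo-time (BDF) until the
transient has decayed, then polish with damped Newton iterations using a
finite-difference banded Jacobian, and report the final residual norm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded
from scipy.sparse import lil_matrix


class ConvergenceError(RuntimeError):
    """Raised when the pseudo-time/Newton cascade fails to reach tolerance."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass
class SteadyResult:
    y: np.ndarray
    residual: float
    converged: bool
    residual_history: list[float]


def banded_sparsity(n_cells: int, n_solutes: int) -> lil_matrix:
    """Jacobian sparsity for shell-major ordering with neighbour coupling."""
    n = n_cells * n_solutes
    J = lil_matrix((n, n), dtype=np.int8)
    for i in range(n_cells):
        lo, hi = i * n_solutes, (i + 1) * n_solutes
        J[lo:hi, lo:hi] = 1
        if i > 0:
            for s in range(n_solutes):
                J[lo + s, lo + s - n_solutes] = 1
        if i < n_cells - 1:
            for s in range(n_solutes):
                J[lo + s, lo + s + n_solutes] = 1
    return J


def _banded_jacobian(
    f: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    f0: np.ndarray,
    band: int,
    eps: float = 1e-7,
) -> np.ndarray:
    """FD Jacobian in LAPACK banded storage, grouped by band stride."""
    n = y.size
    width = 2 * band + 1
    ab = np.zeros((width, n))
    scale = np.maximum(np.abs(y), 1e-6)
    for g in range(width):
        cols = np.arange(g, n, width)
        dy = np.zeros(n)
        dy[cols] = eps * scale[cols]
        f1 = f(y + dy)
        df = (f1 - f0)
        for j in cols:
            lo = max(0, j - band)
            hi = min(n, j + band + 1)
            rows = np.arange(lo, hi)
            ab[band + rows - j, j] = df[rows] / dy[j]
    return ab


def solve_steady(
    f: Callable[[np.ndarray], np.ndarray],
    y0: np.ndarray,
    band: int,
    *,
    t_relax: float = 500.0,
    tol: float = 1e-8,
    max_newton: int = 30,
    floor: float = 0.0,
    rtol: float = 1e-6,
    atol: float = 1e-10,
    max_rounds: int = 3,
    newton_first: bool = False,
) -> SteadyResult:
    """Drive dy/dt = f(y) to steady state.

    ``band`` is the Jacobian half-bandwidth (number of solutes per cell).
    ``floor`` clamps the state from below between steps (concentrations).
    ``newton_first`` skips the initial relaxation when ``y0`` is already a
    good guess (warm start from a neighbouring solve).
    Raises :class:`ConvergenceError` if the residual never reaches ``tol``
    after ``max_rounds`` relaxation/Newton cycles.
    """
    n = y0.size
    n_cells = n // band
    sparsity = banded_sparsity(n_cells, band)
    history: list[float] = []
    y = y0.copy()

    def resid(v: np.ndarray) -> float:
        return float(np.max(np.abs(f(v))))

    def newton(y: np.ndarray) -> tuple[np.ndarray, bool]:
        for _ in range(max_newton):
            f0 = f(y)
            r = float(np.max(np.abs(f0)))
            history.append(r)
            if r < tol:
                return y, True
            ab = _banded_jacobian(f, y, f0, band)
            try:
                step = solve_banded((band, band), ab, -f0)
            except np.linalg.LinAlgError:
                return y, False
            lam = 1.0
            for _ in range(8):
                y_try = np.maximum(y + lam * step, floor)
                if resid(y_try) < r:
                    y = y_try
                    break
                lam *= 0.5
            else:
                return y, False
        return y, resid(y) < tol

    if newton_first:
        y, ok = newton(y)
        if ok:
            return SteadyResult(y, resid(y), True, history)

    horizon = t_relax
    for _ in range(max_rounds):
        sol = solve_ivp(
            lambda t, v: f(v),
            (0.0, horizon),
            y,
            method="BDF",
            jac_sparsity=sparsity,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise ConvergenceError(
                f"pseudo-time integration failed: {sol.message}", history
            )
        y = np.maximum(sol.y[:, -1], floor)
        history.append(resid(y))

        y, ok = newton(y)
        if ok:
            return SteadyResult(y, resid(y), True, history)
        horizon *= 4.0

    r = resid(y)
    if r < tol:
        return SteadyResult(y, r, True, history)
    raise ConvergenceError(
        f"steady state not reached: residual {r:.3e} > tol {tol:.1e}", history
    )
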