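"""Minimal-cost intervention within the controllable region.

Regulation pairs omega = (omega_intra, omega_inter) for which diffusion
fails to percolate form the controllable region U_free.  The intervention
problem picks the cheapest such pair,

    omega_o = argmin_{omega in U_free} F(omega),

with the default socio-economic cost

    F(omega) = (exp(-(omega_intra + omega_inter)) - exp(-2)) / (1 - exp(-2)),

which runs from 1 (full suppression, omega = (0, 0)) to 0 (no restriction,
omega = (1, 1)) and grows disproportionately as regulation approaches total
blockage.  Its iso-cost contours are straight lines of slope -1, so the
optimum sits at the tangency between those lines and the U_free boundary:
minimising F is maximising omega_intra + omega_inter over the boundary.
Linear and quadratic cost forms are provided as robustness variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import InfeasibleError, ParameterError
from .phase_analysis import EPS_CONTAIN
from .tl_solver import TLModel, seeded_rho0, tl_contained

__all__ = [
    "cost",
    "COST_FORMS",
    "BoundaryCurve",
    "controllable_boundary",
    "InterventionResult",
    "optimal_intervention",
    "CostCurve",
    "optimal_cost_curve",
]

_E2 = np.exp(-2.0)

COST_FORMS = ("exponential", "linear", "quadratic")


def cost(omega: Sequence[float], form: str = "exponential") -> float:
    """Socio-economic cost of a regulation pair; 0 at (1,1), 1 at (0,0)."""
    wi, we = float(omega[0]), float(omega[1])
    if not (0.0 <= wi <= 1.0 and 0.0 <= we <= 1.0):
        raise ParameterError("omega entries must lie in [0, 1]")
    if form == "exponential":
        return float((np.exp(-(wi + we)) - _E2) / (1.0 - _E2))
    if form == "linear":
        return 1.0 - (wi + we) / 2.0
    if form == "quadratic":
        return ((1.0 - wi) ** 2 + (1.0 - we) ** 2) / 2.0
    raise ParameterError(f"unknown cost form {form!r}; choose from {COST_FORMS}")


@dataclass
class BoundaryCurve:
    """Largest contained omega_inter per omega_intra (NaN where none exists)."""
    omega_intra: np.ndarray
    omega_inter: np.ndarray
    grid_step: float
    bisect_tol: float

    def feasible(self) -> np.ndarray:
        return ~np.isnan(self.omega_inter)


def _containment_fn(model: TLModel, theta, C, rho0_vec, eps_contain, tol) -> Callable:
    def contained(wi: float, we: float) -> bool:
        return tl_contained(model, (wi, we), theta=theta, C=C, rho0=rho0_vec,
                            eps_contain=eps_contain, tol=tol)
    return contained


def controllable_boundary(model: TLModel, theta: float | None = None, rho0: float = 0.1,
                          *, C: float | None = None, seed_module: int = 0,
                          grid_step: float = 0.01, bisect_tol: float = 1e-4,
                          eps_contain: float = EPS_CONTAIN,
                          solve_tol: float = 1e-9) -> BoundaryCurve:
    """Trace the upper edge of U_free: for each omega_intra on the grid, the
    largest omega_inter keeping the tree-like solution non-diffusive.

    The curve is non-increasing in omega_intra (the final density is monotone
    in each regulation entry), which the tracer exploits: each column's
    bisection is bracketed by the previous column's boundary value.
    """
    rho0_vec = seeded_rho0(model, rho0, seed_module)
    contained = _containment_fn(model, theta, C, rho0_vec, eps_contain, solve_tol)
    if not contained(0.0, 0.0):
        raise InfeasibleError("U_free is empty: diffusion percolates even at omega = (0, 0)")

    grid = np.round(np.arange(0.0, 1.0 + 1e-12, grid_step), 12)
    boundary = np.full(len(grid), np.nan)
    prev = 1.0
    for i, wi in enumerate(grid):
        if contained(wi, prev):
            boundary[i] = prev  # monotone: cannot exceed the previous column
            continue
        if not contained(wi, 0.0):
            break  # infeasible here and (by monotonicity) for all larger wi
        lo, hi = 0.0, prev
        while hi - lo > bisect_tol:
            mid = 0.5 * (lo + hi)
            if contained(wi, mid):
                lo = mid
            else:
                hi = mid
        boundary[i] = lo  # contained side
        prev = hi
    return BoundaryCurve(omega_intra=grid, omega_inter=boundary,
                         grid_step=grid_step, bisect_tol=bisect_tol)


@dataclass
class InterventionResult:
    omega_o: tuple[float, float]
    cost: float
    form: str
    boundary: BoundaryCurve
    contained_at_optimum: bool
    diagnostics: dict


def optimal_intervention(model: TLModel, theta: float | None = None, rho0: float = 0.1,
                         form: str = "exponential", *, C: float | None = None,
                         seed_module: int = 0, grid_step: float = 0.01,
                         bisect_tol: float = 1e-4, eps_contain: float = EPS_CONTAIN,
                         solve_tol: float = 1e-9) -> InterventionResult:
    """Minimise the intervention cost over the controllable region.

    The cost forms are strictly decreasing in each omega entry, so the
    optimum lies on the U_free boundary; for the exponential and linear
    forms (iso-cost slope -1) it maximises omega_intra + omega_inter over
    the traced boundary, while the quadratic form is minimised pointwise.
    Ties break toward larger omega_intra; the winner is polished by local
    bisection along both axes.
    """
    if form not in COST_FORMS:
        raise ParameterError(f"unknown cost form {form!r}")
    bc = controllable_boundary(model, theta, rho0, C=C, seed_module=seed_module,
                               grid_step=grid_step, bisect_tol=bisect_tol,
                               eps_contain=eps_contain, solve_tol=solve_tol)
    feas = bc.feasible()
    if not feas.any():
        raise InfeasibleError("no feasible boundary points")
    cand = list(zip(bc.omega_intra[feas], bc.omega_inter[feas]))
    if form == "quadratic":
        score = lambda p: -cost(p, "quadratic")
    else:
        score = lambda p: p[0] + p[1]
    best = max(cand, key=lambda p: (score(p), p[0]))

    rho0_vec = seeded_rho0(model, rho0, seed_module)
    contained = _containment_fn(model, theta, C, rho0_vec, eps_contain, solve_tol)

    # polish: push omega_intra right at fixed omega_inter, then re-lift omega_inter
    wi, we = best
    hi = min(1.0, wi + grid_step)
    if contained(hi, we):
        wi = hi
    else:
        lo = wi
        while hi - lo > bisect_tol:
            mid = 0.5 * (lo + hi)
            if contained(mid, we):
                lo = mid
            else:
                hi = mid
        wi = lo
    hi = 1.0
    if contained(wi, hi):
        we = hi
    else:
        lo = we
        while hi - lo > bisect_tol:
            mid = 0.5 * (lo + hi)
            if contained(wi, mid):
                lo = mid
            else:
                hi = mid
        we = lo

    omega_o = (float(wi), float(we))
    ok = tl_contained(model, omega_o, theta=theta, C=C, rho0=rho0_vec,
                      eps_contain=eps_contain, tol=solve_tol / 10.0)
    return InterventionResult(omega_o=omega_o, cost=cost(omega_o, form), form=form,
                              boundary=bc, contained_at_optimum=bool(ok),
                              diagnostics={"grid_step": grid_step, "bisect_tol": bisect_tol,
                                           "eps_contain": eps_contain})


@dataclass
class CostCurve:
    mu: np.ndarray
    F: np.ndarray
    omega_o: list[tuple[float, float]]
    argmax_mu: float
    unimodal: bool


def optimal_cost_curve(mu_grid: Sequence[float], z: float, theta: float, rho0: float,
                       form: str = "exponential", *,
                       model_factory: Callable[[float], TLModel] | None = None,
                       grid_step: float = 0.01, bisect_tol: float = 1e-4,
                       eps_contain: float = EPS_CONTAIN,
                       solve_tol: float = 1e-9) -> CostCurve:
    """Optimal cost F(omega_o) as a function of the mixing parameter.

    For each mu the total mean degree z is held fixed while its split moves
    (z_intra = (1 - mu) z, z_inter = mu z); each point solves the full
    boundary-tracing optimisation.  Reports the interior maximiser and
    whether the curve is unimodal (its first differences change sign at most
    once, + to -).
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if np.any(mu_grid <= 0) or np.any(mu_grid >= 1):
        raise ParameterError("mu grid must lie strictly inside (0, 1)")
    if model_factory is None:
        model_factory = lambda m: TLModel.two_community_poisson(z, m)
    F = np.empty(len(mu_grid))
    omegas = []
    for i, m in enumerate(mu_grid):
        res = optimal_intervention(model_factory(float(m)), theta, rho0, form,
                                   grid_step=grid_step, bisect_tol=bisect_tol,
                                   eps_contain=eps_contain, solve_tol=solve_tol)
        F[i] = res.cost
        omegas.append(res.omega_o)
    diffs = np.sign(np.round(np.diff(F), 12))
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        unimodal = True
    else:
        sign_changes = int(np.sum(nz[1:] != nz[:-1]))
        unimodal = sign_changes == 0 or (sign_changes == 1 and nz[0] > 0)
    argmax = float(mu_grid[int(np.argmax(F))])
    return CostCurve(mu=mu_grid, F=F, omega_o=omegas, argmax_mu=argmax, unimodal=unimodal)
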