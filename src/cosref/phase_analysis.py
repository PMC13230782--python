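"""Diffusion-regime classification, phase diagrams, and critical points.

Three regimes are distinguished by the per-community final densities:
*non-diffusion* (every community stays within ``eps_contain`` of its seeded
density), *global diffusion* (every community within ``eps_saturate`` of
full adoption), and *localized* diffusion otherwise (typically the seed
community saturates while the other stays near its seed level, giving a
global density near 0.5 for equal halves).  Transitions between regimes are
abrupt, so critical parameter values are located by bisection on the
containment indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dynamics import ContagionConfig, RegulationMatrix, ensemble_rho_inf
from .errors import BracketError, ParameterError
from .tl_solver import (DEFAULT_EPS_CONTAIN, TLModel, seeded_rho0,
                        tl_contained, tl_fixed_point)

__all__ = [
    "Regime",
    "classify_regime",
    "PhaseDiagram",
    "phase_diagram",
    "find_critical",
]

EPS_CONTAIN = DEFAULT_EPS_CONTAIN  # canonical containment tolerance (tl_solver)
EPS_SATURATE = 0.05  # "system-wide": within this of full adoption


class Regime(str, Enum):
    NON_DIFFUSION = "non_diffusion"
    LOCALIZED = "localized"
    GLOBAL_DIFFUSION = "global_diffusion"


def classify_regime(rho_inf: Sequence[float], rho0: Sequence[float],
                    eps_contain: float = EPS_CONTAIN,
                    eps_saturate: float = EPS_SATURATE) -> Regime:
    """Label one evaluated parameter point from its per-community densities."""
    rho_inf = np.asarray(rho_inf, dtype=float)
    rho0 = np.asarray(rho0, dtype=float)
    if np.any(rho_inf < 0) or np.any(rho_inf > 1):
        raise ParameterError("densities must lie in [0, 1]")
    if not (0 < eps_contain < 0.5 and 0 < eps_saturate < 0.5):
        raise ParameterError("classification tolerances must lie in (0, 0.5)")
    if np.all(rho_inf <= rho0 + eps_contain):
        return Regime.NON_DIFFUSION
    if np.all(rho_inf >= 1.0 - eps_saturate):
        return Regime.GLOBAL_DIFFUSION
    return Regime.LOCALIZED


@dataclass
class PhaseDiagram:
    axis_names: tuple[str, str]
    axis_values: tuple[np.ndarray, np.ndarray]
    rho_global: np.ndarray          # shape (len(axis1), len(axis2))
    rho_by_community: np.ndarray    # shape (len(axis1), len(axis2), n)
    regimes: np.ndarray             # dtype object of Regime
    solver: str
    params: dict

    def to_dataframe(self) -> pd.DataFrame:
        a1, a2 = self.axis_values
        rows = []
        for i, v1 in enumerate(a1):
            for j, v2 in enumerate(a2):
                rows.append({
                    self.axis_names[0]: v1,
                    self.axis_names[1]: v2,
                    "rho_inf": self.rho_global[i, j],
                    **{f"rho_{chr(ord('A') + c)}": self.rho_by_community[i, j, c]
                       for c in range(self.rho_by_community.shape[2])},
                    "regime": self.regimes[i, j].value,
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


_AXES = ("omega_intra", "omega_inter", "mu")


def phase_diagram(axes: dict, z: float, theta: float, rho0: float, *,
                  mu: float = 0.5, omega_intra: float = 1.0, omega_inter: float = 1.0,
                  seed_module: int = 0, solver: str = "tl",
                  model_factory: Callable[[float], TLModel] | None = None,
                  N: int = 20_000, n_realizations: int = 20, seed: int = 0,
                  eps_contain: float = EPS_CONTAIN, eps_saturate: float = EPS_SATURATE,
                  C: float | None = None) -> PhaseDiagram:
    """Evaluate the final density over a 2-D parameter grid.

    ``axes`` maps two names from {omega_intra, omega_inter, mu} to 1-D grids.
    The default model family is the symmetric two-community Poisson model
    with total mean degree ``z``; pass ``model_factory(mu)`` to override.
    ``solver`` is "tl" (analytic) or "sim" (ensemble means over
    ``n_realizations`` networks of ``N`` nodes).
    """
    if len(axes) != 2 or any(k not in _AXES for k in axes):
        raise ParameterError(f"axes must be two of {_AXES}")
    if model_factory is None:
        model_factory = lambda m: TLModel.two_community_poisson(z, m)
    names = tuple(axes.keys())
    grids = tuple(np.asarray(axes[k], dtype=float) for k in names)

    base = {"omega_intra": omega_intra, "omega_inter": omega_inter, "mu": mu}
    theta_kw = {"theta": theta} if C is None else {"C": C}

    shape = (len(grids[0]), len(grids[1]))
    model_cache: dict[float, TLModel] = {}
    rho_g = np.empty(shape)
    rho_c = None
    regimes = np.empty(shape, dtype=object)
    for i, v1 in enumerate(grids[0]):
        for j, v2 in enumerate(grids[1]):
            pt = dict(base)
            pt[names[0]] = float(v1)
            pt[names[1]] = float(v2)
            m = pt["mu"]
            if m not in model_cache:
                model_cache[m] = model_factory(m)
            model = model_cache[m]
            Omega = RegulationMatrix.from_pair(pt["omega_intra"], pt["omega_inter"], model.n)
            rho0_vec = seeded_rho0(model, rho0, seed_module)
            try:
                if solver == "tl":
                    res = tl_fixed_point(model, Omega, rho0=rho0_vec, **theta_kw)
                    rho_comm, rho_glob = res.rho_inf, res.rho_global
                elif solver == "sim":
                    cfg = ContagionConfig(rho0=rho0, seed_module=seed_module, seed=seed,
                                          rule="constant" if C is not None else "proportional",
                                          **theta_kw)
                    ens = ensemble_rho_inf(model.block_model(N), Omega, cfg, n_realizations)
                    rho_comm, rho_glob = ens.mean_by_module, ens.mean
                else:
                    raise ParameterError(f"unknown solver {solver!r}")
            except Exception as exc:
                exc.add_note(f"at grid point {names[0]}={v1}, {names[1]}={v2}")
                raise
            if rho_c is None:
                rho_c = np.empty(shape + (len(rho_comm),))
            rho_g[i, j] = rho_glob
            rho_c[i, j] = np.clip(rho_comm, 0.0, 1.0)
            regimes[i, j] = classify_regime(rho_c[i, j], rho0_vec, eps_contain, eps_saturate)
    return PhaseDiagram(axis_names=names, axis_values=grids, rho_global=rho_g,
                        rho_by_community=rho_c, regimes=regimes, solver=solver,
                        params={"z": z, "theta": theta, "C": C, "rho0": rho0, **base,
                                "solver": solver, "N": N, "n_realizations": n_realizations})


def find_critical(model_or_factory, *, moving: str, bracket: tuple[float, float],
                  theta: float | None = None, C: float | None = None,
                  rho0: float = 0.1, seed_module: int = 0,
                  omega_intra: float = 1.0, omega_inter: float = 1.0,
                  tol: float = 1e-3, eps_contain: float = EPS_CONTAIN) -> float:
    """Bisect the containment indicator along one parameter.

    ``moving`` is one of {omega_intra, omega_inter, mu}; for ``mu`` the first
    argument must be a callable ``mu -> TLModel``.  The bracket endpoints
    must fall on different sides of the transition (one contained, one not),
    otherwise a BracketError is raised.  Returns the bracket midpoint once
    its width is <= tol.
    """
    if moving not in _AXES:
        raise ParameterError(f"moving must be one of {_AXES}")

    def contained(v: float) -> bool:
        pt = {"omega_intra": omega_intra, "omega_inter": omega_inter}
        if moving == "mu":
            model = model_or_factory(v)
        else:
            model = model_or_factory
            pt[moving] = v
        Omega = RegulationMatrix.from_pair(pt["omega_intra"], pt["omega_inter"], model.n)
        return tl_contained(model, Omega, theta=theta, C=C,
                            rho0=seeded_rho0(model, rho0, seed_module),
                            eps_contain=eps_contain)

    lo, hi = sorted((float(bracket[0]), float(bracket[1])))
    c_lo, c_hi = contained(lo), contained(hi)
    if c_lo == c_hi:
        raise BracketError(
            f"containment is {c_lo} at both bracket endpoints {bracket}; no transition inside")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if contained(mid) == c_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
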