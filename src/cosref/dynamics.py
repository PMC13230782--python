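"""Regulated threshold contagion on explicit networks.

States are susceptible (0) or adopted (1); there is no recovery.  All
susceptible nodes are updated synchronously against the previous step's
state: node ``i`` of total degree ``k`` in module ``I`` adopts when the
regulated influence of its adopted neighbours strictly exceeds the
threshold,

    sum_J omega[I, J] * m_J  >  theta * k        (proportional rule)
    sum_J omega[I, J] * m_J  >  C                (constant rule)

where ``m_J`` counts adopted neighbours living in module ``J`` and
``omega`` is the matrix of effective transmissibilities (1 - omega is the
regulatory intensity).  Adoption is monotone, so a fixed point is reached in
at most N sweeps.  Randomness (network realisation and seed placement) uses
the MT19937 generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from .errors import ParameterError
from .network_gen import BlockModel, ModularNetwork

__all__ = [
    "RegulationMatrix",
    "ContagionConfig",
    "Trajectory",
    "threshold_rule",
    "constant_threshold_rule",
    "seed_initial",
    "run_cascade",
    "ensemble_rho_inf",
    "EnsembleResult",
    "mt19937",
]


def mt19937(seed: int) -> np.random.Generator:
    """The package-wide RNG: a Generator over the MT19937 bit stream."""
    return np.random.Generator(np.random.MT19937(seed))


@dataclass(frozen=True)
class RegulationMatrix:
    """n x n effective transmissibilities; entry (I, J) scales the influence
    of module-J neighbours on module-I nodes."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if m.shape[0] != m.shape[1]:
            raise ParameterError("regulation matrix must be square")
        if np.any(m < 0) or np.any(m > 1):
            raise ParameterError("regulation entries must lie in [0, 1]")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def omega_intra(self) -> float:
        return float(self.matrix[0, 0])

    @property
    def omega_inter(self) -> float:
        return float(self.matrix[0, 1]) if self.n > 1 else float("nan")

    @classmethod
    def from_pair(cls, omega_intra: float, omega_inter: float, n: int = 2) -> "RegulationMatrix":
        m = np.full((n, n), float(omega_inter))
        np.fill_diagonal(m, float(omega_intra))
        return cls(m)


@dataclass(frozen=True)
class ContagionConfig:
    """Dynamics parameters.

    ``rho0`` is the initial adopter fraction of ALL N nodes, placed entirely
    inside ``seed_module`` (so the seed module's initial density is
    rho0 * N / |module|).  Exactly one of ``theta``/``C`` is active according
    to ``rule``.
    """

    rho0: float
    rule: str = "proportional"
    theta: float | None = None
    C: float | None = None
    seed_module: int = 0
    seed: int = 0
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho0 < 1.0:
            raise ParameterError("rho0 must lie in [0, 1)")
        if self.rule == "proportional":
            if self.theta is None or self.C is not None:
                raise ParameterError("proportional rule requires theta (and no C)")
            if not 0.0 <= self.theta <= 1.0:
                raise ParameterError("theta must lie in [0, 1]")
        elif self.rule == "constant":
            if self.C is None or self.theta is not None:
                raise ParameterError("constant rule requires C (and no theta)")
            if self.C < 0:
                raise ParameterError("C must be >= 0")
        else:
            raise ParameterError(f"unknown rule {self.rule!r}")


def threshold_rule(m: Sequence[float], omega_row: Sequence[float], theta: float, k: int) -> int:
    """Proportional rule: adopt iff m . omega > theta * k (strict)."""
    return int(float(np.dot(m, omega_row)) > theta * k)


def constant_threshold_rule(m: Sequence[float], omega_row: Sequence[float], C: float) -> int:
    """Constant rule: adopt iff m . omega > C (strict)."""
    return int(float(np.dot(m, omega_row)) > C)


def seed_initial(net: ModularNetwork, rho0: float, seed_module: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Place round(rho0 * N) adopters uniformly inside ``seed_module``."""
    n_seed = int(round(rho0 * net.N))
    members = net.module_nodes(seed_module)
    if n_seed > len(members):
        raise ParameterError(
            f"rho0={rho0} needs {n_seed} seeds but module {seed_module} has {len(members)} nodes")
    x = np.zeros(net.N, dtype=bool)
    if n_seed:
        x[rng.choice(members, size=n_seed, replace=False)] = True
    return x


@dataclass
class Trajectory:
    rho: np.ndarray                 # global density per step, rho[0] = rho0
    rho_by_module: np.ndarray       # (steps+1, n_modules)
    x: np.ndarray = field(repr=False)  # final 0/1 state
    converged: bool = True

    @property
    def steps_to_fixed_point(self) -> int:
        return len(self.rho) - 1

    @property
    def rho_inf(self) -> float:
        return float(self.rho[-1])

    @property
    def rho_inf_by_module(self) -> np.ndarray:
        return self.rho_by_module[-1]


def run_cascade(net: ModularNetwork, Omega: RegulationMatrix, config: ContagionConfig,
                rng: np.random.Generator | None = None,
                x0: np.ndarray | None = None) -> Trajectory:
    """Synchronous-update cascade to its fixed point.

    All susceptible nodes evaluate the rule simultaneously against the
    previous step's adopted set; adopted nodes never revert.
    """
    n_mod = net.n_modules
    if Omega.n != n_mod:
        raise ParameterError("regulation matrix size does not match module count")
    if rng is None:
        rng = mt19937(config.seed)
    x = seed_initial(net, config.rho0, config.seed_module, rng) if x0 is None else x0.astype(bool).copy()

    N = net.N
    E = len(net.edges)
    rows = np.concatenate([net.edges[:, 0], net.edges[:, 1]])
    cols = np.concatenate([net.edges[:, 1], net.edges[:, 0]])
    A = sparse.csr_matrix((np.ones(2 * E), (rows, cols)), shape=(N, N))

    labels = net.community_labels
    module_size = net.module_sizes.astype(float)
    w = Omega.matrix[labels]  # (N, n_mod) regulation row per node
    if config.rule == "proportional":
        gate = config.theta * net.degree.astype(float)
    else:
        gate = np.full(N, float(config.C))

    max_steps = config.max_steps if config.max_steps is not None else N
    rho = [x.mean()]
    rho_mod = [np.bincount(labels, weights=x, minlength=n_mod) / module_size]
    converged = False
    for _ in range(max_steps):
        counts = np.empty((N, n_mod))
        for J in range(n_mod):
            counts[:, J] = A @ (x & (labels == J)).astype(float)
        s = np.einsum("ij,ij->i", w, counts)
        new = (~x) & (s > gate)
        if not new.any():
            converged = True
            break
        x |= new
        rho.append(x.mean())
        rho_mod.append(np.bincount(labels, weights=x, minlength=n_mod) / module_size)
    return Trajectory(rho=np.asarray(rho), rho_by_module=np.asarray(rho_mod),
                      x=x.astype(np.int8), converged=converged)


@dataclass
class EnsembleResult:
    mean: float
    sd: float
    values: np.ndarray
    mean_by_module: np.ndarray


def ensemble_rho_inf(model: BlockModel, Omega: RegulationMatrix, config: ContagionConfig,
                     n_realizations: int = 100) -> EnsembleResult:
    """Mean/SD of rho_inf over independent realisations.

    Each realisation draws a fresh network and fresh seed placement from its
    own MT19937 stream, derived from ``config.seed`` by fixed increments.
    """
    if n_realizations < 1:
        raise ParameterError("n_realizations must be >= 1")
    vals = np.empty(n_realizations)
    mods = []
    for r in range(n_realizations):
        rng = mt19937(config.seed + r)
        net = model.build(rng)
        traj = run_cascade(net, Omega, config, rng=rng)
        vals[r] = traj.rho_inf
        mods.append(traj.rho_inf_by_module)
    return EnsembleResult(mean=float(vals.mean()), sd=float(vals.std(ddof=0)),
                          values=vals, mean_by_module=np.mean(mods, axis=0))
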