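"""Tree-like (message-passing) fixed point for the regulated threshold
contagion on modular networks.

The solver computes, without simulation, the probability ``y^I`` that a node
in community ``I`` reached along a link is adopted, by iterating the cavity
recursion from ``y_0 = rho_0`` per community: a level-l node is influenced
only by its level-(l-1) neighbours, and the arriving link's channel loses
one link in the binomial influence counts while the adoption gate keeps the
node's full degree (the cavity removes an influencer, not threshold mass).  The iteration is monotone (componentwise non-decreasing and
bounded by 1), so it always converges; final per-community densities are
then evaluated with full binomials over the node's degrees and the
undecremented total degree.

Two code paths exist: a compiled two-community recursion (the workhorse for
phase diagrams and intervention optimisation) and a literal n-community
recursion in NumPy, used for multi-module systems and as an internal
cross-check — the two agree to machine precision at n = 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np
from scipy import stats

from . import _tl_kernels
from ._tl_kernels import TIE_EPS
from .degree_models import (DEFAULT_TRUNCATION_MASS, DegreeDistribution,
                            calibrate_power_law_mean, make_distribution)
from .dynamics import RegulationMatrix
from .errors import ComplexityError, ParameterError
from .network_gen import BlockModel

__all__ = [
    "TLModel",
    "TLResult",
    "seeded_rho0",
    "tl_update_two",
    "tl_update_general",
    "tl_fixed_point",
    "tl_contained",
    "DEFAULT_EPS_CONTAIN",
]

# Containment ("fails to percolate") allows the global density to exceed the
# seeded fraction by this much.  The non-diffusive plateau carries a small
# perturbative fringe of adoption around the seeds (up to ~0.05 globally just
# below the jump at the z=15, theta=0.25 reference conditions), so the
# threshold sits above that fringe and far below the localized plateau
# (>= ~0.3 above rho0); the transitions are abrupt, so located boundaries are
# insensitive to the exact value inside that window.
DEFAULT_EPS_CONTAIN = 0.1


@dataclass(frozen=True)
class TLModel:
    """Analytic description of a block network.

    ``dists[I][j]`` is the degree distribution of a community-``I`` node's
    links toward community ``j`` (``j == I`` is the intra channel).
    ``weights[I]`` is the fraction of all nodes in community ``I``.
    """

    dists: tuple
    weights: tuple

    def __post_init__(self) -> None:
        n = len(self.weights)
        if len(self.dists) != n or any(len(row) != n for row in self.dists):
            raise ParameterError("dists must be an n x n table of channel distributions")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ParameterError("community weights must be positive and sum to 1")

    @property
    def n(self) -> int:
        return len(self.weights)

    def z_community(self, I: int) -> float:
        """Mean total degree of a community-I node."""
        return float(sum(d.mean for d in self.dists[I]))

    @property
    def z(self) -> float:
        """Population mean total degree."""
        return float(sum(w * self.z_community(I) for I, w in enumerate(self.weights)))

    @property
    def mu(self) -> float:
        """Mixing parameter z_inter / z of community 0 (two-community use)."""
        z0 = self.z_community(0)
        z_inter = sum(d.mean for j, d in enumerate(self.dists[0]) if j != 0)
        return float(z_inter / z0) if z0 > 0 else 0.0

    # -- constructors -------------------------------------------------------

    @classmethod
    def two_community(cls, intra: DegreeDistribution, inter: DegreeDistribution,
                      weights=(0.5, 0.5)) -> "TLModel":
        return cls(((intra, inter), (inter, intra)), tuple(weights))

    @classmethod
    def two_community_poisson(cls, z: float, mu: float,
                              truncation_mass: float = DEFAULT_TRUNCATION_MASS) -> "TLModel":
        """Symmetric halves; Poisson channels with z_intra = (1 - mu) z."""
        if not 0.0 <= mu <= 1.0:
            raise ParameterError("mu must lie in [0, 1]")
        intra = make_distribution("poisson", {"z": (1.0 - mu) * z}, truncation_mass)
        inter = make_distribution("poisson", {"z": mu * z}, truncation_mass)
        return cls.two_community(intra, inter)

    @classmethod
    def two_community_power_law(cls, lam: float, z: float, mu: float,
                                k_max: int | None = None) -> "TLModel":
        """Symmetric halves; truncated power-law channels with mean-matched
        k_min and k_max defaulting to ten times the channel mean."""
        def channel(mean: float) -> DegreeDistribution:
            km = k_max if k_max is not None else max(int(np.ceil(10 * mean)), 10)
            cal = calibrate_power_law_mean(lam, mean, km)
            return make_distribution("power_law", {"lam": lam, "k_min": cal.k_min, "k_max": km})

        if not 0.0 < mu < 1.0:
            raise ParameterError("power-law channels need mu strictly inside (0, 1)")
        return cls.two_community(channel((1.0 - mu) * z), channel(mu * z))

    @classmethod
    def symmetric(cls, n: int, intra: DegreeDistribution, inter: DegreeDistribution) -> "TLModel":
        """n equal communities, one intra channel and identical pairwise
        inter channels."""
        row = lambda I: tuple(intra if j == I else inter for j in range(n))
        return cls(tuple(row(I) for I in range(n)), tuple([1.0 / n] * n))

    def block_model(self, N: int) -> BlockModel:
        """Finite realisation spec with module sizes proportional to weights."""
        sizes = [int(round(w * N)) for w in self.weights]
        sizes[-1] = N - sum(sizes[:-1])
        inter = {}
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.dists[i][j] is not self.dists[j][i] and \
                        self.dists[i][j].params != self.dists[j][i].params:
                    raise ParameterError("block realisation requires symmetric inter channels")
                inter[(i, j)] = self.dists[i][j]
        return BlockModel(tuple(sizes), tuple(self.dists[I][I] for I in range(self.n)), inter)


def seeded_rho0(model: TLModel, rho0_global: float, seed_module: int = 0) -> np.ndarray:
    """Per-community initial densities for a global fraction ``rho0_global``
    placed entirely in ``seed_module``."""
    rho = np.zeros(model.n)
    rho[seed_module] = rho0_global / model.weights[seed_module]
    if rho[seed_module] > 1.0:
        raise ParameterError("rho0 exceeds the seed community's size")
    return rho


@lru_cache(maxsize=32)
def _comb_table(K: int) -> np.ndarray:
    comb = np.zeros((K + 1, K + 1))
    comb[:, 0] = 1.0
    for a in range(1, K + 1):
        for m in range(1, a + 1):
            comb[a, m] = comb[a - 1, m - 1] + comb[a - 1, m]
    return comb


def _rule_args(theta, C):
    if (theta is None) == (C is None):
        raise ParameterError("exactly one of theta / C must be given")
    if theta is not None:
        if not 0.0 <= theta <= 1.0:
            raise ParameterError("theta must lie in [0, 1]")
        return float(theta), True
    if C < 0:
        raise ParameterError("C must be >= 0")
    return float(C), False


def _as_omega(Omega) -> np.ndarray:
    if isinstance(Omega, RegulationMatrix):
        return Omega.matrix
    return RegulationMatrix(np.atleast_2d(np.asarray(Omega, dtype=float))).matrix


def _pair_omega(Omega) -> np.ndarray:
    """Accept a RegulationMatrix, an n x n array, or an (omega_intra,
    omega_inter) pair."""
    arr = np.asarray(Omega.matrix if isinstance(Omega, RegulationMatrix) else Omega, dtype=float)
    if arr.ndim == 1 and arr.shape == (2,):
        return RegulationMatrix.from_pair(arr[0], arr[1]).matrix
    return _as_omega(arr)


# ---------------------------------------------------------------------------
# two-community fast path
# ---------------------------------------------------------------------------

def tl_update_two(y, model: TLModel, Omega, theta=None, C=None, rho0=None) -> np.ndarray:
    """One cavity update ``y -> y'`` for a two-community model."""
    if model.n != 2:
        raise ParameterError("tl_update_two requires a two-community model")
    thr, scaled = _rule_args(theta, C)
    W = _pair_omega(Omega)
    y = np.asarray(y, dtype=float)
    rho0 = np.asarray(rho0, dtype=float)
    out = np.empty(2)
    for I in (0, 1):
        o = 1 - I
        pmf_own = model.dists[I][I].dense_pmf()
        pmf_oth = model.dists[I][o].dense_pmf()
        comb = _comb_table(max(len(pmf_own), len(pmf_oth)) - 1)
        out[I] = _tl_kernels.update_one(
            float(y[I]), float(y[o]), pmf_own, pmf_oth, model.z_community(I),
            float(W[I, I]), float(W[I, o]), thr, scaled, float(rho0[I]), comb)
    return out


def _tl_rho_two(y, model: TLModel, W, thr, scaled, rho0) -> np.ndarray:
    out = np.empty(2)
    for I in (0, 1):
        o = 1 - I
        pmf_own = model.dists[I][I].dense_pmf()
        pmf_oth = model.dists[I][o].dense_pmf()
        comb = _comb_table(max(len(pmf_own), len(pmf_oth)) - 1)
        out[I] = _tl_kernels.rho_one(
            float(y[I]), float(y[o]), pmf_own, pmf_oth,
            float(W[I, I]), float(W[I, o]), thr, scaled, float(rho0[I]), comb)
    return out


# ---------------------------------------------------------------------------
# general n-community recursion (literal nested sums, NumPy)
# ---------------------------------------------------------------------------

def _min_count_py(rem: float, w: float) -> int:
    if rem < 0.0:
        return 0
    if w <= 0.0:
        return 1 << 30
    return max(int(np.floor(rem / w + TIE_EPS)) + 1, 0)


def _min_count_vec(rem: np.ndarray, w: float, b: int) -> np.ndarray:
    """Vectorised _min_count_py, clipped into the survival-row index range."""
    if w <= 0.0:
        return np.where(rem < 0.0, 0, b + 1)
    j = np.floor(rem / w + TIE_EPS).astype(int) + 1
    return np.clip(np.where(rem < 0.0, 0, j), 0, b + 1)


class _BinomialTables:
    """Per-update cache of binomial pmf and survival rows (one y per channel)."""

    def __init__(self, ys):
        self.ys = [float(v) for v in ys]
        self._pmf: dict = {}
        self._surv: dict = {}

    def pmf(self, channel: int, b: int) -> np.ndarray:
        key = (channel, b)
        if key not in self._pmf:
            self._pmf[key] = stats.binom.pmf(np.arange(b + 1), b, self.ys[channel])
        return self._pmf[key]

    def survival(self, channel: int, b: int) -> np.ndarray:
        """S[j] = P(Binomial(b, y) >= j) for j in 0..b+1."""
        key = (channel, b)
        if key not in self._surv:
            s = np.zeros(b + 2)
            s[:-1] = np.cumsum(self.pmf(channel, b)[::-1])[::-1]
            self._surv[key] = s
        return self._surv[key]


def _exceed_prob(sizes, channels, ws, c, tables: _BinomialTables) -> float:
    """P(sum_j ws[j] m_j > c) with independent m_j ~ Binomial(sizes[j], y_j)."""
    if len(sizes) == 1:
        b = sizes[0]
        j = _min_count_py(c, ws[0])
        if j > b:
            return 0.0
        return float(tables.survival(channels[0], b)[max(j, 0)])
    if len(sizes) == 2:
        b0, b1 = sizes
        pm = tables.pmf(channels[0], b0)
        rems = c - ws[0] * np.arange(b0 + 1)
        j = _min_count_vec(rems, ws[1], b1)
        return float(pm @ tables.survival(channels[1], b1)[j])
    pm = tables.pmf(channels[0], sizes[0])
    return float(sum(pm[m] * _exceed_prob(sizes[1:], channels[1:], ws[1:],
                                          c - ws[0] * m, tables)
                     for m in range(sizes[0] + 1)))


def _check_budget(Ks, n, op_budget):
    enum = float(np.prod([k + 1.0 for k in Ks]))
    if enum * enum * n > op_budget:
        raise ComplexityError(
            f"general recursion would need ~{enum * enum * n:.2g} operations "
            f"(budget {op_budget:.2g}); reduce supports or community count")


def tl_update_general(y, model: TLModel, Omega, theta=None, C=None, rho0=None,
                      op_budget: float = 5e8) -> np.ndarray:
    """One cavity update for an n-community model (literal nested sums)."""
    thr, scaled = _rule_args(theta, C)
    W = _as_omega(Omega) if model.n != 2 else _pair_omega(Omega)
    y = np.asarray(y, dtype=float)
    rho0 = np.asarray(rho0, dtype=float)
    n = model.n

    out = np.empty(n)
    for I in range(n):
        pmfs = [model.dists[I][j].dense_pmf() for j in range(n)]
        Ks = [len(p) - 1 for p in pmfs]
        _check_budget(Ks, n, op_budget)
        ws = [float(W[I, j]) for j in range(n)]
        tables = _BinomialTables(y)
        channels = list(range(n))

        total = 0.0
        for k in product(*(range(K + 1) for K in Ks)):
            p_k = 1.0
            for j in range(n):
                p_k *= pmfs[j][k[j]]
            if p_k <= 0.0:
                continue
            ktot = sum(k)
            if ktot == 0:
                continue
            # gate on the full degree; only the influence counts lose the
            # arriving link (see _tl_kernels.update_one)
            c = thr * ktot if scaled else thr
            for i in range(n):
                if k[i] == 0:
                    continue
                sizes = list(k)
                sizes[i] -= 1
                total += p_k * k[i] * _exceed_prob(sizes, channels, ws, c, tables)
        out[I] = rho0[I] + (1.0 - rho0[I]) * total / model.z_community(I)
    return out


def _tl_rho_general(y, model: TLModel, W, thr, scaled, rho0,
                    op_budget: float = 5e8) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    n = model.n
    out = np.empty(n)
    for I in range(n):
        pmfs = [model.dists[I][j].dense_pmf() for j in range(n)]
        Ks = [len(p) - 1 for p in pmfs]
        _check_budget(Ks, n, op_budget)
        ws = [float(W[I, j]) for j in range(n)]
        tables = _BinomialTables(y)
        channels = list(range(n))

        total = 0.0
        for k in product(*(range(K + 1) for K in Ks)):
            p_k = 1.0
            for j in range(n):
                p_k *= pmfs[j][k[j]]
            if p_k <= 0.0:
                continue
            c = thr * sum(k) if scaled else thr
            total += p_k * _exceed_prob(list(k), channels, ws, c, tables)
        out[I] = rho0[I] + (1.0 - rho0[I]) * total
    return out


# ---------------------------------------------------------------------------
# fixed point
# ---------------------------------------------------------------------------

@dataclass
class TLResult:
    y_inf: np.ndarray
    rho_inf: np.ndarray
    rho_global: float
    iterations: int
    converged: bool
    residual: float
    escaped: bool = False


def tl_fixed_point(model: TLModel, Omega, theta=None, C=None, rho0=None,
                   seed_module: int = 0, tol: float = 1e-10, max_iter: int = 10_000,
                   escape_rho: float | None = None, check_every: int = 16) -> TLResult:
    """Iterate the cavity recursion from ``y_0 = rho_0`` to its fixed point
    and evaluate the steady-state densities.

    ``rho0`` may be a per-community vector or a global fraction (then placed
    in ``seed_module``).  When ``escape_rho`` is given, the iteration stops
    early — flagged ``escaped`` — as soon as the (monotonically growing)
    density bound exceeds it; this is how containment queries avoid fully
    converging deep inside the diffusive phase.
    """
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    rho0_vec = (np.asarray(rho0, dtype=float) if np.ndim(rho0) == 1
                else seeded_rho0(model, float(rho0), seed_module))
    if np.any(rho0_vec < 0) or np.any(rho0_vec > 1):
        raise ParameterError("per-community rho0 must lie in [0, 1]")
    thr, scaled = _rule_args(theta, C)
    weights = np.asarray(model.weights)

    if model.n == 2:
        W = _pair_omega(Omega)
        update = lambda y: tl_update_two(y, model, W, theta=theta, C=C, rho0=rho0_vec)
        rho_of = lambda y: _tl_rho_two(y, model, W, thr, scaled, rho0_vec)
    else:
        W = _as_omega(Omega)
        update = lambda y: tl_update_general(y, model, W, theta=theta, C=C, rho0=rho0_vec)
        rho_of = lambda y: _tl_rho_general(y, model, W, thr, scaled, rho0_vec)

    y = rho0_vec.copy()
    residual = np.inf
    converged = False
    for it in range(1, max_iter + 1):
        y_new = update(y)
        residual = float(np.max(np.abs(y_new - y)))
        y = y_new
        if escape_rho is not None and (it % check_every == 0 or residual < tol):
            rho_now = rho_of(y)
            if float(weights @ rho_now) > escape_rho:
                return TLResult(y_inf=y, rho_inf=rho_now, rho_global=float(weights @ rho_now),
                                iterations=it, converged=False, residual=residual, escaped=True)
        if residual < tol:
            converged = True
            break
    rho = rho_of(y)
    return TLResult(y_inf=y, rho_inf=rho, rho_global=float(weights @ rho),
                    iterations=it, converged=converged, residual=residual)


def tl_contained(model: TLModel, Omega, theta=None, C=None, rho0=None,
                 seed_module: int = 0, eps_contain: float = DEFAULT_EPS_CONTAIN,
                 tol: float = 1e-9, max_iter: int = 10_000) -> bool:
    """Whether diffusion fails to percolate: the tree-like global density
    stays within ``eps_contain`` of the seeded fraction."""
    rho0_vec = (np.asarray(rho0, dtype=float) if np.ndim(rho0) == 1
                else seeded_rho0(model, float(rho0), seed_module))
    rho0_global = float(np.asarray(model.weights) @ rho0_vec)
    res = tl_fixed_point(model, Omega, theta=theta, C=C, rho0=rho0_vec, tol=tol,
                         max_iter=max_iter, escape_rho=rho0_global + eps_contain)
    if res.escaped:
        return False
    return res.rho_global <= rho0_global + eps_contain
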