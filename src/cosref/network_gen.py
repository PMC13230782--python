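"""Modular random networks with prescribed per-block degree distributions.

Networks are realised with a blockwise configuration model: each module's
internal edges come from stub matching on a sampled intra-degree sequence,
and each pair of modules is wired by bipartite stub matching on sampled
inter-degree sequences.  Self-loops and multi-edges are rejected and
re-paired for a bounded number of sweeps, after which leftover stubs are
dropped (counted in the returned diagnostics); odd stub totals are fixed by
incrementing one uniformly chosen node's stub count.

A degree-preserving rewiring move (`rewire_to_mu`) retunes the mixing
parameter mu = z_inter / (z_intra + z_inter) of an existing network while
keeping every node's total degree exactly unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .degree_models import DegreeDistribution, make_distribution, sample_degrees, \
    calibrate_power_law_mean, DEFAULT_TRUNCATION_MASS
from .errors import GenerationError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ModularNetwork",
    "BlockModel",
    "build_modular_network",
    "mixing_parameter",
    "rewire_to_mu",
    "RewireResult",
]


@dataclass
class ModularNetwork:
    """An explicit node/edge realisation with community labels.

    ``edges`` is an ``(E, 2)`` integer array of unordered pairs stored as
    ``(min, max)``, with no self-loops and no duplicates.  Node ids are
    ``0 .. N-1``; ``community_labels[i]`` is the module of node ``i``.
    """

    community_labels: np.ndarray
    edges: np.ndarray
    n_dropped_stubs: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.community_labels = np.asarray(self.community_labels, dtype=np.int64)
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.edges = np.sort(edges, axis=1)

    @property
    def N(self) -> int:
        return len(self.community_labels)

    @property
    def n_modules(self) -> int:
        return int(self.community_labels.max()) + 1 if self.N else 0

    @property
    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.community_labels, minlength=self.n_modules)

    def _edge_is_inter(self) -> np.ndarray:
        lab = self.community_labels
        return lab[self.edges[:, 0]] != lab[self.edges[:, 1]]

    def _degree_split(self) -> tuple[np.ndarray, np.ndarray]:
        if "split" not in self._cache:
            inter = self._edge_is_inter()
            intra_deg = np.zeros(self.N, dtype=np.int64)
            inter_deg = np.zeros(self.N, dtype=np.int64)
            for col in (0, 1):
                np.add.at(intra_deg, self.edges[~inter, col], 1)
                np.add.at(inter_deg, self.edges[inter, col], 1)
            self._cache["split"] = (intra_deg, inter_deg)
        return self._cache["split"]

    @property
    def intra_degree(self) -> np.ndarray:
        return self._degree_split()[0]

    @property
    def inter_degree(self) -> np.ndarray:
        return self._degree_split()[1]

    @property
    def degree(self) -> np.ndarray:
        return self.intra_degree + self.inter_degree

    @property
    def z(self) -> float:
        return 2.0 * len(self.edges) / self.N

    @property
    def z_intra(self) -> float:
        return float(self.intra_degree.mean())

    @property
    def z_inter(self) -> float:
        return float(self.inter_degree.mean())

    @property
    def mu(self) -> float:
        return mixing_parameter(self)

    def module_nodes(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.community_labels == module)

    def validate(self) -> None:
        """Check the structural invariants (no loops, no dupes, degree split)."""
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise GenerationError("self-loop present")
        keys = self.edges[:, 0] * self.N + self.edges[:, 1]
        if len(np.unique(keys)) != len(keys):
            raise GenerationError("duplicate edge present")
        deg = np.zeros(self.N, dtype=np.int64)
        for col in (0, 1):
            np.add.at(deg, self.edges[:, col], 1)
        if not np.array_equal(deg, self.degree):
            raise GenerationError("degree split inconsistent with edge set")


def mixing_parameter(net: ModularNetwork) -> float:
    """mu = (# inter-community edges) / (# edges)."""
    if len(net.edges) == 0:
        raise ParameterError("mixing parameter undefined for an empty edge set")
    return float(net._edge_is_inter().mean())


# ---------------------------------------------------------------------------
# configuration-model construction
# ---------------------------------------------------------------------------

def _even_stub_counts(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if counts.sum() % 2 == 1:
        counts = counts.copy()
        counts[rng.integers(len(counts))] += 1
    return counts


def _match_stubs(stubs: np.ndarray, seen: set, rng: np.random.Generator,
                 max_sweeps: int, bipartite_other: np.ndarray | None = None,
                 same_side=None) -> tuple[list, int]:
    """Pair stubs into edges, rejecting self-loops and duplicates.

    Unipartite when ``bipartite_other`` is None, else ``stubs`` is one side
    and ``bipartite_other`` the other (equal lengths).  Colliding stubs are
    re-shuffled for up to ``max_sweeps`` sweeps, then dropped.
    """
    edges: list[tuple[int, int]] = []

    def repair(pairs: list[tuple[int, int]]) -> int:
        """Splice colliding stub pairs into random accepted edges: replace an
        accepted (u, v) with (a, u) and (b, v) when both are admissible."""
        lost = 0
        for a, b in pairs:
            done = False
            for _ in range(max_sweeps):
                if not edges:
                    break
                idx = int(rng.integers(len(edges)))
                u, v = edges[idx]
                for x, y in ((u, v), (v, u)):
                    if a == x or b == y:
                        continue
                    # bipartite repair must keep both new edges crossing sides
                    if same_side is not None and (same_side(a, x) or same_side(b, y)):
                        continue
                    e1 = (min(a, x), max(a, x))
                    e2 = (min(b, y), max(b, y))
                    if e1 == e2 or e1 in seen or e2 in seen:
                        continue
                    seen.discard((u, v))
                    edges[idx] = e1
                    edges.append(e2)
                    seen.update((e1, e2))
                    done = True
                    break
                if done:
                    break
            if not done:
                lost += 2
        return lost

    if bipartite_other is None:
        pool = stubs.copy()
        for _ in range(max_sweeps):
            if len(pool) < 2:
                break
            rng.shuffle(pool)
            u, v = pool[0::2], pool[1::2]
            leftovers = []
            for a, b in zip(u, v):
                if a == b:
                    leftovers.extend((a, b))
                    continue
                key = (min(a, b), max(a, b))
                if key in seen:
                    leftovers.extend((a, b))
                    continue
                seen.add(key)
                edges.append(key)
            if len(pool) % 2 == 1:
                leftovers.append(pool[-1])
            if not leftovers:
                return edges, 0
            pool = np.asarray(leftovers, dtype=np.int64)
        if len(pool) >= 2:
            return edges, repair(list(zip(pool[0::2], pool[1::2]))) + len(pool) % 2
        return edges, len(pool)

    a_pool, b_pool = stubs.copy(), bipartite_other.copy()
    for _ in range(max_sweeps):
        if len(a_pool) == 0:
            return edges, 0
        rng.shuffle(a_pool)
        rng.shuffle(b_pool)
        left_a, left_b = [], []
        for a, b in zip(a_pool, b_pool):
            key = (min(a, b), max(a, b))
            if key in seen:
                left_a.append(a)
                left_b.append(b)
                continue
            seen.add(key)
            edges.append(key)
        if not left_a:
            return edges, 0
        a_pool = np.asarray(left_a, dtype=np.int64)
        b_pool = np.asarray(left_b, dtype=np.int64)
    return edges, repair(list(zip(a_pool, b_pool)))


def build_modular_network(
    module_sizes: Sequence[int],
    intra_dists: Sequence[DegreeDistribution],
    inter_dists: Mapping[tuple[int, int], DegreeDistribution],
    rng: np.random.Generator,
    max_sweeps: int = 100,
) -> ModularNetwork:
    """Realise a modular network by blockwise configuration-model matching.

    Parameters
    ----------
    module_sizes:
        Node count per module (each >= 2).
    intra_dists:
        One intra-degree distribution per module.
    inter_dists:
        One inter-degree distribution per unordered module pair ``(I, J)``
        with ``I < J``; each node in either module draws one inter degree
        toward the other module from this distribution.
    """
    sizes = [int(s) for s in module_sizes]
    n_mod = len(sizes)
    if any(s < 2 for s in sizes):
        raise ParameterError("every module needs at least 2 nodes")
    if len(intra_dists) != n_mod:
        raise ParameterError("need one intra distribution per module")

    offsets = np.concatenate([[0], np.cumsum(sizes)])
    labels = np.concatenate([np.full(s, b, dtype=np.int64) for b, s in enumerate(sizes)])
    seen: set[tuple[int, int]] = set()
    all_edges: list[tuple[int, int]] = []
    dropped = 0

    for b, (size, dist) in enumerate(zip(sizes, intra_dists)):
        counts = sample_degrees(dist, size, rng) if dist.mean > 0 or dist.k_hi > 0 else np.zeros(size, dtype=int)
        counts = _even_stub_counts(np.asarray(counts, dtype=np.int64), rng)
        stubs = np.repeat(np.arange(offsets[b], offsets[b + 1]), counts)
        if len(stubs):
            edges, lost = _match_stubs(stubs, seen, rng, max_sweeps)
            if lost:
                logger.info("module %d: dropped %d unmatched intra stubs", b, lost)
            all_edges.extend(edges)
            dropped += lost

    for i in range(n_mod):
        for j in range(i + 1, n_mod):
            dist = inter_dists.get((i, j), inter_dists.get((j, i)))
            if dist is None:
                raise ParameterError(f"missing inter distribution for module pair ({i}, {j})")
            ci = np.asarray(sample_degrees(dist, sizes[i], rng), dtype=np.int64)
            cj = np.asarray(sample_degrees(dist, sizes[j], rng), dtype=np.int64)
            # balance the two sides' stub totals by topping up random nodes
            diff = int(ci.sum() - cj.sum())
            if diff > 0:
                np.add.at(cj, rng.integers(sizes[j], size=diff), 1)
            elif diff < 0:
                np.add.at(ci, rng.integers(sizes[i], size=-diff), 1)
            stubs_i = np.repeat(np.arange(offsets[i], offsets[i + 1]), ci)
            stubs_j = np.repeat(np.arange(offsets[j], offsets[j + 1]), cj)
            if len(stubs_i):
                boundary = offsets[i + 1]
                edges, lost = _match_stubs(stubs_i, seen, rng, max_sweeps,
                                           bipartite_other=stubs_j,
                                           same_side=lambda p, q, b=boundary: (p < b) == (q < b))
                if lost:
                    logger.info("pair (%d,%d): dropped %d unmatched inter stubs", i, j, lost)
                all_edges.extend(edges)
                dropped += lost

    if not all_edges:
        edges_arr = np.empty((0, 2), dtype=np.int64)
    else:
        edges_arr = np.asarray(all_edges, dtype=np.int64)
    return ModularNetwork(community_labels=labels, edges=edges_arr, n_dropped_stubs=dropped)


@dataclass(frozen=True)
class BlockModel:
    """Generative specification of a modular network (sizes + distributions)."""

    module_sizes: tuple[int, ...]
    intra_dists: tuple[DegreeDistribution, ...]
    inter_dists: Mapping[tuple[int, int], DegreeDistribution]

    def build(self, rng: np.random.Generator) -> ModularNetwork:
        return build_modular_network(self.module_sizes, self.intra_dists, self.inter_dists, rng)

    @classmethod
    def two_community_poisson(cls, N: int, z: float, mu: float,
                              truncation_mass: float = DEFAULT_TRUNCATION_MASS) -> "BlockModel":
        """Equal halves with Poisson intra/inter degrees; z_intra = (1-mu) z."""
        if not 0.0 <= mu <= 1.0:
            raise ParameterError("mu must lie in [0, 1]")
        intra = make_distribution("poisson", {"z": (1.0 - mu) * z}, truncation_mass)
        inter = make_distribution("poisson", {"z": mu * z}, truncation_mass)
        half = N // 2
        return cls((half, N - half), (intra, intra), {(0, 1): inter})

    @classmethod
    def two_community_power_law(cls, N: int, lam: float, z: float, mu: float,
                                k_max: int | None = None) -> "BlockModel":
        """Equal halves with truncated power-law intra/inter degrees.

        Each channel's k_min is calibrated so the truncated mean matches the
        target channel mean ((1-mu) z intra, mu z inter); k_max defaults to
        ten times the channel mean.
        """
        def channel(mean: float) -> DegreeDistribution:
            km = k_max if k_max is not None else max(int(np.ceil(10 * mean)), 10)
            cal = calibrate_power_law_mean(lam, mean, km)
            return make_distribution("power_law", {"lam": lam, "k_min": cal.k_min, "k_max": km})

        if not 0.0 < mu < 1.0:
            raise ParameterError("power-law blocks need mu strictly inside (0, 1)")
        intra = channel((1.0 - mu) * z)
        inter = channel(mu * z)
        half = N // 2
        return cls((half, N - half), (intra, intra), {(0, 1): inter})


# ---------------------------------------------------------------------------
# degree-preserving mu rewiring
# ---------------------------------------------------------------------------

@dataclass
class RewireResult:
    network: ModularNetwork
    converged: bool
    mu: float
    n_swaps: int


def rewire_to_mu(net: ModularNetwork, target_mu: float, rng: np.random.Generator,
                 max_steps: int | None = None) -> RewireResult:
    """Retune mu by degree-preserving two-edge swaps.

    Raising mu replaces an intra edge in one module and an intra edge in
    another with two cross edges; lowering mu applies the inverse move to two
    inter edges between the same module pair, grouping endpoints by module.
    Every node's total degree is exactly preserved; moves that would create a
    self-loop or duplicate edge are rejected.  The achieved mu is within one
    edge of the closest parity-reachable count for ``target_mu``.
    """
    if not 0.0 <= target_mu <= 1.0:
        raise ParameterError("target_mu must lie in [0, 1]")
    if net.n_modules < 2:
        raise ParameterError("rewiring requires at least 2 modules")
    E = len(net.edges)
    if E == 0:
        raise ParameterError("cannot rewire an empty network")
    if max_steps is None:
        max_steps = 200 * E

    labels = net.community_labels
    seen = {tuple(e) for e in net.edges.tolist()}
    inter_flag = net._edge_is_inter()
    intra = [tuple(e) for e in net.edges[~inter_flag].tolist()]
    inter = [tuple(e) for e in net.edges[inter_flag].tolist()]

    # closest reachable inter-edge count: counts move in steps of 2
    t = target_mu * E
    parity = len(inter) % 2
    cand = [c for c in (int(np.floor(t)), int(np.ceil(t)), int(np.floor(t)) - 1, int(np.ceil(t)) + 1)
            if 0 <= c <= E and c % 2 == parity]
    target_count = min(cand, key=lambda c: abs(c - t)) if cand else len(inter)

    def pop_random(pool: list) -> tuple:
        i = rng.integers(len(pool))
        pool[i], pool[-1] = pool[-1], pool[i]
        return pool.pop()

    n_swaps = 0
    steps = 0
    while len(inter) != target_count and steps < max_steps:
        steps += 1
        if len(inter) < target_count:
            if len(intra) < 2:
                break
            e1 = pop_random(intra)
            e2 = pop_random(intra)
            if labels[e1[0]] == labels[e2[0]]:
                intra.extend((e1, e2))
                continue
            a1, a2 = e1
            b1, b2 = e2
            new1 = (min(a1, b1), max(a1, b1))
            new2 = (min(a2, b2), max(a2, b2))
            if new1 == new2 or new1 in seen or new2 in seen:
                intra.extend((e1, e2))
                continue
            seen.discard(e1)
            seen.discard(e2)
            seen.update((new1, new2))
            inter.extend((new1, new2))
            n_swaps += 1
        else:
            if len(inter) < 2:
                break
            e1 = pop_random(inter)
            e2 = pop_random(inter)
            # group endpoints by module; both edges must join the same pair
            m1 = (labels[e1[0]], labels[e1[1]])
            m2 = (labels[e2[0]], labels[e2[1]])
            if set(m1) != set(m2):
                inter.extend((e1, e2))
                continue
            p1 = e1
            p2 = e2 if m1 == m2 else (e2[1], e2[0])
            x1, x2 = p1[0], p2[0]  # same module
            y1, y2 = p1[1], p2[1]  # same module
            if x1 == x2 or y1 == y2:
                inter.extend((e1, e2))
                continue
            new1 = (min(x1, x2), max(x1, x2))
            new2 = (min(y1, y2), max(y1, y2))
            if new1 in seen or new2 in seen:
                inter.extend((e1, e2))
                continue
            seen.discard(e1)
            seen.discard(e2)
            seen.update((new1, new2))
            intra.extend((new1, new2))
            n_swaps += 1

    edges = np.asarray(intra + inter, dtype=np.int64) if intra or inter else np.empty((0, 2), np.int64)
    out = ModularNetwork(community_labels=labels.copy(), edges=edges)
    return RewireResult(network=out, converged=len(inter) == target_count,
                        mu=mixing_parameter(out), n_swaps=n_swaps)
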