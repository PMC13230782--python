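"""SNAP-dialect network I/O, two-community extraction, and synthetic fixtures.

Edge lists are whitespace-separated node-id pairs with '#' comment lines;
ground-truth community files hold one community per line as tab/whitespace
separated node ids.  From a network with ground-truth communities the
pipeline selects a well-connected community pair, resolves overlapping
members into a disjoint two-module labelling, and induces the subnetwork
(edges leaving the pair are dropped) so the regulated-contagion machinery
applies directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .network_gen import ModularNetwork, mixing_parameter

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list", "write_edge_list", "read_communities", "write_communities",
    "select_community_pair", "assign_overlaps", "build_subnetwork",
    "empirical_stats", "EmpiricalStats", "make_snap_fixture", "FixtureInfo",
]


def read_edge_list(path) -> np.ndarray:
    """Undirected, deduplicated (E, 2) edge array; self-loops dropped."""
    edges = set()
    loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParameterError(f"{path}:{lineno}: malformed edge line {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ParameterError(f"{path}:{lineno}: non-integer node id") from exc
            if u == v:
                loops += 1
                continue
            edges.add((min(u, v), max(u, v)))
    if loops:
        logger.info("%s: dropped %d self-loops", path, loops)
    if not edges:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(sorted(edges), dtype=np.int64)


def write_edge_list(path, edges, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for u, v in np.asarray(edges, dtype=np.int64):
            fh.write(f"{u}\t{v}\n")


def read_communities(path) -> list[set[int]]:
    """One community per line; empty lines skipped."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.info("%s:%d: skipped empty line", path, lineno)
                continue
            out.append({int(t) for t in line.split()})
    return out


def write_communities(path, communities) -> None:
    with open(path, "w") as fh:
        for comm in communities:
            fh.write("\t".join(str(i) for i in sorted(comm)) + "\n")


def _cross_edges(edges: np.ndarray, a: set, b: set) -> int:
    # clean cross edges only: one endpoint exclusive to each side
    ea, eb = a - b, b - a
    return int(sum((u in ea and v in eb) or (u in eb and v in ea) for u, v in edges))


def select_community_pair(edges: np.ndarray, communities: list[set[int]],
                          min_inter_edges: int = 1) -> tuple[int, int]:
    """Indices of the qualifying pair with the most nodes.

    Pairs need at least ``min_inter_edges`` edges between their exclusive
    members; ties break by more inter edges, then lower indices.
    """
    if len(communities) < 2:
        raise ParameterError("need at least two communities")
    best = None
    candidates = []
    for i in range(len(communities)):
        for j in range(i + 1, len(communities)):
            x = _cross_edges(edges, communities[i], communities[j])
            size = len(communities[i] | communities[j])
            candidates.append((size, x, i, j))
            if x < min_inter_edges:
                continue
            key = (size, x, -i, -j)
            if best is None or key > best[0]:
                best = (key, (i, j))
    if best is None:
        top = sorted(candidates, reverse=True)[:3]
        raise ParameterError(
            f"no community pair has >= {min_inter_edges} inter edges; "
            f"best candidates (size, inter_edges, i, j): {top}")
    return best[1]


def assign_overlaps(pair: tuple[set[int], set[int]], mode: str = "biased",
                    rng: np.random.Generator | None = None) -> tuple[set[int], set[int]]:
    """Resolve shared nodes into a disjoint partition.

    ``biased``: each shared node (ascending id) goes to the currently smaller
    community, re-counting after every assignment, which balances sizes.
    ``random``: a fair coin per shared node.
    """
    a, b = set(pair[0]), set(pair[1])
    shared = sorted(a & b)
    a -= set(shared)
    b -= set(shared)
    if mode == "biased":
        for node in shared:
            (a if len(a) <= len(b) else b).add(node)
    elif mode == "random":
        if rng is None:
            raise ParameterError("random mode needs an rng")
        for node in shared:
            (a if rng.random() < 0.5 else b).add(node)
    else:
        raise ParameterError(f"unknown overlap mode {mode!r}")
    return a, b


def build_subnetwork(edges: np.ndarray, module_a: set[int], module_b: set[int]) -> ModularNetwork:
    """Induced two-module network on a disjoint node pair, relabelled 0..N-1."""
    if module_a & module_b:
        raise ParameterError("modules must be disjoint (run assign_overlaps first)")
    nodes = sorted(module_a) + sorted(module_b)
    index = {n: i for i, n in enumerate(nodes)}
    labels = np.array([0] * len(module_a) + [1] * len(module_b), dtype=np.int64)
    kept = [(index[u], index[v]) for u, v in np.asarray(edges)
            if u in index and v in index]
    arr = np.asarray(kept, dtype=np.int64) if kept else np.empty((0, 2), np.int64)
    return ModularNetwork(community_labels=labels, edges=arr)


@dataclass(frozen=True)
class EmpiricalStats:
    N: int
    mu: float
    z_a: float
    z_b: float


def empirical_stats(net: ModularNetwork) -> EmpiricalStats:
    """N, mixing parameter, and mean intra-degree per module."""
    sizes = net.module_sizes
    if net.n_modules != 2 or np.any(sizes == 0):
        raise ParameterError("stats require two non-empty modules")
    intra = net.intra_degree
    lab = net.community_labels
    return EmpiricalStats(
        N=net.N,
        mu=mixing_parameter(net),
        z_a=float(intra[lab == 0].mean()),
        z_b=float(intra[lab == 1].mean()),
    )


@dataclass(frozen=True)
class FixtureInfo:
    edge_path: str
    community_path: str
    sidecar_path: str
    planted: dict


def make_snap_fixture(out_prefix, module_sizes: tuple[int, int],
                      p_intra: float, p_inter: float, overlap: int,
                      rng: np.random.Generator,
                      n_decoys: int = 0, decoy_size: int = 5) -> FixtureInfo:
    """Write a synthetic SNAP-format edge list + community file with planted
    two-community structure (plus optional small decoy cliques), and a JSON
    sidecar recording the ground truth for assertions."""
    if not (0.0 <= p_intra <= 1.0 and 0.0 <= p_inter <= 1.0):
        raise ParameterError("edge probabilities must lie in [0, 1]")
    na, nb = module_sizes
    if overlap > min(na, nb):
        raise ParameterError("overlap exceeds a module size")
    # community A: 0..na-1; community B re-uses the last `overlap` ids of A
    a = list(range(na))
    b = list(range(na - overlap, na - overlap + nb))
    nodes = sorted(set(a) | set(b))
    edges = set()

    def bernoulli_pairs(members, p):
        members = sorted(members)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                if rng.random() < p:
                    edges.add((u, v))

    bernoulli_pairs(a, p_intra)
    bernoulli_pairs(b, p_intra)
    only_a = sorted(set(a) - set(b))
    only_b = sorted(set(b) - set(a))
    for u in only_a:
        for v in only_b:
            if rng.random() < p_inter:
                edges.add((min(u, v), max(u, v)))

    communities = [set(a), set(b)]
    next_id = max(nodes) + 1
    for _ in range(n_decoys):
        clique = list(range(next_id, next_id + decoy_size))
        next_id += decoy_size
        for i, u in enumerate(clique):
            for v in clique[i + 1:]:
                edges.add((u, v))
        communities.append(set(clique))

    out_prefix = Path(out_prefix)
    edge_path = out_prefix.with_suffix(".edges.txt")
    comm_path = out_prefix.with_suffix(".cmty.txt")
    sidecar = out_prefix.with_suffix(".planted.json")
    write_edge_list(edge_path, sorted(edges), comment="synthetic SNAP-dialect fixture")
    write_communities(comm_path, communities)
    planted = {"module_sizes": [na, nb], "p_intra": p_intra, "p_inter": p_inter,
               "overlap": overlap, "pair": [0, 1], "n_decoys": n_decoys,
               "community_a": sorted(a), "community_b": sorted(b)}
    sidecar.write_text(json.dumps(planted, indent=1))
    return FixtureInfo(str(edge_path), str(comm_path), str(sidecar), planted)
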