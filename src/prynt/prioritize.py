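"""Candidate scoring and ranking on a (possibly collapsed) network.

Every node that is not a deregulated protein (DP) is a candidate. Two
closeness scores are computed against the DP seed set:

* shortest-path score ``SP(x) = 1 / sum_y d(x, y)`` where ``d(x, y)`` is
  the directed hop count from candidate ``x`` to seed ``y``;
* random-walk-with-restart score ``RW(x)``, the steady-state visiting
  probability of the iteration ``P_{t+1} = (1 - r) A P_t + r P_0`` with
  column-normalized adjacency ``A`` (walker moves along edge direction),
  restart probability ``r`` and the uniform seed distribution ``P_0``.

Candidates are ranked separately by each score (descending, competition
ranking) and combined through the rank product ``CS = rank_sp * rank_rw``;
smaller combined scores rank first. On collapsed networks, clique
super-nodes are finally expanded back to one representative protein each —
the member ranking best in a companion run on the uncollapsed network.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import ConsistencyError, ConvergenceError, EmptySeedError
from .network import CliquePartition, PPINetwork, VariantBuild
from .string_io import DPSet

DEFAULT_RESTART = 0.7
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000

UNREACHABLE_POLICIES = ("count-first", "penalty", "exclude")


# ---------------------------------------------------------------------------
# score records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SPScore:
    node: str
    sp: float                 # reciprocal summed hop distance, >= 0
    reachable_dp_count: int   # seeds reachable from this candidate


@dataclass(frozen=True)
class RWScore:
    node: str
    rw: float                 # steady-state visiting probability
    iterations: int
    residual: float


@dataclass(frozen=True)
class CandidateRecord:
    node: str
    sp: float
    rank_sp: int
    rw: float
    rank_rw: int
    cs: int
    final_rank: int
    reachable_dp_count: int = 0
    in_clique: bool = False
    clique_members_dropped: int = 0


@dataclass
class PrioritizationResult:
    records: list
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def nodes(self) -> list:
        return [rec.node for rec in self.records]

    def rank_of(self) -> dict:
        return {rec.node: rec.final_rank for rec in self.records}


def _seeds_in(net: PPINetwork, dps: DPSet) -> frozenset:
    seeds = dps.members & net.nodes
    if not seeds:
        raise EmptySeedError(
            f"no deregulated protein of {dps.dataset_name!r} is present "
            "in the network"
        )
    return seeds


# ---------------------------------------------------------------------------
# shortest-path scoring
# ---------------------------------------------------------------------------

def shortest_path_scores(net: PPINetwork, dps: DPSet,
                         unreachable: str = "count-first") -> list:
    """Reciprocal summed directed distance from each candidate to the seeds.

    Distances are unweighted hop counts along edge direction (candidate
    towards seed); DP nodes may serve as intermediate hops. Seeds a
    candidate cannot reach are handled by ``unreachable``:

    * ``"count-first"`` (default) — sum over reachable seeds only; the
      downstream ranking orders by reachable-seed count first, then score;
      candidates reaching no seed get ``sp = 0``;
    * ``"penalty"`` — unreachable pairs contribute a distance of
      ``|nodes|``;
    * ``"exclude"`` — like count-first sums, but ranking uses the score
      alone.
    """
    if unreachable not in UNREACHABLE_POLICIES:
        raise ValueError(f"unknown unreachable policy {unreachable!r}")
    seeds = _seeds_in(net, dps)
    reversed_view = net.graph.reverse(copy=False)
    n_nodes = net.n_nodes

    totals: dict = {}
    counts: dict = {}
    for seed in seeds:
        # BFS on the reversed graph: distance to x == d(x, seed) in net
        lengths = nx.single_source_shortest_path_length(reversed_view, seed)
        for node, dist in lengths.items():
            if node in seeds or dist == 0:
                continue
            totals[node] = totals.get(node, 0) + dist
            counts[node] = counts.get(node, 0) + 1

    scores = []
    for node in sorted(net.nodes - seeds):
        reached = counts.get(node, 0)
        total = totals.get(node, 0)
        if unreachable == "penalty":
            total += (len(seeds) - reached) * n_nodes
            sp_value = 1.0 / total if total else 0.0
        else:
            sp_value = 1.0 / total if total else 0.0
        scores.append(SPScore(node=node, sp=sp_value,
                              reachable_dp_count=reached))
    return scores


def shortest_path_scores_bruteforce(net: PPINetwork, dps: DPSet,
                                    unreachable: str = "count-first") -> list:
    """Per-pair BFS reference implementation (small graphs only)."""
    seeds = _seeds_in(net, dps)
    scores = []
    for node in sorted(net.nodes - seeds):
        total, reached = 0, 0
        for seed in seeds:
            try:
                dist = nx.shortest_path_length(net.graph, node, seed)
            except nx.NetworkXNoPath:
                if unreachable == "penalty":
                    total += net.n_nodes
                continue
            total += dist
            reached += 1
        sp_value = 1.0 / total if total else 0.0
        scores.append(SPScore(node=node, sp=sp_value,
                              reachable_dp_count=reached))
    return scores


# ---------------------------------------------------------------------------
# random walk with restart
# ---------------------------------------------------------------------------

def _transition_matrix(net: PPINetwork, order: list) -> sp.csr_matrix:
    """Column-stochastic matrix over out-edges: A[v, u] = 1/outdeg(u)."""
    index = {node: i for i, node in enumerate(order)}
    rows, cols, vals = [], [], []
    for u in order:
        out = list(net.graph.successors(u))
        if not out:
            continue
        weight = 1.0 / len(out)
        for v in out:
            rows.append(index[v])
            cols.append(index[u])
            vals.append(weight)
    n = len(order)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def random_walk_scores(net: PPINetwork, dps: DPSet,
                       r: float = DEFAULT_RESTART,
                       tol: float = DEFAULT_TOL,
                       max_iter: int = DEFAULT_MAX_ITER,
                       dangling: str = "none") -> list:
    """Steady state of the restart iteration, one score per network node.

    ``P_0`` puts mass ``1/|seeds|`` on each seed present in the network.
    Iteration stops when the L1 change drops below ``tol``. Dangling nodes
    (out-degree zero) leak mass by default (``dangling="none"``, the
    restart term keeps the iteration well-behaved); ``dangling="restart"``
    redistributes their mass onto ``P_0`` instead, restoring a proper
    probability vector.
    """
    if not 0 < r <= 1:
        raise ValueError(f"restart probability r={r} outside (0, 1]")
    if dangling not in ("none", "restart"):
        raise ValueError(f"unknown dangling policy {dangling!r}")
    seeds = _seeds_in(net, dps)
    order = sorted(net.nodes)
    index = {node: i for i, node in enumerate(order)}
    matrix = _transition_matrix(net, order)
    dangling_mask = np.asarray(matrix.sum(axis=0)).ravel() == 0.0

    p0 = np.zeros(len(order))
    for seed in seeds:
        p0[index[seed]] = 1.0 / len(seeds)

    p = p0.copy()
    residual = math.inf
    for iteration in range(1, max_iter + 1):
        spread = matrix @ p
        if dangling == "restart":
            spread = spread + p[dangling_mask].sum() * p0
        p_next = (1.0 - r) * spread + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return [
                RWScore(node=node, rw=float(p[index[node]]),
                        iterations=iteration, residual=residual)
                for node in order
            ]
    raise ConvergenceError(
        f"random walk not converged after {max_iter} iterations "
        f"(residual {residual:.3e})", residual=residual, iterations=max_iter,
    )


def random_walk_scores_closed_form(net: PPINetwork, dps: DPSet,
                                   r: float = DEFAULT_RESTART) -> list:
    """Direct linear solve P = r (I - (1-r) A)^-1 P0 (small graphs only)."""
    seeds = _seeds_in(net, dps)
    order = sorted(net.nodes)
    index = {node: i for i, node in enumerate(order)}
    matrix = _transition_matrix(net, order).toarray()
    p0 = np.zeros(len(order))
    for seed in seeds:
        p0[index[seed]] = 1.0 / len(seeds)
    system = np.eye(len(order)) - (1.0 - r) * matrix
    p = r * np.linalg.solve(system, p0)
    return [
        RWScore(node=node, rw=float(p[index[node]]), iterations=0,
                residual=0.0)
        for node in order
    ]


# ---------------------------------------------------------------------------
# rank combination
# ---------------------------------------------------------------------------

def _competition_ranks(keys: list) -> list:
    """Competition ("1224") ranks for already-ordered, comparable keys."""
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    ranks = [0] * len(keys)
    for position, i in enumerate(order):
        if position > 0 and keys[i] == keys[order[position - 1]]:
            ranks[i] = ranks[order[position - 1]]
        else:
            ranks[i] = position + 1
    return ranks


def combine_ranks(sp_scores: Sequence[SPScore],
                  rw_scores: Sequence[RWScore],
                  unreachable: str = "count-first",
                  metadata: dict | None = None) -> PrioritizationResult:
    """Rank-product combination of the two score lists.

    Both lists must cover the same candidate set (seeds already excluded).
    ``rank_sp`` orders by descending SP (reachable-seed count first under
    the default policy), ``rank_rw`` by descending RW, ties sharing the
    better rank; ``CS = rank_sp * rank_rw`` and the final order is
    ascending CS with deterministic lexicographic tie-break.
    """
    sp_by_node = {s.node: s for s in sp_scores}
    rw_by_node = {s.node: s for s in rw_scores}
    if set(sp_by_node) != set(rw_by_node):
        only_sp = set(sp_by_node) - set(rw_by_node)
        only_rw = set(rw_by_node) - set(sp_by_node)
        raise ConsistencyError(
            f"candidate sets differ (sp-only {sorted(only_sp)[:3]}, "
            f"rw-only {sorted(only_rw)[:3]})"
        )
    nodes = sorted(sp_by_node)
    if unreachable == "count-first":
        sp_keys = [
            (-sp_by_node[n].reachable_dp_count, -sp_by_node[n].sp)
            for n in nodes
        ]
    else:
        sp_keys = [(-sp_by_node[n].sp,) for n in nodes]
    rw_keys = [(-rw_by_node[n].rw,) for n in nodes]
    rank_sp = _competition_ranks(sp_keys)
    rank_rw = _competition_ranks(rw_keys)

    combined = [
        (rank_sp[i] * rank_rw[i], node) for i, node in enumerate(nodes)
    ]
    final_order = sorted(range(len(nodes)), key=lambda i: combined[i])
    records = []
    for final_rank, i in enumerate(final_order, start=1):
        node = nodes[i]
        records.append(CandidateRecord(
            node=node,
            sp=sp_by_node[node].sp,
            rank_sp=rank_sp[i],
            rw=rw_by_node[node].rw,
            rank_rw=rank_rw[i],
            cs=rank_sp[i] * rank_rw[i],
            final_rank=final_rank,
            reachable_dp_count=sp_by_node[node].reachable_dp_count,
        ))
    return PrioritizationResult(records=records, metadata=metadata or {})


# ---------------------------------------------------------------------------
# clique expansion
# ---------------------------------------------------------------------------

def expand_cliques(result: PrioritizationResult,
                   partition: CliquePartition,
                   raw_result: PrioritizationResult) -> PrioritizationResult:
    """Replace each clique super-node by its best-ranked member protein.

    The reference ranking is ``raw_result``, a prioritization of the
    uncollapsed network with the same seeds; members it does not rank fall
    back to lexicographic order. The other members are dropped and final
    ranks renumbered, preserving order.
    """
    reference_rank = raw_result.rank_of()
    records = []
    for rec in result.records:
        members = partition.groups.get(rec.node)
        if members is None:
            records.append(rec)
            continue
        if not members:
            warnings.warn(f"clique {rec.node!r} has no member; dropped",
                          stacklevel=2)
            continue
        best = min(members,
                   key=lambda m: (reference_rank.get(m, math.inf), m))
        records.append(CandidateRecord(
            node=best, sp=rec.sp, rank_sp=rec.rank_sp, rw=rec.rw,
            rank_rw=rec.rank_rw, cs=rec.cs, final_rank=0,
            reachable_dp_count=rec.reachable_dp_count,
            in_clique=True, clique_members_dropped=len(members) - 1,
        ))
    renumbered = [
        CandidateRecord(**{**rec.__dict__, "final_rank": i})
        for i, rec in enumerate(records, start=1)
    ]
    metadata = dict(result.metadata)
    metadata["clique_expansion"] = "representative by companion uncollapsed run"
    return PrioritizationResult(records=renumbered, metadata=metadata)


# ---------------------------------------------------------------------------
# ranked-list serialization
# ---------------------------------------------------------------------------

RANKED_COLUMNS = ["rank", "node", "gene_symbol", "sp", "rank_sp", "rw",
                  "rank_rw", "cs", "in_clique", "clique_members_dropped"]


def write_ranking(result: PrioritizationResult, path,
                  symbols: dict | None = None) -> None:
    """Write the ranked candidate table as TSV (byte-stable ordering)."""
    symbols = symbols or {}
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(RANKED_COLUMNS) + "\n")
        for rec in result.records:
            handle.write("\t".join([
                str(rec.final_rank), rec.node,
                symbols.get(rec.node, rec.node),
                f"{rec.sp:.12g}", str(rec.rank_sp),
                f"{rec.rw:.12g}", str(rec.rank_rw), str(rec.cs),
                str(int(rec.in_clique)), str(rec.clique_members_dropped),
            ]) + "\n")


def read_ranking(path) -> list:
    """Ordered candidate identifiers from a ranked TSV."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={"node": str})
    return frame.sort_values("rank")["node"].tolist()


# ---------------------------------------------------------------------------
# direct-neighbour baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectScore:
    node: str
    direct: int
    rank: int


def direct_scores(net: PPINetwork, dps: DPSet) -> list:
    """Guilt-by-association baseline: count seed out-neighbours.

    Each candidate is scored by how many DPs sit among its direct
    out-neighbours and ranked descending (competition ranks, lexicographic
    order inside ties).
    """
    seeds = _seeds_in(net, dps)
    nodes = sorted(net.nodes - seeds)
    counts = [
        sum(1 for v in net.graph.successors(n) if v in seeds) for n in nodes
    ]
    ranks = _competition_ranks([(-c,) for c in counts])
    order = sorted(range(len(nodes)), key=lambda i: (ranks[i], nodes[i]))
    return [
        DirectScore(node=nodes[i], direct=counts[i], rank=ranks[i])
        for i in order
    ]


# ---------------------------------------------------------------------------
# full prioritization of a built variant
# ---------------------------------------------------------------------------

def prioritize(build: VariantBuild, dps: DPSet,
               r: float = DEFAULT_RESTART,
               tol: float = DEFAULT_TOL,
               max_iter: int = DEFAULT_MAX_ITER,
               unreachable: str = "count-first",
               dangling: str = "none") -> PrioritizationResult:
    """Run SP + RW + rank combination on a built network variant.

    Collapsed variants additionally run the same prioritization on the
    uncollapsed base network and expand each clique super-node to its
    best-ranked member protein.
    """

    def run(net: PPINetwork) -> PrioritizationResult:
        sp_list = shortest_path_scores(net, dps, unreachable=unreachable)
        rw_all = random_walk_scores(net, dps, r=r, tol=tol,
                                    max_iter=max_iter, dangling=dangling)
        seeds = dps.members & net.nodes
        rw_candidates = [s for s in rw_all if s.node not in seeds]
        return combine_ranks(sp_list, rw_candidates, unreachable=unreachable)

    metadata = {
        "variant": build.variant,
        "restart_probability": r,
        "tolerance": tol,
        "max_iterations": max_iter,
        "unreachable_policy": unreachable,
        "dangling_policy": dangling,
        "n_seeds_in_network": len(dps.members & build.network.nodes),
    }
    result = run(build.network)
    if build.partition is not None:
        base_result = run(build.base_network)
        result = expand_cliques(result, build.partition, base_result)
    result.metadata.update(metadata)
    return result
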