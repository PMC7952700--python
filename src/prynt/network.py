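"""Construction of the four contextualized PPI network variants.

The raw network keeps only directional interactions at or above the
confidence threshold, oriented from the acting protein to the acted-on
protein, with duplicates and self-interactions removed. Two
contextualizations can then be applied for a given proteomic dataset:

* ``+DP`` — every directional interaction incident to a deregulated
  protein (DP) is injected back regardless of its confidence score, so the
  seeds are maximally represented;
* ``+C`` — maximal cliques of the undirected projection are consolidated:
  overlapping cliques are resolved into disjoint groups greedily by
  decreasing size, and each group is collapsed into a single super-node.

``build_variant`` composes these into the ``raw``, ``dp``, ``c`` and
``dp_c`` variants. Seeds are never absorbed into clique super-nodes: they
must stay addressable as distinct nodes for shortest-path targets and for
the random-walk restart distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import ConsistencyError, EmptyNetworkError
from .string_io import DPSet, RawInteraction

DEFAULT_MIN_SCORE = 900   # STRING "highest confidence" cutoff, 0-999 scale
DEFAULT_MIN_CLIQUE_SIZE = 3

VARIANTS = ("raw", "dp", "c", "dp_c")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PPINetwork:
    """A directed protein-interaction graph with per-edge confidence.

    Edge attributes: ``score`` (int, 0-999) and ``contextual`` (True for
    edges injected by DP contextualization). The graph never holds
    self-loops or duplicate ordered pairs.
    """

    graph: nx.DiGraph
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    def edge_set(self) -> frozenset:
        return frozenset(self.graph.edges)

    def undirected_projection(self) -> nx.Graph:
        return self.graph.to_undirected(as_view=False)

    def validate(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ConsistencyError(f"self-loop edges present: {loops[:3]}")

    def copy(self) -> "PPINetwork":
        return PPINetwork(graph=self.graph.copy(), meta=dict(self.meta))


@dataclass(frozen=True)
class CliquePartition:
    """Disjoint assignment of proteins to named clique groups."""

    groups: dict  # group id -> frozenset of member proteins
    policy: str = "greedy-size-desc"

    @property
    def n_grouped(self) -> int:
        return sum(len(m) for m in self.groups.values())

    def member_index(self) -> dict:
        index = {}
        for gid, members in self.groups.items():
            for m in members:
                if m in index:
                    raise ConsistencyError(
                        f"protein {m!r} claimed by {index[m]!r} and {gid!r}"
                    )
                index[m] = gid
        return index


@dataclass
class CollapsedNetwork(PPINetwork):
    """A PPINetwork whose nodes are proteins or clique super-nodes."""

    back_map: dict = field(default_factory=dict)  # clique node -> members

    def expand_node(self, node) -> frozenset:
        return self.back_map.get(node, frozenset([node]))


@dataclass
class VariantBuild:
    """A contextualized network plus everything needed downstream.

    ``network`` is the graph the prioritization runs on. For collapsed
    variants, ``base_network`` is the uncollapsed graph (used to pick each
    clique's representative protein) and ``partition`` the clique
    assignment; otherwise both base and network coincide.
    """

    variant: str
    network: PPINetwork
    base_network: PPINetwork
    partition: CliquePartition | None = None


# ---------------------------------------------------------------------------
# raw filtering
# ---------------------------------------------------------------------------

def _orient(record: RawInteraction) -> tuple:
    """Edge direction: acting protein -> acted-on protein.

    ``a_is_acting`` False flips the stated pair; a missing annotation keeps
    the stated a -> b orientation.
    """
    if record.a_is_acting is False:
        return record.target_id, record.source_id
    return record.source_id, record.target_id


def build_raw_network(interactions: Sequence[RawInteraction],
                      min_score: int = DEFAULT_MIN_SCORE,
                      directional_only: bool = True,
                      strict_greater: bool = False) -> PPINetwork:
    """Filter interactions into the raw directed network.

    Keeps directional records whose confidence meets ``min_score``
    (``>=`` by default, ``>`` when ``strict_greater``), oriented from the
    acting protein; self-interactions are dropped and duplicate ordered
    pairs merged (max score wins). The node set is exactly the endpoints of
    the surviving edges.
    """
    graph = nx.DiGraph()
    for record in interactions:
        if directional_only and not record.is_directional:
            continue
        keep = record.score > min_score if strict_greater \
            else record.score >= min_score
        if not keep:
            continue
        u, v = _orient(record)
        if u == v:
            continue
        _add_edge(graph, u, v, record.score, contextual=False)
    if graph.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"no directional interaction survives min_score={min_score}"
        )
    return PPINetwork(graph=graph)


def _add_edge(graph: nx.DiGraph, u, v, score: int, contextual: bool) -> None:
    if graph.has_edge(u, v):
        data = graph.edges[u, v]
        data["score"] = max(data["score"], score)
    else:
        graph.add_edge(u, v, score=score, contextual=contextual)


# ---------------------------------------------------------------------------
# +DP contextualization
# ---------------------------------------------------------------------------

def add_deregulated_proteins(net: PPINetwork,
                             all_interactions: Sequence[RawInteraction],
                             dps: DPSet) -> PPINetwork:
    """Inject every directional DP-incident interaction, score regardless.

    Newly added edges are flagged ``contextual``; edges already present are
    untouched, which makes the operation idempotent. DPs appearing in no
    directional interaction at all stay absent and are listed in
    ``meta["missing_dps"]``.
    """
    out = net.copy()
    members = dps.members
    for record in all_interactions:
        if not record.is_directional:
            continue
        if record.source_id not in members and record.target_id not in members:
            continue
        u, v = _orient(record)
        if u == v:
            continue
        _add_edge(out.graph, u, v, record.score, contextual=True)
    missing = sorted(members - set(out.graph.nodes))
    out.meta["missing_dps"] = tuple(missing)
    return out


# ---------------------------------------------------------------------------
# clique detection, disjoint assignment, collapse
# ---------------------------------------------------------------------------

def find_cliques(net: PPINetwork,
                 min_clique_size: int = DEFAULT_MIN_CLIQUE_SIZE,
                 exclude: frozenset = frozenset()) -> list:
    """Maximal cliques of the undirected projection, smallest size bounded.

    Edge direction is ignored inside cliques. Nodes in ``exclude`` (the
    seeds, when clique consolidation follows DP injection) are removed
    before enumeration. The result is deterministically ordered by
    decreasing size, then lexicographically smallest member.
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError("cannot enumerate cliques of an empty network")
    projection = net.undirected_projection()
    projection.remove_nodes_from([n for n in exclude if n in projection])
    cliques = [
        frozenset(c) for c in nx.find_cliques(projection)
        if len(c) >= min_clique_size
    ]
    cliques.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return cliques


def assign_disjoint_cliques(cliques: Iterable[frozenset],
                            min_clique_size: int = DEFAULT_MIN_CLIQUE_SIZE
                            ) -> CliquePartition:
    """Resolve overlapping maximal cliques into disjoint groups.

    Greedy selection in order of decreasing size (ties broken by the
    lexicographically smallest member): each clique is stripped of proteins
    already claimed by an earlier group and kept only if at least
    ``min_clique_size`` members remain. Subsets of cliques are cliques, so
    every surviving group is still fully connected.
    """
    ordered = sorted(cliques, key=lambda c: (-len(c), tuple(sorted(c))))
    claimed: set = set()
    groups: dict = {}
    for clique in ordered:
        remaining = frozenset(clique) - claimed
        if len(remaining) >= min_clique_size:
            gid = f"CLQ{len(groups):04d}"
            groups[gid] = frozenset(remaining)
            claimed |= remaining
    return CliquePartition(groups=groups)


def collapse_cliques(net: PPINetwork,
                     partition: CliquePartition) -> CollapsedNetwork:
    """Replace each clique group by a single super-node.

    A collapsed edge ``(u, G)`` exists iff some member of ``G`` receives an
    edge from ``u`` in the source network (symmetrically for outgoing and
    group-group edges); intra-group edges vanish and merged duplicates keep
    the maximum witness score. The back-map records each super-node's
    members.
    """
    index = partition.member_index()
    missing = [m for m in index if m not in net.graph]
    if missing:
        raise ConsistencyError(
            f"partition members absent from network: {sorted(missing)[:5]}"
        )
    graph = nx.DiGraph()
    graph.add_nodes_from(
        index.get(n, n) for n in net.graph.nodes
    )
    for u, v, data in net.graph.edges(data=True):
        cu, cv = index.get(u, u), index.get(v, v)
        if cu == cv:
            continue  # intra-group (or duplicate-collapsed) edge
        if graph.has_edge(cu, cv):
            edge = graph.edges[cu, cv]
            edge["score"] = max(edge["score"], data["score"])
            edge["contextual"] = edge["contextual"] or data.get("contextual", False)
        else:
            graph.add_edge(cu, cv, score=data["score"],
                           contextual=data.get("contextual", False))
    back_map = {gid: members for gid, members in partition.groups.items()}
    collapsed = CollapsedNetwork(graph=graph, meta=dict(net.meta),
                                 back_map=back_map)
    expected = net.n_nodes - partition.n_grouped + len(partition.groups)
    if collapsed.n_nodes != expected:
        raise ConsistencyError(
            f"collapsed node count {collapsed.n_nodes} != expected {expected}"
        )
    return collapsed


# ---------------------------------------------------------------------------
# variant composition
# ---------------------------------------------------------------------------

def build_variant(variant: str,
                  interactions: Sequence[RawInteraction],
                  dps: DPSet | None = None,
                  min_score: int = DEFAULT_MIN_SCORE,
                  min_clique_size: int = DEFAULT_MIN_CLIQUE_SIZE,
                  directional_only: bool = True,
                  strict_greater: bool = False,
                  cliques_after_dp: bool = True) -> VariantBuild:
    """Build one of the four network variants: raw, dp, c, dp_c.

    For collapsed variants the seeds are excluded from clique membership so
    they remain addressable, and ``base_network`` keeps the uncollapsed
    graph for later selection of clique representatives. In ``dp_c``,
    cliques are by default detected after DP injection (injected edges can
    create cliques); ``cliques_after_dp=False`` detects them on the raw
    network instead.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if variant in ("dp", "dp_c") and dps is None:
        raise ValueError(f"variant {variant!r} requires a DP set")

    raw = build_raw_network(interactions, min_score=min_score,
                            directional_only=directional_only,
                            strict_greater=strict_greater)
    if variant == "raw":
        return VariantBuild("raw", raw, raw)

    seeds = frozenset(dps.members) if dps is not None else frozenset()
    if variant == "dp":
        net = add_deregulated_proteins(raw, interactions, dps)
        return VariantBuild("dp", net, net)

    if variant == "c":
        base = raw
    else:  # dp_c
        base = add_deregulated_proteins(raw, interactions, dps)

    clique_source = base if (variant == "c" or cliques_after_dp) else raw
    cliques = find_cliques(clique_source, min_clique_size=min_clique_size,
                           exclude=seeds)
    partition = assign_disjoint_cliques(cliques,
                                        min_clique_size=min_clique_size)
    if variant == "dp_c" and not cliques_after_dp:
        # cliques found on raw may reference nodes absent from +DP? no:
        # +DP only adds nodes/edges, so raw nodes all survive.
        pass
    collapsed = collapse_cliques(base, partition)
    return VariantBuild(variant, collapsed, base, partition)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_network(net: PPINetwork, path) -> None:
    rows = sorted(
        (u, v, d["score"], int(d.get("contextual", False)))
        for u, v, d in net.graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["source", "target", "score", "contextual"]) \
        .to_csv(path, sep="\t", index=False)


def read_network(path) -> PPINetwork:
    frame = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    graph = nx.DiGraph()
    for row in frame.itertuples(index=False):
        graph.add_edge(row.source, row.target, score=int(row.score),
                       contextual=bool(row.contextual))
    return PPINetwork(graph=graph)


def write_partition(partition: CliquePartition, path) -> None:
    rows = [
        (gid, member)
        for gid in sorted(partition.groups)
        for member in sorted(partition.groups[gid])
    ]
    pd.DataFrame(rows, columns=["group_id", "member"]) \
        .to_csv(path, sep="\t", index=False)


def read_partition(path) -> CliquePartition:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    groups: dict = {}
    for row in frame.itertuples(index=False):
        groups.setdefault(row.group_id, set()).add(row.member)
    return CliquePartition(
        groups={gid: frozenset(m) for gid, m in groups.items()}
    )
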