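"""Synthetic interaction networks and studies with planted structure.

The generator emulates the three external inputs of the tool — a directed,
confidence-scored interaction table, a deregulated-protein (DP) seed list
and a scored reference-candidate list — at a scale where brute-force
oracles (per-pair BFS, dense linear solves, exhaustive clique enumeration)
stay fast. Planted features with recorded ground truth:

* fully connected cliques (bidirectional high-confidence edges), disjoint
  by construction, optionally wired close to the seeds so that clique
  consolidation measurably de-clutters the top of the ranking;
* a controlled fraction of reference candidates placed one or two directed
  hops from the seeds, with reciprocal seed-to-candidate edges feeding the
  random walk; a tunable share of this seed-incident wiring is scored
  below the confidence threshold, which is exactly the signal the ``+DP``
  contextualization recovers;
* the remaining reference candidates drawn uniformly, so a zero-overlap
  study is an exact null against chance-level precision.

Everything is driven by one seeded generator; identical specs give
identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import SyntheticSpecError
from .network import PPINetwork, build_raw_network
from .string_io import DPSet, RawInteraction, ReferenceCandidates


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Scores are on the internal 0-999 scale; ``background_score_range``
    sits above the default confidence threshold of 900 while
    ``low_score_range`` sits below it.
    """

    n_background_nodes: int = 120
    edge_probability: float = 0.04
    n_planted_cliques: int = 4
    clique_size_range: tuple = (5, 9)
    n_dps: int = 15
    n_reference: int = 25
    planted_overlap_fraction: float = 0.8
    rng_seed: int = 0
    low_confidence_fraction: float = 0.5
    background_score_range: tuple = (900, 999)
    low_score_range: tuple = (150, 899)
    nondirectional_fraction: float = 0.1
    wire_cliques_to_dps: bool = True

    def __post_init__(self) -> None:
        counts = (self.n_background_nodes, self.n_planted_cliques,
                  self.n_dps, self.n_reference)
        if any(c < 0 for c in counts):
            raise SyntheticSpecError(f"negative count in {counts}")
        fractions = (self.edge_probability, self.planted_overlap_fraction,
                     self.low_confidence_fraction,
                     self.nondirectional_fraction)
        if any(not 0 <= f <= 1 for f in fractions):
            raise SyntheticSpecError(f"fraction outside [0, 1] in {fractions}")
        lo, hi = self.clique_size_range
        if lo < 3 or hi < lo:
            raise SyntheticSpecError(
                f"clique sizes must satisfy 3 <= lo <= hi, got {lo, hi}"
            )
        budget = self.n_dps + self.n_planted_cliques * hi + self.n_reference
        if budget > self.n_background_nodes:
            raise SyntheticSpecError(
                f"{self.n_background_nodes} nodes cannot host {self.n_dps} "
                f"seeds + {self.n_planted_cliques} cliques of up to {hi} + "
                f"{self.n_reference} reference candidates"
            )


@dataclass
class SyntheticStudy:
    """One generated dataset: inputs, filtered network and ground truth."""

    interactions: list
    network: PPINetwork           # raw-filtered at the default threshold
    dps: DPSet
    reference: ReferenceCandidates
    ground_truth: dict = field(default_factory=dict)


def _node_names(n: int) -> list:
    return [f"P{i:04d}" for i in range(n)]


class _EdgePool:
    """Deduplicated directed edge accumulator (max score wins)."""

    def __init__(self) -> None:
        self.directed: dict = {}
        self.nondirected: dict = {}

    def add(self, u: str, v: str, score: int, directional: bool = True) -> None:
        if u == v:
            return
        pool = self.directed if directional else self.nondirected
        pool[(u, v)] = max(pool.get((u, v), 0), int(score))

    def to_interactions(self) -> list:
        records = [
            RawInteraction(source_id=u, target_id=v, is_directional=True,
                           a_is_acting=True, score=s, mode="activation")
            for (u, v), s in sorted(self.directed.items())
        ]
        records += [
            RawInteraction(source_id=u, target_id=v, is_directional=False,
                           a_is_acting=None, score=s, mode="binding")
            for (u, v), s in sorted(self.nondirected.items())
        ]
        return records


def _score(rng: np.random.Generator, lo_hi: tuple) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def _background(pool: _EdgePool, nodes: list, spec: SyntheticSpec,
                rng: np.random.Generator) -> None:
    n = len(nodes)
    mask = rng.random((n, n)) < spec.edge_probability
    np.fill_diagonal(mask, False)
    for i, j in zip(*np.nonzero(mask)):
        directional = rng.random() >= spec.nondirectional_fraction
        pool.add(nodes[i], nodes[j],
                 _score(rng, spec.background_score_range), directional)


def _plant_cliques(pool: _EdgePool, candidates: list, spec: SyntheticSpec,
                   rng: np.random.Generator) -> list:
    lo, hi = spec.clique_size_range
    cliques = []
    available = list(candidates)
    for _ in range(spec.n_planted_cliques):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(
            rng.choice(available, size=size, replace=False).tolist()
        )
        available = [n for n in available if n not in set(members)]
        for a in members:
            for b in members:
                if a != b:
                    pool.add(a, b, _score(rng, spec.background_score_range))
        cliques.append(frozenset(members))
    return cliques


def generate_network(spec: SyntheticSpec) -> tuple:
    """Directed random background plus planted cliques, with ground truth.

    Returns the full network (no confidence filtering; every directional
    edge included) and a ground-truth record listing the planted clique
    membership.
    """
    rng = np.random.default_rng(spec.rng_seed)
    nodes = _node_names(spec.n_background_nodes)
    pool = _EdgePool()
    _background(pool, nodes, spec, rng)
    cliques = _plant_cliques(pool, nodes, spec, rng)

    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    for (u, v), score in sorted(pool.directed.items()):
        graph.add_edge(u, v, score=score, contextual=False)
    ground_truth = {
        "planted_cliques": cliques,
        "rng_seed": spec.rng_seed,
        "n_directed_edges": len(pool.directed),
    }
    return PPINetwork(graph=graph), ground_truth


def _wire_reference(pool: _EdgePool, ref: str, dp_list: list,
                    transit: list, spec: SyntheticSpec,
                    rng: np.random.Generator) -> dict:
    """Place one planted reference candidate 1-2 hops from the seeds.

    The candidate gets a forward path into a seed (shortest-path signal)
    and a reciprocal seed edge (random-walk signal). Seed-incident edges
    drop below the confidence threshold with probability
    ``low_confidence_fraction``.
    """
    def seed_incident_score() -> int:
        if rng.random() < spec.low_confidence_fraction:
            return _score(rng, spec.low_score_range)
        return _score(rng, spec.background_score_range)

    dp = dp_list[int(rng.integers(len(dp_list)))]
    two_hop = bool(rng.random() < 0.5) and transit
    wiring = {"reference": ref, "dp": dp, "hops": 2 if two_hop else 1}
    if two_hop:
        mid = transit[int(rng.integers(len(transit)))]
        pool.add(ref, mid, _score(rng, spec.background_score_range))
        pool.add(mid, dp, seed_incident_score())
        wiring["via"] = mid
    else:
        pool.add(ref, dp, seed_incident_score())
    pool.add(dp, ref, seed_incident_score())
    return wiring


def generate_study(spec: SyntheticSpec) -> SyntheticStudy:
    """Full synthetic study: interactions, seeds, reference, ground truth.

    ``planted_overlap_fraction`` of the reference candidates are wired
    close to the seeds (see :func:`_wire_reference`); the rest are drawn
    uniformly from the non-seed, non-clique background so that at fraction
    zero the reference is independent of the topology.
    """
    rng = np.random.default_rng(spec.rng_seed)
    nodes = _node_names(spec.n_background_nodes)
    pool = _EdgePool()
    _background(pool, nodes, spec, rng)

    dp_list = sorted(rng.choice(nodes, size=spec.n_dps, replace=False).tolist())
    dp_set = set(dp_list)
    non_dp = [n for n in nodes if n not in dp_set]

    cliques = _plant_cliques(pool, non_dp, spec, rng)
    clique_members = set().union(*cliques) if cliques else set()
    if spec.wire_cliques_to_dps and dp_list:
        for clique in cliques:
            anchors = rng.choice(dp_list, size=min(2, len(dp_list)),
                                 replace=False).tolist()
            for member in sorted(clique):
                pool.add(member, anchors[0],
                         _score(rng, spec.background_score_range))
                pool.add(anchors[-1], member,
                         _score(rng, spec.background_score_range))

    free = [n for n in non_dp if n not in clique_members]
    n_planted = int(round(spec.planted_overlap_fraction * spec.n_reference))
    n_planted = min(n_planted, spec.n_reference)
    planted = sorted(
        rng.choice(free, size=n_planted, replace=False).tolist()
    ) if n_planted else []
    remaining_pool = [n for n in non_dp if n not in set(planted)]
    n_uniform = spec.n_reference - n_planted
    uniform = sorted(
        rng.choice(remaining_pool, size=n_uniform, replace=False).tolist()
    ) if n_uniform else []

    wirings = []
    if dp_list:
        transit = [n for n in non_dp if n not in set(planted)]
        for ref in planted:
            wirings.append(
                _wire_reference(pool, ref, dp_list, transit, spec, rng)
            )

    reference_ids = planted + uniform
    inference = np.sort(rng.uniform(1.0, 100.0, len(reference_ids)))[::-1]
    shuffled = list(reference_ids)
    rng.shuffle(shuffled)
    entries = tuple(zip(shuffled, (float(s) for s in inference)))

    interactions = pool.to_interactions()
    network = build_raw_network(interactions)  # propagates empty-network error

    pvalues = {
        dp: float(p) for dp, p in
        zip(dp_list, rng.uniform(1e-5, 0.05, len(dp_list)))
    }
    dps = DPSet(
        dataset_name=f"synthetic-{spec.rng_seed}",
        members=frozenset(dp_list),
        pvalues=pvalues,
    )
    reference = ReferenceCandidates(
        disease_name=f"synthetic-disease-{spec.rng_seed}",
        entries=entries,
    )
    ground_truth = {
        "planted_cliques": cliques,
        "dps": tuple(dp_list),
        "planted_reference": tuple(planted),
        "uniform_reference": tuple(uniform),
        "wirings": wirings,
        "rng_seed": spec.rng_seed,
    }
    return SyntheticStudy(
        interactions=interactions,
        network=network,
        dps=dps,
        reference=reference,
        ground_truth=ground_truth,
    )
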