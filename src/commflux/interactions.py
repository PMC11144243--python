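"""Cross-feeding inference from community solutions.

A member's exchange profile is the set of member↔pool link fluxes above the
reporting threshold ε (positive = secreted into the shared pool, negative =
consumed from it).  A directed cross-feeding edge producer→metabolite→consumer
is emitted whenever, in the same optimal solution, one member secretes and
another consumes the same shared metabolite; when several producers and
consumers coexist the transferred rate is apportioned proportionally to each
party's flux magnitude (flux balance alone cannot identify pairings, so a
declared convention beats an implicit one).

Because LP optima are degenerate, each edge can be tagged by flux variability
at a fixed objective fraction γ: ``stable`` if both the producer's secretion
and the consumer's uptake keep their sign over the whole FVA interval,
``variable`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import lp as _lp
from .community import CommunityModel, CommunitySolution
from .media import Medium

MEDIUM_NODE = "medium"

STABLE = "stable"
VARIABLE = "variable"


@dataclass
class ExchangeFlux:
    strain: str
    metabolite: str
    rate: float  # positive = secreted to pool, negative = consumed


@dataclass
class Edge:
    producer: str
    metabolite: str
    consumer: str
    rate: float
    robustness: Optional[str] = None


@dataclass
class InteractionGraph:
    nodes: List[str]
    edges: List[Edge] = field(default_factory=list)
    #: medium→consumer supply edges (pool imports), kept separate from
    #: interspecies transfers
    medium_edges: List[Edge] = field(default_factory=list)

    def edge_set(self) -> set:
        return {(e.producer, e.metabolite, e.consumer) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"producer": e.producer, "metabolite": e.metabolite,
             "consumer": e.consumer, "rate": e.rate,
             "robustness": e.robustness or ""}
            for e in self.edges + self.medium_edges
        ]
        return pd.DataFrame(
            rows, columns=["producer", "metabolite", "consumer", "rate", "robustness"]
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges + self.medium_edges:
            g.add_edge(e.producer, e.consumer, metabolite=e.metabolite,
                       rate=e.rate, robustness=e.robustness or "")
        return g


class SolutionContractError(RuntimeError):
    """The operation requires an optimal community solution."""


def member_exchange_profile(
    solution: CommunitySolution, epsilon: float = _lp.DEFAULT_TOLERANCES.zero_flux
) -> List[ExchangeFlux]:
    if not solution.optimal:
        raise SolutionContractError(
            f"exchange profile requires an optimal solution, got {solution.status}"
        )
    profile = [
        ExchangeFlux(sid, met, rate)
        for sid, per_met in sorted(solution.member_exchanges.items())
        for met, rate in sorted(per_met.items())
        if abs(rate) > epsilon
    ]
    return profile


def infer_cross_feeding(
    solution: CommunitySolution, epsilon: float = _lp.DEFAULT_TOLERANCES.zero_flux
) -> InteractionGraph:
    """Directed producer→metabolite→consumer transfers in one solution."""
    if not solution.optimal:
        raise SolutionContractError(
            f"cross-feeding inference requires an optimal solution, got {solution.status}"
        )
    members = sorted(solution.member_exchanges)
    by_met: Dict[str, Dict[str, float]] = {}
    for sid in members:
        for met, rate in solution.member_exchanges[sid].items():
            if abs(rate) > epsilon:
                by_met.setdefault(met, {})[sid] = rate

    edges: List[Edge] = []
    medium_edges: List[Edge] = []
    for met in sorted(by_met):
        rates = by_met[met]
        producers = {s: v for s, v in rates.items() if v > 0}
        consumers = {s: -v for s, v in rates.items() if v < 0}
        total_sec = sum(producers.values())
        total_con = sum(consumers.values())
        if producers and consumers:
            transferred = min(total_sec, total_con)
            for p, sp in sorted(producers.items()):
                for c, uc in sorted(consumers.items()):
                    rate = transferred * (sp / total_sec) * (uc / total_con)
                    if rate > epsilon:
                        edges.append(Edge(p, met, c, rate))
        imported = solution.pool_import.get(met, 0.0)
        if imported > epsilon and consumers:
            supplied = min(imported, total_con)
            for c, uc in sorted(consumers.items()):
                rate = supplied * (uc / total_con)
                if rate > epsilon:
                    medium_edges.append(Edge(MEDIUM_NODE, met, c, rate))
    return InteractionGraph(nodes=members + [MEDIUM_NODE], edges=edges,
                            medium_edges=medium_edges)


def classify_edge_robustness(
    cm: CommunityModel,
    medium: Medium,
    graph: InteractionGraph,
    gamma: float = 1.0,
    objective_id: Optional[str] = None,
    epsilon: float = _lp.DEFAULT_TOLERANCES.zero_flux,
    tolerances: _lp.Tolerances = _lp.DEFAULT_TOLERANCES,
) -> InteractionGraph:
    """Tag every interspecies edge ``stable`` or ``variable`` by FVA.

    An edge is stable only if at objective fraction ``gamma`` the producer's
    link flux stays strictly positive and the consumer's strictly negative
    over their whole variability intervals.
    """
    link_ids = set()
    for e in graph.edges:
        link_ids.add(cm.links[(e.producer, e.metabolite)])
        link_ids.add(cm.links[(e.consumer, e.metabolite)])
    if not link_ids:
        return InteractionGraph(nodes=list(graph.nodes), edges=[],
                                medium_edges=list(graph.medium_edges))
    intervals = {
        iv.reaction_id: iv
        for iv in _lp.fva(cm, medium, gamma=gamma, reaction_ids=sorted(link_ids),
                          objective_id=objective_id, tolerances=tolerances)
    }
    tagged = []
    for e in graph.edges:
        prod = intervals[cm.links[(e.producer, e.metabolite)]]
        cons = intervals[cm.links[(e.consumer, e.metabolite)]]
        stable = prod.min_flux > epsilon and cons.max_flux < -epsilon
        tagged.append(replace(e, robustness=STABLE if stable else VARIABLE))
    return InteractionGraph(nodes=list(graph.nodes), edges=tagged,
                            medium_edges=list(graph.medium_edges))


def write_edges_tsv(graph: InteractionGraph, path) -> None:
    graph.to_frame().to_csv(path, sep="\t", index=False)


def write_graphml(graph: InteractionGraph, path) -> None:
    import networkx as nx

    nx.write_graphml(graph.to_networkx(), str(path))
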