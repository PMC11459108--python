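"""Directly-follows process graphs and complexity metrics.

The miner builds the directly-follows graph (DFG) of a cohort: nodes are
unit activities plus artificial START/END, arcs count immediate successions
across traces.  The complexity metrics quantify how tangled the graph is:

* density — arcs over all possible arcs, |E| / (|V|·(|V|−1));
* extended cyclomatic metric (ECyM) — |E| − |V| + number of strongly
  connected components;
* extended Cardoso metric (ECaM) — here the sum of out-degrees over split
  nodes (out-degree > 1).  The original Cardoso metric penalizes XOR/OR/AND
  split constructs of a Petri net; a DFG has no gateway semantics, so this
  simplification counts every split at its fan-out and is **not comparable
  in absolute value** to Petri-net ECaM figures.

These DFG-based numbers serve before/after comparisons on the same cohort;
they are not substitutes for metrics computed on a mined Petri net.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .model import EventLog

START_NODE = "__START__"
END_NODE = "__END__"


@dataclass
class ProcessGraph:
    graph: nx.DiGraph
    variant_count: int
    activity_count: int

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def arcs(self) -> dict[tuple[str, str], int]:
        return {(u, v): d["count"] for u, v, d in self.graph.edges(data=True)}


def cohort_filter(log: EventLog, unit: str, registry=None) -> EventLog:
    """Restrict the log to the traces containing at least one stage in
    ``unit``."""
    if registry is not None and unit not in registry:
        raise KeyError(f"unit {unit!r} not in registry")
    return EventLog([p for p in log if unit in p.trace.activities])


def mine_dfg(log: EventLog, noise_threshold: float = 0.0) -> ProcessGraph:
    """Mine the directly-follows graph of a log.

    Arcs whose traversal count falls below ``noise_threshold`` times the most
    traversed arc are pruned (0 keeps everything); isolated nodes left by
    pruning are removed.  Deterministic.
    """
    if not 0 <= noise_threshold < 1:
        raise ValueError("noise_threshold must be in [0, 1)")
    counts: dict[tuple[str, str], int] = {}
    variants: set[tuple[str, ...]] = set()
    activities: set[str] = set()
    for pathway in log:
        acts = pathway.trace.activities
        if not acts:
            continue
        variants.add(acts)
        activities.update(acts)
        walk = (START_NODE,) + acts + (END_NODE,)
        for a, b in zip(walk, walk[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    if counts and noise_threshold > 0:
        top = max(counts.values())
        counts = {arc: c for arc, c in counts.items() if c / top >= noise_threshold}
    g = nx.DiGraph()
    for (a, b), c in counts.items():
        g.add_edge(a, b, count=c)
    return ProcessGraph(
        graph=g, variant_count=len(variants), activity_count=len(activities)
    )


def _as_digraph(graph) -> nx.DiGraph:
    return graph.graph if isinstance(graph, ProcessGraph) else graph


def density(graph) -> float:
    """|E| / (|V|·(|V|−1)); needs at least two nodes."""
    g = _as_digraph(graph)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return g.number_of_edges() / (n * (n - 1))


def ecym(graph) -> int:
    """Extended cyclomatic metric: |E| − |V| + #strongly-connected
    components."""
    g = _as_digraph(graph)
    return (
        g.number_of_edges()
        - g.number_of_nodes()
        + nx.number_strongly_connected_components(g)
    )


def ecam(graph) -> int:
    """Split-penalty metric: sum of out-degrees over nodes with out-degree
    above one; 0 for a linear chain."""
    g = _as_digraph(graph)
    return sum(d for _, d in g.out_degree() if d > 1)


def graph_metrics(pg: ProcessGraph) -> dict:
    g = pg.graph
    return {
        "variants": pg.variant_count,
        "activities": pg.activity_count,
        "nodes": g.number_of_nodes(),
        "arcs": g.number_of_edges(),
        "density": density(g) if g.number_of_nodes() >= 2 else float("nan"),
        "ecam": ecam(g),
        "ecym": ecym(g),
    }


def compare_graphs(
    historical: EventLog,
    corrected: EventLog,
    unit: str,
    noise_threshold: float = 0.0,
    registry=None,
) -> pd.DataFrame:
    """Side-by-side DFG metrics for one unit's cohort in the historical and
    corrected logs, with deltas (corrected − historical)."""
    rows = {}
    for name, log in (("historical", historical), ("corrected", corrected)):
        cohort = cohort_filter(log, unit, registry)
        if not len(cohort):
            rows[name] = {k: float("nan") for k in
                          ("variants", "activities", "nodes", "arcs", "density", "ecam", "ecym")}
            rows[name]["warning"] = "empty cohort"
            continue
        rows[name] = graph_metrics(mine_dfg(cohort, noise_threshold))
    df = pd.DataFrame(rows).T
    delta = df.loc["corrected"].drop(labels=["warning"], errors="ignore") - df.loc[
        "historical"
    ].drop(labels=["warning"], errors="ignore")
    df.loc["delta"] = delta
    return df


def to_dot(pg: ProcessGraph) -> str:
    """DOT serialization (arc labels = traversal counts)."""
    lines = ["digraph dfg {", "  rankdir=LR;"]
    for node in sorted(pg.graph.nodes):
        shape = "circle" if node in (START_NODE, END_NODE) else "box"
        lines.append(f'  "{node}" [shape={shape}];')
    for (a, b), c in sorted(pg.arcs.items()):
        lines.append(f'  "{a}" -> "{b}" [label="{c}"];')
    lines.append("}")
    return "\n".join(lines)
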