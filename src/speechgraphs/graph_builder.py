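"""Construction of structural and semantic speech graphs.

Both graph types are directed, simple (no self-loops, no parallel edges)
and integer-weighted: the first occurrence of a relation weighs 1 and every
repetition increments the weight.

*Structural* graphs chain each content lemma to the next in spoken order,
across utterance boundaries ("The kid is grabbing the cookie jar." gives
kid -> grab -> cookie -> jar).

*Semantic* graphs combine, within each utterance, predication relations
(verb predicate -> each core argument A0/A1/A2) and action relations
(A0 actor -> A1/A2 undergoers), with multiword argument spans kept as
single nodes ("cookie jar").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx

from .corpus_model import DEFAULT_FILLED_PAUSES, Utterance, argument_label

__all__ = ["SpeechGraph", "build_structural", "build_semantic", "export_graph", "import_graph"]

GRAPH_TYPES = ("structural", "semantic")


@dataclass
class SpeechGraph:
    """A directed, integer-weighted simple graph over string-labeled nodes."""

    graph_type: str
    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.graph_type not in GRAPH_TYPES:
            raise ValueError(f"graph_type must be one of {GRAPH_TYPES}, got {self.graph_type!r}")
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop {u!r} not allowed")
            if w < 1:
                raise ValueError(f"edge weight must be >= 1, got {w} on {u!r}->{v!r}")
            self.nodes.add(u)
            self.nodes.add(v)

    @property
    def nn(self) -> int:
        return len(self.nodes)

    @property
    def ne(self) -> int:
        return len(self.edges)

    @property
    def total_weight(self) -> int:
        return sum(self.edges.values())

    def add_relation(self, source: str, target: str) -> None:
        """Record one occurrence of source -> target.  Self-loops are
        silently skipped (their endpoints are still registered as nodes)."""
        self.nodes.add(source)
        self.nodes.add(target)
        if source == target:
            return
        self.edges[(source, target)] = self.edges.get((source, target), 0) + 1

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(graph_type=self.graph_type, **{f"prov_{k}": str(v) for k, v in self.provenance.items()})
        g.add_nodes_from(sorted(self.nodes))
        for (u, v), w in sorted(self.edges.items()):
            g.add_edge(u, v, weight=int(w))
        return g

    def to_igraph(self) -> tuple[ig.Graph, list[str]]:
        """igraph view plus the node-label order used for vertex ids."""
        labels = sorted(self.nodes)
        index = {lab: i for i, lab in enumerate(labels)}
        pairs = sorted(self.edges.items())
        g = ig.Graph(
            n=len(labels),
            edges=[(index[u], index[v]) for (u, v), _ in pairs],
            directed=True,
        )
        g.es["weight"] = [w for _, w in pairs]
        return g, labels

    def __eq__(self, other) -> bool:  # provenance is metadata, not identity
        if not isinstance(other, SpeechGraph):
            return NotImplemented
        return (
            self.graph_type == other.graph_type
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


def build_structural(
    lemma_sequence: Sequence[str],
    provenance: Mapping | None = None,
) -> SpeechGraph:
    """Build a structural graph from an ordered content-lemma sequence.

    Each consecutive pair (w_i, w_{i+1}) adds one unit of weight to the
    directed edge w_i -> w_{i+1}; immediate repetitions of the same lemma
    (self-loops) are skipped.
    """
    g = SpeechGraph(graph_type="structural", provenance=dict(provenance or {}))
    seq = list(lemma_sequence)
    g.nodes.update(seq)
    for a, b in zip(seq, seq[1:]):
        g.add_relation(a, b)
    return g


def build_semantic(
    utterances: Iterable[Utterance],
    provenance: Mapping | None = None,
    *,
    stoplist: frozenset[str] = DEFAULT_FILLED_PAUSES,
) -> SpeechGraph:
    """Build a semantic (action-predication) graph from SRL-annotated
    utterances.

    Per frame: predication edges predicate -> A0, predicate -> A1,
    predicate -> A2 for each present argument, and action edges A0 -> A1
    and A0 -> A2 when both endpoints exist.  Relations never cross
    utterance boundaries; repeated relations anywhere in the scope
    increment the edge weight.
    """
    g = SpeechGraph(graph_type="semantic", provenance=dict(provenance or {}))
    for utt in utterances:
        for frame in utt.frames:
            pred = frame.predicate_lemma
            g.nodes.add(pred)
            labels = {
                arg: argument_label(span, utt, stoplist=stoplist)
                for arg, span in frame.arguments.items()
            }
            for arg in ("A0", "A1", "A2"):
                if arg in labels:
                    g.add_relation(pred, labels[arg])
            if "A0" in labels:
                for undergoer in ("A1", "A2"):
                    if undergoer in labels:
                        g.add_relation(labels["A0"], labels[undergoer])
    return g


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def export_graph(graph: SpeechGraph, path: str | Path, format: str = "graphml") -> None:
    """Write a graph to ``graphml`` (edge attribute ``weight``, graph
    attributes ``graph_type`` / ``provenance``) or ``tsv`` (columns
    source, target, weight; isolated nodes listed with empty target)."""
    path = Path(path)
    if format == "graphml":
        g = graph.to_networkx()
        g.graph["provenance"] = json.dumps(graph.provenance, sort_keys=True)
        nx.write_graphml(g, path)
    elif format == "tsv":
        lines = ["source\ttarget\tweight"]
        linked = {n for edge in graph.edges for n in edge}
        for (u, v), w in sorted(graph.edges.items()):
            lines.append(f"{u}\t{v}\t{w}")
        for n in sorted(graph.nodes - linked):
            lines.append(f"{n}\t\t0")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'graphml' or 'tsv')")


def import_graph(path: str | Path, format: str = "graphml") -> SpeechGraph:
    """Inverse of `export_graph`; round-trips nodes, edges and weights."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        provenance = json.loads(g.graph.get("provenance", "{}"))
        out = SpeechGraph(
            graph_type=g.graph.get("graph_type", "structural"), provenance=provenance
        )
        out.nodes.update(g.nodes())
        for u, v, data in g.edges(data=True):
            out.edges[(u, v)] = int(data["weight"])
        return out
    if format == "tsv":
        out = SpeechGraph(graph_type="structural")
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            u, v, w = line.split("\t")
            out.nodes.add(u)
            if v:
                out.nodes.add(v)
                out.edges[(u, v)] = int(w)
        return out
    raise ValueError(f"unknown format {format!r} (expected 'graphml' or 'tsv')")
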